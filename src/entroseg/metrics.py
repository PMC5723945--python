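"""Region-overlap metrics between binary masks.

Dice similarity coefficient DSC = 2|A∩B|/(|A|+|B|) and Jaccard similarity
JS = |A∩B|/|A∪B|; the two are linked by DSC = 2·JS/(1+JS).  Two empty
masks agree perfectly (1); exactly one empty mask scores 0.
"""

from __future__ import annotations

import numpy as np

__all__ = ["dsc", "js"]


def _pair(s1, s2):
    s1 = np.asarray(s1)
    s2 = np.asarray(s2)
    if s1.shape != s2.shape:
        raise ValueError(f"mask shapes differ: {s1.shape} vs {s2.shape}")
    for s in (s1, s2):
        if s.dtype != bool and not np.isin(s, (0, 1)).all():
            raise ValueError("masks must be binary")
    return s1.astype(bool), s2.astype(bool)


def dsc(s1, s2) -> float:
    """Dice similarity coefficient, in [0, 1]."""
    s1, s2 = _pair(s1, s2)
    total = int(s1.sum()) + int(s2.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((s1 & s2).sum()) / total


def js(s1, s2) -> float:
    """Jaccard similarity (intersection over union), in [0, 1]."""
    s1, s2 = _pair(s1, s2)
    union = int((s1 | s2).sum())
    if union == 0:
        return 1.0
    return int((s1 & s2).sum()) / union
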