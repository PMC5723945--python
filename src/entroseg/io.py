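"""Image readers/writers and run-output plumbing.

Images are single-channel 2-D arrays on a 0–255 intensity convention:
8-bit files load as-is, 16-bit files are rescaled so their dtype maximum
maps to 255, multi-channel images are reduced by the channel average with
a warning.  Whitespace-delimited text matrices round-trip bit-exactly and
are never rescaled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .core import ModelParams, SegmentationResult

__all__ = ["RunConfig", "read_image", "write_image", "write_outputs", "parse_config_file"]

logger = logging.getLogger(__name__)

_TEXT_SUFFIXES = {".txt", ".dat", ".csv", ".tsv"}


@dataclass
class RunConfig:
    input_path: Path | None = None
    output_dir: Path = Path(".")
    params: ModelParams = field(default_factory=ModelParams)
    init: tuple | None = None
    save_bias: bool = True
    save_corrected: bool = True
    save_trace: bool = True
    verbosity: int = 0
    seed: int = 0


def read_image(path) -> np.ndarray:
    """Load a PNG/TIFF/PGM image or a whitespace text matrix as float64."""
    path = Path(path)
    if not path.exists():
        raise OSError(f"no such image file: {path}")
    try:
        if path.suffix.lower() in _TEXT_SUFFIXES:
            arr = np.loadtxt(path, dtype=float, ndmin=2)
        else:
            arr = iio.imread(path)
    except OSError:
        raise
    except Exception as exc:  # imageio/loadtxt raise assorted types
        raise OSError(f"could not read image {path}: {exc}") from exc
    if arr.size == 0:
        raise OSError(f"empty image file: {path}")
    if arr.ndim == 3:
        logger.warning("%s is multi-channel; averaging channels to luminance", path)
        arr = arr.mean(axis=2)
    if arr.ndim != 2:
        raise OSError(f"{path} is not a 2-D image (ndim={arr.ndim})")

    dtype = arr.dtype
    arr = arr.astype(float)
    if path.suffix.lower() in _TEXT_SUFFIXES:
        return arr  # text matrices are taken literally
    if dtype == np.uint16:
        arr *= 255.0 / 65535.0
    elif dtype == np.bool_:
        arr *= 255.0
    elif np.issubdtype(dtype, np.floating) and arr.size and arr.max() <= 1.0:
        arr *= 255.0
    return arr


def write_image(path, arr: np.ndarray) -> None:
    """Write a text matrix (full precision) or an 8-bit image (clipped)."""
    path = Path(path)
    arr = np.asarray(arr)
    if path.suffix.lower() in _TEXT_SUFFIXES:
        np.savetxt(path, arr.astype(float), fmt="%.17e")
    else:
        iio.imwrite(path, np.clip(arr, 0, 255).astype(np.uint8))


def write_outputs(result: SegmentationResult, config: RunConfig) -> dict[str, Path]:
    """Write the run artifacts enabled by the config flags; return and save
    a manifest mapping artifact names to paths.

    Always writes the binary mask (PNG, 0/255) and a key-value echo of the
    run parameters; optionally the bias field (text matrix), the corrected
    image (PNG) and the energy trace (one value per line, initial energy
    included)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}

    mask_path = out / "mask.png"
    iio.imwrite(mask_path, (result.mask.astype(np.uint8) * 255))
    manifest["mask"] = mask_path

    if config.save_bias:
        bias_path = out / "bias.txt"
        np.savetxt(bias_path, result.bias, fmt="%.17e")
        manifest["bias"] = bias_path
    if config.save_corrected:
        corr_path = out / "corrected.png"
        write_image(corr_path, result.corrected)
        manifest["corrected"] = corr_path
    if config.save_trace:
        trace_path = out / "energy_trace.txt"
        np.savetxt(trace_path, result.energy_trace, fmt="%.17e")
        manifest["energy_trace"] = trace_path

    params_path = out / "params.txt"
    lines = [f"{k} = {v}" for k, v in vars(config.params).items()]
    lines += [
        f"input = {config.input_path}",
        f"init = {config.init}",
        f"seed = {config.seed}",
        f"iterations_run = {result.iterations_run}",
        f"converged = {result.converged}",
    ]
    params_path.write_text("\n".join(lines) + "\n")
    manifest["params"] = params_path

    manifest_path = out / "manifest.txt"
    manifest_path.write_text(
        "".join(f"{name}\t{p.name}\n" for name, p in manifest.items())
    )
    manifest["manifest"] = manifest_path
    return manifest


def parse_config_file(path) -> dict[str, str]:
    """Parse a flat ``key = value`` config file (``#`` comments allowed)."""
    entries: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"bad config line (expected key = value): {line!r}")
        key, value = line.split("=", 1)
        entries[key.strip()] = value.strip()
    return entries
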