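"""Independent brute-force implementations used as test oracles.

Everything here is written as per-pixel double loops over explicit window
offsets, deliberately avoiding the convolution-based code paths of the
package, so that agreement between the two is a meaningful check.
"""

from __future__ import annotations

import numpy as np

LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def random_instance(seed: int, n: int = 8) -> dict:
    """A random small fitting state (image, weights, level set, bias...)."""
    rng = np.random.default_rng(seed)
    return dict(
        image=rng.uniform(0.0, 255.0, (n, n)),
        entropy=rng.uniform(0.2, 1.0, (n, n)),
        phi=rng.uniform(-3.0, 3.0, (n, n)),
        bias=rng.uniform(0.5, 1.5, (n, n)),
        c=(float(rng.uniform(20, 220)), float(rng.uniform(20, 220))),
        sigma_sq=(float(rng.uniform(50, 900)), float(rng.uniform(50, 900))),
    )


def heaviside_ref(x, epsilon=1.0):
    return 0.5 * (1.0 + (2.0 / np.pi) * np.arctan(np.asarray(x, float) / epsilon))


def dirac_ref(x, epsilon=1.0):
    x = np.asarray(x, float)
    return (epsilon / np.pi) / (epsilon**2 + x * x)


def entropy_map_loops(image, radius, window="square", offset=0.0):
    """Per-pixel normalized local entropy by direct window enumeration."""
    image = np.asarray(image, float) + offset
    h, w = image.shape
    out = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            vals = []
            for di in range(-radius, radius + 1):
                for dj in range(-radius, radius + 1):
                    if window == "disk" and di * di + dj * dj > radius * radius:
                        continue
                    y, x = i + di, j + dj
                    if 0 <= y < h and 0 <= x < w:
                        vals.append(image[y, x])
            vals = np.asarray(vals)
            s = vals.sum()
            if s <= 0:
                out[i, j] = 1.0
                continue
            p = vals / s
            p = p[p > 0]
            out[i, j] = -np.sum(p * np.log(p)) / np.log(len(vals))
    return np.clip(out, 0.0, 1.0)


def _window_sum(field, i, j, kernel_weights, radius):
    """Σ_x K(x − y)·field(x) for centre pixel y=(i,j), zero outside."""
    h, w = field.shape
    acc = 0.0
    for di in range(-radius, radius + 1):
        for dj in range(-radius, radius + 1):
            y, x = i + di, j + dj
            if 0 <= y < h and 0 <= x < w:
                acc += kernel_weights[radius + di, radius + dj] * field[y, x]
    return acc


def force_maps_loops(image, entropy, bias, c, sigma_sq, kernel_weights, radius):
    """e_i(y) = Σ_x K(x−y)·E(x)·[log(√2π σ_i) + (I(y) − b(x)c_i)²/(2σ_i²)]."""
    h, w = image.shape
    maps = []
    for ci, s2 in zip(c, sigma_sq):
        e = np.empty((h, w))
        for i in range(h):
            for j in range(w):
                acc = 0.0
                for di in range(-radius, radius + 1):
                    for dj in range(-radius, radius + 1):
                        y, x = i + di, j + dj
                        if 0 <= y < h and 0 <= x < w:
                            k = kernel_weights[radius + di, radius + dj]
                            resid = image[i, j] - bias[y, x] * ci
                            acc += k * entropy[y, x] * (
                                LOG_SQRT_2PI + 0.5 * np.log(s2) + resid**2 / (2.0 * s2)
                            )
                e[i, j] = acc
        maps.append(e)
    return maps[0], maps[1]


def update_c_loops(image, entropy, bias, phi, kernel_weights, radius, epsilon=1.0):
    """c_i = Σ_y I(y)·M_i(y)·(K*(E·b))(y) / Σ_y M_i(y)·(K*(E·b²))(y)."""
    h, w = image.shape
    m1 = heaviside_ref(phi, epsilon)
    keb = np.empty((h, w))
    keb2 = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            keb[i, j] = _window_sum(entropy * bias, i, j, kernel_weights, radius)
            keb2[i, j] = _window_sum(entropy * bias * bias, i, j, kernel_weights, radius)
    out = []
    for m in (m1, 1.0 - m1):
        out.append(float(np.sum(image * keb * m)) / float(np.sum(keb2 * m)))
    return out[0], out[1]


def update_bias_loops(image, phi, c, sigma_sq, kernel_weights, radius, epsilon=1.0):
    """b(x) = K*(I·Σ_i M_i c_i/σ_i²)(x) / K*(Σ_i M_i c_i²/σ_i²)(x)."""
    h, w = image.shape
    m1 = heaviside_ref(phi, epsilon)
    num_f = image * (m1 * c[0] / sigma_sq[0] + (1 - m1) * c[1] / sigma_sq[1])
    den_f = m1 * c[0] ** 2 / sigma_sq[0] + (1 - m1) * c[1] ** 2 / sigma_sq[1]
    b = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            b[i, j] = _window_sum(num_f, i, j, kernel_weights, radius) / _window_sum(
                den_f, i, j, kernel_weights, radius
            )
    return np.maximum(b, 1e-3)


def update_sigma_loops(image, entropy, bias, phi, c, kernel_weights, radius,
                       epsilon=1.0, floor=0.0):
    """σ_i² = ΣΣ K(x−y)E(x)(I(y) − c_i b(x))² M_i(φ(y)) / ΣΣ K(x−y)E(x)M_i(φ(y))."""
    h, w = image.shape
    m1 = heaviside_ref(phi, epsilon)
    out = []
    for ci, m in zip(c, (m1, 1.0 - m1)):
        num = den = 0.0
        for i in range(h):
            for j in range(w):
                for di in range(-radius, radius + 1):
                    for dj in range(-radius, radius + 1):
                        y, x = i + di, j + dj
                        if 0 <= y < h and 0 <= x < w:
                            k = kernel_weights[radius + di, radius + dj] * entropy[y, x]
                            num += k * (image[i, j] - ci * bias[y, x]) ** 2 * m[i, j]
                            den += k * m[i, j]
        out.append(max(num / den, floor))
    return out[0], out[1]


def data_energy_loops(image, entropy, bias, phi, c, sigma_sq, kernel_weights, radius,
                      lambda1=1.0, lambda2=1.0, epsilon=1.0):
    """Σ_i λ_i Σ_y M_i(y) Σ_x K(x−y)E(x)[log(√2π σ_i) + (I(y)−b(x)c_i)²/(2σ_i²)]."""
    e1, e2 = force_maps_loops(image, entropy, bias, c, sigma_sq, kernel_weights, radius)
    m1 = heaviside_ref(phi, epsilon)
    return float(np.sum(lambda1 * m1 * e1 + lambda2 * (1.0 - m1) * e2))


def gradient_loops(phi):
    """np.gradient-style: central differences inside, one-sided at borders."""
    h, w = phi.shape
    gy = np.empty((h, w))
    gx = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            if i == 0:
                gy[i, j] = phi[1, j] - phi[0, j]
            elif i == h - 1:
                gy[i, j] = phi[i, j] - phi[i - 1, j]
            else:
                gy[i, j] = 0.5 * (phi[i + 1, j] - phi[i - 1, j])
            if j == 0:
                gx[i, j] = phi[i, 1] - phi[i, 0]
            elif j == w - 1:
                gx[i, j] = phi[i, j] - phi[i, j - 1]
            else:
                gx[i, j] = 0.5 * (phi[i, j + 1] - phi[i, j - 1])
    return gy, gx


def total_energy_loops(image, entropy, bias, phi, c, sigma_sq, kernel_weights, radius,
                       nu, mu, lambda1=1.0, lambda2=1.0, epsilon=1.0):
    data = data_energy_loops(image, entropy, bias, phi, c, sigma_sq,
                             kernel_weights, radius, lambda1, lambda2, epsilon)
    gy, gx = gradient_loops(phi)
    mag = np.sqrt(gy * gy + gx * gx)
    length = float(np.sum(dirac_ref(phi, epsilon) * mag))
    reg = float(np.sum(0.5 * (mag - 1.0) ** 2))
    return data + nu * length + mu * reg


def _clamp(v, lo, hi):
    return max(lo, min(v, hi))


def evolve_loops(phi, e1, e2, dt, nu, mu, lambda1=1.0, lambda2=1.0,
                 epsilon=1.0, grad_eps=1e-10):
    """One explicit step with replicated borders, coded index-by-index."""
    h, w = phi.shape

    def at(f, i, j):
        return f[_clamp(i, 0, h - 1), _clamp(j, 0, w - 1)]

    def grads(f):
        gy = np.empty((h, w))
        gx = np.empty((h, w))
        for i in range(h):
            for j in range(w):
                gy[i, j] = 0.5 * (at(f, i + 1, j) - at(f, i - 1, j))
                gx[i, j] = 0.5 * (at(f, i, j + 1) - at(f, i, j - 1))
        return gy, gx

    gy, gx = grads(phi)
    mag = np.sqrt(gy * gy + gx * gx) + grad_eps
    ny, nx = gy / mag, gx / mag
    dyy, _ = grads(ny)
    _, dxx = grads(nx)
    kappa = dyy + dxx

    lap = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            lap[i, j] = (at(phi, i + 1, j) + at(phi, i - 1, j)
                         + at(phi, i, j + 1) + at(phi, i, j - 1) - 4.0 * phi[i, j])

    delta = dirac_ref(phi, epsilon)
    dphi = (-delta * (lambda1 * e1 - lambda2 * e2)
            + nu * delta * kappa + mu * (lap - kappa))
    return phi + dt * dphi
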