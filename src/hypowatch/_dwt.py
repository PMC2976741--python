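"""Discrete Meyer wavelet filter bank and pyramidal DWT.

No DWT library ships with the target environment, so the two pieces needed
for the wavelet-energy features are built here:

* a 62-tap FIR approximation of the Meyer wavelet's orthogonal filter pair,
  obtained by sampling the analytic Meyer scaling-function spectrum and
  inverse-transforming with a linear-phase (half-sample) delay — the same
  construction that yields the "dmey" filters found in common toolboxes;
* a single- and multi-level analysis DWT using half-point symmetric signal
  extension, with the usual output length ``floor((n + L - 1) / 2)`` per
  level.

The Meyer filter is far longer (62 taps) than the 30- or 60-sample windows it
is applied to, so every decomposition level is boundary-dominated. That is
acceptable for the downstream use: relative band energies are normalized by
the total coefficient energy and remain well-defined regardless of the
extension mode.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = ["meyer_filters", "dwt_level", "wavedec", "FILTER_LENGTH"]

FILTER_LENGTH = 62


def _meyer_aux(x: np.ndarray) -> np.ndarray:
    """Meyer auxiliary polynomial nu(x) = x^4 (35 - 84x + 70x^2 - 20x^3), clipped to [0, 1]."""
    x = np.clip(x, 0.0, 1.0)
    return x**4 * (35.0 - 84.0 * x + 70.0 * x**2 - 20.0 * x**3)


def _meyer_scaling_spectrum(omega: np.ndarray) -> np.ndarray:
    """Fourier transform of the Meyer scaling function, phi_hat(omega).

    1 on |omega| <= 2*pi/3, a raised-cosine roll-off up to 4*pi/3, 0 beyond.
    """
    a = np.abs(omega)
    out = np.zeros_like(a)
    out[a <= 2.0 * np.pi / 3.0] = 1.0
    band = (a > 2.0 * np.pi / 3.0) & (a <= 4.0 * np.pi / 3.0)
    out[band] = np.cos(np.pi / 2.0 * _meyer_aux(3.0 * a[band] / (2.0 * np.pi) - 1.0))
    return out


@lru_cache(maxsize=1)
def meyer_filters(length: int = FILTER_LENGTH) -> tuple[np.ndarray, np.ndarray]:
    """Return the (lowpass, highpass) analysis pair of the discrete Meyer wavelet.

    The lowpass response on [-pi, pi] is ``H(w) = sqrt(2) * phi_hat(2 w)``
    (two-scale relation; ``phi_hat`` is identically 1 on the support of
    ``phi_hat(2 w)``). Taps come from a dense inverse discrete-time Fourier
    transform with group delay ``(length - 1) / 2``, truncated to ``length``
    and rescaled so the DC gain is exactly ``sqrt(2)``. The highpass is the
    quadrature-mirror partner ``g[n] = (-1)^n h[length - 1 - n]``.
    """
    n_grid = 1 << 16
    omega = np.linspace(0.0, np.pi, n_grid)
    response = np.sqrt(2.0) * _meyer_scaling_spectrum(2.0 * omega)
    tau = (length - 1) / 2.0
    taps = np.arange(length)
    # h[n] = (1/pi) * \int_0^pi H(w) cos(w (n - tau)) dw  (H real and even)
    kernel = np.cos(np.outer(taps - tau, omega))
    h = np.trapezoid(kernel * response, omega, axis=1) / np.pi
    h *= np.sqrt(2.0) / h.sum()
    g = ((-1.0) ** taps) * h[::-1]
    return h, g


def _symmetric_extend(x: np.ndarray, pad: int) -> np.ndarray:
    """Half-point symmetric extension by ``pad`` samples on each side.

    ``[x3 x2 x1 | x1 x2 x3 | x3 x2 x1 ...]`` — reflections repeat as needed,
    so ``pad`` may exceed ``len(x)`` (the Meyer filter usually does).
    """
    n = len(x)
    idx = np.arange(-pad, n + pad)
    m = np.mod(idx, 2 * n)
    return x[np.where(m < n, m, 2 * n - 1 - m)]


def dwt_level(x: np.ndarray, h: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One analysis level: (approximation, detail) coefficient vectors.

    Output length is ``floor((len(x) + L - 1) / 2)`` for filter length L.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("dwt_level expects a 1-D signal of length >= 2")
    pad = len(h) - 1
    ext = _symmetric_extend(x, pad)
    approx = np.convolve(ext, h[::-1], mode="valid")[1::2]
    detail = np.convolve(ext, g[::-1], mode="valid")[1::2]
    return approx, detail


def wavedec(x: np.ndarray, levels: int = 5) -> list[np.ndarray]:
    """Multi-level Meyer decomposition ``[a_L, d_L, d_{L-1}, ..., d_1]``."""
    h, g = meyer_filters()
    coeffs: list[np.ndarray] = []
    approx = np.asarray(x, dtype=float)
    for _ in range(levels):
        approx, detail = dwt_level(approx, h, g)
        coeffs.append(detail)
    coeffs.append(approx)
    return coeffs[::-1]


def relative_energies(x: np.ndarray, levels: int = 5) -> np.ndarray:
    """Relative band energies ``(Er_a, Er_d1, ..., Er_dL)``.

    Each entry is the squared Euclidean norm of one coefficient vector
    divided by the total over all L+1 vectors; they are nonnegative and sum
    to 1 by construction. Raises for an identically zero signal (zero total
    energy leaves the ratios undefined).
    """
    coeffs = wavedec(x, levels)
    energies = np.array([float(c @ c) for c in coeffs])
    total = energies.sum()
    if total <= 0.0:
        raise ValueError("zero total energy: relative band energies undefined")
    rel = energies / total
    # coeffs order is [a_L, d_L, ..., d_1] -> report (a_L, d_1, ..., d_L)
    return np.concatenate([rel[:1], rel[1:][::-1]])
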