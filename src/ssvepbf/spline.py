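"""Spherical-spline interpolation of scalp potentials (Perrin-style).

Bad channels are reconstructed from surviving channels by a spherical
spline of order m on the unit sphere: the kernel is

    g(cos gamma) = (1/4pi) sum_{l=1}^{L} (2l+1) / (l(l+1))^m  P_l(cos gamma)

with Legendre polynomials P_l. With m = 4 the series converges fast and
L = 7 terms suffice; a small ridge on the kernel matrix stabilises the
solve for near-coincident electrodes. The interpolation is linear in the
data, so a single weight matrix maps surviving-channel samples to the
reconstructed channels for all time points at once.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial import legendre

from .errors import ConfigurationError


def spline_kernel(cosang: np.ndarray, m: int = 4, n_terms: int = 7) -> np.ndarray:
    """Evaluate the spherical-spline kernel at cos(angle) values."""
    coef = np.zeros(n_terms + 1)
    for l in range(1, n_terms + 1):
        coef[l] = (2 * l + 1) / (l * (l + 1)) ** m
    return legendre.legval(np.clip(cosang, -1.0, 1.0), coef) / (4 * np.pi)


def interpolation_weights(good_pos: np.ndarray, bad_pos: np.ndarray,
                          m: int = 4, n_terms: int = 7,
                          ridge: float = 1e-5) -> np.ndarray:
    """Weight matrix W with  reconstructed = W @ good_channel_data.

    ``good_pos`` (k, 3) and ``bad_pos`` (b, 3) are unit vectors. The
    spline solves [G + ridge*I, 1; 1^T, 0] [c; d] = [v; 0] for each time
    sample; linearity lets us return the (b, k) map directly.
    """
    k = good_pos.shape[0]
    if k < 3:
        raise ConfigurationError("need at least 3 surviving channels to interpolate")
    g_kk = spline_kernel(good_pos @ good_pos.T, m, n_terms)
    g_bk = spline_kernel(bad_pos @ good_pos.T, m, n_terms)
    a = np.zeros((k + 1, k + 1))
    a[:k, :k] = g_kk + ridge * np.eye(k)
    a[:k, k] = 1.0
    a[k, :k] = 1.0
    b = np.hstack([g_bk, np.ones((bad_pos.shape[0], 1))])
    # est = [g_bk, 1] @ A^{-1} @ [v; 0]  ->  W = ([g_bk, 1] A^{-1})[:, :k]
    return np.linalg.solve(a.T, b.T).T[:, :k]


def interpolate_channels(data: np.ndarray, positions: np.ndarray,
                         bad_idx: np.ndarray, m: int = 4, n_terms: int = 7,
                         ridge: float = 1e-5) -> np.ndarray:
    """Return a copy of (channels x time) data with ``bad_idx`` rebuilt."""
    bad_idx = np.asarray(bad_idx, dtype=int)
    if bad_idx.size == 0:
        return data.copy()
    good = np.setdiff1d(np.arange(data.shape[0]), bad_idx)
    w = interpolation_weights(positions[good], positions[bad_idx], m, n_terms, ridge)
    out = data.copy()
    out[bad_idx] = w @ data[good]
    return out
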