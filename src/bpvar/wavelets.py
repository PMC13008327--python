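"""Orthogonal discrete wavelet transform with periodized boundaries.

Implements decimated analysis filter banks for the Daubechies family
(``dbN`` = N vanishing moments, 2N taps) with circular (periodized)
boundary handling.  Filters are built by spectral factorization of the
Daubechies binomial polynomial, so any order is available without lookup
tables.  Because each filter pair is a paraunitary QMF pair, the transform
is exactly orthonormal for any even signal length, so energy is conserved
between the signal and its coefficients — the property the band-energy
features rely on.  Supports batched input along the leading axes.
"""

from __future__ import annotations

from functools import lru_cache
from math import comb

import numpy as np


@lru_cache(maxsize=None)
def daubechies_filter(n_moments: int) -> np.ndarray:
    """Daubechies scaling (low-pass) filter with *n_moments* vanishing
    moments (2*n_moments taps), by spectral factorization.

    The half-band polynomial P(y) = sum_k C(N-1+k, k) y^k is expressed in z
    with y = (2 - z - 1/z)/4; the minimum-phase spectral factor (roots inside
    the unit circle) times (1+z)^N, normalised to sum sqrt(2), is the filter.
    """
    N = int(n_moments)
    if N < 1:
        raise ValueError("need at least one vanishing moment")
    if N == 1:  # Haar
        return np.array([1.0, 1.0]) / np.sqrt(2.0)
    P = np.array([comb(N - 1 + j, j) for j in range(N)], dtype=float)
    y_poly = np.array([-0.25, 0.5, -0.25])  # y as Laurent poly in z (causalised)
    total = np.zeros(2 * N - 1)
    total[N - 1] = P[0]
    cur = np.array([1.0])
    for j in range(1, N):
        cur = np.convolve(cur, y_poly)
        c = np.zeros(2 * N - 1)
        off = (2 * N - 1 - cur.size) // 2
        c[off : off + cur.size] = cur
        total += P[j] * c
    roots = np.roots(total[::-1])
    inside = roots[np.abs(roots) < 1.0 - 1e-10]
    binom = np.array([1.0])
    for _ in range(N):
        binom = np.convolve(binom, [1.0, 1.0])
    h = np.convolve(binom, np.poly(inside)).real
    return h * np.sqrt(2.0) / h.sum()


def qmf_pair(lo: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Quadrature-mirror high-pass: g[k] = (-1)^k h[L-1-k]."""
    hi = ((-1.0) ** np.arange(lo.size)) * lo[::-1]
    return lo, hi


def get_filters(family: str) -> tuple[np.ndarray, np.ndarray]:
    if not family.startswith("db"):
        raise KeyError(f"unknown wavelet family {family!r}")
    return qmf_pair(daubechies_filter(int(family[2:])))


class _FamilyRegistry:
    """Mapping-like view so ``family in FAMILIES`` and indexing both work."""

    def __contains__(self, family) -> bool:
        try:
            get_filters(family)
            return True
        except (KeyError, ValueError):
            return False

    def __getitem__(self, family):
        return get_filters(family)


FAMILIES = _FamilyRegistry()

# Reference instance used throughout tests; standard published values.
DB4_LO, DB4_HI = qmf_pair(daubechies_filter(4))


def _analysis_step(x: np.ndarray, lo: np.ndarray, hi: np.ndarray):
    """One level of the periodized decimated filter bank.

    ``x`` has even length n along the last axis; returns (approx, detail)
    of length n/2 each.
    """
    n = x.shape[-1]
    if n % 2:
        raise ValueError("periodized DWT step requires even length")
    idx = (2 * np.arange(n // 2)[:, None] + np.arange(lo.size)[None, :]) % n
    y = x[..., idx]
    return y @ lo, y @ hi


def wavedec(x: np.ndarray, levels: int, family: str = "db8"):
    """Multi-level periodized DWT along the last axis.

    Length must be divisible by ``2**levels``. Returns
    ``(approx, [d1, ..., d_levels])`` with d1 the finest detail level.
    """
    lo, hi = FAMILIES[family]
    x = np.asarray(x, dtype=float)
    if x.shape[-1] % (1 << levels):
        raise ValueError(f"length {x.shape[-1]} not divisible by 2**{levels}")
    details = []
    a = x
    for _ in range(levels):
        a, d = _analysis_step(a, lo, hi)
        details.append(d)
    return a, details


def usable_length(n: int, levels: int) -> int:
    """Largest prefix length of an n-sample span usable at this depth."""
    block = 1 << levels
    return (n // block) * block


def band_energies(x: np.ndarray, levels: int = 5, family: str = "db8"):
    """Normalised detail-band and approximation energies of a span.

    The span is truncated to the largest dyadic-compatible prefix, the mean
    is subtracted, and each level's energy is the sum of squared detail
    coefficients divided by the truncated span length (units: signal^2 per
    sample).  Returns ``(detail_energies[levels], approx_energy, n_used)``
    with index 0 the finest level (shortest periods).
    """
    x = np.asarray(x, dtype=float)
    n_used = usable_length(x.shape[-1], levels)
    if n_used == 0:
        raise ValueError("span too short for requested decomposition depth")
    x = x[..., :n_used]
    x = x - x.mean(axis=-1, keepdims=True)
    approx, details = wavedec(x, levels, family)
    det = np.stack([np.sum(d * d, axis=-1) for d in details], axis=-1) / n_used
    app = np.sum(approx * approx, axis=-1) / n_used
    return det, app, n_used


def level_period_bands(levels: int, dt_min: float = 1.0, finest_period: float | None = None):
    """Oscillation-period labels (lo, hi) in minutes for each detail level.

    By default level j covers periods ``[2^j, 2^(j+1)] * dt`` (the physical
    mapping for a sampling step dt).  Passing ``finest_period`` shifts the
    ladder so level 1 is labelled ``[finest_period, 2*finest_period]``.
    """
    base = 2.0 * dt_min if finest_period is None else float(finest_period)
    return [(base * 2**j, base * 2 ** (j + 1)) for j in range(levels)]
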