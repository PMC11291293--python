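"""Normalized global spatial complexity (NGSC) — eigen-spectrum entropy.

NGSC quantifies spatial desynchronization of multichannel signals.  A
temporal PCA of the channels × frames matrix yields eigenvalues λ_i; each is
normalized to λ'_i = λ_i / Σλ_i and the measure is the normalized entropy

    NGSC = − Σ λ'_i ln λ'_i / ln m,       with 0·ln 0 := 0,

where m is the number of channels.  NGSC = 0 when every channel carries the
same time course (one spatial mode, maximal synchrony); NGSC = 1 when the
total variance is spread uniformly over all m components (maximal spatial
complexity).  The value is independent of the logarithm base and of the
number of channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "NGSCResult",
    "ngsc",
    "ngsc_from_spectrum",
    "parcel_ngsc",
    "ngsc_change",
    "spatial_map_correlation",
]


@dataclass
class NGSCResult:
    whole_brain: float
    eigen_spectrum: np.ndarray   # normalized eigenvalues, length m, sums to 1
    m: int


def ngsc_from_spectrum(eigenvalues: np.ndarray, m: int | None = None) -> float:
    """Normalized entropy of an eigenvalue spectrum (0·ln 0 := 0)."""
    lam = np.asarray(eigenvalues, dtype=float)
    if np.any(lam < -1e-12 * max(lam.max(initial=0.0), 1.0)):
        raise ValueError("eigenvalues must be nonnegative")
    lam = np.clip(lam, 0.0, None)
    total = lam.sum()
    if total <= 0:
        raise ValueError("zero total variance")
    if m is None:
        m = len(lam)
    if m < 2:
        raise ValueError("need at least 2 channels")
    p = lam / total
    nz = p > 0
    return float(-(p[nz] * np.log(p[nz])).sum() / np.log(m))


def ngsc(signals: np.ndarray, *, use_correlation: bool = False) -> NGSCResult:
    """NGSC of a channels × frames matrix.

    Channels are demeaned; by default amplitudes are kept (covariance PCA)
    so channels with larger fluctuations weigh more, matching a
    total-variance normalization.  ``use_correlation`` additionally scales
    each channel to unit variance.  m is the channel count even when the
    matrix is rank deficient — zero eigenvalues contribute no entropy but
    still enter the ln m normalization.
    """
    x = np.asarray(signals, dtype=float)
    if x.ndim != 2:
        raise ValueError("signals must be a 2-D channels × frames matrix")
    m, t = x.shape
    if m < 2 or t < 2:
        raise ValueError("need at least 2 channels and 2 frames")
    x = x - x.mean(axis=1, keepdims=True)
    if use_correlation:
        sd = x.std(axis=1, keepdims=True)
        good = sd[:, 0] > 0
        x = np.divide(x, sd, out=np.zeros_like(x), where=sd > 0)
        if not good.any():
            raise ValueError("all channels constant")
    if not np.any(x):
        raise ValueError("all channels constant (zero variance)")
    # eigenvalues of the channel covariance via singular values
    s = np.linalg.svd(x, compute_uv=False)
    lam = np.zeros(m)
    lam[: len(s)] = s**2 / (t - 1)
    value = ngsc_from_spectrum(lam, m)
    return NGSCResult(whole_brain=value, eigen_spectrum=lam / lam.sum(), m=m)


def parcel_ngsc(
    subchannels: np.ndarray,
    membership: np.ndarray,
    *,
    use_correlation: bool = False,
) -> dict[int, float]:
    """NGSC per parcel from a sub-channel matrix and its parcel membership.

    ``subchannels`` is (channels × frames) and ``membership`` assigns each
    row to a parcel.  Singleton groups are undefined and reported as NaN.
    """
    subchannels = np.asarray(subchannels, dtype=float)
    membership = np.asarray(membership)
    if subchannels.shape[0] != membership.shape[0]:
        raise ValueError("membership length must match channel count")
    out: dict[int, float] = {}
    for parcel in np.unique(membership):
        rows = subchannels[membership == parcel]
        if rows.shape[0] < 2:
            out[int(parcel)] = float("nan")
            continue
        out[int(parcel)] = ngsc(rows, use_correlation=use_correlation).whole_brain
    return out


def ngsc_change(
    drug_per_parcel: dict[int, float] | np.ndarray,
    baseline_per_parcel: list[dict[int, float]] | list[np.ndarray],
) -> np.ndarray:
    """Per-parcel NGSC delta: drug minus the mean of baseline maps."""

    def as_array(m):
        if isinstance(m, dict):
            keys = sorted(m)
            return np.array([m[k] for k in keys]), keys
        return np.asarray(m, dtype=float), None

    drug, keys = as_array(drug_per_parcel)
    bases = []
    for b in baseline_per_parcel:
        arr, bkeys = as_array(b)
        if arr.shape != drug.shape or (keys is not None and bkeys != keys):
            raise ValueError("mismatched parcel sets")
        bases.append(arr)
    if not bases:
        raise ValueError("need at least one baseline map")
    return drug - np.mean(bases, axis=0)


def spatial_map_correlation(
    map_a: np.ndarray, map_b: np.ndarray, mask: np.ndarray | None = None
) -> float:
    """Pearson correlation between two per-parcel maps over unmasked parcels.

    Used e.g. to compare an NGSC-change map against a receptor-density
    reference map.
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("maps must have identical shape")
    if mask is not None:
        keep = np.asarray(mask, dtype=bool)
        a, b = a[keep], b[keep]
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if len(a) < 3:
        raise ValueError("need at least 3 unmasked parcels")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant map")
    return float(stats.pearsonr(a, b)[0])
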