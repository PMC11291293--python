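"""Permutation machinery: wild bootstrap, TFCE, and the spherical spin test.

The per-parcel t-map from the scan-level mixed model is assessed with a
Rademacher wild bootstrap: residuals from the reduced (drug-effect-removed)
model are randomly sign-flipped — by default per session cluster, so the
within-session correlation structure is respected — and the model is refit
to each bootstrap sample.  Threshold-free cluster enhancement (TFCE)
integrates supra-threshold cluster extent and height over the parcel
adjacency graph, and family-wise-corrected p-values come from the
maximum-statistic null distribution.  Network specificity of a fixed map is
assessed with a rotation-based null that spins the network labels over the
spherical parcel geometry, preserving each network's size and shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .cohort import ParcelSet
from .inference import BalancedNestedLME, build_design

__all__ = [
    "StatMap",
    "SpinResult",
    "rademacher_flips",
    "wild_bootstrap_map",
    "tfce",
    "tfce_p_values",
    "random_rotation",
    "spin_test",
]

TFCE_E = 0.5
TFCE_H = 2.0


@dataclass
class StatMap:
    """Observed per-parcel t-map with its bootstrap null maps."""

    t: np.ndarray                    # (n_parcels,)
    null_t: np.ndarray               # (B, n_parcels)
    B: int
    seed: int
    excluded_parcels: list[int]
    tfce_pos: np.ndarray | None = None
    tfce_neg: np.ndarray | None = None
    p: np.ndarray | None = None


@dataclass
class SpinResult:
    networks: list[str]
    observed: dict[str, float]
    null: dict[str, np.ndarray]       # (n_perm,) per network
    p: dict[str, float]
    n_perm: int
    flagged: list[str]


def rademacher_flips(n: int, seed: int | np.random.Generator) -> np.ndarray:
    """n independent ±1 signs with equal probability."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    return rng.integers(0, 2, size=n) * 2 - 1


def wild_bootstrap_map(
    y_per_parcel: np.ndarray,
    design: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    *,
    contrast_condition: str = "psilocybin",
    flip_unit: str = "session",
) -> StatMap:
    """Wild-bootstrap null t-maps for the per-parcel scan-level LME.

    ``y_per_parcel`` is (n_obs, n_parcels); ``design`` carries participant,
    session, condition, fd, task per observation.  Per parcel the variance
    components are estimated once under the reduced model (the tested drug
    term removed) and the observed t is the generalized-least-squares t of
    the full model at those components.  Bootstrap samples are built under
    the reduced model — y* = fitted_reduced + flips · residuals_reduced,
    with Rademacher flips drawn per session cluster
    (``flip_unit='observation'`` flips every observation independently) —
    and each is pushed through exactly the same statistic, so the null
    distribution replicates the observed computation and the max-statistic
    procedure controls the family-wise error rate.  Parcels whose fit
    fails are excluded and reported.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if flip_unit not in ("session", "observation"):
        raise ValueError("flip_unit must be 'session' or 'observation'")
    Y = np.asarray(y_per_parcel, float)
    n_obs, n_parcels = Y.shape
    X, names = build_design(design, contrast_condition)
    contrast = f"drug[{contrast_condition}]"
    if contrast not in names:
        raise ValueError(f"no {contrast_condition} observations in design")
    ci = names.index(contrast)
    keep = [j for j in range(len(names)) if j != ci]

    part = design["participant"].to_numpy()
    sess = design["session"].to_numpy()
    full = BalancedNestedLME(X, part, sess)
    reduced = BalancedNestedLME(X[:, keep], part, sess)

    rng = np.random.default_rng(seed)
    skey = np.array([f"{p}//{s}" for p, s in zip(part, sess)])
    _, sess_inv = np.unique(skey, return_inverse=True)
    n_sessions = sess_inv.max() + 1

    t_obs = np.full(n_parcels, np.nan)
    null_t = np.full((B, n_parcels), np.nan)
    excluded: list[int] = []
    for parcel in range(n_parcels):
        y = Y[:, parcel]
        try:
            fit_red = reduced.fit(y)
            t_obs[parcel] = full.gls_t(fit_red.theta, y[:, None], ci)[0]
        except (np.linalg.LinAlgError, ValueError):
            excluded.append(parcel)
            continue
        if flip_unit == "session":
            signs = rng.integers(0, 2, size=(n_sessions, B)) * 2 - 1
            flips = signs[sess_inv]
        else:
            flips = rng.integers(0, 2, size=(n_obs, B)) * 2 - 1
        y_star = fit_red.fitted_marginal[:, None] + flips * fit_red.residuals[:, None]
        null_t[:, parcel] = full.gls_t(fit_red.theta, y_star, ci)
    return StatMap(
        t=t_obs, null_t=null_t, B=B, seed=seed, excluded_parcels=excluded
    )


def tfce(
    values: np.ndarray,
    adjacency: csr_matrix | np.ndarray,
    E: float = TFCE_E,
    H: float = TFCE_H,
    dh: float | None = None,
) -> np.ndarray:
    """Threshold-free cluster enhancement on a parcel graph (positive tail).

    For each parcel p,  TFCE(p) = Σ_h extent_h(p)^E · h^H · dh  over
    thresholds h = dh, 2dh, … up to max t, where extent_h(p) is the size of
    the connected supra-threshold (t ≥ h) component containing p.  Values
    ≤ 0 enhance to 0; run on −t for the negative tail.  ``dh`` defaults to
    max(t)/100.
    """
    t = np.asarray(values, float)
    adj = csr_matrix(adjacency)
    if adj.shape[0] != len(t):
        raise ValueError("adjacency size must match map length")
    if adj.shape[0] == 0:
        raise ValueError("empty graph")
    out = np.zeros_like(t)
    tmax = np.nanmax(t) if len(t) else 0.0
    if not np.isfinite(tmax) or tmax <= 0:
        return out
    if dh is None:
        dh = tmax / 100.0
    if dh <= 0:
        raise ValueError("dh must be positive")
    n_steps = int(np.floor(tmax / dh + 1e-12))
    # descending thresholds with an incremental union-find: nodes activate
    # as h drops, components only merge, so each step costs O(active)
    n = len(t)
    parent = np.arange(n)
    size = np.ones(n, dtype=np.int64)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    indptr, indices = adj.indptr, adj.indices
    order = np.argsort(np.where(np.isfinite(t), t, -np.inf))[::-1]
    active = np.zeros(n, dtype=bool)
    pos = 0
    active_nodes: list[int] = []
    for k in range(n_steps, 0, -1):
        h = k * dh
        thresh = h - 1e-12 * tmax
        while pos < n and np.isfinite(t[order[pos]]) and t[order[pos]] >= thresh:
            node = order[pos]
            active[node] = True
            active_nodes.append(node)
            for nb in indices[indptr[node] : indptr[node + 1]]:
                if active[nb]:
                    ra, rb = find(node), find(nb)
                    if ra != rb:
                        if size[ra] < size[rb]:
                            ra, rb = rb, ra
                        parent[rb] = ra
                        size[ra] += size[rb]
            pos += 1
        if active_nodes:
            inc = h**H * dh
            for node in active_nodes:
                out[node] += size[find(node)] ** E * inc
    return out


def tfce_p_values(
    observed: np.ndarray, null_maps: np.ndarray
) -> np.ndarray:
    """Max-statistic family-wise p per parcel.

    p(parcel) = (1 + #{b : max_parcel null_b ≥ observed(parcel)}) / (B + 1),
    so p is floored at 1/(B+1) and never zero.
    """
    null_maps = np.atleast_2d(np.asarray(null_maps, float))
    if null_maps.shape[0] < 1:
        raise ValueError("need at least one null map")
    null_max = np.nanmax(null_maps, axis=1)
    B = null_maps.shape[0]
    obs = np.asarray(observed, float)
    exceed = (null_max[:, None] >= obs[None, :]).sum(axis=0)
    return (1.0 + exceed) / (B + 1.0)


def random_rotation(seed: int | np.random.Generator) -> np.ndarray:
    """Uniform (Haar) random proper rotation of R^3."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    return stats.special_ortho_group.rvs(3, random_state=rng)


_MIRROR_X = np.diag([-1.0, 1.0, 1.0])


def _spin_assignment(
    centroids: np.ndarray, rotation: np.ndarray
) -> np.ndarray:
    """Exact one-to-one reassignment of labels under a rotation.

    Rotated source centroids are matched to target centroids by minimizing
    total angular distance (Hungarian assignment), so each target parcel
    receives exactly one source label and label counts are preserved.
    Returns ``source_of[target] = source index``.
    """
    rotated = centroids @ rotation.T
    cost = -(centroids @ rotated.T)          # target x source, maximize dot
    rows, cols = linear_sum_assignment(cost)
    source_of = np.empty(len(centroids), dtype=int)
    source_of[rows] = cols
    return source_of


def spin_test(
    values: np.ndarray,
    parcels: ParcelSet,
    n_perm: int = 1000,
    seed: int = 0,
    target_networks: list[str] | None = None,
) -> SpinResult:
    """Rotation-based network-specificity null for a per-parcel map.

    One rotation is sampled per permutation and applied to the left
    hemisphere; its x-mirrored version rotates the right hemisphere, so the
    two hemispheres move together and networks keep their sizes, shapes and
    relative positions.  Labels are reassigned by exact matching of rotated
    centroids; labels landing on (or arriving from) medial-wall parcels are
    excluded from that permutation's network means, as are parcels without
    a finite map value.  The one-sided p per network is the fraction of
    permutations whose rotated-network mean meets or exceeds the observed
    mean (with the +1 floor).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    values = np.asarray(values, float)
    if len(values) != parcels.n_parcels:
        raise ValueError("map length must match parcel count")
    rng = np.random.default_rng(seed)
    networks = parcels.networks if target_networks is None else list(target_networks)
    labels = parcels.network_labels
    valid = ~parcels.medial_wall & np.isfinite(values)

    observed = {}
    for net in networks:
        mask = (labels == net) & valid
        observed[net] = float(values[mask].mean()) if mask.any() else np.nan

    left = parcels.hemisphere == "L"
    right = ~left
    idx_l = np.where(left)[0]
    idx_r = np.where(right)[0]

    null = {net: np.empty(n_perm) for net in networks}
    absent = {net: 0 for net in networks}
    for b in range(n_perm):
        R = random_rotation(rng)
        Rr = _MIRROR_X @ R @ _MIRROR_X
        src = np.empty(parcels.n_parcels, dtype=int)
        src[idx_l] = idx_l[_spin_assignment(parcels.centroids[idx_l], R)]
        src[idx_r] = idx_r[_spin_assignment(parcels.centroids[idx_r], Rr)]
        rotated_labels = labels[src]
        # a label arriving from a medial-wall source parcel is dropped
        ok = valid & ~parcels.medial_wall[src]
        for net in networks:
            mask = (rotated_labels == net) & ok
            if mask.any():
                null[net][b] = values[mask].mean()
            else:
                null[net][b] = np.nan
                absent[net] += 1
    p = {}
    flagged = []
    for net in networks:
        nd = null[net]
        good = np.isfinite(nd)
        if absent[net] > n_perm // 2:
            flagged.append(net)
        if not good.any() or not np.isfinite(observed[net]):
            p[net] = np.nan
            continue
        p[net] = float((1 + np.sum(nd[good] >= observed[net])) / (good.sum() + 1))
    return SpinResult(
        networks=networks,
        observed=observed,
        null=null,
        p=p,
        n_perm=n_perm,
        flagged=flagged,
    )
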