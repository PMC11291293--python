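"""Functional-connectivity matrices and FC-change distance scores.

FC is the Fisher-z-transformed bivariate correlation between parcel time
series.  "FC change" is a distance from a scan's connectivity to a
same-participant baseline: per parcel as the mean seedmap distance to each
baseline scan, whole-brain as the RMS Euclidean distance between linearized
upper triangles.  Condition means of the scan-by-scan distance matrix are
normalized so within-session distance maps to 0 and day-to-day variability
to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import ScanRecord

__all__ = [
    "ConnectivityMatrix",
    "FCChangeMap",
    "ScanDistanceMatrix",
    "censor_mask_from_fd",
    "compute_fc",
    "seedmap",
    "fc_change_map",
    "whole_brain_fc_change",
    "scan_distance_matrix",
    "condition_fc_change",
    "normalize_fc_change",
]

R_CLIP = 1.0 - 1e-7
FD_SCRUB_THRESHOLD_MM = 0.3


@dataclass
class ConnectivityMatrix:
    """Symmetric parcel × parcel Fisher-z connectivity for one scan."""

    values: np.ndarray                       # (n, n), zero diagonal, NaN rows for flagged
    scan: ScanRecord | None = None
    flagged_parcels: list[int] = field(default_factory=list)

    @property
    def n_parcels(self) -> int:
        return self.values.shape[0]

    def upper_triangle(self) -> np.ndarray:
        """Linearized strict upper triangle (diagonal excluded)."""
        iu = np.triu_indices(self.n_parcels, k=1)
        return self.values[iu]


@dataclass
class FCChangeMap:
    """Per-parcel FC-change score for one scan vs a baseline set (≥ 0)."""

    values: np.ndarray
    scan: ScanRecord | None = None
    n_baselines: int = 0
    metric: str = "rms"


@dataclass
class ScanDistanceMatrix:
    """Scan × scan whole-brain FC change with design labels."""

    values: np.ndarray
    labels: pd.DataFrame   # columns: scan_id, participant, session, condition, task, mean_fd


def censor_mask_from_fd(
    fd: np.ndarray, threshold: float = FD_SCRUB_THRESHOLD_MM
) -> np.ndarray:
    """Frames retained after motion scrubbing (True = keep)."""
    return np.asarray(fd) < threshold


def compute_fc(
    scan: ScanRecord | np.ndarray, censor_mask: np.ndarray | None = None
) -> ConnectivityMatrix:
    """Fisher-z bivariate correlation matrix over retained frames.

    Pearson r is clipped to ±(1 − 1e−7) before atanh so identical series
    stay finite.  Constant (zero-variance) parcels are flagged and their
    rows/columns set to NaN rather than silently zeroed.
    """
    signals = scan.signals if isinstance(scan, ScanRecord) else np.asarray(scan)
    if censor_mask is not None:
        censor_mask = np.asarray(censor_mask, dtype=bool)
        if censor_mask.shape[0] != signals.shape[1]:
            raise ValueError(
                f"censor mask length {censor_mask.shape[0]} != frames "
                f"{signals.shape[1]}"
            )
        signals = signals[:, censor_mask]
    if signals.shape[1] < 3:
        raise ValueError(
            f"need at least 3 retained frames, got {signals.shape[1]}"
        )
    sd = signals.std(axis=1)
    flagged = np.where(sd == 0)[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(signals)
    r = np.clip(r, -R_CLIP, R_CLIP)
    z = np.arctanh(r)
    z[flagged, :] = np.nan
    z[:, flagged] = np.nan
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(
        values=z,
        scan=scan if isinstance(scan, ScanRecord) else None,
        flagged_parcels=list(flagged),
    )


def seedmap(fc: ConnectivityMatrix, parcel: int) -> np.ndarray:
    """One parcel's FC to every other parcel (self excluded, length n−1)."""
    n = fc.n_parcels
    if not 0 <= parcel < n:
        raise IndexError(f"parcel {parcel} not in matrix of size {n}")
    row = fc.values[parcel]
    return np.delete(row, parcel)


def _seedmap_distance(a: np.ndarray, b: np.ndarray, metric: str) -> float:
    d2 = (a - b) ** 2
    if metric == "rms":
        return float(np.sqrt(np.nanmean(d2)))
    if metric == "euclidean":
        return float(np.sqrt(np.nansum(d2)))
    raise ValueError(f"unknown metric {metric!r}")


def fc_change_map(
    scan_fc: ConnectivityMatrix,
    baseline_fcs: list[ConnectivityMatrix],
    exclude_same_session: bool = True,
    metric: str = "rms",
) -> FCChangeMap:
    """Per-parcel mean seedmap distance from a scan to each baseline scan.

    The score is the mean of per-baseline distances (not the distance to the
    mean seedmap).  With ``exclude_same_session`` baselines sharing the
    scan's session are dropped first — the rule used when scoring baseline
    scans themselves to obtain day-to-day variability.  ``metric='rms'``
    divides the squared seedmap difference by its length before the square
    root; ``'euclidean'`` is the raw norm.
    """
    eligible = baseline_fcs
    if exclude_same_session and scan_fc.scan is not None:
        key = (scan_fc.scan.participant_id, scan_fc.scan.session_id)
        eligible = [
            b
            for b in baseline_fcs
            if b.scan is None
            or (b.scan.participant_id, b.scan.session_id) != key
        ]
    if not eligible:
        raise ValueError("no eligible baseline scans after exclusion")
    n = scan_fc.n_parcels
    for b in eligible:
        if b.n_parcels != n:
            raise ValueError("baseline parcel count mismatch")
    out = np.zeros(n)
    for p in range(n):
        s = seedmap(scan_fc, p)
        out[p] = float(
            np.mean([_seedmap_distance(s, seedmap(b, p), metric) for b in eligible])
        )
    return FCChangeMap(
        values=out, scan=scan_fc.scan, n_baselines=len(eligible), metric=metric
    )


def whole_brain_fc_change(
    fc_a: ConnectivityMatrix | np.ndarray, fc_b: ConnectivityMatrix | np.ndarray
) -> float:
    """RMS Euclidean distance between linearized upper triangles.

    The squared z-differences over the E = n(n−1)/2 edges are averaged
    before the square root, making the score comparable across parcel
    counts.
    """
    a = fc_a.values if isinstance(fc_a, ConnectivityMatrix) else np.asarray(fc_a)
    b = fc_b.values if isinstance(fc_b, ConnectivityMatrix) else np.asarray(fc_b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    iu = np.triu_indices(a.shape[0], k=1)
    return float(np.sqrt(np.nanmean((a[iu] - b[iu]) ** 2)))


def scan_distance_matrix(fcs: list[ConnectivityMatrix]) -> ScanDistanceMatrix:
    """Second-order scan × scan distance matrix of whole-brain FC change."""
    if len(fcs) < 2:
        raise ValueError("need at least 2 scans")
    n_parcels = fcs[0].n_parcels
    if any(f.n_parcels != n_parcels for f in fcs):
        raise ValueError("heterogeneous parcel sets")
    iu = np.triu_indices(n_parcels, k=1)
    vecs = np.array([f.values[iu] for f in fcs])
    # pairwise RMS distance via the Gram expansion
    sq = np.nansum(vecs**2, axis=1)
    gram = vecs @ vecs.T
    d2 = (sq[:, None] + sq[None, :] - 2 * gram) / vecs.shape[1]
    d2 = np.maximum(d2, 0.0)
    dist = np.sqrt(d2)
    np.fill_diagonal(dist, 0.0)
    rows = []
    for i, f in enumerate(fcs):
        s = f.scan
        rows.append(
            {
                "scan_id": s.scan_id if s is not None else f"scan{i}",
                "participant": s.participant_id if s is not None else "",
                "session": s.session_id if s is not None else "",
                "condition": s.condition if s is not None else "",
                "task": bool(s.task) if s is not None else False,
                "mean_fd": float(s.mean_fd) if s is not None else np.nan,
            }
        )
    return ScanDistanceMatrix(values=dist, labels=pd.DataFrame(rows))


def _pairs_mean(dist: np.ndarray, pairs: list[tuple[int, int]]) -> float | None:
    if not pairs:
        return None
    return float(np.mean([dist[i, j] for i, j in pairs]))


def condition_fc_change(sdm: ScanDistanceMatrix) -> dict[str, float | None]:
    """Average whole-brain FC change per comparison category.

    Categories (a missing category is reported as None, never zero):

    - ``within_session``: same participant, same session, baseline rest scans
    - ``day_to_day``: same participant, different sessions, baseline rest
    - ``task_vs_rest``: same participant, baseline task vs baseline rest,
      different sessions
    - ``MTP`` / ``psilocybin``: drug rest scans vs same-participant baseline
      rest scans
    - ``hi_lo_motion``: the two highest-motion non-drug rest scans vs that
      participant's other baseline rest scans
    - ``between_person``: baseline rest scans pooled across participants
    """
    d = sdm.values
    lab = sdm.labels
    part = lab["participant"].to_numpy()
    sess = lab["session"].to_numpy()
    cond = lab["condition"].to_numpy()
    task = lab["task"].to_numpy()
    fd = lab["mean_fd"].to_numpy()
    n = len(lab)

    base_rest = (cond == "baseline") & ~task
    base_task = (cond == "baseline") & task
    nondrug_rest = np.isin(cond, ["baseline", "between", "after"]) & ~task

    within, day, taskrest, between_person = [], [], [], []
    drug_pairs: dict[str, list[tuple[int, int]]] = {"MTP": [], "psilocybin": []}
    for i in range(n):
        for j in range(i + 1, n):
            same_p = part[i] == part[j]
            same_s = same_p and sess[i] == sess[j]
            if base_rest[i] and base_rest[j]:
                if same_s:
                    within.append((i, j))
                elif same_p:
                    day.append((i, j))
                else:
                    between_person.append((i, j))
            if same_p and not same_s and (
                (base_task[i] and base_rest[j]) or (base_rest[i] and base_task[j])
            ):
                taskrest.append((i, j))
    for drug in ("MTP", "psilocybin"):
        idx = np.where((cond == drug) & ~task)[0]
        for i in idx:
            for j in np.where(base_rest & (part == part[i]))[0]:
                drug_pairs[drug].append((min(i, j), max(i, j)))

    # hi:lo motion — two non-drug rest scans with highest mean FD vs the
    # same participant's other baseline rest scans
    hi_lo: list[tuple[int, int]] = []
    nd_idx = np.where(nondrug_rest)[0]
    if len(nd_idx) >= 3:
        hi = nd_idx[np.argsort(fd[nd_idx])[-2:]]
        for i in hi:
            for j in np.where(base_rest & (part == part[i]))[0]:
                if j not in hi and sess[j] != sess[i]:
                    hi_lo.append((min(i, j), max(i, j)))

    return {
        "within_session": _pairs_mean(d, within),
        "day_to_day": _pairs_mean(d, day),
        "task_vs_rest": _pairs_mean(d, taskrest),
        "MTP": _pairs_mean(d, drug_pairs["MTP"]),
        "psilocybin": _pairs_mean(d, drug_pairs["psilocybin"]),
        "hi_lo_motion": _pairs_mean(d, hi_lo),
        "between_person": _pairs_mean(d, between_person),
    }


def normalize_fc_change(
    condition_means: dict[str, float | None]
) -> dict[str, float | None]:
    """Normalize condition means to the day-to-day scale.

    Subtracts the within-session mean from every condition, then divides by
    the (shifted) day-to-day mean, so within-session maps to exactly 0 and
    day-to-day to exactly 1; other conditions read as multiples of
    day-to-day variability.
    """
    within = condition_means.get("within_session")
    day = condition_means.get("day_to_day")
    if within is None or day is None:
        raise ValueError("within_session and day_to_day means are required")
    denom = day - within
    if denom <= 0:
        raise ValueError(
            "day-to-day distance does not exceed within-session distance; "
            "cohort is degenerate for normalization"
        )
    out: dict[str, float | None] = {}
    for key, value in condition_means.items():
        out[key] = None if value is None else (value - within) / denom
    return out
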