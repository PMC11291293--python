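"""Synthetic longitudinal pharmaco-fMRI cohorts with known planted effects.

This module generates parcellated BOLD-like time series for a densely
sampled crossover design: a handful of participants, each scanned over many
sessions spanning baseline visits, a stimulant control (methylphenidate,
MTP), a psychedelic (psilocybin) session, and follow-up visits.  Signals are
built from block-structured network covariance — every parcel loads on its
network's latent series, default-mode parcels share an anticorrelation drive
with task-positive networks at opposite sign — and the psilocybin condition
desynchronizes parcels from those latents.  All planted parameters are
returned in a truth record so downstream estimators can be checked against
ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.sparse import csr_matrix

__all__ = [
    "NETWORK_NAMES",
    "CohortConfig",
    "ParcelSet",
    "ScanRecord",
    "SubjectiveReport",
    "CohortTruth",
    "default_schedule",
    "make_parcel_set",
    "simulate_scan",
    "generate_cohort",
]

# The twelve canonical individual-defined networks tracked in the study
# design this generator emulates.  The first entry is the default-mode
# network (DMN); TASK_POSITIVE networks are those typically anticorrelated
# with it; MOTOR networks are the ones a stimulant perturbs.
NETWORK_NAMES = (
    "default_mode",
    "fronto_parietal",
    "dorsal_attention",
    "parietal_memory",
    "ventral_attention",
    "action_mode",
    "salience",
    "context",
    "visual",
    "somatomotor_lateral",
    "somatomotor_medial",
    "auditory",
)

TASK_POSITIVE = frozenset(
    {"fronto_parietal", "dorsal_attention", "salience", "action_mode"}
)
MOTOR = frozenset({"somatomotor_lateral", "somatomotor_medial", "action_mode"})

#: AR(1) coefficient for latent network series (BOLD-like autocorrelation).
AR_PHI = 0.4
#: Strength of the shared DMN/task-positive anticorrelation drive.
ANTICORR_GAMMA = 0.3


@dataclass(frozen=True)
class ParcelSet:
    """Parcel geometry: labels, spherical centroids and adjacency.

    Centroids live on the unit sphere (one hemisphere each side of the x=0
    plane, right hemisphere mirrored from the left).  ``adjacency`` is a
    symmetric boolean k-nearest-neighbour graph with no self edges.
    ``medial_wall`` marks parcels inside the medial cap; they keep a network
    label but are excluded from map statistics and may swallow rotated
    labels in the spin test.
    """

    parcel_ids: np.ndarray            # (n,) int
    network_labels: np.ndarray        # (n,) str
    hemisphere: np.ndarray            # (n,) "L" / "R"
    centroids: np.ndarray             # (n, 3) unit vectors
    adjacency: csr_matrix             # (n, n) symmetric, zero diagonal
    medial_wall: np.ndarray           # (n,) bool

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_ids)

    @property
    def networks(self) -> list[str]:
        seen: dict[str, None] = {}
        for name in self.network_labels:
            seen.setdefault(str(name), None)
        return list(seen)

    def network_mask(self, network: str) -> np.ndarray:
        return self.network_labels == network

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "parcel_id": self.parcel_ids,
                "network": self.network_labels,
                "hemisphere": self.hemisphere,
                "x": self.centroids[:, 0],
                "y": self.centroids[:, 1],
                "z": self.centroids[:, 2],
                "medial_wall": self.medial_wall.astype(int),
            }
        )

    def edge_list(self) -> np.ndarray:
        coo = self.adjacency.tocoo()
        mask = coo.row < coo.col
        return np.column_stack([coo.row[mask], coo.col[mask]])


@dataclass
class ScanRecord:
    """One 15-minute scan: a parcels × frames signal matrix plus design metadata."""

    participant_id: str
    session_id: str
    day_index: int
    condition: str                    # baseline | psilocybin | MTP | between | after
    task: bool
    mean_fd: float                    # mm
    signals: np.ndarray               # (n_parcels, frames)
    subchannels: np.ndarray | None = None        # (n_parcels * k, frames)
    subchannel_parcel: np.ndarray | None = None  # (n_parcels * k,) parcel index
    scan_index: int = 0

    @property
    def scan_id(self) -> str:
        kind = "task" if self.task else "rest"
        return (
            f"{self.participant_id}_{self.session_id}_{self.scan_index}_{kind}"
        )


@dataclass(frozen=True)
class SubjectiveReport:
    """MEQ30-style questionnaire outcome for one drug session (total 0–150)."""

    participant_id: str
    session_id: str
    meq30_total: float
    subscales: dict[str, float]


@dataclass
class CohortTruth:
    """Ground-truth planted parameters, for estimator-recovery tests."""

    config: "CohortConfig"
    hippocampus_parcel: int
    drug_effect_by_session: dict[tuple[str, str], float]
    emesis_session: tuple[str, str] | None
    schedule_by_participant: dict[str, dict[int, str]]


@dataclass(frozen=True)
class CohortConfig:
    """Study-design and effect-size knobs for :func:`generate_cohort`.

    Defaults mirror the longitudinal crossover design the generator
    emulates: 6 participants with ~18 MRI visits each, 510 frames per scan
    at TR 1.761 s.
    """

    n_participants: int = 6
    sessions_per_participant: int = 18
    scans_per_session: int = 3
    frames_per_scan: int = 510
    tr_seconds: float = 1.761
    n_parcels: int = 60
    n_networks: int = 12
    condition_schedule: dict[int, str] | None = None
    task_scan_indices: tuple[int, ...] = (2,)
    baseline_sync: float = 0.9
    drug_desync_strength: float = 0.6
    mtp_motor_effect: float = 0.25
    noise_sd: float = 1.0
    day_to_day_sd: float = 0.25
    participant_loading_sd: float = 0.5
    fd_baseline: float = 0.12
    fd_drug_increment: float = 0.08
    meq_coupling: float = 150.0
    meq_noise_sd: float = 8.0
    persistent_offset: float = 0.1
    emesis_outlier: bool = False
    n_subchannels: int = 0
    seed: int = 0

    def __post_init__(self):
        for name in (
            "n_participants",
            "sessions_per_participant",
            "scans_per_session",
            "frames_per_scan",
            "n_parcels",
            "n_networks",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive count")
        if not 0.0 <= self.drug_desync_strength <= 1.0:
            raise ValueError("drug_desync_strength must lie in [0, 1]")
        if not 0.0 <= self.baseline_sync <= 1.0:
            raise ValueError("baseline_sync must lie in [0, 1]")
        if self.condition_schedule is not None:
            missing = set(range(self.sessions_per_participant)) - set(
                self.condition_schedule
            )
            if missing:
                raise ValueError(
                    f"condition_schedule misses sessions {sorted(missing)}"
                )
        if any(
            i < 0 or i >= self.scans_per_session for i in self.task_scan_indices
        ):
            raise ValueError("task_scan_indices out of range")


def default_schedule(
    n_sessions: int, order: tuple[str, str] = ("MTP", "psilocybin")
) -> dict[int, str]:
    """Baseline block, first drug, between block, second drug, follow-up.

    Emulates a two-drug crossover: roughly the first third of sessions are
    baseline, one session per drug, a short between-drug washout and the
    remainder labelled ``after``.
    """
    if n_sessions < 5:
        raise ValueError("need at least 5 sessions for the crossover schedule")
    n_base = max(2, n_sessions // 3)
    n_between = max(1, (n_sessions - n_base - 2) // 3)
    schedule: dict[int, str] = {}
    for s in range(n_sessions):
        if s < n_base:
            schedule[s] = "baseline"
        elif s == n_base:
            schedule[s] = order[0]
        elif s < n_base + 1 + n_between:
            schedule[s] = "between"
        elif s == n_base + 1 + n_between:
            schedule[s] = order[1]
        else:
            schedule[s] = "after"
    return schedule


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """Quasi-uniform points on the x>0 half of the unit sphere."""
    i = np.arange(n) + 0.5
    # map onto half-sphere: polar angle from the +x axis in (0, pi/2)-ish band
    cos_t = i / n          # x in (0, 1)
    phi = np.pi * (1 + 5**0.5) * i
    sin_t = np.sqrt(1 - cos_t**2)
    pts = np.column_stack([cos_t, sin_t * np.cos(phi), sin_t * np.sin(phi)])
    return pts


def make_parcel_set(
    n_parcels: int,
    n_networks: int,
    seed: int,
    *,
    k_neighbors: int = 5,
    medial_cap_cos: float = 0.95,
) -> ParcelSet:
    """Build a two-hemisphere spherical parcellation with contiguous networks.

    Each hemisphere holds ``n_parcels // 2`` quasi-uniform centroids; network
    labels are grown as nearest-anchor patches so every network forms one
    contiguous territory per hemisphere (the geometry the spherical rotation
    null requires).  The right hemisphere is the x-mirror of the left.
    """
    if n_parcels < 2:
        raise ValueError("need at least 2 parcels")
    if n_parcels % 2:
        raise ValueError("n_parcels must be even (split across hemispheres)")
    if n_parcels < 2 * n_networks:
        raise ValueError(
            "n_parcels must be at least 2*n_networks so every network can "
            "appear on both hemispheres"
        )
    rng = np.random.default_rng(seed)
    n_h = n_parcels // 2
    left = _fibonacci_hemisphere(n_h)
    # random rotation about the x axis so different seeds give different maps
    theta = rng.uniform(0, 2 * np.pi)
    rot = np.array(
        [
            [1.0, 0.0, 0.0],
            [0.0, np.cos(theta), -np.sin(theta)],
            [0.0, np.sin(theta), np.cos(theta)],
        ]
    )
    left = left @ rot.T
    right = left * np.array([-1.0, 1.0, 1.0])

    # contiguous patches of near-equal size: anchor parcels get repeated
    # capacity slots and parcels are matched to the closest slot, so every
    # network holds floor/ceil(n_h / n_networks) parcels per hemisphere
    from scipy.optimize import linear_sum_assignment

    anchors = rng.choice(n_h, size=n_networks, replace=False)
    capacity = np.full(n_networks, n_h // n_networks)
    capacity[: n_h % n_networks] += 1
    slot_net = np.repeat(np.arange(n_networks), capacity)
    cost = -(left @ left[anchors].T)[:, slot_net]
    _, cols = linear_sum_assignment(cost)
    patch = slot_net[cols]
    names = [
        NETWORK_NAMES[i] if i < len(NETWORK_NAMES) else f"network_{i+1}"
        for i in range(n_networks)
    ]
    labels_h = np.array([names[p] for p in patch])

    centroids = np.vstack([left, right])
    labels = np.concatenate([labels_h, labels_h])
    hemisphere = np.array(["L"] * n_h + ["R"] * n_h)

    # medial wall: cap around the +x pole (mirrored on the right)
    medial_dir = np.where(hemisphere == "L", 1.0, -1.0)
    medial = centroids[:, 0] * medial_dir > medial_cap_cos

    k = min(k_neighbors, n_h - 1) if n_h > 1 else 0
    rows, cols = [], []
    for h_mask in (hemisphere == "L", hemisphere == "R"):
        idx = np.where(h_mask)[0]
        if k < 1:
            continue
        tree = cKDTree(centroids[idx])
        _, nn = tree.query(centroids[idx], k=k + 1)
        for a, neigh in zip(idx, nn):
            for b in neigh[1:]:
                rows.append(a)
                cols.append(idx[b])
    rows, cols = np.array(rows, dtype=int), np.array(cols, dtype=int)
    data = np.ones(len(rows))
    adj = csr_matrix((data, (rows, cols)), shape=(n_parcels, n_parcels))
    adj = ((adj + adj.T) > 0).astype(np.int8)
    adj.setdiag(0)
    adj.eliminate_zeros()

    return ParcelSet(
        parcel_ids=np.arange(n_parcels),
        network_labels=labels,
        hemisphere=hemisphere,
        centroids=centroids,
        adjacency=adj,
        medial_wall=medial,
    )


def _ar1(rng: np.random.Generator, n_series: int, frames: int, phi: float) -> np.ndarray:
    innov_sd = np.sqrt(1.0 - phi**2)
    x = np.empty((n_series, frames))
    x[:, 0] = rng.standard_normal(n_series)
    eps = rng.standard_normal((n_series, frames - 1)) * innov_sd
    for t in range(1, frames):
        x[:, t] = phi * x[:, t - 1] + eps[:, t - 1]
    return x


def simulate_scan(
    parcels: ParcelSet,
    condition: str,
    sync_level: float,
    noise_sd: float,
    frames: int,
    seed: int,
    *,
    gamma: float = ANTICORR_GAMMA,
    ar_phi: float = AR_PHI,
    loadings: np.ndarray | None = None,
    hippocampus_parcel: int | None = None,
    hippocampus_mix: float = 0.0,
    n_subchannels: int = 0,
    subchannel_noise_sd: float = 1.0,
    strict_rank: bool = False,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Simulate one parcels × frames BOLD-like matrix.

    Each parcel's series is ``sync_level * loading * (network latent ±
    gamma * anticorrelation drive) + noise``.  ``sync_level`` may be a
    scalar or a per-parcel vector (e.g. to desynchronize one network only).  Latents follow an AR(1) with
    coefficient ``ar_phi``.  Lowering ``sync_level`` detaches parcels from
    their shared latents — the desynchronization the psychedelic condition
    plants.  When ``n_subchannels`` > 0, a (parcels*k) × frames sub-channel
    matrix is also returned (each sub-channel re-expresses its parcel's
    composite at the same sync level with private noise) for parcel-level
    entropy analyses.

    Returns ``(signals, subchannels-or-None)``.
    """
    sync_level = np.asarray(sync_level, dtype=float)
    if np.any(sync_level < 0.0) or np.any(sync_level > 1.0):
        raise ValueError("sync_level must lie in [0, 1]")
    n = parcels.n_parcels
    if sync_level.ndim not in (0, 1) or (
        sync_level.ndim == 1 and sync_level.shape[0] != n
    ):
        raise ValueError("sync_level must be a scalar or a per-parcel vector")
    if frames < n:
        msg = f"frames ({frames}) < n_parcels ({n}): NGSC input will be rank-deficient"
        if strict_rank:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    rng = np.random.default_rng(seed)
    networks = parcels.networks
    net_index = {name: i for i, name in enumerate(networks)}
    latents = _ar1(rng, len(networks), frames, ar_phi)
    drive = _ar1(rng, 1, frames, ar_phi)[0]

    sign = np.zeros(n)
    for i, name in enumerate(parcels.network_labels):
        if name == "default_mode":
            sign[i] = 1.0
        elif name in TASK_POSITIVE:
            sign[i] = -1.0
    if loadings is None:
        loadings = np.ones(n)

    net_of = np.array([net_index[name] for name in parcels.network_labels])
    shared = latents[net_of] + sign[:, None] * gamma * drive[None, :]
    if hippocampus_parcel is not None and hippocampus_mix:
        # persistent-effect analogue: remix one parcel toward another
        # network's latent, shifting its seedmap without touching others
        other = (net_of[hippocampus_parcel] + 1) % len(networks)
        shared[hippocampus_parcel] = (1 - hippocampus_mix) * shared[
            hippocampus_parcel
        ] + hippocampus_mix * latents[other]
    sync_col = sync_level if sync_level.ndim == 0 else sync_level[:, None]
    clean = sync_col * loadings[:, None] * shared
    signals = clean + noise_sd * rng.standard_normal((n, frames))

    sub = None
    if n_subchannels > 0:
        k = n_subchannels
        sub_noise = subchannel_noise_sd * rng.standard_normal((n * k, frames))
        sub = np.repeat(clean, k, axis=0) + sub_noise
    return signals, sub


def _meq_subscales(rng: np.random.Generator, total: float) -> dict[str, float]:
    # subscale maxima follow the 30-item instrument's factor structure
    maxima = {"mystical": 75.0, "positive_mood": 30.0, "transcendence": 30.0,
              "ineffability": 15.0}
    frac = total / 150.0
    out = {}
    # shared draw makes subscales highly correlated (r > 0.8) across sessions
    shared = rng.normal(0.0, 0.04)
    for name, mx in maxima.items():
        noisy = np.clip(frac + shared + rng.normal(0.0, 0.025), 0.0, 1.0)
        out[name] = float(np.round(noisy * mx, 1))
    return out


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[ScanRecord], list[SubjectiveReport], ParcelSet, CohortTruth]:
    """Generate the full longitudinal cohort with planted effects.

    Per-participant crossover order alternates (even-index participants get
    MTP first).  Session-level network loadings jitter with scale
    ``day_to_day_sd`` (shared by scans within a session), psilocybin scans
    scale sync by ``1 - drug_desync_strength`` (with a per-session realized
    multiplier recorded in the truth record), MTP perturbs motor-network
    loadings only, and post-psilocybin sessions within 21 days remix the
    hippocampus-analogue parcel by ``persistent_offset``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    parcels = make_parcel_set(
        cfg.n_parcels, cfg.n_networks, seed=int(rng.integers(2**31))
    )
    # hippocampus analogue: a non-medial default-mode parcel
    dmn = np.where(
        (parcels.network_labels == "default_mode") & ~parcels.medial_wall
    )[0]
    hippo = int(dmn[0]) if len(dmn) else 0

    motor_mask = np.array(
        [name in MOTOR for name in parcels.network_labels]
    )

    scans: list[ScanRecord] = []
    reports: list[SubjectiveReport] = []
    drug_effects: dict[tuple[str, str], float] = {}
    schedules: dict[str, dict[int, str]] = {}
    emesis: tuple[str, str] | None = None

    psil_sessions: list[tuple[str, str]] = []
    for p in range(cfg.n_participants):
        pid = f"P{p + 1:02d}"
        if cfg.condition_schedule is not None:
            schedule = dict(cfg.condition_schedule)
        else:
            order = ("MTP", "psilocybin") if p % 2 == 0 else ("psilocybin", "MTP")
            schedule = default_schedule(cfg.sessions_per_participant, order)
        schedules[pid] = schedule
        for s, cond in schedule.items():
            if cond == "psilocybin":
                psil_sessions.append((pid, f"S{s + 1:02d}"))
    if cfg.emesis_outlier and psil_sessions:
        emesis = psil_sessions[int(rng.integers(len(psil_sessions)))]

    for p in range(cfg.n_participants):
        pid = f"P{p + 1:02d}"
        schedule = schedules[pid]
        # stable individual connectome: participant-specific parcel loadings
        base_loadings = 1.0 + cfg.participant_loading_sd * rng.standard_normal(
            cfg.n_parcels
        )
        psil_day = min(
            (s for s, c in schedule.items() if c == "psilocybin"), default=None
        )
        for s in range(cfg.sessions_per_participant):
            sid = f"S{s + 1:02d}"
            cond = schedule[s]
            day = 3 * s
            post_psil = (
                psil_day is not None
                and s > psil_day
                and (day - 3 * psil_day) <= 21
            )
            loadings = base_loadings + cfg.day_to_day_sd * rng.standard_normal(
                cfg.n_parcels
            )
            sync = cfg.baseline_sync
            effect = 0.0
            if cond == "psilocybin":
                mult = float(np.clip(rng.normal(1.0, 0.15), 0.3, 1.7))
                if emesis == (pid, sid):
                    mult *= 0.1
                effect = cfg.drug_desync_strength * mult
                effect = min(effect, 1.0)
                sync = cfg.baseline_sync * (1.0 - effect)
                drug_effects[(pid, sid)] = effect
            elif cond == "MTP":
                loadings = loadings + cfg.mtp_motor_effect * motor_mask * (
                    rng.standard_normal(cfg.n_parcels)
                )
                drug_effects[(pid, sid)] = 0.0
            hippo_mix = cfg.persistent_offset if post_psil else 0.0

            is_drug = cond in ("psilocybin", "MTP")
            base_fd = cfg.fd_baseline + (cfg.fd_drug_increment if is_drug else 0.0)
            for scan_i in range(cfg.scans_per_session):
                task = scan_i in cfg.task_scan_indices
                # task engagement attenuates the acute desynchronization
                sync_scan = sync
                if task and cond == "psilocybin":
                    sync_scan = cfg.baseline_sync * (1.0 - 0.5 * effect)
                mean_fd = float(max(base_fd + rng.normal(0.0, 0.02), 0.01))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    signals, sub = simulate_scan(
                        parcels,
                        cond,
                        sync_scan,
                        cfg.noise_sd,
                        cfg.frames_per_scan,
                        seed=int(rng.integers(2**31)),
                        loadings=loadings,
                        hippocampus_parcel=hippo,
                        hippocampus_mix=hippo_mix,
                        n_subchannels=cfg.n_subchannels,
                    )
                scans.append(
                    ScanRecord(
                        participant_id=pid,
                        session_id=sid,
                        day_index=day,
                        condition=cond,
                        task=task,
                        mean_fd=mean_fd,
                        signals=signals,
                        subchannels=sub,
                        subchannel_parcel=(
                            np.repeat(np.arange(cfg.n_parcels), cfg.n_subchannels)
                            if sub is not None
                            else None
                        ),
                        scan_index=scan_i,
                    )
                )
            if is_drug:
                total = float(
                    np.clip(
                        cfg.meq_coupling * drug_effects[(pid, sid)]
                        + rng.normal(0.0, cfg.meq_noise_sd),
                        0.0,
                        150.0,
                    )
                )
                reports.append(
                    SubjectiveReport(
                        participant_id=pid,
                        session_id=sid,
                        meq30_total=total,
                        subscales=_meq_subscales(rng, total),
                    )
                )

    truth = CohortTruth(
        config=cfg,
        hippocampus_parcel=hippo,
        drug_effect_by_session=drug_effects,
        emesis_session=emesis,
        schedule_by_participant=schedules,
    )
    return scans, reports, parcels, truth
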