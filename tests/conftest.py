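import numpy as np
import pandas as pd
import pytest

from desync.cohort import CohortConfig, generate_cohort, make_parcel_set


def small_config(**overrides) -> CohortConfig:
    """A compact cohort: 4 participants x 6 sessions x 2 rest scans."""
    defaults = dict(
        n_participants=4,
        sessions_per_participant=6,
        scans_per_session=2,
        frames_per_scan=80,
        n_parcels=30,
        n_networks=6,
        task_scan_indices=(),
        seed=7,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


#: Two-dose crossover schedule (8 sessions) used for embedding analyses:
#: more drug scans concentrate the shared drug direction in the embedding.
TWO_DOSE_SCHEDULE = {
    0: "baseline",
    1: "baseline",
    2: "MTP",
    3: "between",
    4: "psilocybin",
    5: "between",
    6: "psilocybin",
    7: "after",
}


def two_dose_config(**overrides):
    defaults = dict(
        n_participants=6,
        sessions_per_participant=8,
        frames_per_scan=120,
        condition_schedule=TWO_DOSE_SCHEDULE,
    )
    defaults.update(overrides)
    return small_config(**defaults)


@pytest.fixture(scope="session")
def two_dose_cohort():
    return generate_cohort(two_dose_config(seed=11))


@pytest.fixture(scope="session")
def two_dose_fcs(two_dose_cohort):
    from desync.connectivity import compute_fc

    scans, _, _, _ = two_dose_cohort
    return [compute_fc(s) for s in scans]


@pytest.fixture(scope="session")
def parcels24():
    return make_parcel_set(24, 4, seed=1)


@pytest.fixture(scope="session")
def small_cohort():
    """Cohort with the default planted desynchronization (0.6)."""
    return generate_cohort(small_config())


@pytest.fixture(scope="session")
def small_cohort_fcs(small_cohort):
    from desync.connectivity import compute_fc

    scans, reports, parcels, truth = small_cohort
    return [compute_fc(s) for s in scans]


def metadata_frame(scans) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "scan_id": [s.scan_id for s in scans],
            "participant": [s.participant_id for s in scans],
            "session": [s.session_id for s in scans],
            "day": [s.day_index for s in scans],
            "condition": [s.condition for s in scans],
            "task": [s.task for s in scans],
            "mean_fd": [s.mean_fd for s in scans],
        }
    )


def rng_seeds(base: int, n: int) -> np.ndarray:
    return np.random.default_rng(base).integers(0, 2**31, size=n)
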