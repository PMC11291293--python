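"""Wild bootstrap, TFCE graph enhancement and the spherical spin test."""

import numpy as np
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from desync.cohort import generate_cohort, make_parcel_set, simulate_scan
from desync.connectivity import compute_fc, fc_change_map
from desync.pipeline import _fc_change_maps
from desync.resampling import (
    _spin_assignment,
    rademacher_flips,
    random_rotation,
    spin_test,
    tfce,
    tfce_p_values,
    wild_bootstrap_map,
)

from conftest import metadata_frame, small_config


def tfce_brute_force(t, adj, E=0.5, H=2.0, dh=None):
    """Direct threshold-integration oracle (independent of the module path)."""
    t = np.asarray(t, float)
    adj = csr_matrix(adj)
    out = np.zeros_like(t)
    tmax = np.nanmax(t)
    if tmax <= 0:
        return out
    if dh is None:
        dh = tmax / 100.0
    n_steps = int(np.floor(tmax / dh + 1e-12))
    for k in range(1, n_steps + 1):
        h = k * dh
        supra = t >= h - 1e-12 * tmax
        if not supra.any():
            continue
        _, comp = connected_components(adj[supra][:, supra], directed=False)
        sizes = np.bincount(comp)
        idx = np.where(supra)[0]
        out[idx] += sizes[comp] ** E * h**H * dh
    return out


class TestRademacher:
    def test_values_and_reproducibility(self):
        a = rademacher_flips(1000, seed=3)
        b = rademacher_flips(1000, seed=3)
        assert np.array_equal(a, b)
        assert set(np.unique(a)) == {-1, 1}

    def test_mean_near_zero(self):
        flips = rademacher_flips(10**5, seed=4)
        assert abs(flips.mean()) < 0.01

    def test_rejects_nonpositive_n(self):
        with pytest.raises(ValueError):
            rademacher_flips(0, seed=1)


class TestTFCE:
    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(2, 11))
            A = (rng.random((n, n)) < 0.35).astype(int)
            A = ((A + A.T) > 0).astype(int)
            np.fill_diagonal(A, 0)
            t = rng.normal(0, 1.5, n)
            np.testing.assert_allclose(
                tfce(t, csr_matrix(A)),
                tfce_brute_force(t, csr_matrix(A)),
                atol=1e-9,
            )

    def test_isolated_parcel_analytic_sum(self):
        # sum_{k=1..20} 1 * (0.1 k)^2 * 0.1 = 2.87
        out = tfce(np.array([2.0]), csr_matrix((1, 1)), E=0.5, H=2.0, dh=0.1)
        assert out[0] == pytest.approx(2.87, abs=1e-9)

    def test_nonpositive_map_enhances_to_zero(self):
        adj = csr_matrix(np.array([[0, 1], [1, 0]]))
        out = tfce(np.array([-1.0, 0.0]), adj)
        np.testing.assert_array_equal(out, 0.0)

    def test_disconnected_equal_clusters_symmetric(self):
        A = np.zeros((6, 6), int)
        A[0, 1] = A[1, 2] = A[3, 4] = A[4, 5] = 1
        A = A + A.T
        t = np.array([1.0, 2.0, 1.0, 1.0, 2.0, 1.0])
        out = tfce(t, csr_matrix(A))
        np.testing.assert_allclose(out[:3], out[3:], atol=1e-12)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            tfce(np.array([]), csr_matrix((0, 0)))


class TestTFCEPValues:
    def test_extreme_orderings(self):
        null = np.random.default_rng(6).uniform(0, 1, size=(99, 5))
        below = np.zeros(5)
        above = np.full(5, 10.0)
        assert np.all(tfce_p_values(below, null) == 1.0)
        np.testing.assert_allclose(tfce_p_values(above, null), 1.0 / 100)

    def test_floor_is_one_over_b_plus_one(self):
        null = np.zeros((9, 3))
        p = tfce_p_values(np.ones(3), null)
        np.testing.assert_allclose(p, 0.1)


@pytest.fixture(scope="module")
def cohort_maps():
    scans, _, parcels, _ = generate_cohort(small_config(seed=42))
    fcs = [compute_fc(s) for s in scans]
    meta = metadata_frame(scans)
    maps, design = _fc_change_maps(meta, fcs)
    return maps, design, parcels


class TestWildBootstrap:
    def test_null_map_count_and_determinism(self, cohort_maps):
        maps, design, _ = cohort_maps
        a = wild_bootstrap_map(maps, design, B=25, seed=9)
        b = wild_bootstrap_map(maps, design, B=25, seed=9)
        assert a.null_t.shape == (25, maps.shape[1])
        np.testing.assert_array_equal(a.null_t, b.null_t)
        np.testing.assert_array_equal(a.t, b.t)

    def test_identity_flips_reconstruct_observed_data(self, cohort_maps):
        """All-plus-one flips rebuild y exactly from fitted + residuals."""
        from desync.inference import BalancedNestedLME, build_design

        maps, design, _ = cohort_maps
        X, names = build_design(design)
        keep = [j for j, n in enumerate(names) if n != "drug[psilocybin]"]
        reduced = BalancedNestedLME(
            X[:, keep],
            design["participant"].to_numpy(),
            design["session"].to_numpy(),
        )
        y = maps[:, 0]
        fit = reduced.fit(y)
        np.testing.assert_allclose(
            fit.fitted_marginal + fit.residuals, y, atol=1e-10
        )

    def test_null_t_distribution_centered(self, cohort_maps):
        maps, design, _ = cohort_maps
        sm = wild_bootstrap_map(maps, design, B=60, seed=10)
        assert abs(np.nanmean(sm.null_t)) < 0.15

    def test_observed_effect_detected_with_fwe_control(self, cohort_maps):
        maps, design, parcels = cohort_maps
        sm = wild_bootstrap_map(maps, design, B=99, seed=11)
        sm.tfce_pos = tfce(sm.t, parcels.adjacency)
        null_tfce = np.array(
            [tfce(row, parcels.adjacency) for row in sm.null_t]
        )
        p = tfce_p_values(sm.tfce_pos, null_tfce)
        assert p.min() <= 0.05  # planted desynchronization is detected
        assert np.all(p >= 1 / 100)

    def test_missing_drug_condition_rejected(self, cohort_maps):
        maps, design, _ = cohort_maps
        with pytest.raises(ValueError, match="no nothere"):
            wild_bootstrap_map(maps, design, B=5, seed=1,
                               contrast_condition="nothere")


class TestRandomRotation:
    def test_proper_orthonormal(self):
        for seed in range(10):
            R = random_rotation(seed)
            np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-12)
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)

    def test_isometry_on_centroids(self):
        ps = make_parcel_set(30, 3, seed=1)
        R = random_rotation(2)
        rotated = ps.centroids @ R.T
        before = ps.centroids @ ps.centroids.T
        after = rotated @ rotated.T
        np.testing.assert_allclose(before, after, atol=1e-9)


@pytest.fixture(scope="module")
def parcels():
    return make_parcel_set(40, 5, seed=13)


class TestSpinTest:
    def test_assignment_is_a_permutation(self, parcels):
        rng = np.random.default_rng(3)
        left = parcels.centroids[parcels.hemisphere == "L"]
        for _ in range(25):
            src = _spin_assignment(left, random_rotation(rng))
            assert sorted(src) == list(range(len(left)))

    def test_label_counts_preserved_every_permutation(self, parcels):
        # a permutation of sources implies preserved label counts
        rng = np.random.default_rng(4)
        labels = parcels.network_labels
        left = np.where(parcels.hemisphere == "L")[0]
        base = np.unique(labels[left], return_counts=True)
        for _ in range(25):
            src = _spin_assignment(
                parcels.centroids[left], random_rotation(rng)
            )
            rotated = labels[left][src]
            rot_counts = np.unique(rotated, return_counts=True)
            assert np.array_equal(base[0], rot_counts[0])
            assert np.array_equal(base[1], rot_counts[1])

    def test_constant_map_shows_no_specificity(self, parcels):
        res = spin_test(np.ones(40), parcels, n_perm=50, seed=5)
        for net in res.networks:
            assert res.p[net] == 1.0

    def test_indicator_map_maximal_significance(self, parcels):
        target = parcels.networks[0]
        values = parcels.network_mask(target).astype(float)
        res = spin_test(values, parcels, n_perm=99, seed=6)
        # a few patch-preserving (near-identity) rotations can tie with the
        # observed mean, so the p-value sits at or just above its floor
        assert res.p[target] <= 0.05
        assert res.p[target] >= 1 / 100

    def test_deterministic_given_seed(self, parcels):
        v = np.random.default_rng(7).uniform(0, 1, 40)
        a = spin_test(v, parcels, n_perm=30, seed=8)
        b = spin_test(v, parcels, n_perm=30, seed=8)
        for net in a.networks:
            np.testing.assert_array_equal(a.null[net], b.null[net])
            assert a.p[net] == b.p[net]

    def test_planted_network_effect_detected(self):
        """Desynchronizing only the DMN-analogue network must yield a small
        spin-test p for that network."""
        parcels = make_parcel_set(120, 12, seed=20)
        dmn = parcels.network_mask("default_mode")
        sync_drug = np.full(120, 0.9)
        sync_drug[dmn] = 0.05
        base_fcs = [
            compute_fc(
                simulate_scan(parcels, "baseline", 0.9, 1.0, 510, seed=s)[0]
            )
            for s in range(6)
        ]
        drug_maps = [
            fc_change_map(
                compute_fc(
                    simulate_scan(
                        parcels, "psilocybin", sync_drug, 1.0, 510, seed=10 + s
                    )[0]
                ),
                base_fcs,
            ).values
            for s in range(4)
        ]
        res = spin_test(np.mean(drug_maps, axis=0), parcels, n_perm=99, seed=9)
        assert res.p["default_mode"] < 0.05
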