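"""FC matrices, seedmaps, FC-change distances and condition normalization."""

import numpy as np
import pytest

from desync.cohort import ScanRecord, make_parcel_set, simulate_scan
from desync.connectivity import (
    censor_mask_from_fd,
    compute_fc,
    condition_fc_change,
    fc_change_map,
    normalize_fc_change,
    scan_distance_matrix,
    seedmap,
    whole_brain_fc_change,
)

from conftest import metadata_frame, small_config


def _scan(signals, participant="P01", session="S01", condition="baseline",
          task=False, fd=0.1):
    return ScanRecord(
        participant_id=participant,
        session_id=session,
        day_index=0,
        condition=condition,
        task=task,
        mean_fd=fd,
        signals=np.asarray(signals, float),
    )


class TestComputeFC:
    def test_hand_computed_zero_correlation(self):
        x = [0, 1, 0, 1]
        y = [0, 1, 1, 0]
        z = [0, 1, 2, 3.5]
        fc = compute_fc(np.array([x, y, z]))
        assert fc.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_identical_series_clipped_finite(self):
        x = np.array([0.0, 1.0, 0.5, 2.0])
        fc = compute_fc(np.vstack([x, x, x + 1]))
        expected = np.arctanh(1 - 1e-7)
        assert fc.values[0, 1] == pytest.approx(expected)
        assert np.isfinite(fc.values).all()

    def test_parcel_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        sig = rng.standard_normal((6, 40))
        perm = rng.permutation(6)
        a = compute_fc(sig).values
        b = compute_fc(sig[perm]).values
        np.testing.assert_allclose(b, a[np.ix_(perm, perm)], atol=1e-12)

    def test_constant_series_flagged_not_silent(self):
        sig = np.vstack([np.zeros(10), np.arange(10), np.arange(10) ** 2])
        fc = compute_fc(sig)
        assert fc.flagged_parcels == [0]
        assert np.isnan(fc.values[0, 1])
        assert np.isfinite(fc.values[1, 2])

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError, match="3 retained frames"):
            compute_fc(np.random.default_rng(1).standard_normal((4, 2)))

    def test_censor_mask_applied_before_correlation(self):
        rng = np.random.default_rng(2)
        sig = rng.standard_normal((4, 50))
        fd = np.full(50, 0.1)
        fd[10:20] = 0.5
        mask = censor_mask_from_fd(fd)
        assert mask.sum() == 40
        fc = compute_fc(_scan(sig), censor_mask=mask)
        direct = compute_fc(sig[:, mask])
        np.testing.assert_allclose(fc.values, direct.values)


class TestSeedmap:
    def test_row_equals_column_and_length(self):
        fc = compute_fc(np.random.default_rng(3).standard_normal((5, 30)))
        sm = seedmap(fc, 2)
        assert sm.shape == (4,)
        np.testing.assert_allclose(
            sm, np.delete(fc.values[:, 2], 2), atol=1e-12
        )

    def test_missing_parcel_rejected(self):
        fc = compute_fc(np.random.default_rng(3).standard_normal((5, 30)))
        with pytest.raises(IndexError):
            seedmap(fc, 7)


class TestFCChangeMap:
    def test_identical_scans_give_zero_map(self):
        sig = np.random.default_rng(4).standard_normal((6, 40))
        a = compute_fc(_scan(sig))
        b = compute_fc(_scan(sig, session="S02"))
        fcm = fc_change_map(a, [b])
        np.testing.assert_allclose(fcm.values, 0.0, atol=1e-12)

    def test_toy_euclidean_example(self):
        # 3 parcels; one parcel's seedmap differs by (0.3, 0.4) -> 0.5
        base = np.zeros((3, 3))
        other = base.copy()
        other[0, 1] = other[1, 0] = 0.3
        other[0, 2] = other[2, 0] = 0.4
        a = compute_fc(np.random.default_rng(0).standard_normal((3, 30)))
        a.values = base
        b = compute_fc(np.random.default_rng(1).standard_normal((3, 30)))
        b.values = other
        a.scan = b.scan = None
        fcm = fc_change_map(a, [b], metric="euclidean")
        assert fcm.values[0] == pytest.approx(0.5)

    def test_mean_of_distances_not_distance_to_mean(self):
        rng = np.random.default_rng(5)
        sig = rng.standard_normal((5, 60))
        scan_fc = compute_fc(_scan(sig))
        b1 = compute_fc(_scan(rng.standard_normal((5, 60)), session="S02"))
        b2 = compute_fc(_scan(rng.standard_normal((5, 60)), session="S03"))
        fcm = fc_change_map(scan_fc, [b1, b2])
        d1 = fc_change_map(scan_fc, [b1]).values
        d2 = fc_change_map(scan_fc, [b2]).values
        np.testing.assert_allclose(fcm.values, (d1 + d2) / 2, atol=1e-12)

    def test_same_session_exclusion_can_empty_baselines(self):
        sig = np.random.default_rng(6).standard_normal((4, 40))
        a = compute_fc(_scan(sig))
        b = compute_fc(_scan(sig))  # same participant + session
        with pytest.raises(ValueError, match="no eligible baseline"):
            fc_change_map(a, [b])


class TestWholeBrainFCChange:
    def test_identical_matrices_zero(self):
        fc = compute_fc(np.random.default_rng(7).standard_normal((6, 50)))
        assert whole_brain_fc_change(fc, fc) == 0.0

    def test_single_edge_difference(self):
        a = np.zeros((3, 3))
        b = a.copy()
        b[0, 1] = b[1, 0] = 0.3
        assert whole_brain_fc_change(a, b) == pytest.approx(
            np.sqrt(0.09 / 3), abs=1e-9
        )

    def test_scaling_matches_brute_force(self):
        rng = np.random.default_rng(8)
        z = rng.standard_normal((5, 5))
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0.0)
        for c in (0.5, 2.0, -1.0):
            iu = np.triu_indices(5, k=1)
            brute = np.sqrt(np.mean((c * z[iu] - z[iu]) ** 2))
            assert whole_brain_fc_change(c * z, z) == pytest.approx(brute)
            rms = np.sqrt(np.mean(z[iu] ** 2))
            assert brute == pytest.approx(abs(c - 1) * rms)

    def test_pseudometric_on_random_scans(self, parcels24):
        fcs = [
            compute_fc(
                simulate_scan(parcels24, "baseline", 0.7, 1.0, 60, seed=s)[0]
            )
            for s in range(20)
        ]
        d = np.array(
            [[whole_brain_fc_change(a, b) for b in fcs] for a in fcs]
        )
        np.testing.assert_allclose(d, d.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(d), 0.0, atol=1e-12)
        for i in range(20):
            for j in range(20):
                for k in range(20):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9

    def test_rms_map_aggregation_consistent_with_whole_brain(self, parcels24):
        a = compute_fc(
            simulate_scan(parcels24, "baseline", 0.8, 1.0, 80, seed=1)[0]
        )
        b = compute_fc(
            simulate_scan(parcels24, "baseline", 0.8, 1.0, 80, seed=2)[0]
        )
        b.scan = _scan(np.zeros((24, 4)), session="S09")
        fcm = fc_change_map(a, [b])
        rms_over_parcels = np.sqrt(np.mean(fcm.values**2))
        wb = whole_brain_fc_change(a, b)
        assert abs(rms_over_parcels - wb) / wb < 0.10


class TestScanDistanceMatrix:
    def test_matches_pairwise_loop_oracle(self, small_cohort_fcs):
        fcs = small_cohort_fcs[:10]
        sdm = scan_distance_matrix(fcs)
        for i in range(10):
            for j in range(10):
                expected = (
                    0.0 if i == j else whole_brain_fc_change(fcs[i], fcs[j])
                )
                assert sdm.values[i, j] == pytest.approx(expected, abs=1e-9)

    def test_duplicated_scan_zero_distance(self):
        sig = np.random.default_rng(9).standard_normal((5, 50))
        fc = compute_fc(_scan(sig))
        sdm = scan_distance_matrix([fc, fc, compute_fc(_scan(sig * 2 + 1))])
        assert sdm.values[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_heterogeneous_parcel_sets_rejected(self):
        a = compute_fc(np.random.default_rng(0).standard_normal((4, 30)))
        b = compute_fc(np.random.default_rng(0).standard_normal((5, 30)))
        with pytest.raises(ValueError, match="heterogeneous"):
            scan_distance_matrix([a, b])


class TestConditionAggregation:
    def test_identical_scans_all_zero(self):
        sig = np.random.default_rng(10).standard_normal((5, 50))
        fcs = []
        for p in ("P01", "P02"):
            for s in ("S01", "S02"):
                for _ in range(2):
                    fcs.append(compute_fc(_scan(sig, participant=p, session=s)))
        means = condition_fc_change(scan_distance_matrix(fcs))
        assert means["within_session"] == pytest.approx(0.0, abs=1e-7)
        assert means["day_to_day"] == pytest.approx(0.0, abs=1e-7)
        assert means["between_person"] == pytest.approx(0.0, abs=1e-7)

    def test_single_participant_has_no_between_person(self):
        rng = np.random.default_rng(11)
        fcs = [
            compute_fc(
                _scan(rng.standard_normal((4, 40)), session=f"S{k}")
            )
            for k in range(4)
        ]
        means = condition_fc_change(scan_distance_matrix(fcs))
        assert means["between_person"] is None

    def test_null_cohort_drug_close_to_day_to_day(self):
        from desync.cohort import generate_cohort

        cfg = small_config(
            drug_desync_strength=0.0, fd_drug_increment=0.0, seed=77
        )
        scans, _, _, _ = generate_cohort(cfg)
        means = condition_fc_change(
            scan_distance_matrix([compute_fc(s) for s in scans])
        )
        ratio = means["psilocybin"] / means["day_to_day"]
        assert 0.8 < ratio < 1.25


class TestNormalization:
    def test_day_to_day_maps_to_one_within_to_zero(self, small_cohort_fcs):
        means = condition_fc_change(scan_distance_matrix(small_cohort_fcs))
        norm = normalize_fc_change(means)
        assert norm["day_to_day"] == 1.0
        assert norm["within_session"] == 0.0

    def test_arithmetic_example(self):
        norm = normalize_fc_change(
            {"within_session": 0.1, "day_to_day": 0.3, "psilocybin": 0.8}
        )
        assert norm["psilocybin"] == pytest.approx(3.5)

    def test_degenerate_cohort_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            normalize_fc_change({"within_session": 0.3, "day_to_day": 0.3})

    def test_psilocybin_exceeds_mtp_across_cohorts(self):
        """Planted desynchronization (0.6) must dominate the motor-only
        stimulant perturbation in nearly every simulated cohort."""
        from desync.cohort import generate_cohort

        wins = 0
        n_cohorts = 100
        for seed in range(n_cohorts):
            cfg = small_config(
                n_participants=2,
                sessions_per_participant=5,
                frames_per_scan=60,
                n_parcels=20,
                n_networks=4,
                seed=1000 + seed,
            )
            scans, _, _, _ = generate_cohort(cfg)
            means = condition_fc_change(
                scan_distance_matrix([compute_fc(s) for s in scans])
            )
            # raw-mean comparison orders identically to normalized scores
            if means["psilocybin"] > means["MTP"]:
                wins += 1
        assert wins >= 95
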