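"""Synthetic cohort generator: parcellation, covariance, motion, behavior."""

import numpy as np
import pandas as pd
import pytest

from hubdegree import (
    CohortModel,
    attach_behavior,
    block_covariance,
    calibrate_behavior_noise,
    make_parcellation,
    simulate_cohort,
    simulate_subject,
)
from hubdegree.connectivity import framewise_displacement
from hubdegree.simulate import DEFAULT_NETWORK_SIZES, NETWORK_LABELS, study_model


class TestMakeParcellation:
    def test_contiguous_assignment(self):
        p = make_parcellation(4, {"DMN": 2, "VAN": 2}, seed=0)
        assert list(p["network"]) == ["DMN", "DMN", "VAN", "VAN"]
        assert list(p["parcel_id"]) == [1, 2, 3, 4]

    def test_default_full_parcellation(self):
        p = make_parcellation(seed=0)
        assert len(p) == 333
        assert set(p["network"]) == set(DEFAULT_NETWORK_SIZES)
        assert set(p["network"]) <= set(NETWORK_LABELS)
        assert len(set(p["network"])) == 13

    def test_determinism(self):
        p1 = make_parcellation(seed=7)
        p2 = make_parcellation(seed=7)
        pd.testing.assert_frame_equal(p1, p2)

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            make_parcellation(5, {"DMN": 2, "VAN": 2}, seed=0)


class TestBlockCovariance:
    def test_block_structure(self):
        m = CohortModel(
            n_controls=2, n_patients=2,
            network_sizes={"DMN": 3, "VAN": 3},
            rho_within=0.4, rho_between=0.1,
        )
        S = block_covariance(m, "control")
        assert S[0, 1] == pytest.approx(0.4, abs=1e-6)
        assert S[0, 4] == pytest.approx(0.1, abs=1e-6)
        np.testing.assert_allclose(np.diag(S), 1.0, atol=1e-6)

    def test_hub_boost_and_group_offset(self):
        m = CohortModel(
            n_controls=2, n_patients=2,
            network_sizes={"DMN": 4, "VAN": 4},
            rho_within=0.3, rho_between=0.05,
            hub_parcels=(1,), rho_hub=0.2, group_delta=0.1,
        )
        Sc = block_covariance(m, "control")
        Sp = block_covariance(m, "patient")
        assert Sc[0, 5] == pytest.approx(0.2, abs=0.02)
        assert Sp[0, 5] == pytest.approx(0.3, abs=0.02)

    def test_psd_after_repair(self):
        m = CohortModel(
            n_controls=2, n_patients=2,
            network_sizes={"DMN": 5, "VAN": 5},
            hub_parcels=(1, 2, 3), rho_hub=0.6, group_delta=0.3,
        )
        S = block_covariance(m, "patient")
        assert np.linalg.eigvalsh(S).min() >= 0

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError):
            CohortModel(rho_within=0.2, rho_between=0.5).validate()
        with pytest.raises(ValueError):
            CohortModel(hub_parcels=(1,), rho_hub=0.9, group_delta=0.2).validate()


class TestSimulateSubject:
    def test_independent_parcels_uncorrelated(self):
        m = CohortModel(
            n_controls=2, n_patients=2,
            network_sizes={"DMN": 3, "VAN": 3},
            rho_within=0.0, rho_between=0.0, n_volumes=2000,
        )
        ts, _ = simulate_subject(m, "control", seed=0)
        r = np.corrcoef(ts, rowvar=False)
        off = r[np.triu_indices(6, 1)]
        assert np.max(np.abs(off)) < 3 / np.sqrt(2000)

    def test_sample_correlations_converge_to_blocks(self):
        m = CohortModel(
            n_controls=2, n_patients=2,
            network_sizes={"DMN": 5, "VAN": 5},
            rho_within=0.5, rho_between=0.1, n_volumes=5000,
        )
        ts, _ = simulate_subject(m, "control", seed=1)
        r = np.corrcoef(ts, rowvar=False)
        within = np.concatenate([r[:5, :5][np.triu_indices(5, 1)],
                                 r[5:, 5:][np.triu_indices(5, 1)]])
        between = r[:5, 5:].ravel()
        assert within.mean() == pytest.approx(0.5, abs=0.05)
        assert between.mean() == pytest.approx(0.1, abs=0.05)

    def test_no_spikes_means_no_scrubbing(self):
        m = CohortModel(
            n_controls=2, n_patients=2,
            network_sizes={"DMN": 3, "VAN": 3},
            spike_rate=0.0, n_volumes=300,
        )
        _, motion = simulate_subject(m, "control", seed=2)
        fd = framewise_displacement(motion)
        assert np.all(fd.fd <= 0.5)

    def test_spikes_exceed_scrub_threshold(self):
        m = CohortModel(
            n_controls=2, n_patients=2,
            network_sizes={"DMN": 3, "VAN": 3},
            spike_rate=0.05, n_volumes=500,
        )
        _, motion = simulate_subject(m, "control", seed=3)
        fd = framewise_displacement(motion)
        assert np.sum(fd.fd > 0.5) >= 5  # ~25 expected

    def test_determinism(self):
        m = CohortModel(n_controls=2, n_patients=2,
                        network_sizes={"DMN": 3, "VAN": 3}, n_volumes=50)
        ts1, mo1 = simulate_subject(m, "patient", seed=9)
        ts2, mo2 = simulate_subject(m, "patient", seed=9)
        np.testing.assert_array_equal(ts1, ts2)
        np.testing.assert_array_equal(mo1, mo2)


class TestAttachBehavior:
    def _degrees(self, n, p, rng):
        return pd.DataFrame(
            rng.standard_normal((n, p)) * 2 + 10,
            index=pd.Index([f"s{i}" for i in range(n)], name="subject_id"),
            columns=range(1, p + 1),
        )

    def test_beta_zero_independent_of_degree(self):
        rng = np.random.default_rng(0)
        deg = self._degrees(200, 3, rng)
        m = CohortModel(n_controls=100, n_patients=100,
                        network_sizes={"DMN": 2, "VAN": 1}, beta=0.0)
        behav = attach_behavior(deg, ["control"] * 100 + ["patient"] * 100, m, 1)
        r = np.corrcoef(deg[1], behav["acc_combined"])[0, 1]
        assert abs(r) < 0.2

    def test_noise_free_coupling_is_exactly_linear(self):
        rng = np.random.default_rng(1)
        deg = self._degrees(30, 3, rng)
        m = CohortModel(
            n_controls=15, n_patients=15,
            network_sizes={"DMN": 2, "VAN": 1},
            coupling_parcels=(2,), beta=1.0, sigma_y=0.0,
            load_noise_sd=0.0, patient_accuracy_offset=0.0,
            accuracy_intercept=50.0,
        )
        behav = attach_behavior(deg, ["control"] * 15 + ["patient"] * 15, m, 2)
        r = np.corrcoef(deg[2], behav["acc_combined"])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_calibrated_r2_yields_expected_correlation_range(self):
        rng = np.random.default_rng(2)
        hits = 0
        n_rep = 200
        for i in range(n_rep):
            score = rng.standard_normal(60) * 3
            sigma = calibrate_behavior_noise(score, beta=1.0, target_r2=0.25)
            y = score + rng.normal(0, sigma, 60)
            r = np.corrcoef(score, y)[0, 1]
            hits += 0.3 <= r <= 0.7
        assert hits / n_rep >= 0.95

    def test_empty_coupling_with_beta_rejected(self):
        m = CohortModel(n_controls=2, n_patients=2,
                        network_sizes={"DMN": 2, "VAN": 1},
                        beta=1.0, coupling_parcels=())
        with pytest.raises(ValueError):
            m.validate()

    def test_accuracy_bounds_and_combined_consistency(self):
        rng = np.random.default_rng(3)
        deg = self._degrees(40, 3, rng)
        m = CohortModel(n_controls=20, n_patients=20,
                        network_sizes={"DMN": 2, "VAN": 1})
        behav = attach_behavior(deg, ["control"] * 20 + ["patient"] * 20, m, 4)
        acc_cols = [f"acc_{l}" for l in (1, 3, 5, 7)]
        assert ((behav[acc_cols] >= 0) & (behav[acc_cols] <= 100)).all().all()
        np.testing.assert_allclose(
            behav["acc_combined"], behav[acc_cols].mean(axis=1)
        )


class TestCohort:
    def test_cohort_determinism(self, small_model):
        c1 = simulate_cohort(small_model, seed=5)
        c2 = simulate_cohort(small_model, seed=5)
        pd.testing.assert_frame_equal(c1.behavior, c2.behavior)
        for sid in c1.subjects:
            np.testing.assert_array_equal(c1.timeseries[sid], c2.timeseries[sid])
            np.testing.assert_array_equal(c1.motion[sid], c2.motion[sid])

    def test_hub_groups_differ_in_expected_degree(self):
        """Boosted hub correlations raise mean composite hub degree.

        Measured on raw connectivity: the planted covariance effect is a
        generator property, checked before confound regression (global
        signal removal can redistribute group differences downstream).
        """
        from hubdegree import composite_degree, connectivity_matrix

        m = CohortModel(
            n_controls=30, n_patients=30,
            network_sizes={"DMN": 10, "VAN": 10, "FPN": 10, "UA": 10},
            n_volumes=150,
            hub_parcels=(3, 17), group_delta=0.12,
        )
        c = simulate_cohort(m, seed=6)
        g = np.array([c.groups[s] for s in c.subjects])
        K = np.stack([
            composite_degree(connectivity_matrix(c.timeseries[s]), m.densities)
            for s in c.subjects
        ])
        for h in m.hub_parcels:
            k = K[:, h - 1]
            assert k[g == "patient"].mean() > k[g == "control"].mean()

    def test_study_model_defaults(self):
        m = study_model()
        assert m.n_controls == m.n_patients == 29
        assert m.n_parcels == 333
        assert m.target_r2 == 0.25
        m.validate()
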