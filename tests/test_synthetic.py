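import numpy as np
import pytest

from braingraph.synthetic import (
    CohortSpec,
    CovarianceSpec,
    SubjectRecord,
    build_covariance,
    cohort_metadata,
    perturb_covariance,
    simulate_cohort,
    simulate_subject,
)


class TestBuildCovariance:
    def test_block_structure_forced_by_construction(self):
        cov = build_covariance(
            CovarianceSpec(n_rois=4, n_modules=2, within_corr=0.6, between_corr=0.1)
        )
        assert cov[0, 1] == cov[2, 3] == 0.6
        assert cov[0, 2] == cov[0, 3] == cov[1, 2] == cov[1, 3] == 0.1
        assert np.all(np.diag(cov) == 1.0)
        assert np.array_equal(cov, cov.T)

    def test_zero_correlations_give_identity(self):
        cov = build_covariance(
            CovarianceSpec(n_rois=5, n_modules=2, within_corr=0.0, between_corr=0.0)
        )
        assert np.array_equal(cov, np.eye(5))

    def test_default_90_roi_matrix_is_positive_definite(self):
        cov = build_covariance(
            CovarianceSpec(n_rois=90, n_modules=6, within_corr=0.5, between_corr=0.1)
        )
        # independent eigen-decomposition check
        assert np.linalg.eigvalsh(cov)[0] > 0

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            CovarianceSpec(within_corr=0.2, between_corr=0.5)
        with pytest.raises(ValueError):
            CovarianceSpec(n_rois=4, n_modules=9)


class TestPerturbCovariance:
    def test_zero_delta_is_identity(self):
        base = build_covariance(CovarianceSpec(n_rois=10, n_modules=2))
        out = perturb_covariance(base, [((1, 2), 0.0)])
        assert np.array_equal(out, base)

    def test_delta_applied_symmetrically(self):
        base = build_covariance(CovarianceSpec(n_rois=10, n_modules=2))
        r12 = base[1, 2]
        out = perturb_covariance(base, [((1, 2), 0.3)])
        assert out[1, 2] == out[2, 1] == pytest.approx(r12 + 0.3)
        mask = np.ones_like(base, dtype=bool)
        mask[1, 2] = mask[2, 1] = False
        assert np.array_equal(out[mask], base[mask])

    def test_delta_beyond_unit_correlation_raises(self):
        base = build_covariance(CovarianceSpec(n_rois=6, n_modules=2))
        with pytest.raises(ValueError, match=">= 1"):
            perturb_covariance(base, [((0, 1), 0.9)])

    def test_nonpd_result_repaired_with_warning(self):
        # a -0.3 path implant on a dense 0.5 block loses PD-ness
        base = build_covariance(
            CovarianceSpec(n_rois=90, n_modules=6, within_corr=0.5)
        )
        deltas = [((i, i + 1), -0.3) for i in range(10)]
        with pytest.warns(UserWarning, match="repaired"):
            out = perturb_covariance(base, deltas)
        assert np.linalg.eigvalsh(out)[0] > 0
        # implanted entries still close to the requested values
        for i in range(10):
            assert out[i, i + 1] == pytest.approx(0.2, abs=0.02)

    def test_implanted_deltas_recovered_in_long_simulation(self):
        # Monte-Carlo oracle: sample correlations from 10,000 time points
        # shift by ~ -0.3 relative to the unperturbed matrix
        base = build_covariance(
            CovarianceSpec(n_rois=30, n_modules=2, within_corr=0.5)
        )
        deltas = [((i, i + 1), -0.3) for i in range(10)]
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            pert = perturb_covariance(base, deltas)
        ts, _ = simulate_subject(pert, n_timepoints=10_000, seed=3)
        sample = np.corrcoef(ts.values, rowvar=False)
        for (i, j), _ in deltas:
            assert sample[i, j] - base[i, j] == pytest.approx(-0.3, abs=0.05)


class TestSimulateSubject:
    def test_identity_covariance_gives_near_zero_correlations(self):
        ts, _ = simulate_subject(np.eye(20), n_timepoints=5000, seed=0)
        r = np.corrcoef(ts.values, rowvar=False)
        off = r[~np.eye(20, dtype=bool)]
        assert np.abs(off).max() < 0.06
        assert np.abs(off).mean() < 0.02

    def test_target_correlation_recovered(self):
        cov = np.eye(4)
        cov[0, 1] = cov[1, 0] = 0.6
        ts, _ = simulate_subject(cov, n_timepoints=5000, seed=1)
        r = np.corrcoef(ts.values[:, 0], ts.values[:, 1])[0, 1]
        assert 0.55 <= r <= 0.65

    def test_same_seed_is_bit_identical(self):
        a, na = simulate_subject(np.eye(5), n_timepoints=50, seed=42)
        b, nb = simulate_subject(np.eye(5), n_timepoints=50, seed=42)
        assert np.array_equal(a.values, b.values)
        assert na.equals(nb)

    def test_nuisance_table_has_nine_columns(self):
        _, nuis = simulate_subject(np.eye(5), n_timepoints=50, seed=0)
        assert nuis.shape == (50, 9)
        assert list(nuis.columns[:6]) == [
            "motion_tx", "motion_ty", "motion_tz",
            "motion_rx", "motion_ry", "motion_rz",
        ]

    def test_short_series_warns_about_rank_deficiency(self):
        with pytest.warns(UserWarning, match="rank deficient"):
            simulate_subject(np.eye(30), n_timepoints=20, seed=0)


class TestSimulateCohort:
    def test_default_cohort_size_and_groups(self):
        cohort = simulate_cohort(CohortSpec(seed=0, n_timepoints=30,
                                            covariance=CovarianceSpec(n_rois=12, n_modules=2),
                                            implanted_component=((0, 1),),
                                            duration_link=None))
        assert len(cohort) == 32
        assert sum(s.record.group == "case" for s in cohort) == 17

    def test_metadata_invariants(self, small_cohort):
        _, cohort = small_cohort
        meta = cohort_metadata(cohort)
        cases = meta[meta.group == "case"]
        controls = meta[meta.group == "control"]
        assert (cases.duration_of_use > 0).all()
        assert controls.duration_of_use.isna().all()
        assert cases.age.between(26, 50).all()
        assert controls.age.between(20, 46).all()

    def test_determinism_under_seed(self, small_cohort):
        spec, cohort = small_cohort
        again = simulate_cohort(spec)
        for a, b in zip(cohort, again):
            assert a.record == b.record
            assert np.array_equal(a.timeseries.values, b.timeseries.values)

    def test_null_cohort_groups_share_covariance(self):
        spec = CohortSpec(
            covariance=CovarianceSpec(n_rois=12, n_modules=2),
            implanted_component=(),
            group_effect=(),
            duration_link=None,
            n_per_group=(3, 3),
            n_timepoints=30,
            seed=5,
        )
        assert spec.case_deltas() == []

    def test_disconnected_implant_rejected(self):
        with pytest.raises(ValueError, match="connected"):
            CohortSpec(implanted_component=((0, 1), (5, 6)))

    def test_duration_link_drives_node_connectivity(self):
        # Monte-Carlo oracle at T=5000: across case subjects, duration and
        # the linked node's mean connectivity correlate positively
        spec = CohortSpec(
            covariance=CovarianceSpec(n_rois=20, n_modules=2),
            n_per_group=(12, 2),
            n_timepoints=5000,
            implanted_component=(),
            duration_link=(3, 0.025),
            seed=2,
        )
        cohort = simulate_cohort(spec)
        cases = [s for s in cohort if s.record.group == "case"]
        conn = [
            np.abs(np.corrcoef(s.timeseries.values, rowvar=False))[3].mean()
            for s in cases
        ]
        dur = [s.record.duration_of_use for s in cases]
        assert np.corrcoef(dur, conn)[0, 1] > 0.5


class TestSubjectRecord:
    def test_case_requires_duration(self):
        with pytest.raises(ValueError, match="duration"):
            SubjectRecord("s1", "case", 30.0, "M", 10.0, duration_of_use=None)

    def test_control_must_not_have_duration(self):
        with pytest.raises(ValueError):
            SubjectRecord("s1", "control", 30.0, "M", 10.0, duration_of_use=5.0)
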