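import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcpain.errors import InvalidParameterError
from mcpain.simulate import (
    CohortSpec,
    gaussian_symmetric_kl,
    generate_cohort,
    planted_matching,
)

finite = st.floats(min_value=-50, max_value=50)
positive = st.floats(min_value=0.05, max_value=20)


class TestGaussianSymmetricKL:
    @pytest.mark.parametrize(
        "args,expected",
        [
            ((0, 1, 0, 1), 0.0),
            ((0, 1, 1, 1), 1.0),  # (mu1-mu2)^2/sigma^2 for equal SDs
            ((0, 1, 0, 2), 1.125),  # 0.5*(0.25+4)-1
        ],
    )
    def test_closed_form_examples(self, args, expected):
        assert gaussian_symmetric_kl(*args) == pytest.approx(expected, abs=1e-12)

    def test_against_numerical_quadrature(self):
        from scipy.integrate import quad
        from scipy.stats import norm

        for mu1, sd1, mu2, sd2 in [(0, 1, 1, 1), (0, 1, 0, 2), (0.3, 0.7, -0.2, 1.4)]:
            p, q = norm(mu1, sd1).pdf, norm(mu2, sd2).pdf
            lo = min(mu1 - 12 * sd1, mu2 - 12 * sd2)
            hi = max(mu1 + 12 * sd1, mu2 + 12 * sd2)
            oracle = quad(
                lambda x: (p(x) - q(x)) * (np.log(p(x)) - np.log(q(x))),
                lo,
                hi,
                limit=200,
            )[0]
            assert gaussian_symmetric_kl(mu1, sd1, mu2, sd2) == pytest.approx(
                oracle, rel=1e-6
            )

    @given(finite, positive, finite, positive)
    @settings(max_examples=50, deadline=None)
    def test_symmetric_and_nonnegative(self, m1, s1, m2, s2):
        a = gaussian_symmetric_kl(m1, s1, m2, s2)
        b = gaussian_symmetric_kl(m2, s2, m1, s1)
        assert a == b
        assert a >= 0.0
        # zero iff the parameter pairs coincide (up to float squaring underflow)
        assert (a == 0.0) == ((m1 - m2) ** 2 == 0.0 and s1 == s2)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(InvalidParameterError):
            gaussian_symmetric_kl(0, 0, 0, 1)


class TestCohortSpecValidation:
    def test_planted_edge_out_of_range_rejected(self):
        with pytest.raises(InvalidParameterError, match="missing ROI"):
            CohortSpec(n_rois=5, planted_edges=[(0, 7)])

    def test_duplicate_planted_edge_rejected(self):
        with pytest.raises(InvalidParameterError, match="duplicate"):
            CohortSpec(n_rois=5, planted_edges=[(0, 1), (1, 0)])

    def test_bad_laser_range_rejected(self):
        with pytest.raises(InvalidParameterError):
            CohortSpec(laser_range=(4.0, 2.0))

    def test_planted_matching_is_vertex_disjoint(self):
        edges = planted_matching(20, 10)
        flat = [i for e in edges for i in e]
        assert len(flat) == len(set(flat)) == 20
        with pytest.raises(InvalidParameterError):
            planted_matching(10, 6)


class TestGenerateCohort:
    def test_determinism_bit_identical(self):
        spec = CohortSpec(n_participants=10, n_rois=5, n_voxels=50, seed=7)
        s1, p1, t1 = generate_cohort(spec)
        s2, p2, t2 = generate_cohort(spec)
        assert p1.equals(p2)
        assert t1.true_mc.equals(t2.true_mc)
        pid, rid = s1.participants[3], s1.roi_ids[2]
        assert np.array_equal(s1.samples(pid, rid), s2.samples(pid, rid))

    def test_noise_free_plant_gives_perfect_correlation(self):
        spec = CohortSpec(
            n_participants=30,
            n_rois=8,
            n_voxels=50,
            planted_edges=planted_matching(8, 3),
            noise_sd=0.0,
            seed=1,
        )
        _, pheno, truth = generate_cohort(spec)
        r = np.corrcoef(
            truth.linear_predictor_laser, pheno["laser_threshold_J"]
        )[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_laser_within_range_and_cold_calibrated(self, small_cohort):
        spec, _, pheno, _ = small_cohort[0], *small_cohort[1:]
        laser = pheno["laser_threshold_J"]
        assert laser.min() >= spec.laser_range[0] - 1e-12
        assert laser.max() <= spec.laser_range[1] + 1e-12
        cold = pheno["cold_threshold_s"]
        assert cold.mean() == pytest.approx(spec.cold_mean_sd[0], abs=1e-9)

    def test_cold_mean_sd_within_three_standard_errors_at_n100(self):
        spec = CohortSpec(n_participants=120, n_rois=6, n_voxels=50, seed=3)
        _, pheno, _ = generate_cohort(spec)
        cold = pheno["cold_threshold_s"].to_numpy()
        n = len(cold)
        se_mean = spec.cold_mean_sd[1] / np.sqrt(n)
        assert abs(cold.mean() - spec.cold_mean_sd[0]) <= 3 * se_mean
        se_sd = spec.cold_mean_sd[1] / np.sqrt(2 * (n - 1))
        assert abs(cold.std() - spec.cold_mean_sd[1]) <= 3 * se_sd

    def test_true_mc_nonnegative_and_consistent_with_closed_form(self, small_cohort):
        _, _, _, truth = small_cohort
        vals = truth.true_mc.to_numpy()
        assert np.all(vals >= 0)
        # spot-check one entry against the closed form on stored parameters
        mu, sigma = truth.mu, truth.sigma
        expected = gaussian_symmetric_kl(
            mu[0, 1], sigma[0, 1], mu[0, 0], sigma[0, 0]
        )
        assert vals[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_target_r2_calibration(self):
        spec = CohortSpec(
            n_participants=200,
            n_rois=10,
            n_voxels=50,
            planted_edges=planted_matching(10, 5),
            target_r2=0.7,
            seed=5,
        )
        _, _, truth = generate_cohort(spec)
        lp = truth.linear_predictor_laser
        r2 = lp.var() / (lp.var() + truth.noise_sd[0] ** 2)
        assert r2 == pytest.approx(0.7, abs=0.001)

    def test_kde_pipeline_consistent_with_closed_form_truth(self):
        # empirical (KDE) MC vs closed-form truth at n_voxels=5000:
        # median relative error over edges with true MC >= 0.5 is below 5%
        from mcpain import cohort_mc_features, toy_parcellation

        spec = CohortSpec(
            n_participants=4, n_rois=10, n_voxels=5000, subject_sd=0.05,
            subject_sigma_sd=0.0, roi_sigma_base=np.linspace(0.09, 0.11, 10),
            noise_sd=1.0, seed=1,
        )
        samples, _, truth = generate_cohort(spec)
        emp = cohort_mc_features(samples, toy_parcellation(10)).to_numpy()
        tru = truth.true_mc.to_numpy()
        mask = tru >= 0.5
        assert mask.sum() >= 20
        rel = np.abs(emp[mask] - tru[mask]) / tru[mask]
        assert np.median(rel) < 0.05
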