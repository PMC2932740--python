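import math

import numpy as np
import pytest

import strucpower as sp


def design_equal(n):
    return sp.StudyDesign(np.r_[np.ones(n, int), np.zeros(n, int)])


class TestClosedFormNcp:
    def test_homogeneous_worked_example(self):
        r = sp.ncp_homogeneous(5000, 0.4, 0.2)
        assert r.ncp == pytest.approx(208.33, abs=0.01)
        assert math.isinf(r.ncp_bound)

    def test_isolated_worked_example(self):
        r = sp.ncp_isolated(5000, 0.4, 0.2, 0.0005)
        assert r.ncp == pytest.approx(34.73, abs=0.01)
        assert r.ncp_bound == pytest.approx(41.67, abs=0.01)

    def test_complete_admixture_worked_example(self):
        """Half the Yoruban-vs-European pairwise index 0.153 feeds the model."""
        r = sp.ncp_complete_admixture(5000, 0.4, 0.2, 0.153 / 2, 0.25, 0.20)
        assert r.ncp == pytest.approx(72.77, abs=0.01)
        assert r.ncp_bound == pytest.approx(108.93, abs=0.01)

    def test_no_drift_limits(self):
        assert sp.ncp_isolated(500, 0.3, 0.2, 0.0).ncp == pytest.approx(
            sp.ncp_homogeneous(500, 0.3, 0.2).ncp, rel=1e-12
        )
        assert sp.ncp_complete_admixture(500, 0.3, 0.2, 0.0, 0.4, 0.1).ncp == pytest.approx(
            sp.ncp_homogeneous(500, 0.3, 0.2).ncp, rel=1e-12
        )

    def test_degenerate_admixture_is_isolated(self):
        a = sp.ncp_complete_admixture(300, 0.4, 0.2, 0.01, 1.0, 0.0)
        b = sp.ncp_isolated(300, 0.4, 0.2, 0.01)
        assert a.ncp == pytest.approx(b.ncp, rel=1e-12)
        assert a.ncp_bound == pytest.approx(b.ncp_bound, rel=1e-12)

    def test_zero_delta(self):
        assert sp.ncp_homogeneous(100, 0.4, 0.0).ncp == 0.0

    def test_linear_in_n_without_structure(self):
        assert sp.ncp_homogeneous(2000, 0.4, 0.2).ncp == pytest.approx(
            2 * sp.ncp_homogeneous(1000, 0.4, 0.2).ncp, rel=1e-12
        )

    @pytest.mark.parametrize(
        "fn, args",
        [
            (sp.ncp_isolated, (0.4, 0.2, 0.0005)),
            (sp.ncp_complete_admixture, (0.4, 0.2, 0.0765, 0.25, 0.20)),
        ],
    )
    def test_increasing_in_n_and_bounded(self, fn, args):
        ns = [100, 1000, 10_000, 10**6, 10**9]
        vals = [fn(n, *args).ncp for n in ns]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        bound = fn(ns[-1], *args).ncp_bound
        assert vals[-1] <= bound
        assert vals[-1] / bound > 0.99


class TestMatrixNcp:
    @pytest.mark.parametrize("n", [200, 250])
    def test_isolated_oracle(self, n):
        k = sp.kinship_isolated_pair(sp.IsolatedPairModel(0.0005, n, n))
        lam = sp.ncp_from_structure(k, design_equal(n), 0.4, 0.2).ncp
        assert lam == pytest.approx(sp.ncp_isolated(n, 0.4, 0.2, 0.0005).ncp, rel=1e-6)

    @pytest.mark.parametrize("n", [200, 250])
    def test_admixed_oracle(self, n):
        fr = np.r_[np.full(n, 0.25), np.full(n, 0.20)]
        k = sp.kinship_admixed(fr, 0.0765)
        lam = sp.ncp_from_structure(k, design_equal(n), 0.4, 0.2).ncp
        assert lam == pytest.approx(
            sp.ncp_complete_admixture(n, 0.4, 0.2, 0.0765, 0.25, 0.20).ncp, rel=1e-6
        )

    def test_identity_k_matches_homogeneous(self):
        k = sp.KinshipMatrix(np.eye(500))
        lam = sp.ncp_from_structure(k, design_equal(250), 0.4, 0.2).ncp
        assert lam == pytest.approx(sp.ncp_homogeneous(250, 0.4, 0.2).ncp, rel=1e-10)


class TestPowerFromNcp:
    def test_null_calibration(self):
        assert sp.power_from_ncp(0.0, 0.05) == pytest.approx(0.05, rel=1e-12)

    def test_worked_examples(self):
        assert sp.power_from_ncp(34.73, 1e-8) == pytest.approx(0.56, abs=0.01)
        assert sp.power_from_ncp(208.33, 1e-8) > 0.9999

    def test_monotone_in_ncp_and_alpha(self):
        lams = [0.0, 5.0, 20.0, 80.0]
        pws = [sp.power_from_ncp(x, 1e-4) for x in lams]
        assert all(b > a for a, b in zip(pws, pws[1:]))
        alphas = [1e-8, 1e-4, 0.05]
        pws = [sp.power_from_ncp(10.0, a) for a in alphas]
        assert all(b > a for a, b in zip(pws, pws[1:]))


class TestBetaAdmixtureNcp:
    PARAMS = dict(p=0.4, delta=0.2, F=0.0765, nu1=0.20, nu2=0.25)

    def test_zero_heterogeneity_limit(self):
        r = sp.ncp_beta_admixture(
            200, 0.4, 0.2, 0.0765, 0.25, 0.20, 1e-8, n_replicates=5, seed=51
        )
        ref = sp.ncp_complete_admixture(200, 0.4, 0.2, 0.0765, 0.25, 0.20).ncp
        assert r.ncp == pytest.approx(ref, rel=1e-3)

    def test_heterogeneity_restores_power(self):
        """NCP grows with within-population ancestry heterogeneity h."""
        p = self.PARAMS
        results = [
            sp.ncp_beta_admixture(
                400, p["p"], p["delta"], p["F"], p["nu1"], p["nu2"], h,
                n_replicates=30, seed=52,
            )
            for h in (0.01, 0.05, 1.0 / 7.0, 0.3)
        ]
        for lo, hi in zip(results, results[1:]):
            assert hi.ncp - lo.ncp > -2.0 * (hi.ncp_se + lo.ncp_se)
        assert results[-1].ncp > results[0].ncp + 2.0 * (results[-1].ncp_se + results[0].ncp_se)

    def test_equal_means_beats_complete(self):
        p = self.PARAMS
        r = sp.ncp_beta_admixture(
            300, p["p"], p["delta"], p["F"], 0.25, 0.25, 1.0 / 7.0, n_replicates=20, seed=53
        )
        ref = sp.ncp_complete_admixture(300, p["p"], p["delta"], p["F"], 0.25, 0.25).ncp
        assert r.ncp >= ref - 3.0 * r.ncp_se

    @pytest.mark.parametrize("n", [50, 200])
    def test_woodbury_matches_dense(self, n):
        p = self.PARAMS
        kw = dict(n_replicates=3, seed=54)
        rw = sp.ncp_beta_admixture(n, p["p"], p["delta"], p["F"], p["nu1"], p["nu2"], 0.1, **kw)
        rd = sp.ncp_beta_admixture(
            n, p["p"], p["delta"], p["F"], p["nu1"], p["nu2"], 0.1, dense=True, **kw
        )
        assert rw.ncp == pytest.approx(rd.ncp, rel=1e-8)


class TestExpectedVarianceUnderAdjustment:
    def test_identity_needs_no_correction(self):
        k = sp.KinshipMatrix(np.eye(80))
        for L in (0, 1, 10):
            var, ratio = sp.expected_variance_under_adjustment(k, design_equal(40), L, 0.3)
            assert ratio == pytest.approx(1.0, rel=1e-10)

    def test_one_eigenvector_absorbs_two_population_structure(self):
        """On the (centered) two-population K, L=1 restores honest variance.

        Pooled-frequency centering in the kinship estimator removes the
        grand-mean direction, so between-population structure is rank one;
        with one retained eigenvector the expected variance estimate matches
        the true variance of the weighted estimator, while the unadjusted
        (L=0) estimate grossly understates it.
        """
        n = 60
        k_true = sp.kinship_isolated_pair(sp.IsolatedPairModel(0.01, n, n))
        cmat = np.eye(2 * n) - np.ones((2 * n, 2 * n)) / (2 * n)
        k_cent = sp.KinshipMatrix(cmat @ k_true.values @ cmat)
        design = design_equal(n)
        p = 0.3
        true_gls_var = 0.2**2 / sp.ncp_from_structure(k_true, design, p, 0.2).ncp
        v0, _ = sp.expected_variance_under_adjustment(k_cent, design, 0, p)
        v1, _ = sp.expected_variance_under_adjustment(k_cent, design, 1, p)
        assert v1 == pytest.approx(true_gls_var, rel=0.02)
        assert v0 < 0.5 * true_gls_var

    def test_variance_non_decreasing_in_L_two_site(self):
        """Adjusting for more eigenvectors never reports less variance."""
        model = sp.BetaAdmixturePairModel(0.0765, 0.20, 0.25, 1.0 / 7.0, 635, 990)
        k = sp.kinship_for_model(model)
        design = sp.StudyDesign(np.r_[np.ones(635, int), np.zeros(990, int)])
        eig = sp.eigendecompose(k)
        vals = [
            sp.expected_variance_under_adjustment(k, design, L, 0.2, eig=eig)[0]
            for L in (1, 2, 10, 50, 200)
        ]
        assert all(b >= a * (1 - 1e-10) for a, b in zip(vals, vals[1:]))
        _, ratio = sp.expected_variance_under_adjustment(k, design, 2, 0.2, eig=eig)
        assert 0.0 < ratio <= 1.05


class TestEffectiveSampleSize:
    @pytest.mark.parametrize(
        "m, factor", [(1, 1.0), (3, 1.5), (1e9, 2.0)]
    )
    def test_matching_ratio(self, m, factor):
        assert sp.effective_n_one_to_m(1000, m) == pytest.approx(1000 * factor, rel=1e-6)
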