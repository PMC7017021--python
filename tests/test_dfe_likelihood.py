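"""Tests for alpha fitting, the joint likelihood, model fitting and the
nested-model machinery."""

import numpy as np
import pytest

from oracle import oracle_joint_loglik

from cubdfe.dfe_likelihood import (
    MODEL_NAMES,
    AlphaCorrection,
    FitResult,
    FoldedSFS,
    ModelSpec,
    default_seed_grid,
    fit_alpha,
    fit_model,
    fold,
    loglik_joint,
    lrt,
    rank_bootstrap_ci,
    select_best_model,
)
from cubdfe.errors import DataError, DomainError
from cubdfe.spectra import (
    DFEModel,
    PopulationModel,
    default_alpha_bins,
    expected_folded_sfs,
)
from cubdfe.synthetic_data import simulate_sfs_counts

TOY = PopulationModel(ne=50, ns=10, theta=0.01)


def _toy_data(dfe=DFEModel.neutral(), L=200_000, seed=0, theta=0.01, ns=10, ne=50):
    pop = PopulationModel(ne=ne, ns=ns, theta=theta)
    e4 = expected_folded_sfs(pop, dfe)
    esi = expected_folded_sfs(pop, DFEModel.neutral())
    return (
        simulate_sfs_counts(e4, L, [seed, 0]),
        simulate_sfs_counts(esi, L, [seed, 1]),
        pop,
    )


class TestFitAlpha:
    def test_neutral_recovery(self):
        pop = PopulationModel(ne=200, ns=20, theta=0.02)
        esi = expected_folded_sfs(pop, DFEModel.neutral())
        thetas, alphas = [], []
        for seed in range(20):
            sfs = simulate_sfs_counts(esi, 300_000, seed)
            alpha, theta = fit_alpha(sfs, ne=200)
            thetas.append(theta)
            alphas.append(alpha.values)
        thetas = np.array(thetas)
        assert abs(thetas.mean() - 0.02) < 3 * thetas.std() / np.sqrt(20) + 1e-5
        alphas = np.array(alphas)
        for j in range(1, alphas.shape[1]):
            se = alphas[:, j].std() / np.sqrt(20)
            assert abs(alphas[:, j].mean() - 1.0) < 3 * se + 1e-3

    def test_skewed_alpha_recovery(self):
        ns, ne = 20, 200
        bins = default_alpha_bins(ns)
        true_vals = (1.0,) + tuple(1.0 + 0.15 * i for i in range(1, len(bins)))
        alpha_true = AlphaCorrection(bins, true_vals)
        pop = PopulationModel(ne=ne, ns=ns, theta=0.02)
        esi = expected_folded_sfs(pop, DFEModel.neutral(), alpha_true)
        est = []
        for seed in range(20):
            sfs = simulate_sfs_counts(esi, 300_000, seed)
            alpha, _ = fit_alpha(sfs, ne=ne)
            est.append(alpha.values)
        est = np.array(est)
        for j in range(1, est.shape[1]):
            se = est[:, j].std() / np.sqrt(20)
            assert abs(est[:, j].mean() - true_vals[j]) < 3 * se + 1e-3

    def test_ml_dominance_over_identity(self):
        sfs4, sfssi, pop = _toy_data(seed=3)
        alpha, theta = fit_alpha(sfssi, ne=50)
        ll_fit = loglik_joint(DFEModel.neutral(), theta, alpha, sfssi, sfssi, pop)
        ident = AlphaCorrection.identity(10)
        ll_ident = loglik_joint(DFEModel.neutral(), theta, ident, sfssi, sfssi, pop)
        assert ll_fit >= ll_ident - 1e-9

    def test_empty_bin_error(self):
        counts = np.array([100, 50, 0, 10, 5])
        sfs = FoldedSFS(counts, 10_000, 10)
        bins = default_alpha_bins(10)
        empty_bin = [i for i, (lo, hi) in enumerate(bins) if lo <= 3 <= hi][0] + 1
        with pytest.raises(DataError, match=f"bin {empty_bin}"):
            fit_alpha(sfs, ne=50)


class TestLoglikJoint:
    def test_matches_bruteforce_oracle(self):
        sfs4, sfssi, pop = _toy_data(
            DFEModel(((-2.0, 0.3), ("lethal", 0.1))), L=5000, seed=1
        )
        bins = default_alpha_bins(10)
        alpha = AlphaCorrection(bins, (1.0,) + (1.1,) * (len(bins) - 1))
        dfe = DFEModel(((-2.0, 0.3), ("lethal", 0.1)))
        got = loglik_joint(dfe, 0.012, alpha, sfs4, sfssi, pop)
        oracle = oracle_joint_loglik(
            50,
            10,
            0.012,
            [(-2.0, 0.3), (None, 0.1)],
            list(alpha.expand(5)),
            (sfs4.k0, list(sfs4.counts)),
            (sfssi.k0, list(sfssi.counts)),
        )
        assert got == pytest.approx(oracle, abs=1e-12 * abs(oracle))

    def test_proportional_counts_attain_multinomial_max(self):
        pop = TOY
        e = expected_folded_sfs(pop, DFEModel.neutral())
        L = 1_000_000
        counts = np.round(e * L).astype(int)
        sfs = FoldedSFS(counts[1:], int(counts[0]), 10)
        ll = loglik_joint(DFEModel.neutral(), 0.01, None, sfs, sfs, pop)
        # multinomial maximum of sum k log q at q = k/L, for both terms
        k = np.concatenate(([sfs.k0], sfs.counts)).astype(float)
        p_hat = k / k.sum()
        ll_max = 2 * float(k[k > 0] @ np.log(p_hat[k > 0]))
        assert ll <= ll_max + 1e-6
        assert ll == pytest.approx(ll_max, abs=0.5)  # rounding of counts

    def test_likelihood_peaks_at_generating_gamma(self):
        truth = DFEModel(((-5.0, 0.4),))
        sfs4, sfssi, pop = _toy_data(truth, L=1_000_000, seed=2)
        ll_true = loglik_joint(truth, 0.01, None, sfs4, sfssi, pop)
        for g in (-1.0, -20.0):
            ll = loglik_joint(DFEModel(((g, 0.4),)), 0.01, None, sfs4, sfssi, pop)
            assert ll < ll_true

    def test_zero_probability_with_count_is_neg_inf(self):
        sfs4, sfssi, pop = _toy_data(seed=4, L=10_000)
        dfe = DFEModel((("lethal", 1.0),))  # no polymorphism allowed
        assert loglik_joint(dfe, 0.01, None, sfs4, sfssi, pop) == -np.inf


class TestModelSpec:
    def test_free_params(self):
        expected = {"n": 0, "n+l": 1, "n+s": 2, "n+s+l": 3, "n+s+s": 4}
        for name, k in expected.items():
            assert ModelSpec.from_name(name).free_params == k

    def test_unknown_name(self):
        with pytest.raises(DomainError):
            ModelSpec.from_name("n+x")

    def test_boundary_in_nss(self):
        spec = ModelSpec.from_name("n+s+s", boundary=10)
        (lw, hw), (ls, hs) = spec.sel_bounds
        assert hw == 10 and ls == 10


class TestFitModel:
    def test_neutral_model_theta_only(self):
        sfs4, sfssi, pop = _toy_data(seed=5)
        fit = fit_model(ModelSpec.from_name("n"), sfs4, sfssi, None, model=pop)
        assert fit.dfe.classes == ()
        assert fit.theta == pytest.approx(0.01, rel=0.05)

    def test_nested_loglik_dominance(self):
        sfs4, sfssi, pop = _toy_data(
            DFEModel(((-3.0, 0.3),)), L=300_000, seed=6
        )
        alpha, _ = fit_alpha(sfssi, ne=50)
        fits = {
            name: fit_model(ModelSpec.from_name(name), sfs4, sfssi, alpha, model=pop)
            for name in MODEL_NAMES
        }
        assert fits["n"].loglik <= fits["n+l"].loglik + 1e-6
        assert fits["n"].loglik <= fits["n+s"].loglik + 1e-6
        assert fits["n+s"].loglik <= fits["n+s+l"].loglik + 1e-4
        assert fits["n+s"].loglik <= fits["n+s+s"].loglik + 1e-4

    def test_seed_grid_covers_regimes(self):
        seeds = default_seed_grid(ModelSpec.from_name("n+s+s"), 0.01)
        gammas_weak = {s[1][0][0] for s in seeds}
        gammas_strong = {s[1][1][0] for s in seeds}
        assert all(-10 < g < 0 for g in gammas_weak)
        assert all(g < -10 for g in gammas_strong)


class TestLrt:
    def _fit(self, name, ll):
        spec = ModelSpec.from_name(name)
        return FitResult(spec, DFEModel.neutral(), 0.01, None, ll, True)

    def test_identical_logliks_p_one(self):
        stat, df, p = lrt(self._fit("n", -100.0), self._fit("n+s", -100.0))
        assert stat == 0.0 and df == 2 and p == 1.0

    def test_delta48_df1(self):
        # delta LL = 48 at one degree of freedom
        stat, df, p = lrt(self._fit("n+l", -1000.0), self._fit("n+s", -952.0))
        assert stat == pytest.approx(96.0)
        assert df == 1
        assert 1e-23 < p < 1e-21

    def test_df_convention(self):
        pairs = {
            ("n", "n+s"): 2,
            ("n+l", "n+s"): 1,
            ("n+s", "n+s+l"): 1,
            ("n+s", "n+s+s"): 2,
        }
        for (a, b), df in pairs.items():
            assert lrt(self._fit(a, -10.0), self._fit(b, -9.0))[1] == df

    def test_non_nested_error(self):
        with pytest.raises(DomainError):
            lrt(self._fit("n+s", -10.0), self._fit("n+l", -9.0))


class TestSelectBestModel:
    def _fits(self, lls):
        return {
            name: FitResult(
                ModelSpec.from_name(name), DFEModel.neutral(), 0.01, None, ll, True
            )
            for name, ll in lls.items()
        }

    def test_all_equal_returns_n(self):
        fits = self._fits({m: -500.0 for m in MODEL_NAMES})
        best, report = select_best_model(fits)
        assert best.name == "n"
        assert [r["model"] for r in report] == list(MODEL_NAMES)

    def test_walks_to_significant_model(self):
        fits = self._fits(
            {"n": -1000.0, "n+l": -900.0, "n+s": -880.0, "n+s+l": -879.9,
             "n+s+s": -879.8}
        )
        best, _ = select_best_model(fits)
        assert best.name == "n+s"

    def test_missing_model_error(self):
        fits = self._fits({"n": -1.0})
        with pytest.raises(DataError):
            select_best_model(fits)


class TestRankBootstrapCi:
    def test_constant_vector(self):
        lo, hi = rank_bootstrap_ci(np.full(200, 3.14))
        assert lo == hi == pytest.approx(3.14)

    def test_values_1_to_200(self):
        lo, hi = rank_bootstrap_ci(np.arange(1, 201))
        assert (lo, hi) == (5.0, 195.0)

    def test_requires_200_unless_ranks_given(self):
        with pytest.raises(DataError):
            rank_bootstrap_ci(np.arange(100))
        lo, hi = rank_bootstrap_ci(np.arange(1, 101), ranks=(3, 98))
        assert (lo, hi) == (3.0, 98.0)

    def test_invalid_ranks(self):
        with pytest.raises(DomainError):
            rank_bootstrap_ci(np.arange(10), ranks=(0, 5))


class TestProfileFitter:
    """fit_model_profile maximizes the same likelihood as the all-parameter
    simplex, exploiting concavity in the class weights at fixed gammas."""

    @pytest.mark.parametrize("name", MODEL_NAMES)
    def test_matches_simplex_likelihood(self, name):
        from cubdfe.dfe_likelihood import fit_model_profile

        truth = DFEModel(((-3.0, 0.25), ("lethal", 0.05)))
        sfs4, sfssi, pop = _toy_data(truth, L=300_000, seed=17)
        alpha, _ = fit_alpha(sfssi, ne=50)
        spec = ModelSpec.from_name(name)
        fp = fit_model_profile(spec, sfs4, sfssi, alpha, model=pop)
        fs = fit_model(spec, sfs4, sfssi, alpha, model=pop)
        assert fp.loglik >= fs.loglik - 1e-6
        assert fp.loglik == pytest.approx(fs.loglik, abs=0.05)

    def test_neutral_boundary_reached(self):
        # under neutral data richer models collapse onto the neutral fit
        from cubdfe.dfe_likelihood import fit_model_profile

        sfs4, sfssi, pop = _toy_data(seed=19, L=300_000)
        alpha, _ = fit_alpha(sfssi, ne=50)
        f_n = fit_model_profile(ModelSpec.from_name("n"), sfs4, sfssi, alpha,
                                model=pop)
        f_ns = fit_model_profile(ModelSpec.from_name("n+s"), sfs4, sfssi, alpha,
                                 model=pop)
        assert f_ns.loglik >= f_n.loglik - 1e-9


def test_fold_reexported():
    f = fold([10, 1, 2, 3, 4])
    assert f.k0 == 14


def test_count_scaling_invariance():
    # scaling all counts leaves the (gamma, f) argmax essentially unchanged
    truth = DFEModel(((-4.0, 0.3),))
    sfs4, sfssi, pop = _toy_data(truth, L=400_000, seed=8)
    alpha, _ = fit_alpha(sfssi, ne=50)
    spec = ModelSpec.from_name("n+s")
    fit1 = fit_model(spec, sfs4, sfssi, alpha, model=pop)
    sfs4x = FoldedSFS(sfs4.counts * 3, sfs4.k0 * 3, 10)
    sfssix = FoldedSFS(sfssi.counts * 3, sfssi.k0 * 3, 10)
    fit3 = fit_model(spec, sfs4x, sfssix, alpha, model=pop)
    assert fit3.dfe.classes[0].f == pytest.approx(fit1.dfe.classes[0].f, rel=0.05)
    assert fit3.dfe.classes[0].gamma == pytest.approx(
        fit1.dfe.classes[0].gamma, rel=0.05
    )
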