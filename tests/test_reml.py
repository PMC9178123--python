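"""AI-REML: oracle equivalence, EM monotonicity, boundaries, recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from methaherd.reml import (
    BivariateREML,
    MixedModelSpec,
    RepeatabilityREML,
    _prepare,
    fit_bivariate,
    fit_reml,
    summarize_ratios,
)
from methaherd.simulate import simulate_pedigree
from methaherd.pedigree import Pedigree

from conftest import simulate_bivariate_records, simulate_repeatability_records


SIMPLE_FE = ("eys_class",)
NO_COV: tuple = ()


def _fit(table, ped, trait="y", mean_only=False, **kw):
    return RepeatabilityREML(
        trait=trait,
        mean_only=mean_only,
        fixed_effects=SIMPLE_FE,
        covariates=NO_COV,
        **kw,
    ).fit(table, ped)


class TestSummarizeRatios:
    def test_reference_mep_components(self):
        r = summarize_ratios(1160.6, 1456.8, 2923.9)
        assert round(r["h2"], 2) == 0.21
        assert round(r["repeatability"], 2) == 0.47
        assert round(r["pe2"], 2) == 0.26

    def test_pure_genetic(self):
        r = summarize_ratios(1.0, 0.0, 0.0)
        assert r["h2"] == 1.0 and r["repeatability"] == 1.0

    def test_partition_sums_to_one(self):
        r = summarize_ratios(3.0, 2.0, 5.0)
        assert r["h2"] + r["pe2"] + (1 - r["repeatability"]) == pytest.approx(1.0)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            summarize_ratios(0.0, 0.0, 0.0)

    def test_delta_method_se_matches_monte_carlo(self):
        rng = np.random.default_rng(0)
        theta = np.array([4.0, 3.0, 8.0])
        cov = np.diag([0.4, 0.3, 0.5])
        r = summarize_ratios(*theta, cov)
        draws = rng.multivariate_normal(theta, cov, size=200_000)
        h2 = draws[:, 0] / draws.sum(axis=1)
        assert r["h2_se"] == pytest.approx(h2.std(), rel=0.05)


class TestUnivariate:
    def test_matches_brute_force_likelihood_maximization(self, small_herd):
        # the AI-REML optimum must agree with a generic optimizer run on the
        # same restricted likelihood surface to < 1e-4 relative
        ped, _, table = small_herd
        est = RepeatabilityREML(trait="mep").fit(table, ped)
        spec = MixedModelSpec("mep")
        engine, _ = _prepare(table, ped, [spec])

        def m2l(log_theta):
            return -2.0 * engine.evaluate(np.exp(log_theta), need_derivs=False)[
                "loglik"
            ]

        res = minimize(
            m2l,
            np.log([2000.0, 2000.0, 2000.0]),
            method="Nelder-Mead",
            options=dict(xatol=1e-10, fatol=1e-12, maxiter=5000),
        )
        oracle = np.exp(res.x)
        ai = np.array([est.sigma2_a_, est.sigma2_pe_, est.sigma2_e_])
        assert est.converged_
        assert np.max(np.abs(ai - oracle) / oracle) < 1e-4

    def test_zero_genetic_variance_boundary(self):
        ped = simulate_pedigree(60, 1, 3, seed=3)
        table = simulate_repeatability_records(
            ped, n_cows=80, n_weeks=6, sigma2_a=0.0, sigma2_pe=2.0,
            sigma2_e=3.0, seed=4,
        )
        est = _fit(table, ped)
        assert est.h2_ < 0.05
        assert est.sigma2_pe_ == pytest.approx(2.0, rel=0.5)

    def test_em_loglik_monotone(self):
        ped = simulate_pedigree(40, 1, 3, seed=5)
        table = simulate_repeatability_records(
            ped, n_cows=50, n_weeks=5, sigma2_a=1.5, sigma2_pe=1.0,
            sigma2_e=2.0, seed=6,
        )
        est = _fit(table, ped, method="em", max_iter=40)
        lls = [h["loglik"] for h in est.result_.history]
        assert len(lls) > 3
        assert np.all(np.diff(lls) >= -1e-9)

    def test_invariant_to_record_and_pedigree_reordering(self):
        ped = simulate_pedigree(40, 1, 3, seed=7)
        table = simulate_repeatability_records(
            ped, n_cows=50, n_weeks=5, sigma2_a=2.0, sigma2_pe=1.0,
            sigma2_e=3.0, seed=8,
        )
        est1 = _fit(table, ped)
        rng = np.random.default_rng(9)
        shuffled = table.sample(frac=1.0, random_state=3).reset_index(drop=True)
        # permute founder block of the pedigree (stays generation-ordered)
        perm = np.concatenate([rng.permutation(40), np.arange(40, len(ped))])
        ped2 = Pedigree(ped.animal[perm], ped.sire[perm], ped.dam[perm])
        est2 = _fit(shuffled, ped2)
        a1 = np.array([est1.sigma2_a_, est1.sigma2_pe_, est1.sigma2_e_])
        a2 = np.array([est2.sigma2_a_, est2.sigma2_pe_, est2.sigma2_e_])
        assert np.max(np.abs(a1 - a2) / a1) < 1e-6

    def test_balanced_anova_limit_with_identity_relationship(self):
        # unrelated cows (founder-only pedigree), balanced design: the
        # identified cow-level variance s2a + s2pe and the residual must
        # match the one-way ANOVA estimators (MSB - MSW)/n and MSW
        n_cows, n_weeks = 60, 6
        ped = Pedigree(
            np.arange(1, n_cows + 1), np.zeros(n_cows, int), np.zeros(n_cows, int)
        )
        table = simulate_repeatability_records(
            ped, n_cows=n_cows, n_weeks=n_weeks, sigma2_a=0.0, sigma2_pe=3.0,
            sigma2_e=2.0, seed=10,
        )
        est = _fit(table, ped, mean_only=True)
        y = table["y"].to_numpy().reshape(n_cows, n_weeks)
        gm = y.mean()
        msb = n_weeks * np.sum((y.mean(axis=1) - gm) ** 2) / (n_cows - 1)
        msw = np.sum((y - y.mean(axis=1, keepdims=True)) ** 2) / (
            n_cows * (n_weeks - 1)
        )
        anova_between = (msb - msw) / n_weeks
        assert est.sigma2_a_ + est.sigma2_pe_ == pytest.approx(
            anova_between, rel=1e-3
        )
        assert est.sigma2_e_ == pytest.approx(msw, rel=1e-3)

    def test_no_repeated_records_rejected(self, trio_pedigree):
        table = pd.DataFrame(
            {
                "cow_id": [1, 2, 3],
                "eys_class": ["a", "a", "b"],
                "y": [1.0, 2.0, 3.0],
            }
        )
        with pytest.raises(ValueError, match="repeated"):
            _fit(table, trio_pedigree)

    def test_non_convergence_is_flagged(self):
        ped = simulate_pedigree(30, 1, 2, seed=11)
        table = simulate_repeatability_records(
            ped, n_cows=30, n_weeks=4, sigma2_a=1.0, sigma2_pe=1.0,
            sigma2_e=1.0, seed=12,
        )
        est = _fit(table, ped, max_iter=1)
        assert not est.converged_


@pytest.mark.parametrize(
    "name,components,mean_only",
    [
        ("mec", (474.8, 956.9, 942.9), False),
        ("rfi1", (0.47, 0.59, 2.57), True),
    ],
)
def test_parameter_recovery_coverage(name, components, mean_only):
    """Truth inside estimate +/- 2 SE in >= 90% of 20 replicates."""
    s2a, s2pe, s2e = components
    total = sum(components)
    hits = {"h2": 0, "s2a": 0}
    n_rep = 20
    for rep in range(n_rep):
        ped = simulate_pedigree(140, 1, 4, seed=100 + rep)
        table = simulate_repeatability_records(
            ped, n_cows=250, n_weeks=10, sigma2_a=s2a, sigma2_pe=s2pe,
            sigma2_e=s2e, seed=200 + rep,
            fixed_sd=0.0 if mean_only else 0.3 * np.sqrt(total),
        )
        est = _fit(table, ped, mean_only=mean_only)
        cov = est.result_.param_cov
        se_a = np.sqrt(max(cov[0, 0], 0.0))
        if abs(est.sigma2_a_ - s2a) <= 2 * se_a:
            hits["s2a"] += 1
        if abs(est.h2_ - s2a / total) <= 2 * est.h2_se_:
            hits["h2"] += 1
    assert hits["h2"] >= int(0.9 * n_rep)
    assert hits["s2a"] >= int(0.9 * n_rep)


class TestBivariate:
    def _toy(self, seed=20, n_cows=60, n_weeks=5, rg=0.6):
        ped = simulate_pedigree(50, 1, 3, seed=seed)
        G = np.array([[2.0, rg * np.sqrt(2.0 * 3.0)], [rg * np.sqrt(6.0), 3.0]])
        PE = np.array([[1.0, 0.3], [0.3, 1.5]])
        E = np.array([[2.0, 0.5], [0.5, 2.5]])
        table = simulate_bivariate_records(
            ped, n_cows=n_cows, n_weeks=n_weeks, G=G, PE=PE, E=E, seed=seed + 1
        )
        return ped, table

    def test_duplicated_trait_correlation_at_boundary(self):
        ped, table = self._toy()
        table["y2"] = table["y1"]
        est = BivariateREML(
            trait_a="y1", trait_b="y2", fixed_effects=SIMPLE_FE, covariates=NO_COV
        ).fit(table, ped)
        assert est.genetic_correlation_ > 0.98

    def test_independent_traits_near_zero(self):
        ped = simulate_pedigree(80, 1, 3, seed=30)
        table = simulate_bivariate_records(
            ped, n_cows=100, n_weeks=6,
            G=np.diag([2.0, 3.0]), PE=np.diag([1.0, 1.5]), E=np.diag([2.0, 2.5]),
            seed=31,
        )
        est = BivariateREML(
            trait_a="y1", trait_b="y2", fixed_effects=SIMPLE_FE, covariates=NO_COV
        ).fit(table, ped)
        assert abs(est.genetic_correlation_) < max(
            3 * est.genetic_correlation_se_, 0.3
        )

    def test_matches_brute_force_bivariate_likelihood(self):
        # 9-parameter surface: AI optimum vs generic optimizer, < 1e-4 rel.
        # Instance sized so the optimum is interior (all blocks comfortably
        # PD); on PSD-boundary optima a free-parameter search is undefined.
        ped = simulate_pedigree(50, 1, 3, seed=40)
        rg = 0.6
        G = np.array([[2.0, rg * np.sqrt(6.0)], [rg * np.sqrt(6.0), 3.0]])
        PE = np.array([[1.5, 0.5], [0.5, 2.0]])
        E = np.array([[2.0, 0.5], [0.5, 2.5]])
        table = simulate_bivariate_records(
            ped, n_cows=60, n_weeks=7, G=G, PE=PE, E=E, seed=41
        )
        specs = [
            MixedModelSpec("y1", fixed_effects=SIMPLE_FE, covariates=NO_COV),
            MixedModelSpec("y2", fixed_effects=SIMPLE_FE, covariates=NO_COV),
        ]
        est = BivariateREML(
            trait_a="y1", trait_b="y2", fixed_effects=SIMPLE_FE, covariates=NO_COV
        ).fit(table, ped)
        engine, _ = _prepare(table, ped, specs)

        def to_theta(x):
            # variances on log scale, covariances free
            th = x.copy()
            for k in (0, 2, 3, 5, 6, 8):
                th[k] = np.exp(x[k])
            return th

        theta_hat = np.concatenate(
            [
                [est.G_[0, 0], est.G_[1, 0], est.G_[1, 1]],
                [est.PE_[0, 0], est.PE_[1, 0], est.PE_[1, 1]],
                [est.E_[0, 0], est.E_[1, 0], est.E_[1, 1]],
            ]
        )
        x0 = theta_hat.copy()
        for k in (0, 2, 3, 5, 6, 8):
            x0[k] = np.log(max(theta_hat[k], 1e-8) * 1.6)

        def m2l(x):
            try:
                v = -2.0 * engine.evaluate(to_theta(x), need_derivs=False)[
                    "loglik"
                ]
                return v if np.isfinite(v) else 1e12
            except (np.linalg.LinAlgError, ValueError):
                return 1e12

        # Nelder-Mead needs restarts to converge on a 9-parameter surface
        x, fun = x0, np.inf
        for _ in range(4):
            res = minimize(
                m2l, x, method="Nelder-Mead",
                options=dict(xatol=1e-12, fatol=1e-13, maxiter=12000, maxfev=12000),
            )
            x = res.x
            if fun - res.fun < 1e-9:
                break
            fun = res.fun
        oracle = to_theta(x)
        assert -2.0 * est.loglik_ <= res.fun + 1e-6
        scale = np.max(np.abs(oracle))
        assert np.max(np.abs(theta_hat - oracle)) / scale < 1e-4

    def test_genetic_correlation_recovery_coverage(self):
        """True r_g = 0.8 inside estimate +/- 2 SE in >= 90% of 20 replicates."""
        rg = 0.8
        G = np.array([[2.0, rg * np.sqrt(2.0 * 3.0)], [rg * np.sqrt(6.0), 3.0]])
        PE = np.array([[1.0, 0.4], [0.4, 1.5]])
        E = np.array([[2.0, 0.6], [0.6, 2.5]])
        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            ped = simulate_pedigree(110, 1, 4, seed=300 + rep)
            table = simulate_bivariate_records(
                ped, n_cows=200, n_weeks=8, G=G, PE=PE, E=E, seed=400 + rep
            )
            est = BivariateREML(
                trait_a="y1", trait_b="y2", fixed_effects=SIMPLE_FE,
                covariates=NO_COV,
            ).fit(table, ped)
            if abs(est.genetic_correlation_ - rg) <= 2 * est.genetic_correlation_se_:
                hits += 1
        assert hits >= int(0.9 * n_rep)

    def test_functional_wrappers(self, small_herd):
        ped, _, table = small_herd
        spec = MixedModelSpec("mep")
        res = fit_reml(spec, table, ped)
        assert res.converged and res.G[0, 0] > 0
        res2 = fit_bivariate(MixedModelSpec("ecm"), spec, table, ped)
        assert res2.genetic_correlation is not None
        assert -1.0 <= res2.genetic_correlation <= 1.0
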