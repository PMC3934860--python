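"""GLS/OLS estimation and lambda profiling, checked against independent
oracles: statsmodels OLS, brute-force multivariate-normal likelihood grids,
and simulation calibration."""

import numpy as np
import pytest

from allogrow import (
    PGLS,
    read_newick,
    simulate_allometry,
    simulate_tree,
    vcv_from_tree,
)
from allogrow.pgls import AIC_PARAM_COUNT, gls_estimate, ols_fit, profile_lambda_fit
from allogrow.trees import feasible_lambda_range, lambda_matrix


def mvn_loglik(y, X, beta, sigma2, V):
    """Explicit multivariate-normal log density (independent oracle)."""
    n = len(y)
    r = y - X @ beta
    sign, logdet = np.linalg.slogdet(sigma2 * V)
    assert sign > 0
    return -0.5 * (n * np.log(2 * np.pi) + logdet + r @ np.linalg.solve(sigma2 * V, r))


def refining_grid_max(f, bounds, rounds=8, pts=15):
    """Maximize f over a box by iteratively refined dense grids.

    Purely enumerative — no gradient or closed form — so it is independent
    of the GLS estimator it checks.
    """
    box = [tuple(b) for b in bounds]
    bounds = [list(b) for b in bounds]
    best, best_x = -np.inf, None
    for _ in range(rounds):
        axes = [np.linspace(lo, hi, pts) for lo, hi in bounds]
        grids = np.meshgrid(*axes, indexing="ij")
        vals = np.empty(grids[0].shape)
        it = np.nditer(grids[0], flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            vals[idx] = f(*(g[idx] for g in grids))
        idx = np.unravel_index(np.argmax(vals), vals.shape)
        if vals[idx] > best:
            best = float(vals[idx])
            best_x = [float(g[idx]) for g in grids]
        # shrink each axis around its argmax, staying inside the original box
        for d, (ax, i) in enumerate(zip(axes, idx)):
            step = ax[1] - ax[0]
            bounds[d] = [
                max(best_x[d] - step, box[d][0]),
                min(best_x[d] + step, box[d][1]),
            ]
    return best, best_x


class TestOLS:
    def test_matches_statsmodels(self, rng):
        """Coefficients, standard errors and 95% CIs agree with an
        independent OLS implementation."""
        import statsmodels.api as sm

        x = rng.uniform(0, 6, 40)
        y = -1.0 + 0.75 * x + rng.normal(0, 0.2, 40)
        res = ols_fit(y, x)
        ref = sm.OLS(y, sm.add_constant(x)).fit()
        assert res.params == pytest.approx(ref.params, rel=1e-10)
        assert res.bse == pytest.approx(ref.bse, rel=1e-10)
        assert res.conf_int() == pytest.approx(ref.conf_int(), rel=1e-8)
        assert res.pvalues == pytest.approx(ref.pvalues, rel=1e-8, abs=1e-12)

    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        res = ols_fit(2.0 + 0.75 * x, x)
        assert res.intercept == pytest.approx(2.0, abs=1e-12)
        assert res.slope == pytest.approx(0.75, abs=1e-12)
        assert np.allclose(res.resid, 0.0, atol=1e-12)
        assert res.perfect_fit

    def test_fixed_slope_perfect_fit_flagged(self):
        x = np.array([1.0, 2.0, 3.0])
        res = ols_fit(0.75 * x, x, fixed_slope=0.75)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.sigma2 == pytest.approx(0.0, abs=1e-300)
        assert res.perfect_fit

    def test_degenerate_predictor_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            ols_fit([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])


class TestGLSEstimate:
    def test_iid_covariance_reduces_to_ols(self, cherry_tree, rng):
        x = rng.uniform(0, 4, 3)
        y = rng.normal(size=3)
        coef_iid, _, _ = gls_estimate(y, x, cov=None)
        ref = ols_fit(y, x)
        assert coef_iid == pytest.approx(ref.params, rel=1e-12)

    def test_lambda_zero_equals_ols_on_equal_height_tree(self, rng):
        """With equal tip heights, lambda = 0 makes the GLS weighting a
        scalar matrix, so coefficients must equal OLS to 1e-10."""
        tree = simulate_tree(30, seed=7)
        taxa = sorted(tree.tip_names)
        cov = vcv_from_tree(tree, taxa)
        x = rng.uniform(0, 6, 30)
        y = -1.0 + 0.75 * x + rng.normal(0, 0.3, 30)
        res = PGLS(y, x, cov=cov).fit(lam=0.0)
        ref = ols_fit(y, x)
        assert res.params == pytest.approx(ref.params, abs=1e-10)

    def test_three_point_grid_oracle(self, cherry_tree, rng):
        """GLS at lambda = 1 on the 3-tip tree matches a brute-force grid
        maximization of the explicit MVN likelihood over
        (intercept, slope, sigma2)."""
        cov = vcv_from_tree(cherry_tree, ["A", "B", "C"])
        V = cov.C
        x = np.array([0.5, 2.0, 4.0])
        y = np.array([-0.4, 0.9, 2.2])
        coefs, sigma2, llf = gls_estimate(y, x, cov=cov, lam=1.0)
        X = np.column_stack([np.ones(3), x])
        best, (b0, b1, s2) = refining_grid_max(
            lambda b0, b1, s2: mvn_loglik(y, X, np.array([b0, b1]), s2, V),
            bounds=[(-5, 5), (-2, 3), (1e-3, 5.0)],
        )
        assert llf == pytest.approx(best, abs=1e-6)
        assert coefs == pytest.approx([b0, b1], abs=1e-4)
        assert sigma2 == pytest.approx(s2, rel=1e-3)

    def test_infeasible_lambda_rejected(self, cherry_tree):
        cov = vcv_from_tree(cherry_tree, ["A", "B", "C"])
        with pytest.raises(ValueError, match="feasible"):
            PGLS([0.0, 1.0, 2.0], [0.0, 1.0, 2.0], cov=cov).fit(lam=99.0)


class TestProfileLambda:
    def test_profile_maximum_matches_exhaustive_grid(self, small_yule_tree):
        """Profiled maximum within 1e-4 log-units of an exhaustive refined
        grid over (lambda, intercept, slope, sigma2) on small trees.

        Lambda is restricted to [0, 1] on both sides of the comparison: at
        the outer PD-feasibility boundary the likelihood diverges, so an
        unbounded comparison would race two optimizers toward a pole.
        """
        taxa = sorted(small_yule_tree.tip_names)
        cov = vcv_from_tree(small_yule_tree, taxa)
        df = simulate_allometry(
            small_yule_tree, -1.0, 0.75, 0.7, 0.05, (0, 5), seed=9, taxa_order=taxa
        )
        y, x = df["log10_agr"].to_numpy(), df["log10_bmatmg"].to_numpy()
        res = profile_lambda_fit(y, x, cov, restrict_lambda=True)
        # centred predictor decorrelates intercept and slope axes so the
        # axis-aligned grid does not stall on the ridge; the maximum itself
        # is invariant under the reparameterization
        Xc = np.column_stack([np.ones(len(y)), x - x.mean()])
        n = len(y)

        def best_at_lambda(lam):
            """Refined dense grid over (intercept, slope, sigma2) at one
            lambda; the MVN exponent is expanded once so the grid sweep is
            vectorized, but the search itself is pure enumeration."""
            V = lambda_matrix(cov, lam)
            sign, logdet = np.linalg.slogdet(V)
            assert sign > 0
            Vi = np.linalg.inv(V)
            yVy = y @ Vi @ y
            u = Xc.T @ Vi @ y
            S = Xc.T @ Vi @ Xc
            bounds = [[-4.0, 4.0], [-1.0, 2.0], [np.log(1e-6), np.log(2.0)]]
            best = -np.inf
            for _ in range(40):
                a0 = np.linspace(*bounds[0], 13)
                b1 = np.linspace(*bounds[1], 13)
                ls2 = np.linspace(*bounds[2], 13)
                q = (
                    yVy
                    - 2 * (a0[:, None] * u[0] + b1[None, :] * u[1])
                    + a0[:, None] ** 2 * S[0, 0]
                    + 2 * a0[:, None] * b1[None, :] * S[0, 1]
                    + b1[None, :] ** 2 * S[1, 1]
                )
                ll = -0.5 * (
                    n * (np.log(2 * np.pi) + ls2[None, None, :])
                    + logdet
                    + q[:, :, None] / np.exp(ls2)[None, None, :]
                )
                idx = np.unravel_index(np.argmax(ll), ll.shape)
                best = max(best, float(ll[idx]))
                for d, (ax, i) in enumerate(zip((a0, b1, ls2), idx)):
                    step = ax[1] - ax[0]
                    width = ax[-1] - ax[0]
                    if i in (0, len(ax) - 1):
                        # argmax on the box edge: slide the box, keep width
                        shift = -width / 2 if i == 0 else width / 2
                        bounds[d] = [ax[0] + shift, ax[-1] + shift]
                    else:
                        bounds[d] = [ax[i] - step, ax[i] + step]
            return best

        lam_grid = np.linspace(1e-6, 1.0, 41)
        best = max(best_at_lambda(l) for l in lam_grid)
        # refine lambda around its coarse argmax
        i = int(np.argmax([best_at_lambda(l) for l in lam_grid]))
        for l in np.linspace(
            lam_grid[max(i - 1, 0)], lam_grid[min(i + 1, len(lam_grid) - 1)], 41
        ):
            best = max(best, best_at_lambda(l))
        assert res.llf >= best - 1e-4
        assert res.llf == pytest.approx(best, abs=1e-3)

    def test_profile_max_not_below_grid(self, rng):
        tree = simulate_tree(40, seed=3)
        taxa = sorted(tree.tip_names)
        cov = vcv_from_tree(tree, taxa)
        df = simulate_allometry(tree, -1.0, 0.75, 0.5, 0.05, (0, 6), seed=4, taxa_order=taxa)
        m = PGLS(df["log10_agr"], df["log10_bmatmg"], cov=cov)
        res = m.fit()
        lo, hi = m.lambda_bounds()
        for lam in np.linspace(lo, hi, 41):
            assert res.llf >= m.profile_loglik(lam) - 1e-9

    def test_iid_residuals_give_lambda_near_zero(self, rng):
        """Residuals generated without phylogenetic signal on a deep tree
        are fit with lambda near 0."""
        tree = simulate_tree(150, seed=11)
        taxa = sorted(tree.tip_names)
        cov = vcv_from_tree(tree, taxa)
        x = rng.uniform(0, 6, 150)
        y = -1.0 + 0.75 * x + rng.normal(0, 0.2, 150)
        res = PGLS(y, x, cov=cov).fit()
        assert abs(res.lambda_) < 0.25

    def test_brownian_residuals_give_lambda_near_one(self):
        """Data generated at lambda = 1 are fit with lambda close to 1 in
        most replicates."""
        hits = 0
        for s in range(10):
            tree = simulate_tree(150, seed=500 + s)
            taxa = sorted(tree.tip_names)
            cov = vcv_from_tree(tree, taxa)
            df = simulate_allometry(
                tree, -1.0, 0.75, 1.0, 0.05, (0, 6), seed=600 + s, taxa_order=taxa
            )
            res = PGLS(df["log10_agr"], df["log10_bmatmg"], cov=cov).fit()
            hits += 0.85 <= res.lambda_ <= 1.15
        assert hits >= 8

    def test_flat_profile_warns_on_star_tree(self, star_tree, rng):
        """On an ultrametric star tree the covariance is diagonal, lambda
        drops out of the likelihood, and the fit must warn and report the
        smallest-magnitude lambda."""
        cov = vcv_from_tree(star_tree, ["A", "B", "C"])
        x = np.array([0.0, 1.0, 2.0])
        y = np.array([0.1, 1.0, 1.7])
        with pytest.warns(UserWarning, match="flat"):
            res = PGLS(y, x, cov=cov).fit()
        assert abs(res.lambda_) < 0.1

    def test_restrict_lambda_flag(self, rng):
        tree = simulate_tree(30, seed=21)
        taxa = sorted(tree.tip_names)
        cov = vcv_from_tree(tree, taxa)
        x = rng.uniform(0, 6, 30)
        y = -1.0 + 0.75 * x + rng.normal(0, 0.2, 30)
        res = PGLS(y, x, cov=cov, restrict_lambda=True).fit()
        assert -1e-6 <= res.lambda_ <= 1.0 + 1e-6


class TestResultsAndAIC:
    def test_aic_parameter_counts(self, rng):
        tree = simulate_tree(25, seed=2)
        taxa = sorted(tree.tip_names)
        cov = vcv_from_tree(tree, taxa)
        df = simulate_allometry(tree, -1.0, 0.75, 0.8, 0.05, (0, 6), seed=3, taxa_order=taxa)
        y, x = df["log10_agr"].to_numpy(), df["log10_bmatmg"].to_numpy()
        fits = {
            "pgls_free": PGLS(y, x, cov=cov).fit(),
            "pgls_fixed": PGLS(y, x, cov=cov, fixed_slope=0.75).fit(),
            "ols_free": PGLS(y, x).fit(),
            "ols_fixed": PGLS(y, x, fixed_slope=0.75).fit(),
        }
        for variant, res in fits.items():
            assert res.variant == variant
            assert res.aic == pytest.approx(-2 * res.llf + 2 * AIC_PARAM_COUNT[variant])

    def test_fixed_slope_nested_in_free(self, rng):
        """The fixed-slope likelihood can never exceed the free-slope one;
        on data generated with the fixed slope its AIC is competitive."""
        tree = simulate_tree(60, seed=31)
        taxa = sorted(tree.tip_names)
        cov = vcv_from_tree(tree, taxa)
        df = simulate_allometry(tree, -1.0, 0.75, 0.8, 0.05, (0, 6), seed=32, taxa_order=taxa)
        y, x = df["log10_agr"].to_numpy(), df["log10_bmatmg"].to_numpy()
        free = PGLS(y, x, cov=cov).fit()
        fixed = PGLS(y, x, cov=cov, fixed_slope=0.75).fit()
        assert fixed.llf <= free.llf + 1e-9
        assert fixed.slope == 0.75
        assert np.isnan(fixed.bse[1])
        ci = fixed.conf_int()
        assert ci[1, 0] == ci[1, 1] == 0.75

    def test_confidence_interval_t_quantile(self):
        """n large, SE 0.02, estimate -0.506: the 95% CI is about
        [-0.545, -0.467] (t quantile ~1.967 at 341 df)."""
        from dataclasses import replace

        x = np.linspace(0, 6, 343)
        res = ols_fit(-0.506 + 0.0 * x + np.sin(np.arange(343)), x, fixed_slope=0.0)
        res = replace(res, params=np.array([-0.506, 0.0]), bse=np.array([0.02, np.nan]))
        lo, hi = res.conf_int()[0]
        assert lo == pytest.approx(-0.545, abs=1e-3)
        assert hi == pytest.approx(-0.467, abs=1e-3)
        assert 0.5 * (lo + hi) == pytest.approx(-0.506, abs=1e-12)

    def test_serializable(self, rng):
        import json

        x = rng.uniform(0, 6, 10)
        y = -1.0 + 0.75 * x + rng.normal(0, 0.2, 10)
        d = ols_fit(y, x).to_dict()
        json.dumps(d)
        assert d["variant"] == "ols_free" and d["n"] == 10

    def test_summary_renders(self, rng):
        x = rng.uniform(0, 6, 10)
        y = -1.0 + 0.75 * x + rng.normal(0, 0.2, 10)
        s = ols_fit(y, x).summary()
        assert "intercept" in s and "AIC" in s
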