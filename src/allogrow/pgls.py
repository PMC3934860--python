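"""Phylogenetic generalized least squares with profiled Pagel's lambda.

The model is a log10-log10 allometry

    log10 AGR = intercept + slope * log10 BMatMG + e,   e ~ N(0, sigma2 * C_lambda)

where C_lambda is the Brownian covariance of the phylogeny with its
off-diagonal scaled by Pagel's lambda.  For a given lambda the mean
parameters and sigma2 have closed-form maximum-likelihood solutions, so
lambda is profiled: a coarse grid over the positive-definite feasible
interval followed by bounded local refinement.  Ordinary least squares is
the special case of an identity covariance (and is also what lambda = 0
reduces to on trees with equal tip heights).

Estimation is ML (not REML) throughout so that AIC values are comparable
across mean structures — in particular between the free-slope model and the
model with the slope fixed at the 3/4 value predicted by metabolic scaling
theory.

Usage follows the Model/Results convention::

    model = PGLS(y, x, cov=vcv_from_tree(tree, taxa))
    res = model.fit()           # profiles lambda
    res.params, res.conf_int(), res.lambda_, res.aic
    print(res.summary())

    PGLS(y, x, cov=cov, fixed_slope=0.75).fit()   # normalization constant
    PGLS(y, x).fit()                              # OLS
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .trees import PhyloCovariance, feasible_lambda_range, lambda_matrix

__all__ = ["PGLS", "PGLSResults", "gls_estimate", "profile_lambda_fit", "ols_fit"]

#: Number of mean+variance+correlation parameters counted in the AIC for
#: each model variant: free slope adds a slope, a phylogenetic fit adds
#: lambda, and every variant counts the intercept and sigma2.
AIC_PARAM_COUNT = {"pgls_free": 4, "pgls_fixed": 3, "ols_free": 3, "ols_fixed": 2}

_FLAT_TOL = 1e-8
_GRID_POINTS = 201
_EDGE = 1e-6  # stay this far inside the PD-feasible lambda interval


class PGLS:
    """Allometric regression model with optional phylogenetic covariance.

    Parameters
    ----------
    endog : array-like
        Response (log10 AGR).
    exog : array-like
        Single predictor (log10 BMatMG); the design matrix is built as
        ``[1, exog]`` internally.
    cov : PhyloCovariance, optional
        Brownian covariance from :func:`~allogrow.trees.vcv_from_tree`,
        ordered like the observations.  ``None`` requests an iid (OLS) fit.
    fixed_slope : float, optional
        Fix the slope (typically at 0.75) and estimate only the intercept —
        the normalization-constant model.
    restrict_lambda : bool
        Restrict the lambda search to [0, 1] instead of the full
        positive-definite feasible interval (which admits negative values).
    """

    def __init__(
        self,
        endog,
        exog,
        cov: Optional[PhyloCovariance] = None,
        fixed_slope: Optional[float] = None,
        restrict_lambda: bool = False,
    ):
        self.endog = np.asarray(endog, float).ravel()
        self.exog = np.asarray(exog, float).ravel()
        if self.endog.shape != self.exog.shape:
            raise ValueError("endog and exog must have equal length")
        if not (np.all(np.isfinite(self.endog)) and np.all(np.isfinite(self.exog))):
            raise ValueError("non-finite values in regression data")
        self.nobs = self.endog.size
        self.cov = cov
        self.fixed_slope = fixed_slope
        self.restrict_lambda = restrict_lambda
        q = 1 if fixed_slope is not None else 2
        if self.nobs < q + 1:
            raise ValueError(f"need at least {q + 1} observations, got {self.nobs}")
        if cov is not None and cov.n != self.nobs:
            raise ValueError("covariance dimension does not match data")
        if fixed_slope is None and np.ptp(self.exog) == 0:
            raise ValueError("predictor has zero variance; free slope not estimable")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        y: str = "log10_agr",
        x: str = "log10_bmatmg",
        **kwargs,
    ) -> "PGLS":
        return cls(df[y].to_numpy(), df[x].to_numpy(), **kwargs)

    # -- likelihood machinery ------------------------------------------------

    def _design(self) -> tuple[np.ndarray, np.ndarray]:
        """(working response, design matrix); the fixed slope is absorbed
        into the response."""
        if self.fixed_slope is not None:
            return self.endog - self.fixed_slope * self.exog, np.ones((self.nobs, 1))
        return self.endog, np.column_stack([np.ones(self.nobs), self.exog])

    def _V(self, lam: Optional[float]) -> Optional[np.ndarray]:
        if self.cov is None:
            return None
        return lambda_matrix(self.cov, 1.0 if lam is None else lam)

    def _gls(self, V: Optional[np.ndarray]):
        """Closed-form ML solve under covariance sigma2*V.

        Returns (beta, cov_beta_unit, sigma2_ml, rss_gls, loglik, resid,
        logdetV) where cov_beta_unit is (X' V^-1 X)^-1, to be scaled by a
        variance estimate.
        """
        y, X = self._design()
        n = self.nobs
        if V is None:
            factor = None
            Vi_y, Vi_X, logdet = y, X, 0.0
        else:
            factor = linalg.cho_factor(V, lower=True)
            logdet = 2.0 * float(np.sum(np.log(np.diag(factor[0]))))
            Vi_y = linalg.cho_solve(factor, y)
            Vi_X = linalg.cho_solve(factor, X)
        XtViX = X.T @ Vi_X
        try:
            xvx_inv = linalg.inv(XtViX)
        except linalg.LinAlgError:
            raise ValueError("rank-deficient design matrix") from None
        beta = xvx_inv @ (X.T @ Vi_y)
        resid = y - X @ beta
        # quadratic form computed from the residual itself (not the shortcut
        # r' V^-1 y) so that near-perfect fits do not lose precision to
        # cancellation against the large fitted part of y
        Vi_r = resid if factor is None else linalg.cho_solve(factor, resid)
        rss = max(float(resid @ Vi_r), 0.0)
        sigma2 = rss / n
        scale = float(y @ y) / n  # mean square of the working response
        if sigma2 <= 1e-24 * max(scale, 1e-300):
            sigma2 = 0.0
            loglik = np.inf  # degenerate perfect fit
        else:
            loglik = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
        return beta, xvx_inv, sigma2, rss, loglik, resid, logdet

    def profile_loglik(self, lam: float) -> float:
        """ML log-likelihood at ``lam`` with mean and sigma2 profiled out."""
        try:
            return self._gls(self._V(lam))[4]
        except (linalg.LinAlgError, np.linalg.LinAlgError):
            return -np.inf

    def lambda_bounds(self) -> tuple[float, float]:
        if self.cov is None:
            raise ValueError("iid model has no lambda")
        lo, hi = feasible_lambda_range(self.cov)
        if self.restrict_lambda:
            lo, hi = max(lo, 0.0), min(hi, 1.0)
        return lo + _EDGE, hi - _EDGE

    # -- fitting -------------------------------------------------------------

    def fit(self, lam: Optional[float] = None) -> "PGLSResults":
        """Fit the model.

        With a phylogenetic covariance and ``lam=None``, lambda is profiled
        (201-point grid over the feasible interval, then Brent refinement
        between the neighbours of the grid optimum; flat-profile ties break
        toward the smallest magnitude lambda).  With ``lam`` given, the fit
        conditions on that value.  Without a covariance this is OLS.
        """
        if self.cov is None:
            return self._finish(None, None)
        if lam is not None:
            lo, hi = self.lambda_bounds()
            if not (lo - _EDGE <= lam <= hi + _EDGE):
                raise ValueError(
                    f"lambda = {lam} outside feasible interval [{lo:.6g}, {hi:.6g}]"
                )
            return self._finish(lam, None)

        lo, hi = self.lambda_bounds()
        grid = np.linspace(lo, hi, _GRID_POINTS)
        ll = np.array([self.profile_loglik(g) for g in grid])
        finite = np.isfinite(ll)
        if np.any(np.isposinf(ll)):
            # perfect fit at some lambda; take it
            best = int(np.argmax(np.isposinf(ll)))
            return self._finish(float(grid[best]), None)
        if not finite.any():
            raise ValueError("likelihood not computable anywhere on the lambda grid")
        span = ll[finite].max() - ll[finite].min()
        if span < _FLAT_TOL:
            warnings.warn(
                "profile likelihood is flat in lambda; reporting the smallest "
                "|lambda| on the grid (lambda is unidentifiable for this data)",
                stacklevel=2,
            )
            lam_hat = float(grid[np.argmin(np.abs(grid))])
            return self._finish(lam_hat, grid_max=ll[finite].max())
        i = int(np.nanargmax(np.where(finite, ll, -np.inf)))
        a = grid[max(i - 1, 0)]
        b = grid[min(i + 1, len(grid) - 1)]
        if a == b:
            lam_hat = float(grid[i])
        else:
            res = optimize.minimize_scalar(
                lambda l: -self.profile_loglik(l),
                bounds=(a, b),
                method="bounded",
                options={"xatol": 1e-8},
            )
            lam_hat = float(res.x) if -res.fun >= ll[i] else float(grid[i])
        return self._finish(lam_hat, grid_max=ll[i])

    def fit_ols(self) -> "PGLSResults":
        """Ordinary least squares on the same data, ignoring the phylogeny."""
        return PGLS(
            self.endog, self.exog, cov=None, fixed_slope=self.fixed_slope
        ).fit()

    def _finish(self, lam: Optional[float], grid_max: Optional[float]) -> "PGLSResults":
        beta, xvx_inv, sigma2, rss, loglik, resid, _ = self._gls(self._V(lam))
        if grid_max is not None and np.isfinite(loglik) and loglik < grid_max - 1e-9:
            # refinement must never lose to the grid
            raise AssertionError("profile refinement below grid maximum")
        q = 1 if self.fixed_slope is not None else 2
        n = self.nobs
        df_resid = n - q
        s2 = rss / df_resid if df_resid > 0 else np.nan
        bse = np.sqrt(np.maximum(np.diag(xvx_inv) * s2, 0.0))
        if self.fixed_slope is not None:
            params = np.array([beta[0], self.fixed_slope])
            bse_full = np.array([bse[0], np.nan])
        else:
            params = beta.copy()
            bse_full = bse
        if self.cov is None:
            variant = "ols_fixed" if self.fixed_slope is not None else "ols_free"
        else:
            variant = "pgls_fixed" if self.fixed_slope is not None else "pgls_free"
        p = AIC_PARAM_COUNT[variant]
        aic = -2.0 * loglik + 2.0 * p if np.isfinite(loglik) else -np.inf
        return PGLSResults(
            model=self,
            params=params,
            bse=bse_full,
            lambda_=lam,
            sigma2=sigma2,
            llf=float(loglik),
            aic=float(aic),
            resid=resid,
            nobs=n,
            df_resid=df_resid,
            variant=variant,
            k_params=p,
        )


@dataclass
class PGLSResults:
    """Results of a PGLS/OLS fit: estimates, uncertainties, diagnostics.

    ``params`` is ``[intercept, slope]``; for fixed-slope variants the slope
    entry is the fixed value and its standard error is NaN.  Confidence
    intervals are Wald t intervals conditional on the estimated lambda.
    """

    model: PGLS
    params: np.ndarray
    bse: np.ndarray
    lambda_: Optional[float]
    sigma2: float
    llf: float
    aic: float
    resid: np.ndarray
    nobs: int
    df_resid: int
    variant: str
    k_params: int

    _NAMES = ("intercept", "slope")

    @property
    def intercept(self) -> float:
        return float(self.params[0])

    @property
    def slope(self) -> float:
        return float(self.params[1])

    @property
    def perfect_fit(self) -> bool:
        return not np.isfinite(self.llf) and self.llf > 0

    def _tq(self, alpha: float) -> float:
        return float(stats.t.ppf(1 - alpha / 2, self.df_resid))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        """Rows ``[low, high]`` for intercept and slope.  A fixed slope has a
        degenerate interval at its value; a zero standard error likewise
        degenerates to a point."""
        tq = self._tq(alpha)
        out = np.empty((2, 2))
        for i in range(2):
            se = self.bse[i]
            if np.isnan(se):
                out[i] = (self.params[i], self.params[i])
            else:
                out[i] = (self.params[i] - tq * se, self.params[i] + tq * se)
        return out

    @property
    def pvalues(self) -> np.ndarray:
        """Two-sided t tests of each coefficient against zero (the fixed
        slope has no test)."""
        out = np.full(2, np.nan)
        for i in range(2):
            if np.isnan(self.bse[i]) or self.bse[i] == 0:
                continue
            t = self.params[i] / self.bse[i]
            out[i] = 2 * stats.t.sf(abs(t), self.df_resid)
        return out

    @property
    def normalization_constant(self) -> float:
        """Back-transformed intercept, 10^intercept: predicted AGR (g/day)
        of a 1 g mass at maximum growth."""
        return float(10.0 ** self.intercept)

    def residual_variation(self) -> np.ndarray:
        """Per-species residual plus the intercept — the deviation of each
        species re-centred on the group's regression level, used to compare
        within-group spread across groups."""
        return self.resid + self.intercept

    def to_dict(self) -> dict:
        ci = self.conf_int()
        return {
            "variant": self.variant,
            "n": int(self.nobs),
            "intercept": self.intercept,
            "se_intercept": float(self.bse[0]),
            "ci95_intercept": [float(ci[0, 0]), float(ci[0, 1])],
            "slope": self.slope,
            "se_slope": None if np.isnan(self.bse[1]) else float(self.bse[1]),
            "ci95_slope": [float(ci[1, 0]), float(ci[1, 1])],
            "lambda": None if self.lambda_ is None else float(self.lambda_),
            "sigma2": float(self.sigma2),
            "loglik": self.llf,
            "aic": self.aic,
            "residuals": [float(r) for r in self.resid],
        }

    def summary(self) -> str:
        ci = self.conf_int()
        pv = self.pvalues
        lines = [
            f"PGLS results ({self.variant}), n = {self.nobs}",
            "=" * 64,
            f"{'':12s}{'coef':>10s}{'se':>10s}{'[0.025':>10s}{'0.975]':>10s}{'p':>10s}",
        ]
        for i, name in enumerate(self._NAMES):
            se = "fixed" if np.isnan(self.bse[i]) else f"{self.bse[i]:.4f}"
            p = "" if np.isnan(pv[i]) else f"{pv[i]:.3g}"
            lines.append(
                f"{name:12s}{self.params[i]:>10.4f}{se:>10s}"
                f"{ci[i, 0]:>10.4f}{ci[i, 1]:>10.4f}{p:>10s}"
            )
        lam = "-" if self.lambda_ is None else f"{self.lambda_:.4f}"
        lines += [
            "-" * 64,
            f"lambda = {lam}   sigma2 = {self.sigma2:.6g}   "
            f"loglik = {self.llf:.4f}   AIC = {self.aic:.4f}",
            f"10^intercept (normalization constant) = {self.normalization_constant:.4g} g/day",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional wrappers


def gls_estimate(
    y,
    x,
    cov: Optional[PhyloCovariance],
    lam: Optional[float] = None,
    fixed_slope: Optional[float] = None,
):
    """Closed-form GLS at a fixed lambda: ``(coefficients, sigma2, loglik)``.

    With ``cov=None`` (iid) the coefficients equal ordinary least squares.
    """
    model = PGLS(y, x, cov=cov, fixed_slope=fixed_slope)
    res = model.fit(lam=lam) if cov is not None else model.fit()
    coefs = np.array([res.intercept]) if fixed_slope is not None else res.params
    return coefs, res.sigma2, res.llf


def profile_lambda_fit(
    y, x, cov: PhyloCovariance, fixed_slope: Optional[float] = None, **kwargs
) -> PGLSResults:
    """Fit with lambda profiled over its feasible interval."""
    return PGLS(y, x, cov=cov, fixed_slope=fixed_slope, **kwargs).fit()


def ols_fit(y, x, fixed_slope: Optional[float] = None) -> PGLSResults:
    """Ordinary least squares fit (iid errors)."""
    return PGLS(y, x, cov=None, fixed_slope=fixed_slope).fit()
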