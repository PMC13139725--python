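"""Mixed-effect trend models for cross-channel z-scores.

The response is the standardized effect size z of one cross-channel pair;
fixed effects are longitudinal position (1 = downstream ... 6 = upstream)
and visit (1-4), both entered as numeric covariates so each model reports a
single slope per gradient; a random intercept is fitted for every site
nested in its catchment (i.e. one intercept per catchment:site unit).
Fitting is REML via statsmodels' MixedLM.

Wald t statistics use a residual degrees-of-freedom approximation
(df = n - p); the method is recorded on the fit so readers know the p-values
are not Satterthwaite-corrected. When the REML group variance collapses to
the boundary the model is refit by ordinary least squares, reported with
var_random = 0 and a ``singular`` flag — by construction a zero-variance
fit is then *exactly* the OLS solution on the same design.

Variance explained is summarized with marginal / conditional R2:

    R2_marginal    = var_fixed / (var_fixed + var_random + var_residual)
    R2_conditional = (var_fixed + var_random) / (same denominator)

where var_fixed is the variance of the fixed-effect predictions (n-1
denominator, the convention of the R ecosystem these statistics come from).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLMParams

logger = logging.getLogger(__name__)

FIXED_EFFECTS = ("intercept", "position", "visit")


@dataclass
class TrendFit:
    """Result of one mixed-model fit (one dataset x component)."""

    dataset: str
    component: str
    n_observations: int
    n_dropped: int
    estimates: dict[str, float]
    se: dict[str, float]
    pvalues: dict[str, float]
    var_random: float
    var_residual: float
    r2_marginal: float
    r2_conditional: float
    singular: bool
    df_method: str
    df_resid: float
    random_structure: str = "catchment:site"
    extras: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            "dataset": self.dataset,
            "component": self.component,
            "n_obs": self.n_observations,
            "n_dropped": self.n_dropped,
            "var_random": self.var_random,
            "var_residual": self.var_residual,
            "r2_marginal": self.r2_marginal,
            "r2_conditional": self.r2_conditional,
            "singular": self.singular,
            "df_method": self.df_method,
        }
        for name in FIXED_EFFECTS:
            row[f"{name}_estimate"] = self.estimates[name]
            row[f"{name}_se"] = self.se[name]
            row[f"{name}_p"] = self.pvalues[name]
        return row


def nakagawa_r2(
    var_fixed: float, var_random: float, var_residual: float
) -> tuple[float, float]:
    """Marginal and conditional R2 from variance components.

    Undefined (NaN, NaN) when all three components are zero.
    """
    if min(var_fixed, var_random, var_residual) < 0:
        raise ValueError("variance components must be non-negative")
    total = var_fixed + var_random + var_residual
    if total == 0:
        return float("nan"), float("nan")
    return var_fixed / total, (var_fixed + var_random) / total


def _ols_fit(y: np.ndarray, X: np.ndarray):
    res = sm.OLS(y, X).fit()
    return res.params, res.bse, float(res.mse_resid)


def fit_lmm(
    records: pd.DataFrame,
    dataset: str = "",
    component: str = "total",
    response: str = "z",
    singular_tol: float = 1e-8,
) -> TrendFit:
    """Fit z ~ position + visit + (1 | catchment:site) by REML.

    ``records`` needs columns ``{response}, position, visit, catchment,
    site_code``. Rows with an undefined response are dropped with a logged
    count. A boundary (zero) random-effect variance yields an OLS refit
    flagged ``singular`` rather than an exception.
    """
    needed = {response, "position", "visit", "catchment", "site_code"}
    missing = needed - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    data = records.dropna(subset=[response]).copy()
    n_dropped = len(records) - len(data)
    if n_dropped:
        logger.info("dropped %d record(s) with undefined %s", n_dropped, response)
    if data["position"].nunique() < 2 or data["visit"].nunique() < 2:
        raise ValueError("need >= 2 longitudinal positions and >= 2 visits")
    data["group"] = data["catchment"].astype(str) + ":" + data["site_code"].astype(str)
    data = data.sort_values(["group", "visit"]).reset_index(drop=True)

    y = data[response].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(data)), data["position"].to_numpy(float), data["visit"].to_numpy(float)]
    )
    n, p = X.shape

    singular = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.MixedLM(y, X, groups=data["group"].to_numpy())
            fit = model.fit(reml=True)
            var_random = float(np.squeeze(fit.cov_re))
            var_residual = float(fit.scale)
            params = np.asarray(fit.fe_params, dtype=float)
            bse = np.asarray(fit.bse_fe, dtype=float)
            if var_random <= singular_tol * (var_random + var_residual):
                singular = True
            else:
                # the optimizer can stall short of a boundary optimum:
                # declare the fit singular whenever the profiled REML
                # log-likelihood at zero group variance is at least as good
                boundary = MixedLMParams.from_components(
                    fe_params=params, cov_re=np.array([[1e-10]])
                )
                if model.loglike(boundary, profile_fe=True) >= fit.llf - 1e-8:
                    singular = True
        except Exception:  # numerical failure -> boundary treatment
            singular = True
    if singular:
        params, bse, var_residual = _ols_fit(y, X)
        params = np.asarray(params, dtype=float)
        bse = np.asarray(bse, dtype=float)
        var_random = 0.0

    df_resid = float(n - p)
    tvals = params / bse
    pvals = 2 * stats.t.sf(np.abs(tvals), df_resid)

    var_fixed = float(np.var(X @ params, ddof=1))
    r2m, r2c = nakagawa_r2(var_fixed, var_random, var_residual)

    return TrendFit(
        dataset=dataset,
        component=component,
        n_observations=n,
        n_dropped=n_dropped,
        estimates=dict(zip(FIXED_EFFECTS, params)),
        se=dict(zip(FIXED_EFFECTS, bse)),
        pvalues=dict(zip(FIXED_EFFECTS, pvals)),
        var_random=var_random,
        var_residual=var_residual,
        r2_marginal=r2m,
        r2_conditional=r2c,
        singular=singular,
        df_method="residual-t",
        df_resid=df_resid,
    )


def component_trends(ses: pd.DataFrame, drop_degenerate: bool = False) -> list[TrendFit]:
    """Fit the trend model for every (dataset, component) in a long SES table."""
    fits: list[TrendFit] = []
    data = ses
    if drop_degenerate and "degenerate" in data.columns:
        data = data[~data["degenerate"]]
    for (dataset, component), grp in data.groupby(["dataset", "component"], sort=True):
        fits.append(fit_lmm(grp, dataset=dataset, component=component))
    return fits


def trend_table(fits: list[TrendFit]) -> pd.DataFrame:
    """Flatten TrendFits into one summary row each."""
    return pd.DataFrame([f.to_row() for f in fits])
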