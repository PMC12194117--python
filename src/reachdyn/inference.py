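"""Session-level summarization and statistical inference.

The analysis unit is the session: for each unique combination of grouping
variables (monkey, session, condition, target / target group / rank bin /
movement class) the per-trial response measure is reduced to its median.
Condition effects are expressed as percent change,

    100 * (median during block - median during control) / reference,

with the control median as the default reference (change measures for torque
impulses instead use the maximum absolute target-wise control median, since
impulses near zero make a per-target ratio unstable).

Percent changes are then modelled with a linear mixed-effects model with a
monkey-level random intercept (maximum likelihood), and hypotheses are
tested as Wald contrasts on the fixed effects with a t reference
distribution (residual degrees of freedom).  Families of post hoc contrasts
are corrected with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "EffectEstimate",
    "MixedEffectsModel",
    "MixedEffectsResults",
    "percent_change",
    "session_medians",
    "fit_mixed_model",
    "contrast_test",
    "bh_adjust",
    "partial_correlation",
]


@dataclass
class EffectEstimate:
    """One tested contrast: percent-change estimate, 95% CI and p-values."""

    label: str
    estimate: float
    ci_low: float
    ci_high: float
    p: float
    p_bh: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if not self.ci_low <= self.estimate <= self.ci_high:
            raise ValueError("confidence interval must bracket the estimate")


def percent_change(block_median: float, control_median: float,
                   reference: float | None = None) -> float:
    """Percent change of the block-condition median relative to control."""
    ref = control_median if reference is None else reference
    if ref == 0:
        raise ZeroDivisionError("zero reference median in percent change")
    return 100.0 * (block_median - control_median) / ref


def session_medians(
    table: pd.DataFrame,
    value_col: str = "value",
    by: list[str] = ("monkey", "session", "condition", "target"),
) -> pd.DataFrame:
    """Median of the response over trials for each unique grouping."""
    out = table.groupby(list(by), as_index=False, observed=True)[value_col].median()
    return out


class MixedEffectsModel:
    """Linear mixed-effects model of session summaries (statsmodels-backed).

    Parameters
    ----------
    data : tidy session-summary table, one row per session-level value.
    formula : patsy fixed-effects formula, e.g. ``"value ~ C(group)"``.
    groups : column holding the subject (monkey) identifier; modelled as a
        random intercept.  With fewer than two subjects the model degrades to
        an ordinary fixed-intercept least-squares fit (with a warning).
    """

    def __init__(self, data: pd.DataFrame, formula: str, groups: str = "monkey"):
        self.data = data.reset_index(drop=True)
        self.formula = formula
        self.groups = groups

    @classmethod
    def from_summaries(cls, data: pd.DataFrame, formula: str,
                       groups: str = "monkey") -> "MixedEffectsModel":
        return cls(data, formula, groups)

    def fit(self) -> "MixedEffectsResults":
        n_groups = self.data[self.groups].nunique()
        if n_groups < 2:
            warnings.warn(
                "single subject: random intercept is degenerate, "
                "falling back to a fixed-intercept OLS fit",
                stacklevel=2,
            )
            res = smf.ols(self.formula, data=self.data).fit()
            params = res.params
            cov = res.cov_params()
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                warnings.simplefilter("ignore", UserWarning)
                mod = smf.mixedlm(self.formula, data=self.data,
                                  groups=self.data[self.groups])
                try:
                    res = mod.fit(reml=False, method=["lbfgs", "bfgs", "cg"])
                    fe = res.fe_params
                    sigma2_hat = float(res.scale)
                    tau2_hat = float(np.asarray(res.cov_re)[0, 0])
                except (np.linalg.LinAlgError, ValueError):
                    # ML landed on a degenerate boundary; fall back to OLS
                    # point estimates with method-of-moments variance
                    # components for the GLS covariance below.
                    res = smf.ols(self.formula, data=self.data).fit()
                    fe = res.params
                    sigma2_hat = float(res.mse_resid)
                    resid = np.asarray(res.resid)
                    labels0 = np.asarray(self.data[self.groups])
                    gm = np.array([resid[labels0 == g].mean()
                                   for g in np.unique(labels0)])
                    ng_mean = resid.size / gm.size
                    tau2_hat = max(0.0, float(gm.var(ddof=1)) - sigma2_hat / ng_mean)
            # Recompute the fixed effects and their covariance by explicit
            # GLS at the estimated variance components.  This is robust to
            # boundary fits (tau^2 -> 0), where the optimizer's profiled
            # fixed effects and Hessian-based covariance can be inconsistent:
            # V_g = sigma^2 I + tau^2 11',
            # beta = (sum X_g' V_g^-1 X_g)^-1 sum X_g' V_g^-1 y_g,
            # cov(beta) = (sum X_g' V_g^-1 X_g)^-1.
            sigma2 = max(sigma2_hat, 1e-12)
            tau2 = max(tau2_hat, 0.0)
            X = np.asarray(res.model.exog)
            y = np.asarray(res.model.endog)
            labels = np.asarray(self.data[self.groups])
            k = X.shape[1]
            info = np.zeros((k, k))
            score = np.zeros(k)
            for g in np.unique(labels):
                sel = labels == g
                Xg, yg = X[sel], y[sel]
                ng = Xg.shape[0]
                shrink = tau2 / (sigma2 * (sigma2 + ng * tau2))
                ones_X = Xg.sum(axis=0, keepdims=True)
                info += Xg.T @ Xg / sigma2 - shrink * (ones_X.T @ ones_X)
                score += Xg.T @ yg / sigma2 - shrink * ones_X[0] * yg.sum()
            beta = np.linalg.solve(info, score)
            params = pd.Series(beta, index=fe.index)
            cov = pd.DataFrame(np.linalg.inv(info),
                               index=fe.index, columns=fe.index)
        exog_rank = np.linalg.matrix_rank(res.model.exog)
        if exog_rank < res.model.exog.shape[1]:
            raise ValueError(
                "rank-deficient fixed-effects design: aliased terms "
                f"{list(params.index)}"
            )
        return MixedEffectsResults(
            params=params,
            cov=cov,
            nobs=int(res.model.exog.shape[0]),
            df_resid=int(res.model.exog.shape[0] - exog_rank),
            statsmodels_result=res,
            model=self,
        )


@dataclass
class MixedEffectsResults:
    """Fitted fixed effects, their covariance, and Wald contrast machinery."""

    params: pd.Series
    cov: pd.DataFrame
    nobs: int
    df_resid: int
    statsmodels_result: object = field(repr=False)
    model: MixedEffectsModel = field(repr=False)

    @property
    def coef_names(self) -> list[str]:
        return list(self.params.index)

    def contrast(self, weights: np.ndarray | dict, label: str = "contrast",
                 alpha: float = 0.05) -> EffectEstimate:
        """Wald t-test of ``w' beta = 0`` with a 1 - alpha confidence interval."""
        if isinstance(weights, dict):
            w = np.zeros(len(self.params))
            for name, val in weights.items():
                w[self.coef_names.index(name)] = val
        else:
            w = np.asarray(weights, dtype=float)
        if w.shape != (len(self.params),):
            raise ValueError(
                f"contrast length {w.size} != coefficient count {len(self.params)}"
            )
        if not np.any(w):
            raise ValueError("all-zero contrast weights are degenerate")
        est = float(w @ self.params.to_numpy())
        var = float(w @ self.cov.to_numpy() @ w)
        se = np.sqrt(var)
        df = max(self.df_resid, 1)
        if se == 0:
            p, half = (1.0, 0.0) if est == 0 else (0.0, 0.0)
        else:
            tstat = est / se
            p = 2 * stats.t.sf(abs(tstat), df)
            half = stats.t.ppf(1 - alpha / 2, df) * se
        return EffectEstimate(label=label, estimate=est, ci_low=est - half,
                              ci_high=est + half, p=float(p), n=self.nobs)

    def summary(self) -> str:
        lines = [
            "Mixed-effects fit (ML, random intercept by "
            f"'{self.model.groups}'): {self.model.formula}",
            f"n_obs = {self.nobs}, df_resid = {self.df_resid}",
            f"{'coef':<40s}{'estimate':>12s}{'se':>12s}",
        ]
        se = np.sqrt(np.diag(self.cov.to_numpy()))
        for name, b, s in zip(self.coef_names, self.params, se):
            lines.append(f"{name:<40s}{b:>12.4f}{s:>12.4f}")
        return "\n".join(lines)


def fit_mixed_model(summary_table: pd.DataFrame, formula: str,
                    groups: str = "monkey") -> MixedEffectsResults:
    """Fit ``formula`` on a session-summary table with a monkey random intercept."""
    return MixedEffectsModel(summary_table, formula, groups=groups).fit()


def contrast_test(fit: MixedEffectsResults, weights, label: str = "contrast") -> EffectEstimate:
    """Wald test of a single fixed-effects contrast (see Results.contrast)."""
    return fit.contrast(weights, label=label)


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    controls: np.ndarray | pd.DataFrame,
) -> tuple[float, float]:
    """Correlation of x and y after removing categorical-control means.

    ``controls`` holds one or more categorical factors (e.g. monkey
    identity).  Both variables are residualized on the dummy-coded factors
    (with intercept) by least squares; the Pearson correlation of the
    residuals is returned with a p-value from the t distribution on
    ``n - 2 - k`` degrees of freedom, where k is the number of dummy
    regressors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ctrl = pd.DataFrame(controls)
    dummies = pd.get_dummies(ctrl.astype(str), drop_first=True, dtype=float)
    k = dummies.shape[1]
    n = x.size
    if n <= k + 2:
        raise ValueError("too few observations for the number of control levels")
    design = np.column_stack([np.ones(n), dummies.to_numpy()])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise ValueError("constant residuals: partial correlation undefined")
    rho = float(np.dot(rx, ry) / (n * sx * sy))
    df = n - 2 - k
    rho_c = min(max(rho, -0.9999999999), 0.9999999999)
    tstat = rho_c * np.sqrt(df / (1 - rho_c**2))
    p = float(2 * stats.t.sf(abs(tstat), df))
    return rho, p
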