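"""Linkage statistics: single-mito-predictor linear models with covariates.

The analysis design: a response-independence pre-check between the two
performance responses (take-off energy and flight endurance), a pairwise
collinearity screen over the mitochondrial predictors (justifying one model
per predictor rather than a joint fit), ordinary least squares of each
response on one mitochondrial predictor plus body mass and blood cell count,
standard residual diagnostics, and a leave-one-out refit dropping the single
most influential flagged observation (Cook's distance > 4/n).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.diagnostic import het_breuschpagan
from statsmodels.stats.outliers_influence import OLSInfluence

from .constants import DEFAULT_ALPHA, DEFAULT_COLLINEARITY_THRESHOLD
from .errors import (
    CollinearityError,
    DegenerateVarianceError,
    InsufficientDataError,
)
from .schema import COVARIATES, MITO_PREDICTORS

logger = logging.getLogger(__name__)

__all__ = [
    "ModelFit",
    "InfluenceReport",
    "IndependenceCheck",
    "CollinearityReport",
    "DiagnosticsSummary",
    "response_independence_check",
    "collinearity_screen",
    "fit_single_predictor_model",
    "influence_refit",
    "residual_diagnostics",
    "fit_all_models",
]


@dataclass
class ModelFit:
    """One fitted model: response ~ mito predictor + body mass + cell count.

    For the single-df mitochondrial term the partial F equals (b/SE)^2; the
    reported R² is the full-model coefficient of determination.
    """

    response: str
    predictor: str
    coef: float
    se: float
    t_value: float
    partial_f: float
    p_value: float
    r_squared: float
    nobs: int
    covariates: dict[str, float]
    covariate_p: dict[str, float]
    n_dropped: int = 0
    conf_int: tuple[float, float] = (np.nan, np.nan)
    _results: object = field(default=None, repr=False, compare=False)
    _data: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "predictor": self.predictor,
            "coef": self.coef,
            "se": self.se,
            "t_value": self.t_value,
            "partial_f": self.partial_f,
            "p_value": self.p_value,
            "r_squared": self.r_squared,
            "nobs": self.nobs,
            "n_dropped": self.n_dropped,
            "conf_int_low": self.conf_int[0],
            "conf_int_high": self.conf_int[1],
            "covariates": self.covariates,
            "covariate_p": self.covariate_p,
        }


@dataclass
class IndependenceCheck:
    """Pre-check fit of take-off energy on flight endurance."""

    slope: float
    se: float
    p_value: float
    r_squared: float
    nobs: int
    warning: bool  # True when p < alpha (responses look dependent)


@dataclass
class CollinearityReport:
    corr: pd.DataFrame
    flagged: list[tuple[str, str, float]]
    threshold: float

    @property
    def any_strong(self) -> bool:
        return bool(self.flagged)


@dataclass
class DiagnosticsSummary:
    """Standard OLS assumption checks for one fitted model."""

    shapiro_p: float | None
    breusch_pagan_p: float | None
    n_outliers: int          # studentized residuals with |t| > 3
    degenerate: bool
    passed: bool
    notes: list[str] = field(default_factory=list)


@dataclass
class InfluenceReport:
    cooks: np.ndarray
    threshold: float
    flagged_rows: list
    removed_row: object | None
    refit: ModelFit | None
    classification: str | None   # unchanged / weakened / reversed
    alpha: float = DEFAULT_ALPHA

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "flagged_rows": [str(r) for r in self.flagged_rows],
            "removed_row": None if self.removed_row is None else str(self.removed_row),
            "classification": self.classification,
            "refit": None if self.refit is None else self.refit.to_dict(),
        }


def _complete_rows(table: pd.DataFrame, cols: list[str]) -> tuple[pd.DataFrame, int]:
    sub = table[cols]
    keep = sub.notna().all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropping %d rows with missing values in %s", dropped, cols)
    return table.loc[keep], dropped


def _check_variance(df: pd.DataFrame, cols: list[str]) -> None:
    for c in cols:
        if np.ptp(df[c].to_numpy(dtype=float)) == 0.0:
            raise DegenerateVarianceError(c)


def _ols(df: pd.DataFrame, response: str, predictors: list[str]):
    y = df[response].to_numpy(dtype=float)
    x = sm.add_constant(df[predictors].to_numpy(dtype=float))
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise CollinearityError(
            f"design matrix for {response} ~ {predictors} is rank deficient"
        )
    return sm.OLS(y, x).fit()


def response_independence_check(
    table: pd.DataFrame, alpha: float = DEFAULT_ALPHA
) -> IndependenceCheck:
    """Regress take-off energy on endurance; the slope should be null.

    The two performance responses are analysed in separate model families;
    this pre-check verifies they can be treated as independent. A p-value
    below alpha is logged as a warning but does not stop the run.
    """
    df, _ = _complete_rows(table, ["takeoff_energy_j", "endurance_s"])
    if len(df) < 3:
        raise InsufficientDataError("independence check needs at least 3 complete rows")
    _check_variance(df, ["takeoff_energy_j", "endurance_s"])
    res = _ols(df, "takeoff_energy_j", ["endurance_s"])
    p = float(res.pvalues[1])
    warn = p < alpha
    if warn:
        logger.warning(
            "take-off energy and endurance are correlated (p = %.3g); "
            "treating them as independent responses may be unsafe", p,
        )
    return IndependenceCheck(
        slope=float(res.params[1]),
        se=float(res.bse[1]),
        p_value=p,
        r_squared=float(res.rsquared),
        nobs=int(res.nobs),
        warning=warn,
    )


def collinearity_screen(
    table: pd.DataFrame,
    predictors: list[str] | None = None,
    threshold: float = DEFAULT_COLLINEARITY_THRESHOLD,
) -> CollinearityReport:
    """Pairwise Pearson correlations among the mitochondrial predictors.

    Pairs with |r| above the threshold are flagged; any flag justifies the
    separate-models design (one mitochondrial term per model) and is recorded
    in the run report.
    """
    predictors = [p for p in (predictors or MITO_PREDICTORS) if p in table.columns]
    if len(predictors) < 2:
        raise InsufficientDataError("collinearity screen needs >= 2 predictors")
    df, _ = _complete_rows(table, predictors)
    _check_variance(df, predictors)
    corr = df[predictors].corr(method="pearson")
    flagged = [
        (a, b, float(corr.loc[a, b]))
        for i, a in enumerate(predictors)
        for b in predictors[i + 1 :]
        if abs(corr.loc[a, b]) > threshold
    ]
    return CollinearityReport(corr=corr, flagged=flagged, threshold=threshold)


def fit_single_predictor_model(
    table: pd.DataFrame,
    response: str,
    mito: str,
    covariates: list[str] = COVARIATES,
) -> ModelFit:
    """OLS of one response on one mitochondrial predictor plus the covariates.

    Mitochondrial predictors are never entered jointly; body mass and blood
    cell count accompany every model regardless of their own significance.
    """
    cols = [response, mito, *covariates]
    df, dropped = _complete_rows(table, cols)
    if len(df) < 5:
        raise InsufficientDataError(
            f"model {response} ~ {mito} has {len(df)} complete rows; need >= 5"
        )
    _check_variance(df, cols)
    predictors = [mito, *covariates]
    res = _ols(df, response, predictors)
    b = float(res.params[1])
    se = float(res.bse[1])
    t = float(res.tvalues[1])
    ci = res.conf_int()[1]
    return ModelFit(
        response=response,
        predictor=mito,
        coef=b,
        se=se,
        t_value=t,
        partial_f=t * t,
        p_value=float(res.pvalues[1]),
        r_squared=float(res.rsquared),
        nobs=int(res.nobs),
        covariates={c: float(res.params[2 + i]) for i, c in enumerate(covariates)},
        covariate_p={c: float(res.pvalues[2 + i]) for i, c in enumerate(covariates)},
        n_dropped=dropped,
        conf_int=(float(ci[0]), float(ci[1])),
        _results=res,
        _data=df.reset_index(drop=True),
    )


def influence_refit(
    fit: ModelFit,
    cooks_threshold: float | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> InfluenceReport:
    """Cook's-distance screen and a leave-one-out refit.

    Rows with D > 4/n are flagged; the model is refit once without the single
    largest-D flagged row and the change is classified at alpha: `weakened`
    (significant became non-significant), `reversed` (coefficient changed
    sign), otherwise `unchanged`. With no flagged rows the report carries an
    empty flag set and no refit.
    """
    if fit._results is None or fit._data is None:
        raise InsufficientDataError("influence analysis needs the fitted results")
    n = fit.nobs
    if n < 6:
        raise InsufficientDataError(f"influence refit needs n >= 6, got {n}")
    threshold = cooks_threshold if cooks_threshold is not None else 4.0 / n
    cooks = OLSInfluence(fit._results).cooks_distance[0]
    flagged_idx = np.flatnonzero(cooks > threshold)
    flagged_rows = list(fit._data.index[flagged_idx])
    if not flagged_rows:
        return InfluenceReport(
            cooks=cooks, threshold=threshold, flagged_rows=[],
            removed_row=None, refit=None, classification=None, alpha=alpha,
        )
    worst = fit._data.index[flagged_idx[np.argmax(cooks[flagged_idx])]]
    reduced = fit._data.drop(index=worst)
    refit = fit_single_predictor_model(
        reduced, fit.response, fit.predictor, covariates=list(fit.covariates),
    )
    if np.sign(refit.coef) != np.sign(fit.coef) and fit.coef != 0:
        classification = "reversed"
    elif fit.p_value < alpha <= refit.p_value:
        classification = "weakened"
    else:
        classification = "unchanged"
    return InfluenceReport(
        cooks=cooks, threshold=threshold, flagged_rows=flagged_rows,
        removed_row=worst, refit=refit, classification=classification, alpha=alpha,
    )


def residual_diagnostics(fit: ModelFit, alpha: float = DEFAULT_ALPHA) -> DiagnosticsSummary:
    """Shapiro–Wilk, Breusch–Pagan and a studentized-residual outlier count.

    Replaces simulation-based residual checks with their closed-form
    equivalents for Gaussian linear models. Residuals that are identically
    zero (an exact fit) make the tests meaningless; the summary then reports
    the degenerate case and skips them.
    """
    res = fit._results
    if res is None:
        raise InsufficientDataError("diagnostics need the fitted results")
    resid = np.asarray(res.resid)
    scale = max(1.0, float(np.max(np.abs(res.fittedvalues))))
    if np.ptp(resid) < 1e-10 * scale:
        return DiagnosticsSummary(
            shapiro_p=None, breusch_pagan_p=None, n_outliers=0,
            degenerate=True, passed=True,
            notes=["residuals identically zero; tests skipped"],
        )
    shapiro_p = float(sps.shapiro(resid).pvalue)
    bp_p = float(het_breuschpagan(resid, res.model.exog)[1])
    student = OLSInfluence(res).resid_studentized_external
    n_out = int(np.sum(np.abs(student) > 3.0))
    notes = []
    if shapiro_p < alpha:
        notes.append(f"residual normality rejected (Shapiro–Wilk p = {shapiro_p:.3g})")
    if bp_p < alpha:
        notes.append(f"heteroscedasticity detected (Breusch–Pagan p = {bp_p:.3g})")
    if n_out:
        notes.append(f"{n_out} studentized residual(s) beyond |t| = 3")
    return DiagnosticsSummary(
        shapiro_p=shapiro_p, breusch_pagan_p=bp_p, n_outliers=n_out,
        degenerate=False, passed=not notes, notes=notes,
    )


def fit_all_models(
    table: pd.DataFrame,
    responses: list[str] = ("endurance_s", "takeoff_energy_j"),
    predictors: list[str] | None = None,
    covariates: list[str] = COVARIATES,
) -> list[ModelFit]:
    """One model per (response, mitochondrial predictor) pair."""
    predictors = [p for p in (predictors or MITO_PREDICTORS) if p in table.columns]
    return [
        fit_single_predictor_model(table, r, m, covariates=covariates)
        for r in responses
        for m in predictors
    ]
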