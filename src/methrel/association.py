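"""Downstream phenotypic analyses of predictor estimates.

Distribution summaries (mean, SD, coefficient of variation), age-acceleration
residuals, Cox proportional-hazards mortality association, Spearman rank
correlation, correlation of per-pipeline reliability with downstream
statistics, and cross-pipeline rank aggregation.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

from .errors import DesignError, FittingError, ParameterError

log = logging.getLogger(__name__)


def _frame(estimates) -> pd.DataFrame:
    values = getattr(estimates, "values", estimates)
    if isinstance(values, pd.DataFrame):
        return values
    if isinstance(estimates, pd.DataFrame):
        return estimates
    raise ParameterError("expected PredictorEstimates or DataFrame")


def _series(estimates) -> pd.Series:
    if isinstance(estimates, pd.Series):
        return estimates
    frame = _frame(estimates)
    if frame.shape[1] != 1:
        raise ParameterError("expected a single predictor; got a multi-column table")
    return frame.iloc[:, 0]


# ---------------------------------------------------------------------------
# distribution summaries
# ---------------------------------------------------------------------------


def summarize_distribution(estimates) -> pd.DataFrame:
    """Sample mean, SD (n-1 denominator) and CV = sd/mean per predictor.

    CV is NaN where the mean is zero (undefined marker).
    """
    frame = _frame(estimates)
    if len(frame) < 2:
        raise ParameterError("need at least 2 arrays to summarize")
    mean = frame.mean(axis=0)
    sd = frame.std(axis=0, ddof=1)
    cv = sd / mean.where(mean != 0)
    return pd.DataFrame({"mean": mean, "sd": sd, "cv": cv})


# ---------------------------------------------------------------------------
# age acceleration
# ---------------------------------------------------------------------------


def age_acceleration(estimates, age: pd.Series) -> pd.Series:
    """OLS residual of a DNAm age estimate on chronological age (delta-age).

    Residuals are mean-zero and orthogonal to age by construction.
    """
    series = _series(estimates)
    age = age.reindex(series.index)
    if len(series) < 3:
        raise ParameterError("need at least 3 arrays")
    x = age.to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise DesignError("constant age: acceleration residual undefined")
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, series.to_numpy(dtype=float), rcond=None)
    return pd.Series(series.to_numpy() - X @ coef, index=series.index, name=f"{series.name}_accel")


# ---------------------------------------------------------------------------
# Cox mortality association
# ---------------------------------------------------------------------------


@dataclass
class AssociationResult:
    """Container for rank-correlation and/or hazard statistics."""

    rho: float | None = None
    rho_p: float | None = None
    hr: float | None = None
    coef: float | None = None
    se: float | None = None
    z: float | None = None
    cox_p: float | None = None
    age_r: float | None = None
    n: int | None = None
    statistic: str | None = None


def cox_mortality(
    estimates,
    survival_time: pd.Series,
    event: pd.Series,
    covariates: pd.DataFrame | None = None,
    standardize: bool = False,
    min_events: int = 10,
) -> AssociationResult:
    """Cox proportional-hazards association of one predictor with mortality.

    Partial-likelihood fit with Efron handling of tied event times; the
    hazard ratio is per unit of the raw predictor by default, or per SD with
    ``standardize``.  Covariates (e.g., chronological age) are adjusted for.
    ``min_events`` guards against unstable fits; relax it only for toy data.
    """
    series = _series(estimates).astype(float)
    t = survival_time.reindex(series.index).astype(float)
    e = event.reindex(series.index).astype(int)
    if (t <= 0).any():
        raise ParameterError("survival times must be positive")
    if int(e.sum()) < min_events:
        raise ParameterError(f"need >= {min_events} events, got {int(e.sum())}")

    x = series.copy()
    if standardize:
        sd = x.std(ddof=1)
        if sd == 0:
            raise ParameterError("constant predictor cannot be standardized")
        x = (x - x.mean()) / sd
    df = pd.DataFrame({"time": t, "event": e, "predictor": x})
    if covariates is not None:
        cov = covariates.reindex(series.index)
        df = pd.concat([df, cov], axis=1)
    try:
        fitter = CoxPHFitter()
        fitter.fit(df, duration_col="time", event_col="event")
    except (ConvergenceError, Exception) as err:  # lifelines raises several types
        raise FittingError(f"Cox fit failed: {err}") from err
    coef = float(fitter.params_["predictor"])
    se = float(fitter.standard_errors_["predictor"])
    return AssociationResult(
        hr=math.exp(coef),
        coef=coef,
        se=se,
        z=coef / se if se > 0 else math.inf,
        cox_p=float(fitter.summary.loc["predictor", "p"]),
        n=len(series),
    )


# ---------------------------------------------------------------------------
# Spearman rank correlation
# ---------------------------------------------------------------------------


def _rho_of_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    den = math.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    return float((rx * ry).sum() / den)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks on ties.

    p-value by the t approximation for n >= 10 and by exact enumeration of
    all rank permutations for n < 10.  Returns (nan, nan) when either input
    has zero rank variance (undefined marker).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be equal-length vectors")
    n = len(x)
    if n < 4:
        raise ParameterError("need at least 4 observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return (float("nan"), float("nan"))
    rho = _rho_of_ranks(rx, ry)
    if n >= 10:
        if abs(rho) >= 1.0:
            return (rho, 0.0)
        tstat = rho * math.sqrt((n - 2) / (1.0 - rho ** 2))
        p = 2.0 * stats.t.sf(abs(tstat), n - 2)
    else:
        perms = np.array(list(itertools.permutations(ry)))
        rhos = np.array([_rho_of_ranks(rx, p_) for p_ in perms])
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    return (rho, float(p))


def icc_statistic_correlation(icc_by_pipeline, statistic_by_pipeline, statistic: str = "") -> AssociationResult:
    """Spearman correlation of per-pipeline reliability with a downstream statistic.

    The diagnostic recommended when no study-specific replicates exist:
    correlate published/estimated per-pipeline ICCs with the outcome
    statistic across pipelines.  A constant statistic (or constant ICC)
    yields the undefined marker (NaN rho).
    """
    x = np.asarray(icc_by_pipeline, dtype=float)
    y = np.asarray(statistic_by_pipeline, dtype=float)
    rho, p = spearman(x, y)
    return AssociationResult(rho=rho, rho_p=p, n=len(x), statistic=statistic)


# ---------------------------------------------------------------------------
# pipeline ranking
# ---------------------------------------------------------------------------


@dataclass
class PipelineRanking:
    ranks: pd.DataFrame                # predictors x pipelines, 1 = best ICC
    median_rank: pd.Series             # per pipeline
    best_pipeline: pd.Series           # per predictor, argmax-ICC label
    summary: pd.DataFrame              # per predictor: median/min/max ICC, best label


def rank_pipelines(icc_matrix: pd.DataFrame) -> PipelineRanking:
    """Rank pipelines within each predictor by descending ICC.

    Average ranks on ties; degenerate cells (NaN) rank last so pipeline
    counts stay comparable, and are logged.  Also reports the per-predictor
    median/min/max ICC and the best pipeline label.
    """
    if icc_matrix.size == 0:
        raise ParameterError("empty ICC matrix")
    mat = icc_matrix.astype(float)
    n_degenerate = int(mat.isna().sum().sum())
    if n_degenerate:
        log.info("rank_pipelines: %d degenerate cells ranked last", n_degenerate)
    filled = mat.fillna(-np.inf)
    ranks = filled.rank(axis=1, ascending=False, method="average")
    best = mat.idxmax(axis=1)
    summary = pd.DataFrame(
        {
            "median_icc": mat.median(axis=1),
            "min_icc": mat.min(axis=1),
            "max_icc": mat.max(axis=1),
            "best_pipeline": best,
        }
    )
    return PipelineRanking(
        ranks=ranks,
        median_rank=ranks.median(axis=0),
        best_pipeline=best,
        summary=summary,
    )
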