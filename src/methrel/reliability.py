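"""Replicate reliability: the intraclass-correlation family, batch-effect
variance decomposition, and replicate-sample-size (subsampling) analysis.

The six ICC forms follow the classical two-way ANOVA decomposition for n
subjects (replicate pairs) measured k times: ICC(1,*) from the one-way
model, ICC(2,*) from the two-way random-effects model with absolute
agreement (occasion variance penalizes agreement), ICC(3,*) from the
two-way mixed model (consistency; a constant occasion offset is invisible).
Confidence intervals use the standard F-distribution constructions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, DesignError, ParameterError

log = logging.getLogger(__name__)

ICC_TYPES = ((1, 1), (2, 1), (3, 1), (1, "k"), (2, "k"), (3, "k"))


# ---------------------------------------------------------------------------
# replicate tables
# ---------------------------------------------------------------------------


@dataclass
class ReplicateTable:
    """n_pairs x 2 matrix of estimates; column j = occasion j of each pair."""

    values: np.ndarray
    pair_ids: pd.Index | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] < 2:
            raise ParameterError("replicate table must be n_pairs x k with k >= 2")
        if self.values.shape[0] < 3:
            raise ParameterError("replicate table needs at least 3 pairs")
        if not np.isfinite(self.values).all():
            raise ParameterError("replicate table has missing cells")
        if self.pair_ids is None:
            self.pair_ids = pd.RangeIndex(self.values.shape[0])

    @property
    def n_pairs(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


def replicate_table(
    estimates, sample_sheet: pd.DataFrame, predictor: str, pairs_col: str = "replicate_pair_id"
) -> ReplicateTable:
    """Assemble a replicate table for one predictor from estimates + sample sheet.

    Pairs with a missing member (absent array or non-finite estimate) are
    dropped listwise with a log entry; occasions are ordered by the sheet's
    ``occasion`` column when present, else by array id.
    """
    if isinstance(estimates, pd.Series):
        series = estimates
    elif isinstance(estimates, pd.DataFrame):
        series = estimates[predictor]
    else:
        series = estimates.values[predictor]  # PredictorEstimates
    sheet = sample_sheet[sample_sheet[pairs_col].notna()]
    rows, ids, dropped = [], [], 0
    for pid, grp in sheet.groupby(pairs_col, sort=True):
        if "occasion" in grp.columns:
            grp = grp.sort_values("occasion")
        else:
            grp = grp.sort_index()
        est = series.reindex(grp.index).to_numpy(dtype=float)
        if len(est) != 2 or not np.isfinite(est).all():
            dropped += 1
            continue
        rows.append(est)
        ids.append(pid)
    if dropped:
        log.info("replicate_table[%s]: dropped %d incomplete pairs", predictor, dropped)
    if len(rows) < 3:
        raise ParameterError(f"{predictor}: fewer than 3 complete replicate pairs")
    return ReplicateTable(np.vstack(rows), pd.Index(ids, name=pairs_col))


# ---------------------------------------------------------------------------
# two-way ANOVA mean squares
# ---------------------------------------------------------------------------


@dataclass
class MeanSquares:
    msr: float   # rows (subjects), df n-1; equals the one-way between-subject MS
    msc: float   # columns (occasions), df k-1
    mse: float   # interaction residual, df (n-1)(k-1)
    msw: float   # within-subject, df n(k-1)
    n: int
    k: int


def two_way_anova(pairs: ReplicateTable) -> MeanSquares:
    """Sums-of-squares decomposition of the n x k replicate table.

    Satisfies (n-1)MSR + (k-1)MSC + (n-1)(k-1)MSE = total SS.  Raises
    DegenerateDataError on zero total variance (every ICC undefined).
    """
    y = pairs.values
    n, k = y.shape
    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()
    scale = max(abs(grand), 1.0)
    if ss_total <= (1e-12 * scale) ** 2 * n * k:
        raise DegenerateDataError("zero total variance: ICC undefined")
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    resid = y - row_means[:, None] - col_means[None, :] + grand
    ss_err = (resid ** 2).sum()
    ss_within = ((y - row_means[:, None]) ** 2).sum()
    return MeanSquares(
        msr=ss_rows / (n - 1),
        msc=ss_cols / (k - 1),
        mse=ss_err / ((n - 1) * (k - 1)),
        msw=ss_within / (n * (k - 1)),
        n=n,
        k=k,
    )


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------


@dataclass
class ICCResult:
    icc: dict                          # (form, unit) -> estimate
    ci: dict                           # (form, unit) -> (lower, upper)
    ms: MeanSquares
    f_value: float                     # MSR / MSE
    df1: int
    df2: int
    p_value: float
    f_oneway: float                    # MSB / MSW with df (n-1, n(k-1))
    p_oneway: float
    conf_level: float
    n_pairs: int
    k: int
    negative: bool = False             # any single-measure estimate below zero

    def __getitem__(self, key):
        return self.icc[key]


def _safe_div(num, den):
    if den == 0:
        return 1.0 if num == 0 else np.sign(num) * np.inf
    return num / den


def _single_to_average(x, k):
    den = 1.0 + (k - 1.0) * x
    return _safe_div(k * x, den) if den != 0 else np.inf


def icc(pairs: ReplicateTable, conf_level: float = 0.95) -> ICCResult:
    """All six intraclass correlations with F tests and confidence intervals.

    Negative estimates are reported as computed and flagged, not floored.
    """
    if not 0 < conf_level < 1:
        raise ParameterError("conf_level must be in (0, 1)")
    ms = two_way_anova(pairs)
    n, k = ms.n, ms.k
    msr, msc, mse, msw = ms.msr, ms.msc, ms.mse, ms.msw

    est = {
        (1, 1): _safe_div(msr - msw, msr + (k - 1) * msw),
        (2, 1): _safe_div(msr - mse, msr + (k - 1) * mse + k * (msc - mse) / n),
        (3, 1): _safe_div(msr - mse, msr + (k - 1) * mse),
        (1, "k"): _safe_div(msr - msw, msr),
        (2, "k"): _safe_div(msr - mse, msr + (msc - mse) / n),
        (3, "k"): _safe_div(msr - mse, msr),
    }

    alpha = 1.0 - conf_level
    df1, df2 = n - 1, (n - 1) * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f21 = _safe_div(msr, mse)
        p21 = float(stats.f.sf(f21, df1, df2)) if np.isfinite(f21) else 0.0
        f1 = _safe_div(msr, msw)
        p1 = float(stats.f.sf(f1, df1, n * (k - 1))) if np.isfinite(f1) else 0.0

    ci = {}

    def f_bounds(f_obs, d1, d2):
        if not np.isfinite(f_obs):
            return np.inf, np.inf
        fl = f_obs / stats.f.ppf(1 - alpha / 2, d1, d2)
        fu = f_obs * stats.f.ppf(1 - alpha / 2, d2, d1)
        return fl, fu

    def bound_single(f):
        return 1.0 if np.isinf(f) else (f - 1) / (f + k - 1)

    def bound_average(f):
        if np.isinf(f):
            return 1.0
        return 1 - 1 / f if f > 0 else -np.inf

    # one-way forms
    fl, fu = f_bounds(f1, df1, n * (k - 1))
    ci[(1, 1)] = (bound_single(fl), bound_single(fu))
    ci[(1, "k")] = (bound_average(fl), bound_average(fu))

    # consistency forms
    fl, fu = f_bounds(f21, df1, df2)
    ci[(3, 1)] = (bound_single(fl), bound_single(fu))
    ci[(3, "k")] = (bound_average(fl), bound_average(fu))

    # absolute-agreement form: Satterthwaite-style df for the MSC/MSE mixture
    r2 = est[(2, 1)]
    if np.isfinite(r2) and mse > 0:
        fj = msc / mse
        a_term = n * (1 + (k - 1) * r2) - k * r2
        vn = (k - 1) * (n - 1) * (k * r2 * fj + a_term) ** 2
        vd = (n - 1) * k ** 2 * r2 ** 2 * fj ** 2 + a_term ** 2
        v = vn / vd if vd > 0 else df2
        f_u = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_l = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f_u * mse) / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
        upper = n * (f_l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_l * msr)
    else:
        lower, upper = 1.0, 1.0
    ci[(2, 1)] = (lower, upper)
    ci[(2, "k")] = (_single_to_average(lower, k), _single_to_average(upper, k))

    return ICCResult(
        icc={t: float(est[t]) for t in ICC_TYPES},
        ci={t: (float(ci[t][0]), float(ci[t][1])) for t in ICC_TYPES},
        ms=ms,
        f_value=float(f21),
        df1=df1,
        df2=df2,
        p_value=p21,
        f_oneway=float(f1),
        p_oneway=p1,
        conf_level=conf_level,
        n_pairs=n,
        k=k,
        negative=any(est[t] < 0 for t in ((1, 1), (2, 1), (3, 1))),
    )


# ---------------------------------------------------------------------------
# batch-effect variance decomposition
# ---------------------------------------------------------------------------


@dataclass
class VarianceDecomposition:
    r2_collective: float               # R^2 of estimate on all factors jointly
    per_factor: dict                   # factor -> marginal R^2 of that factor alone
    residualized: pd.Series            # observed - fitted (joint model)
    n_levels: dict


DEFAULT_BATCH_FACTORS = ["chip", "position", "plate", "well"]


def _dummy_design(sheet: pd.DataFrame, factors) -> np.ndarray:
    mats = [pd.get_dummies(sheet[f].astype(str), drop_first=True, dtype=float) for f in factors]
    X = pd.concat(mats, axis=1).to_numpy() if mats else np.empty((len(sheet), 0))
    return np.column_stack([np.ones(len(sheet)), X])


def _ols_r2(y: np.ndarray, X: np.ndarray):
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    ss_tot = ((y - y.mean()) ** 2).sum()
    if ss_tot == 0:
        raise DegenerateDataError("constant estimates: variance decomposition undefined")
    r2 = 1.0 - ((y - fitted) ** 2).sum() / ss_tot
    return float(np.clip(r2, 0.0, 1.0)), fitted


def batch_variance_explained(
    estimates, sample_sheet: pd.DataFrame, factors=None
) -> VarianceDecomposition | dict:
    """Share of estimate variance explained by dummy-encoded batch factors.

    ``r2_collective`` is the coefficient of determination of the joint linear
    model; per-factor contributions are marginal R^2 of each factor alone
    (a deliberate choice: factors are generally non-orthogonal).  Accepts a
    Series (one predictor) or DataFrame / PredictorEstimates (returns a dict
    per predictor).
    """
    factors = list(factors) if factors is not None else list(DEFAULT_BATCH_FACTORS)
    if not isinstance(estimates, pd.Series):
        values = getattr(estimates, "values", estimates)
        if isinstance(values, pd.DataFrame):
            return {
                c: batch_variance_explained(values[c], sample_sheet, factors)
                for c in values.columns
            }
        raise ParameterError("expected a Series, DataFrame or PredictorEstimates")

    series = estimates.dropna()
    sheet = sample_sheet.loc[series.index]
    missing = [f for f in factors if f not in sheet.columns]
    if missing:
        raise ParameterError(f"batch factors absent from sample sheet: {missing}")
    n_levels = {f: int(sheet[f].nunique()) for f in factors}
    if len(series) <= sum(n_levels.values()) + 1:
        raise DesignError(
            f"saturated design: {len(series)} arrays vs {sum(n_levels.values())} factor levels"
        )
    y = series.to_numpy(dtype=float)
    r2_all, fitted = _ols_r2(y, _dummy_design(sheet, factors))
    per = {}
    for f in factors:
        per[f], _ = _ols_r2(y, _dummy_design(sheet, [f]))
    return VarianceDecomposition(
        r2_collective=r2_all,
        per_factor=per,
        residualized=pd.Series(y - fitted, index=series.index, name=series.name),
        n_levels=n_levels,
    )


def regress_out_batch(estimates, sample_sheet: pd.DataFrame, factors=None):
    """Residualize estimates on batch factors; returns residual + grand mean.

    Mirrors the downstream practice of removing chip/position/plate/well
    effects from predictor estimates before reliability analysis.
    """
    if not isinstance(estimates, pd.Series):
        values = getattr(estimates, "values", estimates)
        out = pd.DataFrame(
            {c: regress_out_batch(values[c], sample_sheet, factors) for c in values.columns}
        )
        if hasattr(estimates, "provenance"):
            from .predictors import PredictorEstimates

            return PredictorEstimates(out, provenance=estimates.provenance)
        return out
    dec = batch_variance_explained(estimates, sample_sheet, factors)
    return dec.residualized + estimates.dropna().to_numpy(dtype=float).mean()


# ---------------------------------------------------------------------------
# replicate-sample-size (subsampling) analysis
# ---------------------------------------------------------------------------


def subsample_consistency(
    tables: dict,
    sizes,
    n_draws: int = 50,
    seed: int = 0,
    icc_type=(2, 1),
) -> pd.DataFrame:
    """Concordance of subsample ICC rankings with the full-sample ranking.

    ``tables`` maps cell labels (predictor x pipeline) to ReplicateTables
    over the SAME pairs.  For each subsample size m, ``n_draws`` subsets of
    pairs are drawn without replacement (shared across cells), the ICC of
    the chosen type is recomputed per cell, and the Spearman correlation with
    the full-sample ICC vector is averaged over draws.
    """
    from .association import spearman

    labels = list(tables)
    if len(labels) < 2:
        raise ParameterError("need at least 2 cells to rank")
    n_pairs = {t.n_pairs for t in tables.values()}
    if len(n_pairs) != 1:
        raise ParameterError("all replicate tables must cover the same pairs")
    n = n_pairs.pop()
    sizes = sorted(set(int(m) for m in sizes))
    if min(sizes) < 3 or max(sizes) > n:
        raise ParameterError(f"subsample sizes must lie in [3, {n}]")

    full = np.array([icc(tables[l])[icc_type] for l in labels])
    rng = np.random.default_rng(seed)
    rows = []
    for m in sizes:
        rhos = []
        for _ in range(n_draws):
            take = rng.choice(n, size=m, replace=False)
            sub = np.array(
                [icc(ReplicateTable(tables[l].values[take, :]))[icc_type] for l in labels]
            )
            rho, _ = spearman(sub, full)
            rhos.append(rho)
        rhos = np.asarray(rhos, dtype=float)
        rows.append(
            {"size": m, "mean_concordance": float(np.nanmean(rhos)),
             "sd_concordance": float(np.nanstd(rhos, ddof=1)) if len(rhos) > 1 else 0.0,
             "n_draws": n_draws}
        )
    return pd.DataFrame(rows).set_index("size")
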