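"""Composable preprocessing kernels for two-channel methylation intensities.

Kernels cover detection p-values and sample QC, background correction from
out-of-band or negative-control draws, dye-bias correction (global channel
rescaling or regression on paired internal controls), quantile normalization
at three stratification levels, beta computation, and probe-type calibration
by regression on neighboring type-I/type-II probe pairs.  A pipeline is an
ordered choice of one kernel per axis; the grid enumerator produces the
Cartesian product of axis options, mirroring the structure of large
multi-package preprocessing comparisons without re-implementing any specific
package's internals.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
import statsmodels.api as sm

from .errors import CapabilityError, MethrelError, ParameterError
from .synthetic_data import GREEN, RED, ArrayManifest, IntensityDataset, _CHANNEL_INDEX

log = logging.getLogger(__name__)

BG_METHODS = ("none", "oob", "neg")
DYE_METHODS = ("none", "mean", "relic")
NORM_METHODS = ("none", "q1", "q2", "q3")
PROBE_METHODS = ("none", "rcp")

BACKGROUND_FLOOR = 1.0     # intensity units, after background subtraction
LOGIT_EPS = 1e-6           # beta clipping before logit


# ---------------------------------------------------------------------------
# pipeline specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PipelineSpec:
    """One cell of the preprocessing grid: bg x dye x norm x probe kernels."""

    bg: str = "none"
    dye: str = "none"
    norm: str = "none"
    probe: str = "none"

    def __post_init__(self):
        for value, options, axis in (
            (self.bg, BG_METHODS, "bg"),
            (self.dye, DYE_METHODS, "dye"),
            (self.norm, NORM_METHODS, "norm"),
            (self.probe, PROBE_METHODS, "probe"),
        ):
            if value not in options:
                raise ParameterError(f"{axis}={value!r} not in {options}")

    @property
    def label(self) -> str:
        if self == RAW_SPEC:
            return "raw"
        return f"bg={self.bg}_dye={self.dye}_norm={self.norm}_probe={self.probe}"

    @property
    def is_raw(self) -> bool:
        return self == RAW_SPEC


RAW_SPEC = PipelineSpec()


def enumerate_grid(
    bg=BG_METHODS, dye=DYE_METHODS, norm=NORM_METHODS, probe=PROBE_METHODS
) -> list[PipelineSpec]:
    """Cartesian product of axis options plus the raw spec, deduplicated.

    Order is deterministic (itertools.product order, raw first if produced).
    Duplicate axis levels are rejected because labels must be unique.
    """
    for axis, options in (("bg", bg), ("dye", dye), ("norm", norm), ("probe", probe)):
        options = list(options)
        if not options:
            raise ParameterError(f"axis {axis} has no options")
        if len(set(options)) != len(options):
            raise ParameterError(f"axis {axis} has duplicate levels: {options}")
    specs = [PipelineSpec(b, d, n, p) for b, d, n, p in itertools.product(bg, dye, norm, probe)]
    if RAW_SPEC not in specs:
        specs.insert(0, RAW_SPEC)
    seen, out = set(), []
    for s in specs:
        if s.label not in seen:
            seen.add(s.label)
            out.append(s)
    return out


# ---------------------------------------------------------------------------
# beta matrix
# ---------------------------------------------------------------------------


@dataclass
class BetaMatrix:
    """Methylation fractions (probes x arrays) with pipeline provenance."""

    values: pd.DataFrame
    provenance: str = "raw"
    clipped_cells: int = 0

    def __post_init__(self):
        v = self.values.to_numpy(dtype=float)
        if np.nanmin(v) < 0 or np.nanmax(v) > 1:
            raise ParameterError("beta values must lie in [0, 1]")

    @property
    def values_frame(self) -> pd.DataFrame:
        return self.values

    @property
    def probes(self) -> pd.Index:
        return self.values.index

    @property
    def arrays(self) -> pd.Index:
        return self.values.columns


# ---------------------------------------------------------------------------
# channel bookkeeping
# ---------------------------------------------------------------------------


def _channel_masks(ds: IntensityDataset, manifest: ArrayManifest, channel: str):
    """Boolean masks (over ds rows) of meth / unmeth measurements read in `channel`."""
    meth_ch, unmeth_ch = manifest.measurement_channels()
    idx = ds.meth.index
    return (
        meth_ch.reindex(idx).to_numpy() == channel,
        unmeth_ch.reindex(idx).to_numpy() == channel,
    )


def _negative_totals_by_channel(ds: IntensityDataset, manifest: ArrayManifest, channel: str):
    """All negative-control draws in one channel (meth and unmeth beads pooled)."""
    neg = manifest.negative_ids
    chans = manifest.probes.loc[neg, "channel"]
    ids = neg[chans == channel]
    if len(ids) == 0:
        return np.empty((0, ds.meth.shape[1]))
    return np.vstack([ds.meth.loc[ids].to_numpy(), ds.unmeth.loc[ids].to_numpy()])


# ---------------------------------------------------------------------------
# detection p-values and sample QC
# ---------------------------------------------------------------------------


def detection_pvalues(ds: IntensityDataset, manifest: ArrayManifest) -> pd.DataFrame:
    """One-sided upper-tail p-value of each CpG probe's total intensity.

    The null is the per-array, per-channel background law estimated from
    negative controls (normal approximation with the control mean and SD);
    for a type-I probe the null total is the sum of two draws in its channel,
    for a type-II probe one draw per channel.  Small p = reliably detected.
    """
    if len(manifest.negative_ids) < 20:
        raise CapabilityError("detection p-values require >= 20 negative controls")

    stats_by_ch = {}
    for ch in (RED, GREEN):
        draws = _negative_totals_by_channel(ds, manifest, ch)
        if draws.shape[0] == 0:
            raise CapabilityError(f"no negative controls in {ch} channel")
        stats_by_ch[ch] = (draws.mean(axis=0), draws.std(axis=0, ddof=1))

    cpg = manifest.cpg_ids
    total = ds.meth.loc[cpg].to_numpy() + ds.unmeth.loc[cpg].to_numpy()
    design = manifest.probes.loc[cpg, "design_type"].to_numpy()
    chan = manifest.probes.loc[cpg, "channel"].to_numpy()

    mu0 = np.empty_like(total)
    sd0 = np.empty_like(total)
    for ch in (RED, GREEN):
        m, s = stats_by_ch[ch]
        mask1 = (design == "I") & (chan == ch)
        mu0[mask1, :] = 2.0 * m
        sd0[mask1, :] = np.sqrt(2.0) * s
    m_r, s_r = stats_by_ch[RED]
    m_g, s_g = stats_by_ch[GREEN]
    mask2 = design == "II"
    mu0[mask2, :] = m_r + m_g
    sd0[mask2, :] = np.sqrt(s_r ** 2 + s_g ** 2)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = (total - mu0) / sd0
    pvals = stats.norm.sf(z)
    zero_sd = np.broadcast_to(sd0 == 0, pvals.shape)
    pvals = np.where(zero_sd, np.where(total > mu0, 0.0, 1.0), pvals)
    return pd.DataFrame(pvals, index=cpg, columns=ds.meth.columns)


@dataclass
class QCReport:
    """Per-array QC metrics and exclusion decisions."""

    metrics: pd.DataFrame              # detection_fail_frac, log2 med meth/unmeth
    excluded: pd.Series                # bool per array
    reasons: pd.Series                 # "", "detection", "median", "detection,median"

    @property
    def excluded_ids(self) -> pd.Index:
        return self.excluded.index[self.excluded]


def sample_qc(
    ds: IntensityDataset,
    pvals: pd.DataFrame,
    manifest: ArrayManifest,
    fail_p: float = 0.05,
    fail_frac: float = 0.05,
    median_k: float = 3.0,
) -> QCReport:
    """Flag arrays failing detection or chipwide-median intensity rules.

    An array is excluded when more than ``fail_frac`` of CpG sites have
    detection p > ``fail_p``, or when its log2 median methylated or
    unmethylated intensity falls below median - ``median_k`` * MAD of the
    array medians (normal-consistent MAD).
    """
    if not pvals.columns.equals(ds.meth.columns):
        raise ParameterError("p-value matrix does not match dataset arrays")
    cpg = pvals.index
    frac = (pvals > fail_p).mean(axis=0)
    med_meth = np.log2(ds.meth.loc[cpg].median(axis=0) + 1.0)
    med_unmeth = np.log2(ds.unmeth.loc[cpg].median(axis=0) + 1.0)

    def cutline(med):
        mad = stats.median_abs_deviation(med, scale="normal")
        return np.median(med) - median_k * mad

    low = (med_meth < cutline(med_meth)) | (med_unmeth < cutline(med_unmeth))
    det = frac > fail_frac
    reasons = pd.Series(
        ["" if not (d or m) else ",".join(r for r, f in (("detection", d), ("median", m)) if f)
         for d, m in zip(det, low)],
        index=ds.meth.columns,
    )
    metrics = pd.DataFrame(
        {"detection_fail_frac": frac, "log2_median_meth": med_meth, "log2_median_unmeth": med_unmeth}
    )
    excluded = det | low
    for aid in metrics.index[excluded]:
        log.info("sample_qc: excluding %s (%s)", aid, reasons[aid])
    return QCReport(metrics=metrics, excluded=excluded, reasons=reasons)


def drop_arrays(ds: IntensityDataset, array_ids) -> IntensityDataset:
    """Remove arrays; replicate pairs losing one member become unpaired singletons."""
    keep = ds.meth.columns.difference(pd.Index(array_ids), sort=False)
    sheet = ds.sample_sheet.loc[keep].copy()
    counts = sheet["replicate_pair_id"].value_counts()
    orphaned = counts.index[counts < 2]
    if len(orphaned):
        log.info("drop_arrays: %d replicate pairs lost a member and were unpaired",
                 len(orphaned))
        mask = sheet["replicate_pair_id"].isin(orphaned)
        sheet.loc[mask, "replicate_pair_id"] = None
    return IntensityDataset(ds.meth[keep], ds.unmeth[keep], ds.oob[keep], sheet)


# ---------------------------------------------------------------------------
# background correction
# ---------------------------------------------------------------------------


def background_correct(ds: IntensityDataset, method: str, manifest: ArrayManifest) -> IntensityDataset:
    """Subtract a per-array, per-channel background estimate from every intensity.

    ``oob`` estimates each channel's background from out-of-band draws of
    type-I probes assigned to the *other* channel; ``neg`` uses negative
    controls in the channel itself.  Corrected intensities are floored at
    BACKGROUND_FLOOR.
    """
    if method not in ("oob", "neg"):
        raise ParameterError(f"unknown background method {method!r}")
    n_arrays = ds.meth.shape[1]
    bg = np.zeros((2, n_arrays))
    if method == "oob":
        if ds.oob.shape[0] == 0:
            raise CapabilityError("oob background correction requires out-of-band draws")
        probe_ch = manifest.probes.loc[ds.oob.index, "channel"].to_numpy()
        for ch, opp in ((RED, GREEN), (GREEN, RED)):
            rows = ds.oob.index[probe_ch == opp]  # their unused channel is `ch`
            if len(rows) == 0:
                raise CapabilityError(f"no out-of-band source for {ch} channel")
            bg[_CHANNEL_INDEX[ch]] = ds.oob.loc[rows].mean(axis=0).to_numpy()
    else:
        if len(manifest.negative_ids) == 0:
            raise CapabilityError("neg background correction requires negative controls")
        for ch in (RED, GREEN):
            draws = _negative_totals_by_channel(ds, manifest, ch)
            if draws.shape[0] == 0:
                raise CapabilityError(f"no negative controls in {ch} channel")
            bg[_CHANNEL_INDEX[ch]] = draws.mean(axis=0)

    meth = ds.meth.to_numpy().copy()
    unmeth = ds.unmeth.to_numpy().copy()
    for ch in (RED, GREEN):
        mmask, umask = _channel_masks(ds, manifest, ch)
        meth[mmask, :] -= bg[_CHANNEL_INDEX[ch]][None, :]
        unmeth[umask, :] -= bg[_CHANNEL_INDEX[ch]][None, :]
    meth = np.maximum(meth, BACKGROUND_FLOOR)
    unmeth = np.maximum(unmeth, BACKGROUND_FLOOR)
    return IntensityDataset(
        pd.DataFrame(meth, index=ds.meth.index, columns=ds.meth.columns),
        pd.DataFrame(unmeth, index=ds.unmeth.index, columns=ds.unmeth.columns),
        ds.oob.copy(),
        ds.sample_sheet.copy(),
    )


# ---------------------------------------------------------------------------
# dye-bias correction
# ---------------------------------------------------------------------------


def _control_pair_totals(ds: IntensityDataset, manifest: ArrayManifest):
    pairs = manifest.control_pairs()
    red = ds.meth.loc[pairs[RED]].to_numpy() + ds.unmeth.loc[pairs[RED]].to_numpy()
    green = ds.meth.loc[pairs[GREEN]].to_numpy() + ds.unmeth.loc[pairs[GREEN]].to_numpy()
    return red, green  # pairs x arrays


def dye_correct(ds: IntensityDataset, method: str, manifest: ArrayManifest) -> IntensityDataset:
    """Correct red/green channel imbalance using paired same-target controls.

    ``mean`` rescales every red-channel intensity so the per-array mean red
    control total matches the mean green control total.  ``relic`` fits a
    per-array regression of log green-control on log red-control totals over
    control pairs and maps all red-channel measurements through the fitted
    line, following the regression-on-internal-controls approach.
    """
    if method not in ("mean", "relic"):
        raise ParameterError(f"unknown dye method {method!r}")
    pairs = manifest.control_pairs()
    if method == "relic" and len(pairs) < 10:
        raise CapabilityError("relic dye correction requires >= 10 control pairs")
    if len(pairs) == 0:
        raise CapabilityError("dye correction requires control pairs")

    red, green = _control_pair_totals(ds, manifest)
    meth = ds.meth.to_numpy().copy()
    unmeth = ds.unmeth.to_numpy().copy()
    mmask, umask = _channel_masks(ds, manifest, RED)

    if method == "mean":
        with np.errstate(divide="ignore", invalid="ignore"):
            factor = green.mean(axis=0) / red.mean(axis=0)
        if not np.isfinite(factor).all():
            raise MethrelError("degenerate control intensities: zero mean red total")
        meth[mmask, :] *= factor[None, :]
        unmeth[umask, :] *= factor[None, :]
    else:
        lr = np.log(np.maximum(red, BACKGROUND_FLOOR))
        lg = np.log(np.maximum(green, BACKGROUND_FLOOR))
        for a in range(lr.shape[1]):
            x, y = lr[:, a], lg[:, a]
            vx = x.var()
            if vx < 1e-12:
                raise MethrelError(
                    f"degenerate control intensities on array {ds.meth.columns[a]}: "
                    "zero variance of log red-control totals"
                )
            slope = np.cov(x, y, ddof=1)[0, 1] / x.var(ddof=1)
            intercept = y.mean() - slope * x.mean()
            for mat, mask in ((meth, mmask), (unmeth, umask)):
                vals = np.maximum(mat[mask, a], BACKGROUND_FLOOR)
                mat[mask, a] = np.exp(intercept + slope * np.log(vals))

    return IntensityDataset(
        pd.DataFrame(meth, index=ds.meth.index, columns=ds.meth.columns),
        pd.DataFrame(unmeth, index=ds.unmeth.index, columns=ds.unmeth.columns),
        ds.oob.copy(),
        ds.sample_sheet.copy(),
    )


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------


def _qn_matrix(x: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns to the mean of sorted columns; average-rank ties."""
    n = x.shape[0]
    if n == 0:
        return x
    ref = np.sort(x, axis=0).mean(axis=1)
    ranks = stats.rankdata(x, axis=0)
    return np.interp(ranks, np.arange(1, n + 1), ref)


def quantile_normalize(ds: IntensityDataset, method: str, manifest: ArrayManifest) -> IntensityDataset:
    """Equalize intensity distributions across arrays within strata.

    q1: separately within {meth, unmeth} x {type I, type II};
    q2: within {meth, unmeth}, probe types pooled;
    q3: one pooled normalization of all (meth and unmeth) intensities.
    Control and negative rows are left untouched.
    """
    if method not in ("q1", "q2", "q3"):
        raise ParameterError(f"unknown normalization method {method!r}")
    if ds.meth.shape[1] < 2:
        warnings.warn("quantile normalization skipped: fewer than 2 arrays", stacklevel=2)
        return ds.copy()

    cpg = manifest.cpg_ids
    meth = ds.meth.to_numpy().copy()
    unmeth = ds.unmeth.to_numpy().copy()
    pos = ds.meth.index.get_indexer(cpg)
    design = manifest.probes.loc[cpg, "design_type"].to_numpy()

    if method == "q1":
        for dt in ("I", "II"):
            rows = pos[design == dt]
            if rows.size:
                meth[rows, :] = _qn_matrix(meth[rows, :])
                unmeth[rows, :] = _qn_matrix(unmeth[rows, :])
    elif method == "q2":
        meth[pos, :] = _qn_matrix(meth[pos, :])
        unmeth[pos, :] = _qn_matrix(unmeth[pos, :])
    else:
        stacked = np.vstack([meth[pos, :], unmeth[pos, :]])
        stacked = _qn_matrix(stacked)
        meth[pos, :] = stacked[: len(pos), :]
        unmeth[pos, :] = stacked[len(pos):, :]

    return IntensityDataset(
        pd.DataFrame(meth, index=ds.meth.index, columns=ds.meth.columns),
        pd.DataFrame(unmeth, index=ds.unmeth.index, columns=ds.unmeth.columns),
        ds.oob.copy(),
        ds.sample_sheet.copy(),
    )


# ---------------------------------------------------------------------------
# beta computation and probe-type calibration
# ---------------------------------------------------------------------------


def compute_beta(ds: IntensityDataset, manifest: ArrayManifest, offset: float = 100.0,
                 provenance: str = "raw") -> BetaMatrix:
    """beta = meth / (meth + unmeth + offset) over CpG probes.

    The offset (platform-standard default 100) stabilizes low-intensity
    probes; with zero signal the convention yields beta = 0.
    """
    if offset < 0:
        raise ParameterError("offset must be non-negative")
    cpg = manifest.cpg_ids
    m = ds.meth.loc[cpg].to_numpy()
    u = ds.unmeth.loc[cpg].to_numpy()
    if (m < 0).any() or (u < 0).any():
        raise ParameterError("negative intensities")
    denom = m + u + offset
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(denom > 0, m / denom, 0.0)
    return BetaMatrix(pd.DataFrame(beta, index=cpg, columns=ds.meth.columns), provenance=provenance)


def _logit(b):
    return special.logit(np.clip(b, LOGIT_EPS, 1.0 - LOGIT_EPS))


def _robust_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Robust (Tukey-bisquare IRLS) fit of y = a + b*x; exact OLS on (near-)perfect fits."""
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    spread = max(np.ptp(y), 1.0)
    if np.abs(resid).max() <= 1e-10 * spread:
        return float(coef[0]), float(coef[1])
    fit = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight()).fit(maxiter=50, tol=1e-8)
    return float(fit.params[0]), float(fit.params[1])


def rcp_correct(beta: BetaMatrix, manifest: ArrayManifest, scale: str = "beta") -> BetaMatrix:
    """Recalibrate type-II betas onto the type-I scale via neighbor-pair regression.

    Per array, a robust line of type-I beta on type-II beta is fitted over
    neighbor pairs (probes sharing true methylation) and applied to every
    type-II probe; output clipped to [0, 1].  ``scale`` selects the fitting
    scale: "beta" (a beta-scale linear compression is then exactly inverted)
    or "logit".
    """
    if scale not in ("beta", "logit"):
        raise ParameterError(f"unknown rcp scale {scale!r}")
    pairs = manifest.neighbor_pairs()
    if len(pairs) < 10:
        raise CapabilityError("rcp correction requires >= 10 neighbor pairs")

    vals = beta.values.to_numpy().copy()
    idx = beta.values.index
    i1 = idx.get_indexer(pairs["type_i"])
    i2 = idx.get_indexer(pairs["type_ii"])
    type2_rows = idx.get_indexer(manifest.cpg_ids_of_type("II"))

    clipped = 0
    for a in range(vals.shape[1]):
        if scale == "beta":
            x, y = vals[i2, a], vals[i1, a]
            a0, b0 = _robust_line(x, y)
            new = a0 + b0 * vals[type2_rows, a]
        else:
            x, y = _logit(vals[i2, a]), _logit(vals[i1, a])
            a0, b0 = _robust_line(x, y)
            new = special.expit(a0 + b0 * _logit(vals[type2_rows, a]))
        clipped += int(((new < 0) | (new > 1)).sum())
        vals[type2_rows, a] = np.clip(new, 0.0, 1.0)
    if clipped:
        log.info("rcp_correct: clipped %d cells into [0, 1]", clipped)
    return BetaMatrix(
        pd.DataFrame(vals, index=idx, columns=beta.values.columns),
        provenance=beta.provenance,
        clipped_cells=clipped,
    )


# ---------------------------------------------------------------------------
# pipeline runner
# ---------------------------------------------------------------------------


def run_pipeline(
    ds: IntensityDataset,
    spec: PipelineSpec,
    manifest: ArrayManifest,
    offset: float = 100.0,
    rcp_scale: str = "beta",
) -> BetaMatrix:
    """Apply bg -> dye -> norm on intensities, compute betas, then probe correction."""
    work = ds
    if spec.bg != "none":
        work = background_correct(work, spec.bg, manifest)
    if spec.dye != "none":
        work = dye_correct(work, spec.dye, manifest)
    if spec.norm != "none":
        work = quantile_normalize(work, spec.norm, manifest)
    beta = compute_beta(work, manifest, offset=offset, provenance=spec.label)
    if spec.probe == "rcp":
        beta = rcp_correct(beta, manifest, scale=rcp_scale)
    return beta
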