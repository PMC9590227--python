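"""End-to-end orchestration at configurable scale.

One experiment run: simulate a cohort with technical replicate pairs ->
process the intensity data through a grid of preprocessing pipelines ->
compute predictor estimates per pipeline -> quantify replicate consistency
(ICC) on the replicate subset -> compute distribution/age/mortality
statistics on the disjoint general subset -> rank pipelines and correlate
reliability with the downstream statistics.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .association import (
    cox_mortality,
    icc_statistic_correlation,
    rank_pipelines,
    spearman,
    summarize_distribution,
)
from .errors import MethrelError, ParameterError
from .predictors import apply_predictors
from .preprocessing import (
    PipelineSpec,
    detection_pvalues,
    drop_arrays,
    enumerate_grid,
    run_pipeline,
    sample_qc,
)
from .reliability import ICC_TYPES, batch_variance_explained, icc, replicate_table
from .synthetic_data import (
    PhenoConfig,
    TechConfig,
    generate_manifest,
    make_weight_tables,
    simulate_intensities,
    simulate_truth,
)

log = logging.getLogger(__name__)

_ICC_COLS = {t: f"icc{t[0]}{t[1]}" for t in ICC_TYPES}


def _default_predictors():
    return [
        {"name": "SynthClock", "n_probes": 353, "target": "age", "transform": "horvath_age"},
        {"name": "AgeLinear", "n_probes": 100, "target": "age"},
        {"name": "AgingScore", "n_probes": 150, "target": "latent_score"},
        {"name": "RandomSmall", "n_probes": 50, "target": "random"},
        {"name": "RandomLarge", "n_probes": 200, "target": "random"},
    ]


def _default_grid():
    return {
        "bg": ["none", "oob", "neg"],
        "dye": ["none", "relic"],
        "norm": ["none", "q1"],
        "probe": ["none", "rcp"],
    }


@dataclass
class ExperimentConfig:
    """Validated, serializable description of one experiment."""

    seed: int = 0
    n_probes: int = 2000
    type2_fraction: float = 0.84
    n_neighbor_pairs: int = 100
    n_control_pairs: int = 85
    n_negative_controls: int = 100
    n_subjects: int = 550
    n_replicate_pairs: int = 50
    pheno: dict = field(default_factory=dict)
    tech: dict = field(default_factory=dict)
    grid: dict = field(default_factory=_default_grid)
    predictors: list = field(default_factory=_default_predictors)
    qc_enabled: bool = True
    conf_level: float = 0.95
    icc_type: tuple = (2, 1)
    standardize_hr: bool = True
    outdir: str | None = None

    def validate(self):
        if self.n_replicate_pairs < 3:
            raise ParameterError("need at least 3 replicate pairs")
        if self.n_subjects <= self.n_replicate_pairs:
            raise ParameterError("need non-replicate subjects for the general sample")
        PhenoConfig(**self.pheno).validate()
        TechConfig(**self.tech).validate()
        enumerate_grid(**self.grid)
        if not self.predictors:
            raise ParameterError("at least one predictor config required")
        names = [p["name"] for p in self.predictors]
        if len(set(names)) != len(names):
            raise ParameterError("predictor names must be unique")
        if tuple(self.icc_type) not in ICC_TYPES:
            raise ParameterError(f"unknown ICC type {self.icc_type}")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        if isinstance(cfg.icc_type, list):
            cfg.icc_type = tuple(cfg.icc_type)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> Path:
        data = dataclasses.asdict(self)
        data["icc_type"] = list(self.icc_type)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
        return Path(path)


@dataclass
class ExperimentBundle:
    """All stage outputs of one experiment run."""

    config: ExperimentConfig
    manifest: object
    truth: object
    dataset: object
    qc_report: object
    models: dict
    estimates: dict                    # pipeline label -> PredictorEstimates (all arrays)
    icc_table: pd.DataFrame            # rows predictor x pipeline, six ICCs + CI + p
    icc_matrix: pd.DataFrame           # predictors x pipelines, selected ICC type
    ranking: object
    association_table: pd.DataFrame    # per predictor x pipeline downstream statistics
    icc_correlations: pd.DataFrame     # per predictor x statistic Spearman rho/p
    batch_r2: pd.DataFrame             # per predictor x pipeline collective batch R^2
    replicate_arrays: pd.Index
    general_arrays: pd.Index


def _stage_seeds(seed: int, n: int = 8):
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)]


def run_experiment(config: ExperimentConfig) -> ExperimentBundle:
    """Execute the full evaluation workflow; deterministic for a fixed seed."""
    config.validate()
    s_manifest, s_truth, s_intens, s_weights, *_ = _stage_seeds(config.seed)

    log.info("simulating: %d probes, %d subjects, %d replicate pairs",
             config.n_probes, config.n_subjects, config.n_replicate_pairs)
    manifest = generate_manifest(
        config.n_probes,
        type2_fraction=config.type2_fraction,
        n_neighbor_pairs=config.n_neighbor_pairs,
        n_control_pairs=config.n_control_pairs,
        n_negative_controls=config.n_negative_controls,
        seed=s_manifest,
    )
    truth = simulate_truth(
        manifest,
        config.n_subjects,
        config.n_replicate_pairs,
        PhenoConfig(**config.pheno),
        seed=s_truth,
    )
    dataset = simulate_intensities(truth, manifest, TechConfig(**config.tech), seed=s_intens)
    models = make_weight_tables(manifest, truth, config.predictors, seed=s_weights)

    qc_report = None
    if config.qc_enabled:
        pvals = detection_pvalues(dataset, manifest)
        qc_report = sample_qc(dataset, pvals, manifest)
        if len(qc_report.excluded_ids):
            dataset = drop_arrays(dataset, qc_report.excluded_ids)

    sheet = dataset.sample_sheet
    replicate_subjects = sheet.loc[sheet["replicate_pair_id"].notna(), "subject_id"].unique()
    replicate_arrays = sheet.index[sheet["subject_id"].isin(replicate_subjects)]
    general_arrays = sheet.index[~sheet["subject_id"].isin(replicate_subjects)]
    assert not set(sheet.loc[replicate_arrays, "subject_id"]) & set(
        sheet.loc[general_arrays, "subject_id"]
    ), "replicate and general subsets must be disjoint by subject"

    specs = enumerate_grid(**config.grid)
    log.info("running %d pipelines", len(specs))
    estimates = {}
    for spec in specs:
        beta = run_pipeline(dataset, spec, manifest)
        estimates[spec.label] = apply_predictors(beta, models)

    # --- reliability on the replicate subset --------------------------------
    icc_rows = []
    sel = tuple(config.icc_type)
    for label, est in estimates.items():
        rep_est = est.values.loc[replicate_arrays]
        for pname in rep_est.columns:
            row = {"predictor": pname, "pipeline": label}
            try:
                table = replicate_table(rep_est, sheet.loc[replicate_arrays], pname)
                res = icc(table, conf_level=config.conf_level)
                for t, col in _ICC_COLS.items():
                    row[col] = res.icc[t]
                row["ci_low"], row["ci_high"] = res.ci[sel]
                row["p_value"] = res.p_value
                row["n_pairs"] = res.n_pairs
                row["degenerate"] = False
            except MethrelError:
                for col in _ICC_COLS.values():
                    row[col] = np.nan
                row.update(ci_low=np.nan, ci_high=np.nan, p_value=np.nan,
                           n_pairs=0, degenerate=True)
            icc_rows.append(row)
    icc_table = pd.DataFrame(icc_rows)
    icc_matrix = icc_table.pivot(index="predictor", columns="pipeline",
                                 values=_ICC_COLS[sel])
    ranking = rank_pipelines(icc_matrix)

    # --- associations on the general subset ---------------------------------
    gen_sheet = sheet.loc[general_arrays]
    assoc_rows = []
    batch_rows = []
    for label, est in estimates.items():
        gen_est = est.values.loc[general_arrays]
        summary = summarize_distribution(gen_est)
        for pname in gen_est.columns:
            series = gen_est[pname]
            age_r = float(np.corrcoef(series, gen_sheet["age"])[0, 1])
            try:
                cox = cox_mortality(
                    series,
                    gen_sheet["survival_time"],
                    gen_sheet["event"],
                    covariates=gen_sheet[["age"]],
                    standardize=config.standardize_hr,
                )
                hr, zval, cox_p = cox.hr, cox.z, cox.cox_p
            except MethrelError as err:
                log.warning("cox fit skipped for %s / %s: %s", pname, label, err)
                hr = zval = cox_p = np.nan
            assoc_rows.append(
                {
                    "predictor": pname,
                    "pipeline": label,
                    "mean": summary.loc[pname, "mean"],
                    "sd": summary.loc[pname, "sd"],
                    "cv": summary.loc[pname, "cv"],
                    "age_r": age_r,
                    "hr": hr,
                    "z": zval,
                    "cox_p": cox_p,
                }
            )
            try:
                dec = batch_variance_explained(est.values[pname], sheet)
                batch_rows.append(
                    {"predictor": pname, "pipeline": label, "r2_collective": dec.r2_collective}
                )
            except MethrelError:
                batch_rows.append(
                    {"predictor": pname, "pipeline": label, "r2_collective": np.nan}
                )
    association_table = pd.DataFrame(assoc_rows)
    batch_r2 = pd.DataFrame(batch_rows)

    # --- reliability vs downstream statistics -------------------------------
    corr_rows = []
    if icc_matrix.shape[1] >= 4:  # rank correlation undefined below 4 pipelines
        for pname in icc_matrix.index:
            icc_vec = icc_matrix.loc[pname]
            sub = association_table[association_table["predictor"] == pname].set_index("pipeline")
            sub = sub.loc[icc_vec.index]
            for statistic in ("mean", "sd", "age_r", "hr", "z"):
                vec = sub[statistic].to_numpy(dtype=float)
                keep = np.isfinite(vec) & np.isfinite(icc_vec.to_numpy())
                if keep.sum() < 4:
                    rho = rho_p = np.nan
                else:
                    res = icc_statistic_correlation(icc_vec.to_numpy()[keep], vec[keep],
                                                    statistic=statistic)
                    rho, rho_p = res.rho, res.rho_p
                corr_rows.append(
                    {"predictor": pname, "statistic": statistic, "rho": rho, "p": rho_p}
                )
    else:
        log.info("icc-statistic correlations skipped: fewer than 4 pipelines")
    icc_correlations = pd.DataFrame(corr_rows, columns=["predictor", "statistic", "rho", "p"])

    bundle = ExperimentBundle(
        config=config,
        manifest=manifest,
        truth=truth,
        dataset=dataset,
        qc_report=qc_report,
        models=models,
        estimates=estimates,
        icc_table=icc_table,
        icc_matrix=icc_matrix,
        ranking=ranking,
        association_table=association_table,
        icc_correlations=icc_correlations,
        batch_r2=batch_r2,
        replicate_arrays=replicate_arrays,
        general_arrays=general_arrays,
    )
    if config.outdir:
        write_bundle(bundle, config.outdir)
    return bundle


def compare_icc_types(bundle_or_table) -> pd.DataFrame:
    """6x6 Spearman correlation matrix of the ICC types across grid cells.

    Cells flagged degenerate are excluded (logged).  Requires >= 10 cells.
    """
    table = getattr(bundle_or_table, "icc_table", bundle_or_table)
    cols = list(_ICC_COLS.values())
    valid = table.dropna(subset=cols)
    n_dropped = len(table) - len(valid)
    if n_dropped:
        log.info("compare_icc_types: excluded %d degenerate cells", n_dropped)
    if len(valid) < 10:
        raise ParameterError("need at least 10 non-degenerate cells")
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            rho, _ = spearman(valid[a].to_numpy(), valid[b].to_numpy())
            out.loc[a, b] = out.loc[b, a] = rho
    return out


def write_bundle(bundle: ExperimentBundle, outdir) -> dict:
    """Serialize report tables (TSV), config (YAML) and a checksum manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []

    def _tsv(frame, name, index=False):
        p = outdir / name
        frame.to_csv(p, sep="\t", index=index, float_format="%.10g")
        paths.append(p)

    bundle.config.to_yaml(outdir / "config.yaml")
    paths.append(outdir / "config.yaml")
    mio.write_sample_sheet(bundle.dataset.sample_sheet, outdir / "sample_sheet.csv")
    paths.append(outdir / "sample_sheet.csv")
    _tsv(bundle.icc_table, "icc_table.tsv")
    _tsv(bundle.icc_matrix.reset_index(), "icc_matrix.tsv")
    _tsv(bundle.ranking.ranks.reset_index(), "pipeline_ranks.tsv")
    _tsv(bundle.ranking.median_rank.rename("median_rank").reset_index(), "pipeline_median_rank.tsv")
    _tsv(bundle.ranking.summary.reset_index(), "predictor_summary.tsv")
    _tsv(bundle.association_table, "association_table.tsv")
    _tsv(bundle.icc_correlations, "icc_statistic_correlations.tsv")
    _tsv(bundle.batch_r2, "batch_r2.tsv")
    if bundle.qc_report is not None:
        qc = bundle.qc_report.metrics.copy()
        qc["excluded"] = bundle.qc_report.excluded
        qc["reason"] = bundle.qc_report.reasons
        qc.reset_index(names="array_id").to_csv(outdir / "qc_report.csv", index=False)
        paths.append(outdir / "qc_report.csv")
    mio.write_checksum_manifest(paths, outdir / "MANIFEST.sha256")
    meta = {"n_pipelines": int(bundle.icc_matrix.shape[1]),
            "n_predictors": int(bundle.icc_matrix.shape[0]),
            "n_replicate_arrays": int(len(bundle.replicate_arrays)),
            "n_general_arrays": int(len(bundle.general_arrays))}
    (outdir / "run_meta.json").write_text(json.dumps(meta, indent=2) + "\n")
    return {"outdir": outdir, "paths": paths}
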