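"""Synthetic Infinium-style methylation cohorts with controlled technical artifacts.

The generator emulates the structure of an EPIC-like two-channel bead array at
reduced scale: a probe manifest mixing Infinium type I and type II designs,
same-target control-probe pairs for dye-bias estimation, negative controls,
out-of-band (OOB) background draws for type-I probes, technical replicate
pairs assayed at separate occasions, chip/position/plate/well batch structure,
chronological age, and mortality follow-up. Every artifact class (additive
background, red/green dye imbalance, type-II dynamic-range compression,
multiplicative batch effects, occasion shifts) is injected with an explicit,
independently switchable magnitude so that downstream correction kernels can
be validated against known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .errors import ParameterError, SizingError

RED, GREEN = "red", "green"
_CHANNEL_INDEX = {RED: 0, GREEN: 1}

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ArrayManifest:
    """Probe catalog for a synthetic array.

    ``probes`` is indexed by probe_id with columns ``design_type`` ("I"/"II"),
    ``channel`` ("red"/"green"/"both"), ``neighbor_pair_id`` (links one type-I
    and one type-II probe with equal true methylation), ``control_pair_id``
    (links the red and green entries of a same-target control pair) and
    ``is_negative_control``.
    """

    probes: pd.DataFrame

    def __post_init__(self):
        self.validate()

    # -- accessors ---------------------------------------------------------
    @property
    def cpg_ids(self) -> pd.Index:
        mask = self.probes["control_pair_id"].isna() & ~self.probes["is_negative_control"]
        return self.probes.index[mask]

    def cpg_ids_of_type(self, design_type: str) -> pd.Index:
        sub = self.probes.loc[self.cpg_ids]
        return sub.index[sub["design_type"] == design_type]

    @property
    def negative_ids(self) -> pd.Index:
        return self.probes.index[self.probes["is_negative_control"]]

    def neighbor_pairs(self) -> pd.DataFrame:
        """One row per neighbor pair: columns type_i, type_ii (probe ids)."""
        sub = self.probes[self.probes["neighbor_pair_id"].notna()]
        rows = {}
        for pid, grp in sub.groupby("neighbor_pair_id"):
            t1 = grp.index[grp["design_type"] == "I"]
            t2 = grp.index[grp["design_type"] == "II"]
            rows[pid] = (t1[0], t2[0])
        out = pd.DataFrame.from_dict(rows, orient="index", columns=["type_i", "type_ii"])
        out.index.name = "neighbor_pair_id"
        return out.sort_index()

    def control_pairs(self) -> pd.DataFrame:
        """One row per control pair: columns red, green (probe ids)."""
        sub = self.probes[self.probes["control_pair_id"].notna()]
        rows = {}
        for pid, grp in sub.groupby("control_pair_id"):
            rows[pid] = (
                grp.index[grp["channel"] == RED][0],
                grp.index[grp["channel"] == GREEN][0],
            )
        out = pd.DataFrame.from_dict(rows, orient="index", columns=[RED, GREEN])
        out.index.name = "control_pair_id"
        return out.sort_index()

    def measurement_channels(self) -> tuple[pd.Series, pd.Series]:
        """Per-probe color channel of the methylated / unmethylated read.

        Type I probes read both alleles in their assigned channel; type II
        probes read methylated in green and unmethylated in red; control and
        negative entries are single-channel.
        """
        p = self.probes
        is_cpg2 = (p["design_type"] == "II") & p["control_pair_id"].isna() & ~p["is_negative_control"]
        meth_ch = p["channel"].where(~is_cpg2, GREEN)
        unmeth_ch = p["channel"].where(~is_cpg2, RED)
        return meth_ch, unmeth_ch

    # -- invariants --------------------------------------------------------
    def validate(self):
        p = self.probes
        required = {"design_type", "channel", "neighbor_pair_id", "control_pair_id", "is_negative_control"}
        missing = required - set(p.columns)
        if missing:
            raise ParameterError(f"manifest missing columns: {sorted(missing)}")
        if not p.index.is_unique:
            raise ParameterError("duplicate probe ids in manifest")
        for pid, grp in p[p["neighbor_pair_id"].notna()].groupby("neighbor_pair_id"):
            if sorted(grp["design_type"]) != ["I", "II"]:
                raise ParameterError(f"neighbor pair {pid} must link exactly one type-I and one type-II probe")
        for pid, grp in p[p["control_pair_id"].notna()].groupby("control_pair_id"):
            if sorted(grp["channel"]) != [GREEN, RED]:
                raise ParameterError(f"control pair {pid} must have exactly one entry per channel")
        bad = p["is_negative_control"] & p["neighbor_pair_id"].notna()
        if bad.any():
            raise ParameterError("negative controls cannot be neighbor-pair members")


@dataclass
class GroundTruth:
    """Noise-free cohort state: true betas, phenotypes, array/batch layout."""

    true_beta: pd.DataFrame            # subjects x CpG probes, in [0, 1]
    age: pd.Series                     # years, indexed by subject
    latent_aging_score: pd.Series
    survival_time: pd.Series           # years of follow-up
    event: pd.Series                   # 1 = died within follow-up
    sample_sheet: pd.DataFrame         # one row per array (see IntensityDataset)
    aging_weights: pd.Series           # per aging-CpG weight defining the latent score
    variance_components: dict = field(default_factory=dict)

    @property
    def replicate_pair_ids(self) -> pd.Index:
        col = self.sample_sheet["replicate_pair_id"].dropna()
        return pd.Index(col.unique())


@dataclass
class IntensityDataset:
    """Raw two-channel intensities plus sample metadata.

    ``meth``/``unmeth`` are probes x arrays (all manifest entries, including
    control and negative rows); ``oob`` holds one out-of-band background draw
    per type-I CpG probe per array, taken in the probe's unused channel.
    """

    meth: pd.DataFrame
    unmeth: pd.DataFrame
    oob: pd.DataFrame
    sample_sheet: pd.DataFrame

    def __post_init__(self):
        self.validate()

    def validate(self):
        if (self.meth.values < 0).any() or (self.unmeth.values < 0).any():
            raise ParameterError("intensities must be non-negative")
        if not self.meth.columns.equals(self.unmeth.columns):
            raise ParameterError("meth/unmeth array columns differ")
        pairs = self.sample_sheet["replicate_pair_id"].dropna()
        bad = pairs.value_counts() != 2
        if bad.any():
            raise ParameterError(f"replicate pairs without exactly 2 arrays: {list(bad.index[bad])}")

    def copy(self) -> "IntensityDataset":
        return IntensityDataset(
            self.meth.copy(), self.unmeth.copy(), self.oob.copy(), self.sample_sheet.copy()
        )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class PhenoConfig:
    """Phenotype model: age distribution, aging CpGs, mortality follow-up.

    Defaults mirror a middle-aged population cohort: age ~ N(56.1, 12.4^2)
    years, ~15% observed mortality over a 10-year follow-up window.  The
    hazard is h_i = baseline_hazard * exp(mortality_log_hr * z_i) with z the
    standardized latent aging score; when ``baseline_hazard`` is None it is
    solved so the expected event rate equals ``event_rate``.
    """

    age_mean: float = 56.1
    age_sd: float = 12.4
    age_min: float = 18.0
    aging_cpg_fraction: float = 0.10
    aging_slope_per_year: float = 0.02   # logits per year per unit weight
    subject_sd: float = 0.5              # between-subject SD on the logit scale
    mixture_probs: tuple = (0.45, 0.10, 0.45)     # hypo / hemi / hyper
    mixture_logit_means: tuple = (-2.5, 0.0, 2.5)
    mixture_logit_sd: float = 0.5
    mortality_log_hr: float = 0.5        # per SD of the latent score
    baseline_hazard: float | None = None  # per year; solved from event_rate if None
    event_rate: float = 0.15
    censoring_time: float = 10.0         # years
    replicates_share_chip: bool = False

    def validate(self):
        if self.age_sd <= 0:
            raise ParameterError("age_sd must be > 0")
        if not 0 <= self.aging_cpg_fraction <= 1:
            raise ParameterError("aging_cpg_fraction must be in [0, 1]")
        if self.subject_sd < 0 or self.mixture_logit_sd < 0:
            raise ParameterError("variances must be non-negative")
        if not 0 < self.event_rate < 1:
            raise ParameterError("event_rate must be in (0, 1)")
        if abs(sum(self.mixture_probs) - 1) > 1e-9:
            raise ParameterError("mixture_probs must sum to 1")
        if self.censoring_time <= 0:
            raise ParameterError("censoring_time must be > 0")


@dataclass
class TechConfig:
    """Technical-artifact magnitudes for the intensity model.

    meth = S * beta' * gain + bg,  unmeth = S * (1 - beta') * gain + bg, where
    S is a per-probe lognormal total signal, beta' the (possibly type-II
    compressed) methylation fraction, gain the product of per-array dye,
    batch and occasion multipliers for the measurement's color channel, and
    bg a truncated-normal background draw around a per-array, per-channel
    background level.
    """

    bg_mean_red: float = 300.0
    bg_mean_green: float = 300.0
    bg_sd: float = 50.0
    bg_array_sd: float = 0.10       # log-scale SD of per-array/channel background level
    dye_bias_sd: float = 0.10       # log-scale SD of the per-array red/green imbalance
    type2_compression: float = 0.85  # in (0, 1]; 1 = no compression
    type2_compression_sd: float = 0.04  # per-array SD of the compression factor
    batch_sds: dict = field(
        default_factory=lambda: {"chip": 0.075, "position": 0.045, "plate": 0.06, "well": 0.045}
    )  # sized so batch factors explain ~5% of predictor variance at default scale
    occasion_shift_sd: float = 0.05  # log-scale per-array technical shift
    signal_log_mean: float = math.log(5000.0)
    signal_log_sd: float = 0.4

    def validate(self):
        if not 0 < self.type2_compression <= 1:
            raise ParameterError("type2_compression must be in (0, 1]")
        for name in ("bg_sd", "bg_array_sd", "dye_bias_sd", "occasion_shift_sd",
                     "signal_log_sd", "type2_compression_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if self.bg_mean_red < 0 or self.bg_mean_green < 0:
            raise ParameterError("background means must be non-negative")
        if any(v < 0 for v in self.batch_sds.values()):
            raise ParameterError("batch SDs must be non-negative")

    def noise_free(self) -> "TechConfig":
        """Copy with every stochastic artifact switched off (exact-limit checks)."""
        cfg = TechConfig(**asdict(self))
        cfg.bg_mean_red = cfg.bg_mean_green = 0.0
        cfg.bg_sd = cfg.bg_array_sd = cfg.dye_bias_sd = cfg.occasion_shift_sd = 0.0
        cfg.type2_compression = 1.0
        cfg.type2_compression_sd = 0.0
        cfg.batch_sds = {k: 0.0 for k in cfg.batch_sds}
        return cfg


# ---------------------------------------------------------------------------
# manifest generation
# ---------------------------------------------------------------------------


def generate_manifest(
    n_probes: int,
    type2_fraction: float = 0.84,
    n_neighbor_pairs: int = 100,
    n_control_pairs: int = 85,
    n_negative_controls: int = 100,
    seed: int = 0,
) -> ArrayManifest:
    """Build a reduced-scale probe manifest with control structure.

    ``n_probes`` CpG probes are split into Infinium type I/II by
    ``type2_fraction``; ``n_neighbor_pairs`` disjoint (type-I, type-II) pairs
    are designated as sharing true methylation; ``n_control_pairs``
    same-target control pairs (one red + one green entry each) and
    ``n_negative_controls`` signal-free negative controls are appended.
    Deterministic for a fixed seed.
    """
    if n_probes < 100:
        raise ParameterError("n_probes must be >= 100")
    if not 0 <= type2_fraction <= 1:
        raise ParameterError("type2_fraction must be in [0, 1]")
    for name, v in (("n_neighbor_pairs", n_neighbor_pairs),
                    ("n_control_pairs", n_control_pairs),
                    ("n_negative_controls", n_negative_controls)):
        if v < 0:
            raise ParameterError(f"{name} must be non-negative")

    rng = np.random.default_rng(seed)
    n_type2 = int(round(n_probes * type2_fraction))
    n_type1 = n_probes - n_type2
    if n_neighbor_pairs > min(n_type1, n_type2):
        raise SizingError(
            f"n_neighbor_pairs={n_neighbor_pairs} exceeds available probes "
            f"(type I: {n_type1}, type II: {n_type2})"
        )

    probe_ids = [f"cg{i:07d}" for i in range(n_probes)]
    design = np.array(["I"] * n_type1 + ["II"] * n_type2)
    rng.shuffle(design)
    channel = np.where(design == "II", "both", "").astype(object)
    type1_pos = np.flatnonzero(design == "I")
    channel[type1_pos] = rng.choice([RED, GREEN], size=len(type1_pos))

    neighbor = np.array([None] * n_probes, dtype=object)
    type2_pos = np.flatnonzero(design == "II")
    pick1 = rng.choice(type1_pos, size=n_neighbor_pairs, replace=False)
    pick2 = rng.choice(type2_pos, size=n_neighbor_pairs, replace=False)
    for j, (i1, i2) in enumerate(zip(pick1, pick2)):
        neighbor[i1] = neighbor[i2] = f"np{j:05d}"

    cpg = pd.DataFrame(
        {
            "design_type": design,
            "channel": channel,
            "neighbor_pair_id": neighbor,
            "control_pair_id": None,
            "is_negative_control": False,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )

    ctl_rows = []
    for j in range(n_control_pairs):
        for ch in (RED, GREEN):
            ctl_rows.append((f"ctl{j:04d}_{ch}", "I", ch, None, f"cp{j:04d}", False))
    neg_rows = [
        (f"neg{j:04d}", "I", RED if j % 2 == 0 else GREEN, None, None, True)
        for j in range(n_negative_controls)
    ]
    extra = pd.DataFrame(
        ctl_rows + neg_rows,
        columns=["probe_id", "design_type", "channel", "neighbor_pair_id",
                 "control_pair_id", "is_negative_control"],
    ).set_index("probe_id")

    return ArrayManifest(pd.concat([cpg, extra]))


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


def _solve_baseline_hazard(z: np.ndarray, log_hr: float, censoring_time: float, rate: float) -> float:
    """Baseline hazard b such that mean(1 - exp(-b * exp(log_hr*z) * C)) == rate."""
    relhaz = np.exp(log_hr * z)

    def expected_rate(b):
        return float(np.mean(1.0 - np.exp(-b * relhaz * censoring_time))) - rate

    return optimize.brentq(expected_rate, 1e-12, 1e4 / censoring_time, xtol=1e-12)


def _batch_layout(n_subjects, n_replicate_pairs, share_chip):
    """Chip/position/plate/well assignment per array, occasion-1 block first.

    Chips carry 8 arrays, plates 12 chips (96 wells).  By default the
    occasion-2 block starts on a fresh chip so the two arrays of a replicate
    pair land on different chips.
    """
    order = []  # (subject_idx, occasion)
    if share_chip:
        for i in range(n_replicate_pairs):
            order += [(i, 1), (i, 2)]
        order += [(i, 1) for i in range(n_replicate_pairs, n_subjects)]
        chip_of = list(range(len(order)))
        chips = [i // 8 for i in chip_of]
        pos = [i % 8 + 1 for i in chip_of]
    else:
        order = [(i, 1) for i in range(n_subjects)]
        occ2_offset = math.ceil(n_subjects / 8) * 8
        chips = [i // 8 for i in range(n_subjects)]
        pos = [i % 8 + 1 for i in range(n_subjects)]
        for j in range(n_replicate_pairs):
            order.append((j, 2))
            chips.append((occ2_offset + j) // 8)
            pos.append((occ2_offset + j) % 8 + 1)
    plates = [c // 12 for c in chips]
    wells = []
    for c, p in zip(chips, pos):
        slot = (c % 12) * 8 + (p - 1)
        wells.append(f"{chr(ord('A') + slot // 12)}{slot % 12 + 1:02d}")
    return order, chips, pos, plates, wells


def simulate_truth(
    manifest: ArrayManifest,
    n_subjects: int,
    n_replicate_pairs: int,
    pheno_config: PhenoConfig | None = None,
    seed: int = 0,
) -> GroundTruth:
    """Draw a noise-free cohort: true betas, ages, latent aging score, survival.

    Per-probe mean methylation comes from a hypo/hemi/hyper logit-normal
    mixture; subjects deviate on the logit scale; a designated aging-CpG
    subset drifts linearly with age on the logit scale with per-probe weights
    w_j ~ N(0,1); the latent aging score is sum_j w_j * beta_ij over aging
    CpGs.  Survival times are exponential with hazard proportional to
    exp(log_hr * standardized score), censored administratively.
    """
    cfg = pheno_config or PhenoConfig()
    cfg.validate()
    if n_replicate_pairs > n_subjects:
        raise ParameterError("n_replicate_pairs cannot exceed n_subjects")
    if n_subjects < 1:
        raise ParameterError("n_subjects must be >= 1")

    rng = np.random.default_rng(seed)
    cpg_ids = manifest.cpg_ids
    n_cpg = len(cpg_ids)

    classes = rng.choice(3, size=n_cpg, p=cfg.mixture_probs)
    mu_logit = rng.normal(np.asarray(cfg.mixture_logit_means)[classes], cfg.mixture_logit_sd)

    subjects = pd.Index([f"S{i:05d}" for i in range(n_subjects)], name="subject_id")
    age = np.maximum(rng.normal(cfg.age_mean, cfg.age_sd, n_subjects), cfg.age_min)

    n_aging = int(round(cfg.aging_cpg_fraction * n_cpg))
    aging_idx = rng.choice(n_cpg, size=n_aging, replace=False)
    w = rng.normal(0.0, 1.0, n_aging)

    logit_beta = mu_logit[None, :] + rng.normal(0.0, cfg.subject_sd, (n_subjects, n_cpg))
    if n_aging:
        logit_beta[:, aging_idx] += cfg.aging_slope_per_year * np.outer(age - cfg.age_mean, w)
    true_beta = special.expit(logit_beta)

    # neighbor pairs interrogate the same locus: equal true methylation
    nb = manifest.neighbor_pairs()
    if len(nb):
        i1 = cpg_ids.get_indexer(nb["type_i"])
        i2 = cpg_ids.get_indexer(nb["type_ii"])
        true_beta[:, i2] = true_beta[:, i1]

    score = true_beta[:, aging_idx] @ w if n_aging else np.zeros(n_subjects)
    sd = score.std(ddof=1) if n_subjects > 1 else 0.0
    z = (score - score.mean()) / sd if sd > 0 else np.zeros(n_subjects)

    b0 = cfg.baseline_hazard
    if b0 is None:
        b0 = _solve_baseline_hazard(z, cfg.mortality_log_hr, cfg.censoring_time, cfg.event_rate)
    hazard = b0 * np.exp(cfg.mortality_log_hr * z)
    t_event = rng.exponential(1.0 / hazard)
    event = (t_event <= cfg.censoring_time).astype(int)
    time = np.minimum(t_event, cfg.censoring_time)

    order, chips, pos, plates, wells = _batch_layout(
        n_subjects, n_replicate_pairs, cfg.replicates_share_chip
    )
    rows = []
    for a, ((si, occ), chip, p, plate, well) in enumerate(zip(order, chips, pos, plates, wells)):
        pair = f"P{si:05d}" if si < n_replicate_pairs else None
        rows.append(
            {
                "array_id": f"A{a:05d}",
                "subject_id": subjects[si],
                "replicate_pair_id": pair,
                "occasion": occ,
                "chip": f"chip{chip:04d}",
                "position": f"R{p:02d}",
                "plate": f"plate{plate:03d}",
                "well": well,
                "age": age[si],
                "survival_time": time[si],
                "event": event[si],
            }
        )
    sheet = pd.DataFrame(rows).set_index("array_id")

    return GroundTruth(
        true_beta=pd.DataFrame(true_beta, index=subjects, columns=cpg_ids),
        age=pd.Series(age, index=subjects, name="age"),
        latent_aging_score=pd.Series(score, index=subjects, name="latent_aging_score"),
        survival_time=pd.Series(time, index=subjects, name="survival_time"),
        event=pd.Series(event, index=subjects, name="event"),
        sample_sheet=sheet,
        aging_weights=pd.Series(w, index=cpg_ids[aging_idx], name="weight"),
        variance_components={"subject": float(np.var(score, ddof=1)) if n_subjects > 1 else 0.0},
    )


# ---------------------------------------------------------------------------
# intensities
# ---------------------------------------------------------------------------


def _truncated_normal(rng, mean, sd, size):
    """Non-negative background draws; degenerate (sd=0) collapses to the mean."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size)
    if sd == 0:
        return np.maximum(mean, 0.0).copy()
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_intensities(
    truth: GroundTruth,
    manifest: ArrayManifest,
    tech_config: TechConfig | None = None,
    seed: int = 0,
) -> IntensityDataset:
    """Render ground-truth betas into raw two-channel intensities.

    The two arrays of a replicate pair share true betas but receive fully
    independent technical draws (background, dye, occasion shift) and sit in
    different batch cells, mimicking assays run at separate occasions.
    """
    cfg = tech_config or TechConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)

    sheet = truth.sample_sheet
    arrays = sheet.index
    n_arrays = len(arrays)
    probes = manifest.probes
    all_ids = probes.index
    cpg_ids = manifest.cpg_ids
    n_cpg = len(cpg_ids)

    # per-probe total signal (probe affinity), shared across arrays
    signal_cpg = rng.lognormal(cfg.signal_log_mean, cfg.signal_log_sd, n_cpg)

    # compressed methylation fraction per (array, cpg)
    beta = truth.true_beta.loc[sheet["subject_id"], cpg_ids].to_numpy()  # arrays x cpg
    is_type2 = probes.loc[cpg_ids, "design_type"].to_numpy() == "II"
    beta_prime = beta.copy()
    if cfg.type2_compression != 1.0 or cfg.type2_compression_sd > 0:
        # per-array compression factor: probe-type bias severity varies by array
        c_a = cfg.type2_compression + (
            rng.normal(0.0, cfg.type2_compression_sd, n_arrays)
            if cfg.type2_compression_sd
            else 0.0
        )
        c_a = np.clip(np.atleast_1d(c_a), 0.05, 1.0)
        beta_prime[:, is_type2] = 0.5 + c_a[:, None] * (beta[:, is_type2] - 0.5)

    # per-array, per-channel multiplicative gain: dye x batch x occasion
    log_gain = np.zeros((n_arrays, 2))
    log_gain[:, _CHANNEL_INDEX[RED]] += rng.normal(0.0, cfg.dye_bias_sd, n_arrays) if cfg.dye_bias_sd else 0.0
    for factor, sd in cfg.batch_sds.items():
        levels = sheet[factor].astype(str)
        uniq = pd.Index(sorted(levels.unique()))
        eff = rng.normal(0.0, sd, (len(uniq), 2)) if sd else np.zeros((len(uniq), 2))
        log_gain += eff[uniq.get_indexer(levels), :]
    if cfg.occasion_shift_sd:
        log_gain += rng.normal(0.0, cfg.occasion_shift_sd, n_arrays)[:, None]
    gain = np.exp(log_gain)  # arrays x 2

    # per-array, per-channel background level
    bg_mean_ch = np.array([cfg.bg_mean_red, cfg.bg_mean_green])
    bg_level = bg_mean_ch[None, :] * (
        np.exp(rng.normal(0.0, cfg.bg_array_sd, (n_arrays, 2))) if cfg.bg_array_sd else 1.0
    )  # arrays x 2

    meth_ch, unmeth_ch = manifest.measurement_channels()
    meth_ci = meth_ch.map(_CHANNEL_INDEX).to_numpy(dtype=int)
    unmeth_ci = unmeth_ch.map(_CHANNEL_INDEX).to_numpy(dtype=int)

    # assemble signal and allele-fraction matrices over ALL manifest rows
    n_all = len(all_ids)
    signal = np.zeros(n_all)
    meth_frac = np.zeros((n_all, n_arrays))
    unmeth_frac = np.zeros((n_all, n_arrays))

    cpg_pos = all_ids.get_indexer(cpg_ids)
    signal[cpg_pos] = signal_cpg
    meth_frac[cpg_pos, :] = beta_prime.T
    unmeth_frac[cpg_pos, :] = (1.0 - beta_prime).T

    ctl_pairs = manifest.control_pairs()
    if len(ctl_pairs):
        ctl_signal = rng.lognormal(cfg.signal_log_mean, cfg.signal_log_sd, len(ctl_pairs))
        for s, (_, row) in zip(ctl_signal, ctl_pairs.iterrows()):
            for ch in (RED, GREEN):
                pos = all_ids.get_loc(row[ch])
                signal[pos] = s
                meth_frac[pos, :] = 1.0
                unmeth_frac[pos, :] = 1.0
    # negative controls keep signal 0 / fractions 0

    gain_meth = gain.T[meth_ci, :]      # probes x arrays
    gain_unmeth = gain.T[unmeth_ci, :]
    bg_meth_mean = bg_level.T[meth_ci, :]
    bg_unmeth_mean = bg_level.T[unmeth_ci, :]

    meth = signal[:, None] * meth_frac * gain_meth + _truncated_normal(
        rng, bg_meth_mean, cfg.bg_sd, (n_all, n_arrays)
    )
    unmeth = signal[:, None] * unmeth_frac * gain_unmeth + _truncated_normal(
        rng, bg_unmeth_mean, cfg.bg_sd, (n_all, n_arrays)
    )

    # out-of-band draws: type-I CpG probes read in their unused channel
    type1_ids = manifest.cpg_ids_of_type("I")
    opp_ci = np.where(
        probes.loc[type1_ids, "channel"].to_numpy() == RED,
        _CHANNEL_INDEX[GREEN],
        _CHANNEL_INDEX[RED],
    )
    oob = _truncated_normal(rng, bg_level.T[opp_ci, :], cfg.bg_sd, (len(type1_ids), n_arrays))

    truth.variance_components.update(
        {
            "occasion": cfg.occasion_shift_sd ** 2,
            "batch": float(sum(v ** 2 for v in cfg.batch_sds.values())),
            "residual": cfg.bg_sd ** 2,
        }
    )

    return IntensityDataset(
        meth=pd.DataFrame(meth, index=all_ids, columns=arrays),
        unmeth=pd.DataFrame(unmeth, index=all_ids, columns=arrays),
        oob=pd.DataFrame(oob, index=type1_ids, columns=arrays),
        sample_sheet=sheet.copy(),
    )


# ---------------------------------------------------------------------------
# synthetic predictor weight tables
# ---------------------------------------------------------------------------


def make_weight_tables(manifest: ArrayManifest, truth: GroundTruth, configs, seed: int = 0) -> dict:
    """Construct synthetic predictor models against the ground truth.

    Each config is a mapping with keys ``name``, ``n_probes``, ``target``
    ("age", "latent_score" or "random") and optional ``transform``
    ("identity" or "horvath_age").  For phenotype targets the weights are the
    minimum-norm least-squares fit of the (transformed) target on the true
    betas of the sampled probes, so with n_probes + 1 >= n_subjects the model
    reproduces its target exactly on noise-free data; random models draw
    i.i.d. weights.  The training fit is stored on the model for later
    verification.
    """
    from .predictors import PredictorModel, horvath_forward

    rng = np.random.default_rng(seed)
    cpg_ids = manifest.cpg_ids
    models = {}
    for cfg in configs:
        name = cfg["name"]
        n_probes = int(cfg["n_probes"])
        target = cfg.get("target", "age")
        transform = cfg.get("transform", "identity")
        if n_probes > len(cpg_ids):
            raise SizingError(f"{name}: n_probes={n_probes} exceeds manifest CpG count {len(cpg_ids)}")
        probes = pd.Index(rng.choice(cpg_ids, size=n_probes, replace=False))
        X = truth.true_beta[probes].to_numpy()

        if target == "random":
            weights = rng.normal(0.0, 1.0 / math.sqrt(n_probes), n_probes)
            intercept = 0.0
            fitted_raw = intercept + X @ weights
        else:
            if target == "age":
                y = truth.age.to_numpy()
            elif target == "latent_score":
                y = truth.latent_aging_score.to_numpy()
            else:
                raise ParameterError(f"unknown target {target!r}")
            y_fit = horvath_forward(y, cfg.get("adult_age", 20.0)) if transform == "horvath_age" else y
            Xa = np.column_stack([np.ones(len(y_fit)), X])
            coef, *_ = np.linalg.lstsq(Xa, y_fit, rcond=None)
            intercept, weights = float(coef[0]), coef[1:]
            fitted_raw = Xa @ coef

        model = PredictorModel(
            name=name,
            intercept=float(intercept),
            weights=pd.Series(weights, index=probes, name="weight"),
            transform=transform,
            adult_age=float(cfg.get("adult_age", 20.0)),
        )
        model.training_fit = pd.Series(
            model.apply_transform(fitted_raw), index=truth.true_beta.index, name=name
        )
        models[name] = model
    return models


# ---------------------------------------------------------------------------
# direct two-way replicate-table simulation
# ---------------------------------------------------------------------------


def simulate_replicate_table(
    n_pairs: int,
    var_subject: float = 9.0,
    var_occasion: float = 0.5,
    var_residual: float = 0.5,
    seed: int = 0,
) -> np.ndarray:
    """Draw an (n_pairs x 2) table y_ij = u_i + c_ij + e_ij.

    u_i ~ N(0, var_subject) is the subject effect; c_ij ~ N(0, var_occasion)
    is the occasion effect, drawn independently per measurement because each
    array of a replicate pair is processed at its own occasion; e_ij ~
    N(0, var_residual).  The population single-measurement absolute-agreement
    intraclass correlation is var_subject / (var_subject + var_occasion +
    var_residual).
    """
    for name, v in (("var_subject", var_subject), ("var_occasion", var_occasion),
                    ("var_residual", var_residual)):
        if v < 0:
            raise ParameterError(f"{name} must be non-negative")
    rng = np.random.default_rng(seed)
    u = rng.normal(0.0, math.sqrt(var_subject), (n_pairs, 1))
    c = rng.normal(0.0, math.sqrt(var_occasion), (n_pairs, 2))
    e = rng.normal(0.0, math.sqrt(var_residual), (n_pairs, 2))
    return u + c + e
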