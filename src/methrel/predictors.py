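"""Generic DNAm-predictor engine.

A predictor is a weighted linear combination of CpG beta values plus an
intercept, optionally passed through an output calibration (the piecewise
log-linear age calibration used by first-generation epigenetic clocks), with
a configurable policy for probes missing from the input matrix.  Also
provides reference-based cell-fraction estimation by constrained least
squares.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import MissingProbesError, ParameterError

log = logging.getLogger(__name__)

TRANSFORMS = ("identity", "horvath_age")


# ---------------------------------------------------------------------------
# age calibration
# ---------------------------------------------------------------------------


def horvath_forward(age, adult_age: float = 20.0):
    """Piecewise log-linear age calibration: log-scale below adult_age, linear above.

    F(age) = log(age + 1) - log(adult_age + 1) for age <= adult_age,
    (age - adult_age) / (adult_age + 1) otherwise.  Continuous, strictly
    increasing, F(adult_age) = 0.
    """
    age = np.asarray(age, dtype=float)
    out = np.where(
        age <= adult_age,
        np.log1p(age) - np.log1p(adult_age),
        (age - adult_age) / (adult_age + 1.0),
    )
    return out if out.ndim else float(out)


def horvath_inverse(s, adult_age: float = 20.0):
    """Exact inverse of :func:`horvath_forward`, mapping a raw score to years."""
    if adult_age <= 0:
        raise ParameterError("adult_age must be > 0")
    s = np.asarray(s, dtype=float)
    out = np.where(
        s <= 0,
        (1.0 + adult_age) * np.exp(s) - 1.0,
        (1.0 + adult_age) * s + adult_age,
    )
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------


@dataclass
class PredictorModel:
    """Named linear predictor over CpG betas."""

    name: str
    intercept: float
    weights: pd.Series                 # probe_id -> coefficient
    transform: str = "identity"
    adult_age: float = 20.0
    missing_policy: str = "mean_impute"
    training_fit: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self):
        if len(self.weights) < 1:
            raise ParameterError(f"{self.name}: model needs at least one weight")
        if self.adult_age <= 0:
            raise ParameterError(f"{self.name}: adult_age must be > 0")
        if self.transform not in TRANSFORMS:
            raise ParameterError(f"{self.name}: unknown transform {self.transform!r}")
        if self.missing_policy not in ("error", "mean_impute"):
            raise ParameterError(f"{self.name}: unknown missing_policy {self.missing_policy!r}")

    def apply_transform(self, raw):
        if self.transform == "horvath_age":
            return horvath_inverse(raw, self.adult_age)
        return raw


@dataclass
class PredictorEstimates:
    """Per-array estimates for one or more predictors, tagged with provenance."""

    values: pd.DataFrame               # arrays x predictor names
    provenance: str = "raw"

    def __post_init__(self):
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ParameterError("predictor estimates must be finite")

    def __getitem__(self, name) -> pd.Series:
        return self.values[name]


def apply_predictor(beta, model: PredictorModel) -> PredictorEstimates:
    """Score a beta matrix (probes x arrays) with one predictor model.

    Missing handling under ``mean_impute``: NaN cells of a present probe are
    filled with that probe's mean over the arrays where it is observed;
    probes absent from the matrix altogether are filled per array with the
    mean beta of the model probes that are present.  Imputation counts are
    logged.  Under ``error`` any absent probe raises with the full list.
    """
    values = getattr(beta, "values_frame", None)
    frame = values if values is not None else beta  # BetaMatrix or plain DataFrame
    provenance = getattr(beta, "provenance", "raw")

    probes = model.weights.index
    present = probes.intersection(frame.index)
    absent = probes.difference(frame.index)
    if model.missing_policy == "error" and len(absent):
        raise MissingProbesError(absent)

    sub = frame.reindex(probes)
    n_nan = int(sub.loc[present].isna().sum().sum())
    if n_nan:
        sub.loc[present] = sub.loc[present].apply(lambda r: r.fillna(r.mean()), axis=1)
    if len(absent):
        array_means = sub.loc[present].mean(axis=0)
        sub.loc[absent] = np.broadcast_to(array_means.to_numpy(), (len(absent), len(array_means)))
        log.info("%s: imputed %d absent probes with per-array mean beta", model.name, len(absent))
    if n_nan:
        log.info("%s: imputed %d missing cells with per-probe mean beta", model.name, n_nan)
    if sub.isna().any().any():
        raise MissingProbesError(probes)  # nothing available to impute from

    raw = model.intercept + sub.to_numpy().T @ model.weights.to_numpy()
    est = model.apply_transform(raw)
    return PredictorEstimates(
        pd.DataFrame({model.name: est}, index=frame.columns), provenance=provenance
    )


def apply_predictors(beta, models) -> PredictorEstimates:
    """Score several models (mapping name -> model or iterable) on one beta matrix."""
    items = models.values() if isinstance(models, dict) else list(models)
    parts = [apply_predictor(beta, m) for m in items]
    values = pd.concat([p.values for p in parts], axis=1)
    return PredictorEstimates(values, provenance=parts[0].provenance if parts else "raw")


@dataclass
class CompositeModel:
    """Two-level composite: a linear combination of sub-predictor outputs.

    Mirrors mortality composites built from DNAm surrogate sub-scores; one
    level of nesting only.
    """

    name: str
    intercept: float
    sub_weights: dict                  # sub-model name -> coefficient
    sub_models: dict                   # sub-model name -> PredictorModel

    def __post_init__(self):
        missing = set(self.sub_weights) - set(self.sub_models)
        if missing:
            raise ParameterError(f"{self.name}: sub-models not provided: {sorted(missing)}")


def apply_composite(beta, composite: CompositeModel) -> PredictorEstimates:
    subs = apply_predictors(beta, [composite.sub_models[n] for n in composite.sub_weights])
    coefs = pd.Series(composite.sub_weights)
    est = composite.intercept + subs.values[coefs.index].to_numpy() @ coefs.to_numpy()
    return PredictorEstimates(
        pd.DataFrame({composite.name: est}, index=subs.values.index),
        provenance=subs.provenance,
    )


# ---------------------------------------------------------------------------
# cell-fraction deconvolution
# ---------------------------------------------------------------------------


def deconvolve_cell_fractions(
    beta,
    reference: pd.DataFrame,
    renormalize: bool = False,
    condition_threshold: float = 1e8,
):
    """Estimate cell-type fractions per array by constrained least squares.

    Solves min ||R f - b||^2 subject to f >= 0 and sum(f) <= 1 for each
    array, projecting observed betas onto reference methylation profiles
    (probes x cell types).  NNLS provides the solution when the simplex
    constraint is slack; an SLSQP refinement is applied when it binds.
    Returns (fractions: arrays x cell types, residual_norm: per array).
    With ``renormalize`` the fractions are rescaled to sum to exactly 1.
    """
    values = getattr(beta, "values_frame", None)
    frame = values if values is not None else beta
    if reference.shape[1] < 2:
        raise ParameterError("reference must contain at least 2 cell types")
    missing = reference.index.difference(frame.index)
    if len(missing):
        raise ParameterError(f"{len(missing)} reference probes absent from beta matrix")

    R = reference.to_numpy(dtype=float)
    cond = np.linalg.cond(R)
    if cond > condition_threshold:
        warnings.warn(
            f"reference profiles nearly collinear (condition number {cond:.3g})",
            stacklevel=2,
        )
    B = frame.loc[reference.index].to_numpy(dtype=float)

    n_types = R.shape[1]
    fracs = np.empty((B.shape[1], n_types))
    resid = np.empty(B.shape[1])
    for a in range(B.shape[1]):
        b = B[:, a]
        f, rnorm = optimize.nnls(R, b)
        if f.sum() > 1.0 + 1e-9:
            res = optimize.minimize(
                lambda x: 0.5 * np.sum((R @ x - b) ** 2),
                np.clip(f / f.sum(), 0, 1),
                jac=lambda x: R.T @ (R @ x - b),
                bounds=[(0.0, 1.0)] * n_types,
                constraints=[{"type": "ineq", "fun": lambda x: 1.0 - x.sum()}],
                method="SLSQP",
                options={"ftol": 1e-12, "maxiter": 200},
            )
            f = np.clip(res.x, 0.0, None)
            rnorm = float(np.linalg.norm(R @ f - b))
        fracs[a] = f
        resid[a] = rnorm
    if renormalize:
        totals = fracs.sum(axis=1)
        totals[totals == 0] = 1.0
        fracs = fracs / totals[:, None]
    return (
        pd.DataFrame(fracs, index=frame.columns, columns=reference.columns),
        pd.Series(resid, index=frame.columns, name="residual_norm"),
    )
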