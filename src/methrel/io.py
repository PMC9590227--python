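"""Plain-text readers/writers for the package's tabular formats.

Beta and intensity matrices travel as TSV (probes x arrays, header row of
array ids); sample sheets as CSV; manifests as TSV; predictor models as CSV
with a ``#``-prefixed metadata header block followed by probe_id,weight rows.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd

from .errors import ModelFormatError
from .predictors import PredictorModel
from .synthetic_data import ArrayManifest, IntensityDataset

_FLOAT_FMT = "%.10g"


# ---------------------------------------------------------------------------
# matrices and sheets
# ---------------------------------------------------------------------------


def write_matrix_tsv(frame: pd.DataFrame, path) -> Path:
    path = Path(path)
    frame.to_csv(path, sep="\t", index_label=frame.index.name or "probe_id",
                 float_format=_FLOAT_FMT)
    return path


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_sample_sheet(sheet: pd.DataFrame, path) -> Path:
    path = Path(path)
    sheet.to_csv(path, index_label=sheet.index.name or "array_id", float_format=_FLOAT_FMT)
    return path


def read_sample_sheet(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_manifest(manifest: ArrayManifest, path) -> Path:
    path = Path(path)
    manifest.probes.to_csv(path, sep="\t", index_label="probe_id")
    return path


def read_manifest(path) -> ArrayManifest:
    probes = pd.read_csv(path, sep="\t", index_col=0)
    probes["is_negative_control"] = probes["is_negative_control"].astype(bool)
    for col in ("neighbor_pair_id", "control_pair_id"):
        probes[col] = probes[col].where(probes[col].notna(), None)
    return ArrayManifest(probes)


def write_intensity_dataset(ds: IntensityDataset, outdir) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "meth": write_matrix_tsv(ds.meth, outdir / "meth.tsv"),
        "unmeth": write_matrix_tsv(ds.unmeth, outdir / "unmeth.tsv"),
        "oob": write_matrix_tsv(ds.oob, outdir / "oob.tsv"),
        "sample_sheet": write_sample_sheet(ds.sample_sheet, outdir / "sample_sheet.csv"),
    }
    return paths


def read_intensity_dataset(indir) -> IntensityDataset:
    indir = Path(indir)
    return IntensityDataset(
        meth=read_matrix_tsv(indir / "meth.tsv"),
        unmeth=read_matrix_tsv(indir / "unmeth.tsv"),
        oob=read_matrix_tsv(indir / "oob.tsv"),
        sample_sheet=read_sample_sheet(indir / "sample_sheet.csv"),
    )


# ---------------------------------------------------------------------------
# predictor models
# ---------------------------------------------------------------------------


def write_model_csv(model: PredictorModel, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# name={model.name}\n")
        fh.write(f"# transform={model.transform}\n")
        fh.write(f"# intercept={model.intercept!r}\n")
        fh.write(f"# adult_age={model.adult_age!r}\n")
        fh.write("probe_id,weight\n")
        for pid, w in model.weights.items():
            fh.write(f"{pid},{w!r}\n")
    return path


def read_model_csv(path) -> PredictorModel:
    """Strict parse of the model CSV format; errors carry line numbers."""
    meta = {}
    probes, weights = [], []
    saw_header = False
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if saw_header:
                    raise ModelFormatError(line_no, "metadata after data header")
                body = line.lstrip("#").strip()
                if "=" not in body:
                    raise ModelFormatError(line_no, f"malformed metadata line {line!r}")
                key, value = body.split("=", 1)
                meta[key.strip()] = value.strip()
                continue
            if not saw_header:
                if line.replace(" ", "") != "probe_id,weight":
                    raise ModelFormatError(line_no, f"expected 'probe_id,weight' header, got {line!r}")
                saw_header = True
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise ModelFormatError(line_no, f"expected 2 fields, got {len(parts)}")
            probes.append(parts[0])
            try:
                weights.append(float(parts[1]))
            except ValueError:
                raise ModelFormatError(line_no, f"non-numeric weight {parts[1]!r}") from None
    if "name" not in meta:
        raise ModelFormatError(0, "missing '# name=' metadata")
    if not probes:
        raise ModelFormatError(0, "model has no weights")
    return PredictorModel(
        name=meta["name"],
        intercept=float(meta.get("intercept", 0.0)),
        weights=pd.Series(weights, index=pd.Index(probes, name="probe_id"), name="weight"),
        transform=meta.get("transform", "identity"),
        adult_age=float(meta.get("adult_age", 20.0)),
    )


# ---------------------------------------------------------------------------
# provenance
# ---------------------------------------------------------------------------


def checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_checksum_manifest(paths, out_path) -> Path:
    out_path = Path(out_path)
    lines = [f"{checksum(p)}  {Path(p).name}" for p in sorted(map(str, paths))]
    out_path.write_text("\n".join(lines) + "\n")
    return out_path
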