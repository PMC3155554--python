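"""Readers and writers for the pipeline's plain-text artifacts.

Formats: probe matrix TSV (probe_id, chrom, pos, one column per sample),
per-sample segments in SEG layout (sample, chrom, loc.start, loc.end,
num.mark, seg.mean), common-grid and dose-matrix TSVs, clinical/survival
CSVs, and JSON results.  Writers and readers round-trip exactly; readers
validate schemas and probe ordering.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import ProbeMatrix

__all__ = [
    "write_probe_matrix", "read_probe_matrix",
    "write_seg", "read_seg",
    "write_dose_matrix", "read_dose_matrix",
    "write_grid", "read_grid",
    "write_clinical", "read_clinical",
    "write_survival", "read_survival",
    "write_json", "read_json",
]

SEG_COLUMNS = ["sample", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]


def write_probe_matrix(pm: ProbeMatrix, path):
    sample_cols = pm.values.T.reset_index(drop=True)
    sample_cols.columns = pm.samples
    df = pd.concat([pm.probes.reset_index(drop=True), sample_cols], axis=1)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_probe_matrix(path) -> ProbeMatrix:
    df = pd.read_csv(path, sep="\t")
    required = ["probe_id", "chrom", "pos"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"probe TSV missing columns: {missing}")
    for chrom, grp in df.groupby("chrom", sort=False):
        if np.any(np.diff(grp["pos"].to_numpy()) <= 0):
            raise ValueError(
                f"probe positions not strictly increasing on {chrom}; "
                "sort the file by (chrom, pos) before loading")
    samples = [c for c in df.columns if c not in required]
    values = df[samples].T
    values.columns = df["probe_id"]
    return ProbeMatrix(df[required], values)


def write_seg(profiles: pd.DataFrame, path):
    """Per-sample segments in SEG layout (start/end in bin coordinates)."""
    out = pd.DataFrame({
        "sample": profiles["sample"],
        "chrom": profiles["chrom"],
        "loc.start": profiles["start_bin"],
        "loc.end": profiles["stop_bin"],
        "num.mark": profiles["n_bins"],
        "seg.mean": profiles["seg_mean"],
    })
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_seg(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SEG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"SEG file missing columns: {missing}")
    return df.rename(columns={"loc.start": "start_bin", "loc.end": "stop_bin",
                              "num.mark": "n_bins", "seg.mean": "seg_mean"})


def write_dose_matrix(doses: pd.DataFrame, path):
    doses.rename_axis("sample").to_csv(path, sep="\t")


def read_dose_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample")
    bad = ~df.isin([-1, 0, 1]).all()
    if bad.any():
        raise ValueError(f"dose matrix entries outside {{-1,0,1}} in columns: "
                         f"{list(df.columns[bad])}")
    return df


def write_grid(grid: pd.DataFrame, path):
    grid.to_csv(path, sep="\t", index=False)


def read_grid(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = ["segment_id", "chrom", "start_bin", "stop_bin"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"grid TSV missing columns: {missing}")
    return df


def write_clinical(clinical: pd.DataFrame, path):
    clinical.to_csv(path, index=False)


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "sample" not in df.columns:
        raise ValueError("clinical CSV needs a 'sample' column")
    return df  # rows with missing covariates are retained; fits are complete-case


def write_survival(survival: pd.DataFrame, path):
    survival.to_csv(path, index=False)


def read_survival(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("sample", "time_months", "event") if c not in df.columns]
    if missing:
        raise ValueError(f"survival CSV missing columns: {missing}")
    return df


def _plain(obj):
    """Recursively convert numpy scalars/containers to plain Python."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def write_json(obj, path):
    Path(path).write_text(
        json.dumps(_plain(obj), indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def write_truth(truth, path):
    """Ground-truth table (subtype, doses, risk index) as JSON."""
    payload = {
        "samples": truth.samples.to_dict(orient="records"),
        "doses": {c: truth.doses[c].astype(int).tolist()
                  for c in truth.doses.columns},
    }
    write_json(payload, path)


def read_truth(path):
    from .simulate import TruthTable
    payload = read_json(path)
    samples = pd.DataFrame(payload["samples"])
    doses = pd.DataFrame(payload["doses"], index=samples["sample"].tolist())
    return TruthTable(samples, doses)


def write_simulation_config(config, path):
    """SimulationConfig (planted events included) as YAML."""
    import dataclasses

    import yaml
    d = _plain(dataclasses.asdict(config))
    d["events"] = [_plain(dataclasses.asdict(ev)) for ev in config.events]
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def read_simulation_config(path):
    import yaml

    from .simulate import PlantedEvent, SimulationConfig
    d = yaml.safe_load(Path(path).read_text())
    d["events"] = tuple(PlantedEvent(**ev) for ev in d.pop("events", []))
    return SimulationConfig(**d)
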