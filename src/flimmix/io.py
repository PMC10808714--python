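"""Readers and writers for curves, datasets, configurations and reports.

All artifacts are plain text (CSV + JSON/YAML) and carry enough provenance
(seeds, instrument parameters, format version) to regenerate them exactly.
Curve CSVs use the two-column ``time_ns,counts`` schema, which doubles as an
import shim for generic instrument exports.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .decay import DecayCurve, InstrumentConfig, LabeledDataset
from .errors import FlimmixError
from .spacing import SpacingLaw, SweepResult

FORMAT_VERSION = "1"

__all__ = [
    "write_curve_csv",
    "read_curve_csv",
    "write_dataset",
    "read_dataset",
    "instrument_to_dict",
    "instrument_from_dict",
    "load_config",
    "write_sweep_csv",
    "write_law_json",
]


def write_curve_csv(curve: DecayCurve, path) -> None:
    pd.DataFrame({"time_ns": curve.time_ns, "counts": curve.counts}).to_csv(
        path, index=False
    )


def read_curve_csv(path) -> DecayCurve:
    frame = pd.read_csv(path)
    if list(frame.columns) != ["time_ns", "counts"]:
        raise FlimmixError(f"{path}: expected columns time_ns,counts, got {list(frame.columns)}")
    return DecayCurve(
        counts=frame["counts"].to_numpy(), time_ns=frame["time_ns"].to_numpy()
    )


def instrument_to_dict(instrument: InstrumentConfig) -> dict:
    return dataclasses.asdict(instrument)


def instrument_from_dict(data: dict) -> InstrumentConfig:
    return InstrumentConfig(**data)


def write_dataset(dataset: LabeledDataset, directory) -> None:
    """Directory layout: curves/curve_<id>.csv + labels.csv + manifest.json."""
    directory = Path(directory)
    (directory / "curves").mkdir(parents=True, exist_ok=True)
    n_digits = len(str(len(dataset) - 1))
    for i, curve in enumerate(dataset.curves):
        write_curve_csv(curve, directory / "curves" / f"curve_{i:0{n_digits}d}.csv")
    labels = pd.DataFrame(
        dataset.labels,
        columns=[f"P_{j + 1}" for j in range(dataset.labels.shape[1])],
    )
    labels.insert(0, "curve_id", np.arange(len(dataset)))
    labels.to_csv(directory / "labels.csv", index=False)
    manifest = {
        "format_version": FORMAT_VERSION,
        "seed": dataset.seed,
        "prior_spec": dataset.prior_spec,
        "lifetimes_ns": list(dataset.lifetimes_ns),
        "instrument": instrument_to_dict(dataset.instrument),
        "n_curves": len(dataset),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_dataset(directory) -> LabeledDataset:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    if manifest.get("format_version") != FORMAT_VERSION:
        raise FlimmixError(
            f"dataset format version {manifest.get('format_version')!r} is "
            f"incompatible with expected {FORMAT_VERSION!r}"
        )
    labels_frame = pd.read_csv(directory / "labels.csv")
    label_cols = [c for c in labels_frame.columns if c.startswith("P_")]
    curves = tuple(
        read_curve_csv(p) for p in sorted((directory / "curves").glob("curve_*.csv"))
    )
    return LabeledDataset(
        curves=curves,
        labels=labels_frame[label_cols].to_numpy(),
        seed=manifest["seed"],
        prior_spec=manifest["prior_spec"],
        lifetimes_ns=tuple(manifest["lifetimes_ns"]),
        instrument=instrument_from_dict(manifest["instrument"]),
    )


def load_config(path) -> dict:
    """Parse a YAML (or JSON) run configuration."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise FlimmixError(f"{path}: configuration must be a mapping")
    return data


def write_sweep_csv(result: SweepResult, path, grid_name: str = "grid_value") -> None:
    """Tidy CSV: one row per grid point x component x statistic."""
    rows = []
    for value, report in zip(result.grid, result.stats):
        frame = report.to_frame()
        frame.insert(0, grid_name, value)
        rows.append(frame)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def write_law_json(law: SpacingLaw, path) -> None:
    Path(path).write_text(law.to_json())
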