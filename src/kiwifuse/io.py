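"""On-disk conventions: PNG images and masks, long-format curve CSVs,
feature and record CSVs, YAML configs and JSON reports."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from kiwifuse.imgfeat import FEATURE_NAMES
from kiwifuse.synth import (
    DatasetConfig,
    EnoseSample,
    PHYSCHEM_ATTRIBUTES,
    SensorCurve,
)

__all__ = [
    "read_image", "write_image", "write_mask",
    "write_curves_csv", "read_curves_csv",
    "write_physchem_csv", "write_features_csv",
    "load_dataset_config", "write_dataset", "write_report",
]


def read_image(path) -> np.ndarray:
    """Read an 8-bit RGB PNG (alpha stripped if present)."""
    img = iio.imread(path)
    if img.ndim == 3 and img.shape[2] == 4:
        img = img[..., :3]
    return img


def write_image(path, image: np.ndarray) -> None:
    iio.imwrite(Path(path), np.asarray(image, dtype=np.uint8))


def write_mask(path, mask: np.ndarray) -> None:
    """Binary mask as single-channel 0/255 PNG."""
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def write_curves_csv(path, samples: dict) -> None:
    """Long-format curve CSV: sample_id, sensor_id, t_s, voltage.

    ``samples`` maps sample_id -> EnoseSample.
    """
    rows = []
    for sample_id, enose in samples.items():
        for curve in enose.curves:
            rows.append(pd.DataFrame({
                "sample_id": sample_id,
                "sensor_id": curve.sensor_id,
                "t_s": curve.times,
                "voltage": curve.voltages,
            }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_curves_csv(path) -> dict:
    """Inverse of :func:`write_curves_csv`: sample_id -> EnoseSample."""
    df = pd.read_csv(path)
    out = {}
    for sample_id, g in df.groupby("sample_id", sort=True):
        curves = []
        for sensor_id, gs in g.groupby("sensor_id", sort=False):
            gs = gs.sort_values("t_s")
            curves.append(SensorCurve(sensor_id=str(sensor_id),
                                      times=gs["t_s"].to_numpy(dtype=float),
                                      voltages=gs["voltage"].to_numpy(dtype=float)))
        out[str(sample_id)] = EnoseSample(curves=tuple(curves))
    return out


def write_physchem_csv(path, samples) -> None:
    """One row per sample: sample_id, region, then the 13 attributes."""
    rows = []
    for s in samples:
        row = {"sample_id": s.sample_id, "region": s.label.name}
        row.update(s.physchem.as_dict())
        rows.append(row)
    pd.DataFrame(rows, columns=["sample_id", "region", *PHYSCHEM_ATTRIBUTES]
                 ).to_csv(path, index=False)


def write_features_csv(path, sample_ids, matrix, names=None) -> None:
    """Feature table with one named column per feature."""
    matrix = np.atleast_2d(matrix)
    names = list(names) if names is not None else list(FEATURE_NAMES)
    df = pd.DataFrame(matrix, columns=names)
    df.insert(0, "sample_id", list(sample_ids))
    df.to_csv(path, index=False)


def load_dataset_config(path) -> DatasetConfig:
    """Load a YAML config whose keys mirror DatasetConfig fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return DatasetConfig(**raw)


def write_dataset(samples, out_dir) -> None:
    """Write a generated dataset: PNGs, truth masks, curves and records."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)
    for s in samples:
        write_image(out / "images" / f"{s.sample_id}_whole.png", s.whole_image)
        write_image(out / "images" / f"{s.sample_id}_cut.png", s.cut_image)
        for name in ("section", "outer", "core", "locule"):
            write_mask(out / "masks" / f"{s.sample_id}_{name}.png",
                       getattr(s.truth_masks, name))
    write_curves_csv(out / "enose_curves.csv",
                     {s.sample_id: s.enose for s in samples})
    write_physchem_csv(out / "physchem.csv", samples)


def write_report(report, out_dir) -> None:
    """Write report.json plus one CSV per report table."""
    out = Path(out_dir)
    tables = out / "tables"
    tables.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report.to_json())
    report.msr_summary.to_csv(tables / "msr_summary.csv")

    rows = []
    for (fs, target), stages in sorted(report.entries.items()):
        c, g = report.hyperparameters[(fs, target)]
        for stage, rep in sorted(stages.items()):
            rows.append({"feature_set": fs, "target": target, "stage": stage,
                         "c": c, "gamma": g, "rmse": rep.rmse,
                         "accuracy": rep.accuracy, "r_squared": rep.r_squared})
    pd.DataFrame(rows).to_csv(tables / "model_performance.csv", index=False)

    ev = pd.DataFrame({fs: pd.Series(v) for fs, v in
                       sorted(report.explained_variance.items())})
    ev.index = [f"PC{i + 1}" for i in range(len(ev))]
    ev.to_csv(tables / "explained_variance.csv")


def write_report_json(report, path) -> None:
    Path(path).write_text(report.to_json())


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def dumps(obj) -> str:
    return json.dumps(obj, indent=2, sort_keys=True, default=_json_default)
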