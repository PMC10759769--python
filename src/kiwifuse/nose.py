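"""E-nose signal preprocessing and maximum-sensor-response features.

Raw MOS sensor curves are normalized to fractional change over baseline,

    Ys(t) = (Xs(t) - Xs(0)) / Xs(0),

with the baseline Xs(0) estimated as the mean raw response over the last
10 s of the baseline phase (t in [110, 120] by default) — robust to sample
noise, and exactly the raw baseline for noiseless curves.  The single
feature kept per sensor is the maximum sensor response (MSR): the maximum
normalized value over the headspace window t in [121, 140] s (both
endpoints inclusive).  Thirteen sensors give a 13-element feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from kiwifuse.errors import InvalidSignalError

__all__ = [
    "NormalizedCurve",
    "EnoseFeatureVector",
    "BASELINE_WINDOW",
    "MSR_WINDOW",
    "normalize_curve",
    "compute_msr",
    "extract_enose_features",
    "region_msr_summary",
]

#: Window (s, inclusive) over which the raw baseline Xs(0) is estimated.
BASELINE_WINDOW = (110.0, 120.0)
#: Headspace window (s, inclusive) used for the MSR feature.
MSR_WINDOW = (121.0, 140.0)


@dataclass(frozen=True)
class NormalizedCurve:
    """Dimensionless normalized response Ys(t) of one sensor."""

    sensor_id: str
    times: np.ndarray
    values: np.ndarray


@dataclass(frozen=True)
class EnoseFeatureVector:
    """Ordered 13 MSR values, one per sensor."""

    sensor_ids: tuple
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if len(self.sensor_ids) != 13 or v.shape != (13,):
            raise ValueError("an e-nose feature vector has exactly 13 entries")
        if not np.all(np.isfinite(v)):
            raise ValueError("MSR features must be finite")

    def as_dict(self) -> dict:
        return dict(zip(self.sensor_ids, np.asarray(self.values, dtype=float)))


def normalize_curve(curve, baseline_window=BASELINE_WINDOW) -> NormalizedCurve:
    """Normalize one raw curve to fractional change over its baseline."""
    t = np.asarray(curve.times, dtype=float)
    x = np.asarray(curve.voltages, dtype=float)
    in_base = (t >= baseline_window[0]) & (t <= baseline_window[1])
    if not in_base.any():
        raise InvalidSignalError(
            f"{curve.sensor_id}: no samples in baseline window {baseline_window}")
    x0 = x[in_base].mean()
    if x0 <= 0:
        raise InvalidSignalError(
            f"{curve.sensor_id}: non-positive baseline estimate {x0!r}")
    return NormalizedCurve(sensor_id=curve.sensor_id, times=t,
                           values=(x - x0) / x0)


def compute_msr(norm: NormalizedCurve, window=MSR_WINDOW) -> float:
    """Maximum normalized response over the headspace window (inclusive)."""
    t = np.asarray(norm.times, dtype=float)
    in_win = (t >= window[0]) & (t <= window[1])
    if not in_win.any():
        raise ValueError(f"no samples in MSR window {window}")
    return float(np.asarray(norm.values, dtype=float)[in_win].max())


def extract_enose_features(sample) -> EnoseFeatureVector:
    """Normalize then take the MSR for each of the 13 sensors, in order."""
    ids = [c.sensor_id for c in sample.curves]
    if len(ids) != 13:
        raise ValueError(f"expected 13 curves, got {len(ids)}")
    if len(set(ids)) != 13:
        raise ValueError("duplicate sensor ids in e-nose sample")
    msr = []
    for curve in sample.curves:
        try:
            msr.append(compute_msr(normalize_curve(curve)))
        except (ValueError, InvalidSignalError) as err:
            raise type(err)(f"sensor {curve.sensor_id}: {err}") from err
    return EnoseFeatureVector(sensor_ids=tuple(ids),
                              values=np.asarray(msr, dtype=float))


def region_msr_summary(samples) -> pd.DataFrame:
    """Per-region mean MSR table (regions x 13 sensors), radar-plot ready.

    ``samples`` is an iterable of ``(label, EnoseFeatureVector)`` pairs;
    every region present in the label type must have at least one sample.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("no samples given")
    label_type = type(samples[0][0])
    rows = {}
    for region in label_type:
        vecs = [np.asarray(v.values, dtype=float)
                for lab, v in samples if lab == region]
        if not vecs:
            raise ValueError(f"no samples for region {region.name}")
        rows[region.name] = np.mean(vecs, axis=0)
    sensor_ids = samples[0][1].sensor_ids
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(sensor_ids))
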