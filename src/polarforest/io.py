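"""CSV and YAML interchange for measurements, features and configs.

Measurement CSV: one row per (point, state) with columns
``sample_id, slice_id, point_id, state, s0, s1, s2, s3``.

Feature CSV: one row per point with columns
``sample_id, slice_id, point_id, label, m12..m44`` (15 normalized elements).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

from .polarimetry import CLASS_LABELS, FEATURE_NAMES, STATE_NAMES, MeasurementSet
from .synthetic import ClassCounts, DatasetConfig, NoiseModel, default_config

__all__ = [
    "write_measurements_csv",
    "read_measurements_csv",
    "write_features_csv",
    "read_features_csv",
    "config_from_dict",
    "load_config",
]

_MEAS_COLUMNS = ["sample_id", "slice_id", "point_id", "state", "s0", "s1", "s2", "s3"]


def write_measurements_csv(measurements: Iterable[MeasurementSet], path) -> None:
    rows = []
    for ms in measurements:
        for state in STATE_NAMES:
            if state not in ms.outputs:
                continue
            s = ms.outputs[state]
            rows.append(
                {
                    "sample_id": ms.sample_id,
                    "slice_id": ms.slice_id,
                    "point_id": ms.point_id,
                    "state": state,
                    "s0": s[0], "s1": s[1], "s2": s[2], "s3": s[3],
                }
            )
    pd.DataFrame(rows, columns=_MEAS_COLUMNS).to_csv(path, index=False)


def read_measurements_csv(path) -> list[MeasurementSet]:
    """Group measurement rows by point; completeness is checked downstream."""
    df = pd.read_csv(path)
    missing = set(_MEAS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"measurement CSV lacks column(s): {sorted(missing)}")
    bad = set(df["state"]) - set(STATE_NAMES)
    if bad:
        raise ValueError(f"unknown polarization state(s): {sorted(bad)}")
    out = []
    for (sample, slc, pt), grp in df.groupby(["sample_id", "slice_id", "point_id"], sort=True):
        outputs = {
            r.state: [r.s0, r.s1, r.s2, r.s3] for r in grp.itertuples()
        }
        out.append(MeasurementSet(outputs, sample_id=str(sample), slice_id=int(slc), point_id=int(pt)))
    return out


def write_features_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_features_csv(path, labeled: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = set(FEATURE_NAMES) | ({"label"} if labeled else set())
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"feature CSV lacks column(s): {sorted(missing)}")
    return df


def config_from_dict(d: dict) -> DatasetConfig:
    """Build a DatasetConfig from a plain dict (YAML/JSON schema).

    Recognized keys: ``seed``, ``class_separation``, ``noise_scale`` and an
    optional ``counts`` mapping of class label to
    ``{train_vectors, test_vectors, train_samples, test_samples}``.
    Unknown top-level or class keys raise a validation error naming them.
    """
    known = {"seed", "class_separation", "noise_scale", "counts"}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown config field(s): {sorted(unknown)}")
    cfg = default_config(
        seed=int(d.get("seed", 0)),
        class_separation=float(d.get("class_separation", 1.0)),
    )
    if "noise_scale" in d:
        cfg.noise = NoiseModel().scaled(float(d["noise_scale"]))
    for label, c in (d.get("counts") or {}).items():
        if label not in CLASS_LABELS:
            raise ValueError(f"unknown class name in config counts: {label!r}")
        cfg.counts[label] = ClassCounts(**c)
    return cfg


def load_config(path) -> DatasetConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})
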