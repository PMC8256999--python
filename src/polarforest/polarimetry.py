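"""Stokes-Mueller polarimetry: forward propagation and six-state reconstruction.

A Stokes vector ``s = (s0, s1, s2, s3)`` describes a light beam's polarization
state (total intensity; horizontal/vertical, +-45 deg, and circular
polarization differences).  A sample's polarization transfer is a real 4x4
Mueller matrix ``M`` acting as ``s_out = M @ s_in``.

The measurement protocol probes the sample with six canonical input states --
four linear (0, 45, 90, 135 deg) and two circular (right- and left-handed) --
and recovers all 16 Mueller elements from sums and differences of the six
output Stokes vectors:

    column 1 = (S_0  + S_90)  / 2        column 2 = (S_0  - S_90)  / 2
    column 3 = (S_45 - S_135) / 2        column 4 = (S_RHC - S_LHC) / 2

where row ``k`` of each column is component ``k`` of the corresponding output
vector.  With noise-free measurements the reconstruction is exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "STATE_NAMES",
    "INPUT_STATES",
    "FEATURE_NAMES",
    "CLASS_LABELS",
    "MeasurementSet",
    "ReconstructionError",
    "apply_mueller",
    "measure_all_states",
    "reconstruct_mueller",
    "normalize_and_featurize",
    "degree_of_polarization",
    "check_physical",
]

#: The six canonical input polarization states, in protocol order.
STATE_NAMES: tuple[str, ...] = ("LIN0", "LIN45", "LIN90", "LIN135", "RHC", "LHC")

#: Input Stokes vectors for each state.  s3 > 0 is right-handed circular.
INPUT_STATES: dict[str, np.ndarray] = {
    "LIN0": np.array([1.0, 1.0, 0.0, 0.0]),
    "LIN45": np.array([1.0, 0.0, 1.0, 0.0]),
    "LIN90": np.array([1.0, -1.0, 0.0, 0.0]),
    "LIN135": np.array([1.0, 0.0, -1.0, 0.0]),
    "RHC": np.array([1.0, 0.0, 0.0, 1.0]),
    "LHC": np.array([1.0, 0.0, 0.0, -1.0]),
}

#: Canonical 15-feature order: row-major Mueller elements, m11 excluded
#: (m11 is consumed by normalization and carries no shape information).
FEATURE_NAMES: tuple[str, ...] = (
    "m12", "m13", "m14",
    "m21", "m22", "m23", "m24",
    "m31", "m32", "m33", "m34",
    "m41", "m42", "m43", "m44",
)

#: Tissue class labels in fixed report order.
CLASS_LABELS: tuple[str, ...] = ("BCC", "melanoma", "normal", "SCC")


class ReconstructionError(ValueError):
    """Raised when a measurement set cannot be turned into a Mueller matrix."""


@dataclass
class MeasurementSet:
    """The six output Stokes vectors measured at one sample point.

    Parameters
    ----------
    outputs
        Mapping from state name (see :data:`STATE_NAMES`) to the measured
        output Stokes 4-vector.
    sample_id, slice_id, point_id
        Provenance of the measurement point.
    """

    outputs: dict[str, np.ndarray]
    sample_id: str = ""
    slice_id: int = 0
    point_id: int = 0

    def __post_init__(self) -> None:
        self.outputs = {k: np.asarray(v, dtype=float) for k, v in self.outputs.items()}
        for name, vec in self.outputs.items():
            if vec.shape != (4,):
                raise ValueError(f"output for state {name!r} must be a 4-vector")

    def missing_states(self) -> list[str]:
        return [s for s in STATE_NAMES if s not in self.outputs]


def _as_matrix(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape != (4, 4):
        raise ValueError(f"Mueller matrix must be 4x4, got shape {m.shape}")
    return m


def apply_mueller(m: np.ndarray, s_in: np.ndarray) -> np.ndarray:
    """Propagate a Stokes vector through a Mueller matrix: ``M @ s``."""
    m = _as_matrix(m)
    s_in = np.asarray(s_in, dtype=float)
    if s_in.shape != (4,):
        raise ValueError(f"Stokes vector must have 4 components, got {s_in.shape}")
    return m @ s_in


def degree_of_polarization(s: np.ndarray) -> float:
    """sqrt(s1^2 + s2^2 + s3^2) / s0; physical beams have DoP <= 1."""
    s = np.asarray(s, dtype=float)
    if s[0] <= 0:
        raise ValueError("degree of polarization undefined for s0 <= 0")
    return float(np.sqrt(np.sum(s[1:] ** 2)) / s[0])


def measure_all_states(
    m: np.ndarray,
    noise=None,
    rng: np.random.Generator | int | None = None,
    sample_id: str = "",
    slice_id: int = 0,
    point_id: int = 0,
) -> MeasurementSet:
    """Simulate the six-state measurement protocol on a sample matrix.

    Each of the six canonical input states is propagated through ``m``.  If a
    noise model is given (see :class:`polarforest.synthetic.NoiseModel`), the
    measured outputs are perturbed by it; ``rng`` seeds the perturbation.
    """
    m = _as_matrix(m)
    outputs = {name: apply_mueller(m, s) for name, s in INPUT_STATES.items()}
    if noise is not None:
        rng = np.random.default_rng(rng)
        outputs = noise.perturb(outputs, rng)
    return MeasurementSet(outputs, sample_id=sample_id, slice_id=slice_id, point_id=point_id)


def reconstruct_mueller(ms: MeasurementSet | Mapping[str, np.ndarray]) -> np.ndarray:
    """Recover the 4x4 Mueller matrix from a six-state measurement set.

    Raises
    ------
    ReconstructionError
        If any of the six states is absent.
    """
    if not isinstance(ms, MeasurementSet):
        ms = MeasurementSet(dict(ms))
    missing = ms.missing_states()
    if missing:
        raise ReconstructionError(f"missing measurement state(s): {', '.join(missing)}")
    o = ms.outputs
    cols = [
        0.5 * (o["LIN0"] + o["LIN90"]),
        0.5 * (o["LIN0"] - o["LIN90"]),
        0.5 * (o["LIN45"] - o["LIN135"]),
        0.5 * (o["RHC"] - o["LHC"]),
    ]
    return np.column_stack(cols)


def check_physical(m: np.ndarray, bound: float = 1.0, tol: float = 1e-9) -> bool:
    """Warn (not raise) if a matrix exceeds the element-magnitude bound.

    Measured matrices may be slightly unphysical because of noise; they are
    flagged, never rejected.
    """
    m = _as_matrix(m)
    if m[0, 0] <= 0:
        warnings.warn("Mueller matrix has non-positive m11", stacklevel=2)
        return False
    if np.any(np.abs(m / m[0, 0]) > bound + tol):
        warnings.warn(
            "Mueller matrix has normalized elements exceeding the physical bound",
            stacklevel=2,
        )
        return False
    return True


def normalize_and_featurize(m: np.ndarray) -> np.ndarray:
    """Divide all elements by m11 and return the 15 remaining elements.

    The output follows :data:`FEATURE_NAMES` (row-major order, m11 dropped),
    so an identity matrix maps to ``[0,0,0, 0,1,0,0, 0,0,1,0, 0,0,0,1]``.

    Raises
    ------
    ValueError
        If ``m11 <= 0`` (an unphysical intensity gain or loss of signal).
    """
    m = _as_matrix(m)
    if m[0, 0] <= 0:
        raise ValueError(f"cannot normalize: m11 = {m[0, 0]} is not positive")
    flat = (m / m[0, 0]).ravel()
    return np.delete(flat, 0)


def featurize_measurements(measurements: Iterable[MeasurementSet]) -> "pd.DataFrame":
    """Reconstruct + normalize a stream of measurement sets into a feature table.

    Points with an incomplete state set are skipped with a warning.  Imported
    lazily through :mod:`polarforest.io` for CSV round trips.
    """
    import pandas as pd  # local import keeps numpy-only callers light

    rows = []
    skipped = 0
    for ms in measurements:
        try:
            feats = normalize_and_featurize(reconstruct_mueller(ms))
        except ReconstructionError as exc:
            warnings.warn(
                f"skipping point ({ms.sample_id}, {ms.slice_id}, {ms.point_id}): {exc}",
                stacklevel=2,
            )
            skipped += 1
            continue
        row = {"sample_id": ms.sample_id, "slice_id": ms.slice_id, "point_id": ms.point_id}
        row.update(dict(zip(FEATURE_NAMES, feats)))
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["skipped_points"] = skipped
    return df
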