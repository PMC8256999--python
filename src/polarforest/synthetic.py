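"""Class-conditional synthetic Mueller-matrix datasets.

Real measurements of the four skin tissue classes (BCC, SCC, melanoma,
normal) are not public, so this module generates labeled datasets with the
same statistical fingerprint the study design implies:

* hierarchical sampling -- per-sample optical parameters, perturbed per
  slice and again per measurement point (samples are cut into slices, each
  measured at several positions);
* element magnitudes of similar size across classes, with class-distinct
  parameter distributions;
* within-slice repeat-point standard deviations of 0.03-0.1 for elements
  m12, m13, m14, m21, m24 and m34, and below 0.01 for the rest;
* the reference train/test class counts 282/231/52/42 and 30/23/3/6
  (one held-out sample per class).

Class parameter means are artifact choices calibrated against those
variability bands and the similar-magnitude constraint; they carry no claim
of biological fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .optics import PARAM_NAMES, OpticalParams, compose_sample_matrix
from .polarimetry import (
    CLASS_LABELS,
    FEATURE_NAMES,
    measure_all_states,
    normalize_and_featurize,
    reconstruct_mueller,
)

__all__ = [
    "WIDE_ELEMENTS",
    "NARROW_ELEMENTS",
    "NoiseModel",
    "TissueClassSpec",
    "ClassCounts",
    "DatasetConfig",
    "default_config",
    "balanced_config",
    "generate_dataset",
    "calibrate_noise_bands",
    "NoiseBandReport",
]

#: Elements whose within-slice standard deviation is in the wide 0.03-0.1 band.
WIDE_ELEMENTS: tuple[str, ...] = ("m12", "m13", "m14", "m21", "m24", "m34")
#: Remaining (normalized) elements; within-slice standard deviation < 0.01.
NARROW_ELEMENTS: tuple[str, ...] = tuple(f for f in FEATURE_NAMES if f not in WIDE_ELEMENTS)


def _default_sigma() -> np.ndarray:
    """Per-element measurement-noise sigmas (4x4, indexed like the matrix)."""
    sigma = np.full((4, 4), 0.004)
    sigma[0, 0] = 0.003
    wide = {"m12": 0.055, "m13": 0.050, "m14": 0.065, "m21": 0.060, "m24": 0.075, "m34": 0.050}
    for name, s in wide.items():
        i, j = int(name[1]) - 1, int(name[2]) - 1
        sigma[i, j] = s
    return sigma


@dataclass
class NoiseModel:
    """Measurement noise for the six-state protocol.

    The perturbation is applied to the measured output Stokes vectors, before
    reconstruction.  For each input-state pair feeding one reconstructed
    column (LIN0/LIN90, LIN45/LIN135, RHC/LHC) the two outputs receive a
    *common-mode* and a *differential* Gaussian perturbation per component.
    The reconstruction turns the common mode of the LIN0/LIN90 pair into
    column-1 noise and the differential modes into column 2-4 noise, so the
    matrix ``sigma[i, j]`` is exactly the standard deviation induced on
    reconstructed element ``m(i+1)(j+1)``.

    A simple independent per-component noise cannot reproduce the reported
    variability pattern: m21 and m22 are the sum and difference of the same
    two raw measurements, so independent noise would give them equal
    variance, whereas the wide band contains m21 but not m22.  The
    common/differential structure (shared drift vs. state-dependent error
    between the paired acquisitions) decouples them.
    """

    sigma: np.ndarray = field(default_factory=_default_sigma)

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.sigma.shape != (4, 4):
            raise ValueError("sigma must be a 4x4 array of element noise levels")
        if np.any(self.sigma < 0):
            raise ValueError("noise sigmas must be >= 0")

    def scaled(self, factor: float) -> "NoiseModel":
        return NoiseModel(self.sigma * factor)

    def perturb(self, outputs: dict[str, np.ndarray], rng: np.random.Generator) -> dict[str, np.ndarray]:
        eps = rng.normal(size=(4, 4)) * self.sigma
        out = {k: v.copy() for k, v in outputs.items()}
        # column 1 noise = common mode of the LIN0/LIN90 pair,
        # column 2 noise = differential of the same pair
        out["LIN0"] += eps[:, 0] + eps[:, 1]
        out["LIN90"] += eps[:, 0] - eps[:, 1]
        out["LIN45"] += eps[:, 2]
        out["LIN135"] -= eps[:, 2]
        out["RHC"] += eps[:, 3]
        out["LHC"] -= eps[:, 3]
        return out


#: Per-parameter spread scale used at every level of the hierarchy
#: (multiplied by the level factors in :class:`TissueClassSpec`).
_BASE_SPREAD = np.array(
    [0.03, 0.08, 0.03, 0.10, 0.08, 0.05, 0.04, 0.04, 0.04]
)  # d, theta_d, cd, delta, theta_r, psi, a, b, c


@dataclass
class TissueClassSpec:
    """Mean optical parameters of one tissue class and its spread hierarchy."""

    label: str
    mean: OpticalParams
    sample_scale: float = 0.5
    slice_scale: float = 0.4
    point_scale: float = 0.05
    spread: np.ndarray = field(default_factory=lambda: _BASE_SPREAD.copy())

    def __post_init__(self) -> None:
        self.spread = np.asarray(self.spread, dtype=float)
        if self.spread.shape != (len(PARAM_NAMES),):
            raise ValueError("spread must give one scale per optical parameter")


def _default_class_means() -> dict[str, OpticalParams]:
    # Each class is dominated by a different optical effect so the class
    # means are not collinear in parameter space: normal = weak everything,
    # BCC = strong linear retardance, SCC = strong diattenuation at a
    # rotated axis, melanoma = strong depolarization + circular effects.
    return {
        "normal": OpticalParams(d=0.08, theta_d=0.30, cd=0.04, delta=0.50,
                                theta_r=0.30, psi=0.05, a=0.88, b=0.84, c=0.75),
        "BCC": OpticalParams(d=0.15, theta_d=0.90, cd=0.06, delta=1.30,
                             theta_r=0.50, psi=0.10, a=0.74, b=0.70, c=0.60),
        "SCC": OpticalParams(d=0.30, theta_d=0.35, cd=0.12, delta=0.80,
                             theta_r=0.90, psi=0.28, a=0.70, b=0.62, c=0.46),
        "melanoma": OpticalParams(d=0.20, theta_d=0.60, cd=0.30, delta=1.00,
                                  theta_r=0.70, psi=0.40, a=0.55, b=0.48, c=0.30),
    }


@dataclass
class ClassCounts:
    """How many feature vectors and physical samples one class contributes."""

    train_vectors: int
    test_vectors: int
    train_samples: int
    test_samples: int = 1

    def __post_init__(self) -> None:
        for name in ("train_vectors", "test_vectors", "train_samples", "test_samples"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.train_vectors < self.train_samples or self.test_vectors < self.test_samples:
            raise ValueError("cannot allocate fewer vectors than samples")


# Reference per-class counts: (train vectors, test vectors, train samples).
_TABLE_COUNTS = {
    "BCC": ClassCounts(282, 30, 11),
    "SCC": ClassCounts(231, 23, 11),
    "melanoma": ClassCounts(52, 3, 3),
    "normal": ClassCounts(42, 6, 3),
}


@dataclass
class DatasetConfig:
    """Full recipe for one synthetic train/test dataset."""

    class_specs: dict[str, TissueClassSpec]
    counts: dict[str, ClassCounts]
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.class_specs) != set(CLASS_LABELS):
            raise ValueError(
                f"class_specs must cover exactly {sorted(CLASS_LABELS)}, "
                f"got {sorted(self.class_specs)}"
            )
        if set(self.counts) != set(CLASS_LABELS):
            raise ValueError(
                f"counts must cover exactly {sorted(CLASS_LABELS)}, "
                f"got {sorted(self.counts)}"
            )


def _separated_specs(class_separation: float) -> dict[str, TissueClassSpec]:
    """Class specs with means pulled toward the pooled mean by the dial.

    ``class_separation = 1`` keeps the default class means;
    ``class_separation = 0`` collapses all classes onto the pooled mean, so a
    classifier can do no better than chance.
    """
    means = _default_class_means()
    pooled = np.mean([m.to_array() for m in means.values()], axis=0)
    specs = {}
    for label, m in means.items():
        arr = pooled + class_separation * (m.to_array() - pooled)
        specs[label] = TissueClassSpec(label=label, mean=OpticalParams.from_array(arr))
    return specs


def default_config(seed: int = 0, class_separation: float = 1.0) -> DatasetConfig:
    """The shipped default: reference class counts, calibrated noise bands."""
    return DatasetConfig(
        class_specs=_separated_specs(class_separation),
        counts={k: replace(v) for k, v in _TABLE_COUNTS.items()},
        noise=NoiseModel(),
        seed=seed,
    )


def balanced_config(
    seed: int = 0,
    class_separation: float = 1.0,
    train_samples: int = 6,
    test_samples: int = 24,
    points_per_sample: int = 25,
    test_points_per_sample: int = 6,
) -> DatasetConfig:
    """A diagnostic config with many held-out samples per class.

    With only one held-out sample per class (the reference design), test
    predictions are strongly correlated within each sample, so chance-level
    accuracy has huge sampling variance.  Diagnostics that need a stable
    accuracy estimate (e.g. the zero-separation chance check) use this
    layout instead.
    """
    counts = {
        label: ClassCounts(
            train_vectors=train_samples * points_per_sample,
            test_vectors=test_samples * test_points_per_sample,
            train_samples=train_samples,
            test_samples=test_samples,
        )
        for label in CLASS_LABELS
    }
    return DatasetConfig(
        class_specs=_separated_specs(class_separation),
        counts=counts,
        noise=NoiseModel(),
        seed=seed,
    )


def _allocate(total: int, n_parts: int) -> list[int]:
    """Split ``total`` into ``n_parts`` near-equal positive integers."""
    base, rem = divmod(total, n_parts)
    return [base + 1] * rem + [base] * (n_parts - rem)


def _sample_structure(total_points: int) -> list[int]:
    """Points per slice for a sample with ``total_points`` measurements.

    Prefers the 4-6 slices x 4-6 points design; small held-out samples fall
    back to fewer/smaller slices so class totals are matched exactly.
    """
    n_slices = int(np.clip(round(total_points / 5), 1, 6))
    n_slices = max(n_slices, -(-total_points // 6))  # keep points per slice <= 6
    n_slices = min(n_slices, total_points)
    return _allocate(total_points, n_slices)


def _generate_class_split(
    spec: TissueClassSpec,
    n_vectors: int,
    n_samples: int,
    noise: NoiseModel | None,
    rng: np.random.Generator,
    split: str,
) -> list[dict]:
    rows = []
    mean = spec.mean.to_array()
    for s_idx, sample_total in enumerate(_allocate(n_vectors, n_samples), start=1):
        sample_id = f"{spec.label}_{split}_{s_idx:02d}"
        p_sample = mean + spec.sample_scale * spec.spread * rng.normal(size=mean.size)
        for sl_idx, n_points in enumerate(_sample_structure(sample_total), start=1):
            p_slice = p_sample + spec.slice_scale * spec.spread * rng.normal(size=mean.size)
            for pt_idx in range(1, n_points + 1):
                p_point = p_slice + spec.point_scale * spec.spread * rng.normal(size=mean.size)
                m = compose_sample_matrix(OpticalParams.from_array(p_point))
                ms = measure_all_states(
                    m, noise=noise, rng=rng,
                    sample_id=sample_id, slice_id=sl_idx, point_id=pt_idx,
                )
                feats = normalize_and_featurize(reconstruct_mueller(ms))
                row = {
                    "sample_id": sample_id,
                    "slice_id": sl_idx,
                    "point_id": pt_idx,
                    "label": spec.label,
                }
                row.update(dict(zip(FEATURE_NAMES, feats)))
                rows.append(row)
    return rows


def generate_dataset(cfg: DatasetConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the labeled train and test feature tables.

    The split is by physical sample: held-out samples are drawn
    independently of the training samples of their class.  Deterministic
    under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    train_rows: list[dict] = []
    test_rows: list[dict] = []
    for label in CLASS_LABELS:  # fixed order => reproducible draws
        spec = cfg.class_specs[label]
        counts = cfg.counts[label]
        train_rows += _generate_class_split(
            spec, counts.train_vectors, counts.train_samples, cfg.noise, rng, "train"
        )
        test_rows += _generate_class_split(
            spec, counts.test_vectors, counts.test_samples, cfg.noise, rng, "test"
        )
    columns = ["sample_id", "slice_id", "point_id", "label", *FEATURE_NAMES]
    return (
        pd.DataFrame(train_rows, columns=columns),
        pd.DataFrame(test_rows, columns=columns),
    )


@dataclass
class NoiseBandReport:
    """Within-slice variability of each element versus its target band."""

    element_std: dict[str, float]
    wide_band: tuple[float, float] = (0.03, 0.10)
    narrow_limit: float = 0.01

    @property
    def wide_ok(self) -> bool:
        lo, hi = self.wide_band
        return all(lo <= self.element_std[e] <= hi for e in WIDE_ELEMENTS)

    @property
    def narrow_ok(self) -> bool:
        return all(self.element_std[e] < self.narrow_limit for e in NARROW_ELEMENTS)

    @property
    def passed(self) -> bool:
        return self.wide_ok and self.narrow_ok

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for e in FEATURE_NAMES:
            wide = e in WIDE_ELEMENTS
            lo, hi = self.wide_band if wide else (0.0, self.narrow_limit)
            v = self.element_std[e]
            rows.append(
                {"element": e, "within_slice_std": v, "band": "wide" if wide else "narrow",
                 "lo": lo, "hi": hi, "ok": lo <= v <= hi if wide else v < hi}
            )
        return pd.DataFrame(rows)


def calibrate_noise_bands(dataset: pd.DataFrame) -> NoiseBandReport:
    """Mean over slices of the within-slice standard deviation, per element.

    Slices are (sample_id, slice_id) groups; each must hold at least two
    repeat points for its standard deviation to be defined.
    """
    groups = dataset.groupby(["sample_id", "slice_id"], sort=True)
    sizes = groups.size()
    if (sizes < 2).any():
        bad = sizes[sizes < 2].index.tolist()
        raise ValueError(f"slices with fewer than 2 repeat points: {bad[:5]}")
    stds = groups[list(FEATURE_NAMES)].std(ddof=1).mean(axis=0)
    return NoiseBandReport(element_std={e: float(stds[e]) for e in FEATURE_NAMES})
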