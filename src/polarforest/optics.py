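"""Mueller matrices of the standard polarization building blocks.

Skin tissue exhibits five elementary polarization effects: linear and
circular dichroism (diattenuation), linear and circular birefringence
(retardance and optical rotation), and depolarization.  A synthetic sample
matrix is composed from the three canonical blocks

    M = M_depolarizer @ M_retarder @ M_diattenuator

with all m11 fixed at 1 (intensity units are arbitrary and the feature
pipeline normalizes by m11 anyway).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OpticalParams",
    "build_diattenuator",
    "build_retarder",
    "build_depolarizer",
    "compose_sample_matrix",
]

# Parameter vector layout used for hierarchical perturbations.
PARAM_NAMES = ("d", "theta_d", "cd", "delta", "theta_r", "psi", "a", "b", "c")


@dataclass(frozen=True)
class OpticalParams:
    """Elementary polarization parameters of one synthetic sample.

    Attributes
    ----------
    d : float
        Linear diattenuation magnitude, in [0, 1].
    theta_d : float
        Diattenuation orientation, radians.
    cd : float
        Circular diattenuation, in (-1, 1); sqrt(d^2 + cd^2) <= 1.
    delta : float
        Linear retardance, radians.
    theta_r : float
        Retarder fast-axis angle, radians.
    psi : float
        Optical rotation (circular birefringence), radians.
    a, b, c : float
        Depolarization diagonal in (0, 1]; 1 = no depolarization.
    """

    d: float = 0.0
    theta_d: float = 0.0
    cd: float = 0.0
    delta: float = 0.0
    theta_r: float = 0.0
    psi: float = 0.0
    a: float = 1.0
    b: float = 1.0
    c: float = 1.0

    def __post_init__(self) -> None:
        _validate_diattenuation(self.d, self.cd)
        for name in ("a", "b", "c"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"depolarization {name}={v} outside (0, 1]")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray, clip: bool = True) -> "OpticalParams":
        """Build params from a 9-vector, optionally clipping into valid ranges.

        Clipping keeps hierarchically perturbed parameter draws physical.
        """
        vals = dict(zip(PARAM_NAMES, np.asarray(arr, dtype=float)))
        if clip:
            vals["d"] = float(np.clip(vals["d"], 0.0, 0.99))
            vals["cd"] = float(np.clip(vals["cd"], -0.99, 0.99))
            # joint diattenuation vector must stay inside the unit ball
            norm = np.hypot(vals["d"], vals["cd"])
            if norm > 0.99:
                vals["d"] *= 0.99 / norm
                vals["cd"] *= 0.99 / norm
            for k in ("a", "b", "c"):
                vals[k] = float(np.clip(vals[k], 1e-3, 1.0))
        return cls(**vals)


def _validate_diattenuation(d: float, cd: float) -> None:
    if not 0.0 <= d <= 1.0:
        raise ValueError(f"linear diattenuation d={d} outside [0, 1]")
    if not -1.0 <= cd <= 1.0:
        raise ValueError(f"circular diattenuation cd={cd} outside [-1, 1]")
    if np.hypot(d, cd) > 1.0 + 1e-12:
        raise ValueError(f"diattenuation vector |(d, cd)|={np.hypot(d, cd):.4f} exceeds 1")


def build_diattenuator(d: float, theta_d: float = 0.0, cd: float = 0.0) -> np.ndarray:
    """Mueller diattenuator with linear part ``d`` at ``theta_d`` plus circular ``cd``.

    Uses the standard polar form with the diattenuation vector
    ``D = (d cos 2t, d sin 2t, cd)`` and unit m11:

        M = [[1, D^T], [D, sqrt(1-|D|^2) I + (1 - sqrt(1-|D|^2)) DD^T/|D|^2]]

    ``d = cd = 0`` gives the identity; ``d = 1`` the ideal (rank-deficient)
    polarizer.
    """
    _validate_diattenuation(d, cd)
    dvec = np.array([d * np.cos(2 * theta_d), d * np.sin(2 * theta_d), cd])
    dn = np.linalg.norm(dvec)
    m = np.eye(4)
    m[0, 1:] = dvec
    m[1:, 0] = dvec
    if dn > 0:
        root = np.sqrt(max(0.0, 1.0 - dn**2))
        dhat = dvec / dn
        m[1:, 1:] = root * np.eye(3) + (1.0 - root) * np.outer(dhat, dhat)
    return m


def build_retarder(delta: float, theta_r: float = 0.0, psi: float = 0.0) -> np.ndarray:
    """Linear retarder (retardance ``delta``, fast axis ``theta_r``) followed by
    an optical rotator of angle ``psi``.

    The lower-right 3x3 block is a proper rotation (orthogonal, det = 1);
    first row and column are [1, 0, 0, 0].
    """
    c2, s2 = np.cos(2 * theta_r), np.sin(2 * theta_r)
    cd, sd = np.cos(delta), np.sin(delta)
    linear = np.array(
        [
            [1, 0, 0, 0],
            [0, c2**2 + s2**2 * cd, s2 * c2 * (1 - cd), -s2 * sd],
            [0, s2 * c2 * (1 - cd), s2**2 + c2**2 * cd, c2 * sd],
            [0, s2 * sd, -c2 * sd, cd],
        ]
    )
    cp, sp = np.cos(2 * psi), np.sin(2 * psi)
    rotator = np.array(
        [
            [1, 0, 0, 0],
            [0, cp, sp, 0],
            [0, -sp, cp, 0],
            [0, 0, 0, 1],
        ]
    )
    return rotator @ linear


def build_depolarizer(a: float, b: float, c: float) -> np.ndarray:
    """Diagonal depolarizer diag(1, a, b, c) with a, b, c in (0, 1]."""
    for name, v in (("a", a), ("b", b), ("c", c)):
        if not 0.0 < v <= 1.0:
            raise ValueError(f"depolarization {name}={v} outside (0, 1]")
    return np.diag([1.0, a, b, c])


def compose_sample_matrix(p: OpticalParams) -> np.ndarray:
    """Sample Mueller matrix: depolarizer @ retarder @ diattenuator.

    All-neutral parameters give the identity; m11 of the product is always 1.
    """
    return (
        build_depolarizer(p.a, p.b, p.c)
        @ build_retarder(p.delta, p.theta_r, p.psi)
        @ build_diattenuator(p.d, p.theta_d, p.cd)
    )
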