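"""Water-coordination descriptors {L_i, V_i} and geometric CVs.

Two families of smooth water counts feed the discriminant CV:

* ``L_i`` — coordination of water oxygens around points on the ligand,
  describing the ligand solvation shell;
* ``V_i`` — coordination around points fixed at regular intervals along the
  host axis, describing the water arrangement inside and outside the binding
  pocket with no reference to the ligand.

Counts use the rational switching function common in enhanced sampling,

    f(r) = (1 - (r/r0)^n) / (1 - (r/r0)^m),   m > n even,

which is smooth, equals 1 at r=0 and decays to 0; the removable singularity
at r = r0 has limit n/m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .frames import Frame


@dataclass(frozen=True)
class SwitchingParams:
    """Rational switching function parameters (r0 in nm; n, m even, m > n)."""

    r0: float = 0.35
    n_exp: int = 6
    m_exp: int = 12

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")
        if self.n_exp % 2 or self.m_exp % 2 or self.m_exp <= self.n_exp:
            raise ValueError("need even exponents with m_exp > n_exp")


@dataclass(frozen=True)
class AxisSpec:
    """Host axis: origin plus unit direction; grid of descriptor points.

    ``V_1`` sits deepest in the cavity: the grid starts at
    ``origin + z_start*direction`` (z_start most negative) and advances by
    ``spacing`` towards the solvent.
    """

    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    n_points: int = 8
    spacing: float = 0.2
    z_start: float = -0.7

    def points(self) -> np.ndarray:
        o = np.asarray(self.origin, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        d = d / np.linalg.norm(d)
        k = np.arange(self.n_points)
        return o + (self.z_start + k * self.spacing)[:, None] * d


def switching(r, p: SwitchingParams = SwitchingParams()):
    """Smooth count weight in [0,1], non-increasing in r, continuous at r=r0."""
    r = np.asarray(r, dtype=float)
    scalar = r.ndim == 0
    x = np.atleast_1d(r / p.r0)
    with np.errstate(divide="ignore", invalid="ignore"):
        val = (1.0 - x**p.n_exp) / (1.0 - x**p.m_exp)
    # removable singularity at x=1: (1-x^n)/(1-x^m) = sum_{k<n} x^k / sum_{k<m} x^k
    near = np.abs(x - 1.0) < 1e-6
    if np.any(near):
        xs = x[near]
        num = sum(xs**k for k in range(p.n_exp))
        den = sum(xs**k for k in range(p.m_exp))
        val[near] = num / den
    out = np.clip(val, 0.0, 1.0)
    return float(out[0]) if scalar else out


def coordination(center, oxygens, p: SwitchingParams = SwitchingParams()) -> float:
    """Smooth number of water oxygens around ``center``."""
    oxygens = np.atleast_2d(np.asarray(oxygens, dtype=float))
    if oxygens.size == 0:
        return 0.0
    r = np.linalg.norm(oxygens - np.asarray(center, dtype=float), axis=1)
    return float(np.sum(switching(r, p)))


def ligand_descriptors(
    frame: Frame,
    ligand_label: str = "LG",
    p: SwitchingParams = SwitchingParams(),
) -> np.ndarray:
    """L vector: one water coordination number per ligand bead, frame order."""
    pts = frame.select({ligand_label})
    if len(pts) == 0:
        raise ValueError(f"no ligand beads labelled {ligand_label!r} in frame")
    ox = frame.water_oxygens
    return np.array([coordination(c, ox, p) for c in pts])


def axis_descriptors(
    frame: Frame,
    axis: AxisSpec | None = None,
    p: SwitchingParams = SwitchingParams(),
) -> np.ndarray:
    """V vector: water coordination at the fixed host-axis grid points."""
    if axis is None:
        axis = AxisSpec(
            origin=tuple(frame.axis_origin), direction=tuple(frame.axis_direction)
        )
    if axis.n_points < 2:
        raise ValueError("axis grid needs at least 2 points")
    ox = frame.water_oxygens
    return np.array([coordination(c, ox, p) for c in axis.points()])


def geometry_cvs(
    frame: Frame,
    axis: AxisSpec | None = None,
    ligand_label: str = "LG",
) -> tuple[float, float]:
    """(s_z, cos theta): signed axial projection of the ligand centre of mass,
    and cosine of the angle between the ligand axis (first to last bead) and
    the host axis."""
    if axis is None:
        origin, direction = frame.axis_origin, frame.axis_direction
    else:
        origin = np.asarray(axis.origin, dtype=float)
        direction = np.asarray(axis.direction, dtype=float)
        direction = direction / np.linalg.norm(direction)
    lig = frame.select({ligand_label})
    if len(lig) < 2:
        raise ValueError("ligand needs at least 2 beads to define an orientation")
    com = lig.mean(axis=0)
    s_z = float((com - origin) @ direction)
    lig_axis = lig[-1] - lig[0]
    norm = np.linalg.norm(lig_axis)
    if norm == 0:
        raise ValueError("zero-length ligand axis")
    cos_theta = float(lig_axis @ direction / norm)
    return s_z, cos_theta


def descriptor_table(
    frames: list[Frame],
    axis: AxisSpec | None = None,
    ligand_label: str = "LG",
    p: SwitchingParams = SwitchingParams(),
    dt: float = 1.0,
) -> pd.DataFrame:
    """One row per frame: time, L_1..L_nL, V_1..V_nV, s_z, cos_theta."""
    rows = []
    for i, fr in enumerate(frames):
        L = ligand_descriptors(fr, ligand_label, p)
        V = axis_descriptors(fr, axis, p)
        s_z, cos_theta = geometry_cvs(fr, axis, ligand_label)
        rows.append([i * dt, *L, *V, s_z, cos_theta])
    nL = len(ligand_descriptors(frames[0], ligand_label, p)) if frames else 0
    nV = len(axis_descriptors(frames[0], axis, p)) if frames else 0
    cols = (
        ["time"]
        + [f"L_{i + 1}" for i in range(nL)]
        + [f"V_{i + 1}" for i in range(nV)]
        + ["s_z", "cos_theta"]
    )
    return pd.DataFrame(rows, columns=cols)
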