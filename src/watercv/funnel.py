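"""Funnel-shaped restraint and the standard-state entropic correction.

The restraint confines the unbound ligand inside a cone (near the binding
site) that switches to a cylinder of radius R_cyl beyond z_cc along the host
axis. It costs nothing strictly inside the allowed surface and grows as a
one-sided harmonic wall outside, so the bound-basin statistics are untouched
while the unbound ligand cannot wander off and is funnelled back to the
entrance.

Because the cylinder restricts the unbound state to an area pi*R_cyl^2
instead of the standard-state volume per molecule 1/C0, the binding constant
is K = C0 * pi * R_cyl^2 * integral_bound exp(-beta(F(z) - F_U)) dz and the
area factor enters Delta G as -kT * ln(C0 * pi * R_cyl^2 * 1 nm); the
remaining length scale lives in the explicit z-integral (see
:func:`watercv.fes.delta_g_standard`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .units import STANDARD_CONC_NM3, ThermoParams


@dataclass(frozen=True)
class FunnelGeometry:
    """Cone + cylinder wall around the host axis (lengths nm)."""

    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    z_cc: float = 0.5  # cone-to-cylinder switch along the axis
    r_cyl: float = 0.2  # cylinder radius
    wall_slope: float = 1.0  # cone wall dR/dz (radius grows towards the site)
    k_wall: float = 1000.0  # kcal/mol/nm^2
    z_max: float = 2.0  # outer axial wall

    def __post_init__(self) -> None:
        if self.r_cyl <= 0:
            raise ValueError("r_cyl must be positive")
        if self.z_cc >= self.z_max:
            raise ValueError("z_cc must lie below z_max")

    def allowed_radius(self, z: float) -> float:
        """Wall radius at axial position z: cone below z_cc, cylinder above."""
        if z >= self.z_cc:
            return self.r_cyl
        return self.r_cyl + self.wall_slope * (self.z_cc - z)

    def energy_and_gradient(self, position: np.ndarray) -> tuple[float, np.ndarray]:
        """Restraint energy and its gradient at a 3-D point.

        Continuous and once-differentiable at the wall (one-sided harmonic).
        """
        p = np.asarray(position, dtype=float)
        o = np.asarray(self.origin, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        d = d / np.linalg.norm(d)
        rel = p - o
        z = float(rel @ d)
        radial_vec = rel - z * d
        r = float(np.linalg.norm(radial_vec))
        e = 0.0
        grad = np.zeros(3)
        r_allow = self.allowed_radius(z)
        if r > r_allow:
            over = r - r_allow
            e += 0.5 * self.k_wall * over**2
            r_hat = radial_vec / r
            grad += self.k_wall * over * r_hat
            if z < self.z_cc:
                # cone wall: allowed radius depends on z
                grad += self.k_wall * over * self.wall_slope * d
        if z > self.z_max:
            over = z - self.z_max
            e += 0.5 * self.k_wall * over**2
            grad += self.k_wall * over * d
        return e, grad

    def energy(self, position: np.ndarray) -> float:
        return self.energy_and_gradient(position)[0]


@dataclass(frozen=True)
class AxialFunnel1D:
    """Axial outer wall for dynamics whose first coordinate is z itself.

    The 2-DOF toy landscape has no radial coordinate, so only the outer wall
    of the funnel acts; it keeps the unbound coordinate from drifting away.
    """

    z_max: float = 2.0
    z_min: float | None = None
    k_wall: float = 1000.0

    def energy_and_gradient(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        z = float(x[0])
        e, gz = 0.0, 0.0
        if z > self.z_max:
            e = 0.5 * self.k_wall * (z - self.z_max) ** 2
            gz = self.k_wall * (z - self.z_max)
        elif self.z_min is not None and z < self.z_min:
            e = 0.5 * self.k_wall * (z - self.z_min) ** 2
            gz = self.k_wall * (z - self.z_min)
        g = np.zeros_like(np.asarray(x, dtype=float))
        g[0] = gz
        return e, g


def funnel_correction(
    r_cyl: float,
    thermo: ThermoParams,
    standard_conc: float = STANDARD_CONC_NM3,
) -> float:
    """Area part of the standard-state correction, -kT*ln(C0*pi*R^2*1nm).

    kcal/mol; the 1 nm factor makes the logarithm's argument dimensionless,
    with the axial length scale carried explicitly by the Delta G integral.
    """
    if r_cyl <= 0:
        raise ValueError("r_cyl must be positive")
    return -thermo.kT * math.log(standard_conc * math.pi * r_cyl**2 * 1.0)
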