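"""Free-energy surfaces from reweighted samples, block errors, binding
free energies with the funnel correction, replica combination, benchmark
metrics and cylindrical water-density maps.

A biased run is reweighted with the umbrella-sampling-like weights
w = e^{beta*V} (V the bias at sampling time); the FES is
FES(s) = -kT log P(s), min-shifted to zero. Binding free energies follow

    Delta G = -kT * ln( C0 * pi * R_cyl^2 *
                        integral_bound e^{-beta (F(z) - F_U)} dz ),

with F_U the mean FES over the unbound window inside the funnel cylinder;
the C0*pi*R_cyl^2 factor undoes the funnel's volume restriction and sets the
1 mol/L standard state. Statistical errors come from block averages, and
replicas (e.g. independently trained CVs) combine by inverse-variance
weighting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .funnel import FunnelGeometry
from .units import STANDARD_CONC_NM3, ThermoParams


@dataclass
class FESCurve:
    """Gridded free energy along one CV, min-shifted to 0, with block errors.

    ``values`` is NaN-masked where the bin was never visited.
    """

    grid: np.ndarray  # bin centers
    values: np.ndarray
    errors: np.ndarray | None = None

    def shift_to_zero(self) -> "FESCurve":
        vmin = np.nanmin(self.values)
        return FESCurve(self.grid, self.values - vmin, self.errors)


@dataclass
class BindingResult:
    """Per-replica and combined binding free energy, kcal/mol."""

    delta_g: float
    error: float
    funnel_corrected: bool = True


def reweight_weights(bias_energy: np.ndarray, thermo: ThermoParams) -> np.ndarray:
    """Statistical weights e^{beta*V}, stabilised by subtracting max(V)."""
    v = np.asarray(bias_energy, dtype=float)
    return np.exp(thermo.beta * (v - v.max()))


def reweight_histogram(
    samples: np.ndarray,
    weights: np.ndarray,
    bin_edges: np.ndarray,
) -> np.ndarray:
    """Weighted probability per bin; sums to 1 over the grid.

    Raises if no sample falls in range.
    """
    samples = np.asarray(samples, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights <= 0) or not np.all(np.isfinite(weights)):
        raise ValueError("weights must be positive and finite")
    hist, _ = np.histogram(samples, bins=bin_edges, weights=weights)
    total = hist.sum()
    if total == 0:
        raise ValueError("no samples fall inside the histogram range")
    return hist / total


def fes_from_prob(prob: np.ndarray, grid: np.ndarray, thermo: ThermoParams) -> FESCurve:
    """FES = -kT log P, min-shifted to 0; empty bins masked as NaN."""
    prob = np.asarray(prob, dtype=float)
    with np.errstate(divide="ignore"):
        f = np.where(prob > 0, -thermo.kT * np.log(np.where(prob > 0, prob, 1.0)), np.nan)
    return FESCurve(np.asarray(grid, dtype=float), f, None).shift_to_zero()


def block_error(
    samples: np.ndarray,
    weights: np.ndarray | None,
    statistic,
    n_blocks: int = 5,
) -> float:
    """Standard error of a (weighted) statistic over contiguous blocks.

    ``statistic(samples_block, weights_block) -> float``; the trailing
    remainder of the series is dropped. Requires n_blocks >= 2 and at least
    one sample per block.
    """
    samples = np.asarray(samples)
    n = len(samples)
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    if n < n_blocks:
        raise ValueError(f"series of length {n} cannot fill {n_blocks} blocks")
    size = n // n_blocks
    if weights is None:
        weights = np.ones(n)
    vals = []
    for b in range(n_blocks):
        sl = slice(b * size, (b + 1) * size)
        vals.append(statistic(samples[sl], weights[sl]))
    vals = np.asarray(vals, dtype=float)
    return float(vals.std(ddof=1) / math.sqrt(n_blocks))


def fes_with_errors(
    samples: np.ndarray,
    weights: np.ndarray,
    bin_edges: np.ndarray,
    thermo: ThermoParams,
    n_blocks: int = 5,
) -> FESCurve:
    """Reweighted FES with per-bin block-average errors.

    The error of each bin is the standard error of its per-block free energy
    over contiguous blocks (blocks with an empty bin are excluded for that
    bin).
    """
    prob = reweight_histogram(samples, weights, bin_edges)
    grid = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    fes = fes_from_prob(prob, grid, thermo)
    n = len(samples)
    size = n // n_blocks
    block_f = np.full((n_blocks, len(grid)), np.nan)
    for b in range(n_blocks):
        sl = slice(b * size, (b + 1) * size)
        hist, _ = np.histogram(samples[sl], bins=bin_edges, weights=weights[sl])
        total = hist.sum()
        if total == 0:
            continue
        p = hist / total
        with np.errstate(divide="ignore"):
            f = np.where(p > 0, -thermo.kT * np.log(np.where(p > 0, p, 1.0)), np.nan)
        block_f[b] = f - np.nanmin(f)
    # bins seen by fewer than two blocks get no error estimate (NaN)
    enough = np.sum(np.isfinite(block_f), axis=0) >= 2
    errors = np.full(len(grid), np.nan)
    with np.errstate(invalid="ignore"):
        errors[enough] = (
            np.nanstd(block_f[:, enough], axis=0, ddof=1) / math.sqrt(n_blocks)
        )
    fes.errors = errors
    return fes


def combine_fes_curves(curves: list[FESCurve]) -> FESCurve:
    """Inverse-variance weighted combination of replica FES curves.

    Replicas (independent seeds or independently trained CVs) are first
    aligned on their common minimum bin, then averaged per bin with weights
    1/error^2 from their block errors; the combined error is the standard
    inverse-variance expression. Bins missing (NaN) in a replica are simply
    excluded from that bin's average.
    """
    if not curves:
        raise ValueError("need at least one FES curve")
    grid = curves[0].grid
    for c in curves[1:]:
        if not np.allclose(c.grid, grid):
            raise ValueError("replica FES curves must share a grid")
    vals = np.array([c.shift_to_zero().values for c in curves])
    errs = np.array(
        [
            np.where(np.isfinite(c.errors), np.maximum(c.errors, 1e-6), np.inf)
            if c.errors is not None
            else np.full_like(c.values, 1.0)
            for c in curves
        ]
    )
    errs = np.where(np.isfinite(vals), errs, np.inf)
    w = 1.0 / errs**2
    wsum = w.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(wsum > 0, np.nansum(np.where(np.isfinite(vals), vals, 0.0) * w, axis=0) / wsum, np.nan)
        err = np.where(wsum > 0, 1.0 / np.sqrt(wsum), np.nan)
    return FESCurve(grid, mean, err).shift_to_zero()


def delta_g_standard(
    fes_z: FESCurve,
    bound_window: tuple[float, float],
    unbound_window: tuple[float, float],
    geom: FunnelGeometry,
    thermo: ThermoParams,
    standard_conc: float = STANDARD_CONC_NM3,
) -> float:
    """Funnel-corrected standard binding free energy from FES(z), kcal/mol.

    Trapezoid integral of e^{-beta(F - F_U)} over the bound window, F_U the
    mean FES over the unbound window; negative Delta G means binding is
    favourable at 1 mol/L.
    """
    lo_b, hi_b = bound_window
    lo_u, hi_u = unbound_window
    if max(lo_b, lo_u) < min(hi_b, hi_u):
        raise ValueError("bound and unbound windows must be disjoint")
    z, f = fes_z.grid, fes_z.values
    in_b = (z >= lo_b) & (z <= hi_b) & np.isfinite(f)
    in_u = (z >= lo_u) & (z <= hi_u) & np.isfinite(f)
    if in_b.sum() < 3 or in_u.sum() < 3:
        raise ValueError("each window needs at least 3 populated bins")
    f_u = float(f[in_u].mean())
    integrand = np.exp(-thermo.beta * (f[in_b] - f_u))
    integral = float(np.trapezoid(integrand, z[in_b]))  # nm
    return -thermo.kT * math.log(
        standard_conc * math.pi * geom.r_cyl**2 * integral
    )


def combine_replicas(results: list[tuple[float, float]]) -> tuple[float, float]:
    """Inverse-variance weighted mean and standard error of (value, error) pairs."""
    if not results:
        raise ValueError("need at least one replica")
    vals = np.array([r[0] for r in results], dtype=float)
    errs = np.array([r[1] for r in results], dtype=float)
    if np.any(errs < 0):
        raise ValueError("errors must be non-negative")
    if np.any(errs == 0):
        if np.ptp(vals[errs == 0]) > 0:
            raise ValueError("zero errors with disagreeing values: weights degenerate")
        return float(vals[errs == 0][0]), 0.0
    w = 1.0 / errs**2
    mean = float(np.sum(w * vals) / np.sum(w))
    return mean, float(1.0 / math.sqrt(np.sum(w)))


def sampl_metrics(calc, exp) -> dict[str, float]:
    """Benchmark metrics: rmse, Pearson r^2, OLS slope of calc on exp, and
    Kendall tau (tau-a; no ties expected). kcal/mol in, dimensionless out
    except rmse."""
    calc = np.asarray(calc, dtype=float)
    exp = np.asarray(exp, dtype=float)
    if calc.shape != exp.shape or calc.ndim != 1 or len(calc) < 3:
        raise ValueError("calc and exp must be equal-length 1-D arrays, n >= 3")
    rmse = float(np.sqrt(np.mean((calc - exp) ** 2)))
    lr = sstats.linregress(exp, calc)
    tau = sstats.kendalltau(calc, exp).statistic
    return {
        "rmse": rmse,
        "r2": float(lr.rvalue**2),
        "slope": float(lr.slope),
        "kendall_tau": float(tau),
    }


def cylindrical_density(
    frames,
    z_edges: np.ndarray,
    r_edges: np.ndarray,
) -> np.ndarray:
    """Water-oxygen density map in cylindrical coordinates (z, r) about the
    host axis, normalised by the top-right (largest z, largest r) bin.

    Counts are divided by the shell volume 2*pi*r_mid*dr*dz and the frame
    count before the corner normalisation, so a uniform bath gives ~1
    everywhere. Shape: (n_z_bins, n_r_bins).
    """
    z_edges = np.asarray(z_edges, dtype=float)
    r_edges = np.asarray(r_edges, dtype=float)
    if len(z_edges) < 3 or len(r_edges) < 3:
        raise ValueError("need at least 2 bins in z and r")
    counts = np.zeros((len(z_edges) - 1, len(r_edges) - 1))
    for fr in frames:
        ox = fr.water_oxygens
        if len(ox) == 0:
            continue
        rel = ox - fr.axis_origin
        z = rel @ fr.axis_direction
        radial = rel - z[:, None] * fr.axis_direction
        r = np.linalg.norm(radial, axis=1)
        h, _, _ = np.histogram2d(z, r, bins=[z_edges, r_edges])
        counts += h
    r_mid = 0.5 * (r_edges[:-1] + r_edges[1:])
    dr = np.diff(r_edges)
    dz = np.diff(z_edges)
    volume = 2.0 * math.pi * r_mid[None, :] * dr[None, :] * dz[:, None]
    density = counts / volume / max(len(frames), 1)
    corner = density[-1, -1]
    if corner == 0:
        raise ValueError("top-right reference bin is empty; extend the grid "
                         "into bulk water")
    return density / corner
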