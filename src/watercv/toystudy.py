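"""End-to-end study protocols on the analytic toy system.

These functions bundle the workflows the package is built for, at problem
sizes a desktop machine handles in minutes:

* :func:`binding_fes_study` — OPES-biased Langevin on the toy landscape with
  the (hydration, binding-axis) CV pair, run over several seeds; each run is
  reweighted into FES(z) with block errors, the replicas are combined by
  inverse variance (the same way independently trained CVs are combined),
  and the standard-state, funnel-corrected Delta G is extracted. The
  landscape's exact quadrature FES provides the reference.
* :func:`replica_cv_study` — the robustness protocol: several Deep-LDA CVs
  trained from different initial weights on basin samples, compared through
  held-out projections, then each used (via its exported CV table) to bias
  its own OPES run, giving per-replica Delta G with block errors.

Study conditions (friction 1.5, dt 0.002 ps, deposition stride 250,
2e6 steps, first half discarded as equilibration) are the package's
documented choices for this toy; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .deeplda import DeepLDAModel, train_deep_lda
from .fes import (FESCurve, combine_fes_curves, combine_replicas,
                  delta_g_standard, fes_with_errors, reweight_weights)
from .funnel import FunnelGeometry
from .landscape import ToyLandscape, langevin_trajectory, sample_basin_descriptors
from .opes import CoordinateCV, GridCV, run_opes
from .units import ThermoParams

#: Study conditions for the toy binding landscape.
FRICTION = 1.5  # kcal/mol ps nm^-2
DT = 0.002  # ps
STRIDE = 250  # deposition stride, steps
GAMMA = 10.0
N_STEPS = 2_000_000
EDGES = np.linspace(-1.6, 1.6, 65)
BOUND_WINDOW = (-1.4, -0.6)
UNBOUND_WINDOW = (0.6, 1.4)
R_CYL = 0.3  # nm
N_BLOCKS = 5


def count_crossings(z: np.ndarray, lo: float = -0.5, hi: float = 0.5,
                    subsample: int = 10) -> int:
    """Bound/unbound transitions with hysteresis thresholds at z = lo, hi."""
    state, n = 0, 0
    for zi in np.asarray(z)[::subsample]:
        if zi < lo:
            if state == 1:
                n += 1
            state = -1
        elif zi > hi:
            if state == -1:
                n += 1
            state = 1
    return n


def _delta_g_with_block_error(z, weights, thermo, geom, n_blocks=N_BLOCKS):
    """Delta G from the full window plus its block standard error."""
    curve = fes_with_errors(z, weights, EDGES, thermo, n_blocks=n_blocks)
    dg = delta_g_standard(curve, BOUND_WINDOW, UNBOUND_WINDOW, geom, thermo)
    n = len(z)
    size = n // n_blocks
    per_block = []
    for b in range(n_blocks):
        sl = slice(b * size, (b + 1) * size)
        try:
            cb = fes_with_errors(z[sl], weights[sl], EDGES, thermo, n_blocks=2)
            per_block.append(
                delta_g_standard(cb, BOUND_WINDOW, UNBOUND_WINDOW, geom, thermo)
            )
        except ValueError:
            continue  # a block that never visited one window is skipped
    if len(per_block) < 2:
        raise ValueError("too few complete blocks for a Delta G error estimate")
    err = float(np.std(per_block, ddof=1) / np.sqrt(len(per_block)))
    return curve, dg, err


@dataclass
class BindingStudyResult:
    curves: list[FESCurve]
    combined: FESCurve
    reference: FESCurve
    crossings: list[int]
    unbiased_crossings: list[int]
    delta_gs: list[tuple[float, float]]
    delta_g_combined: tuple[float, float]
    delta_g_reference: float

    @property
    def fes_max_abs_dev(self) -> float:
        """Max |combined FES - quadrature| (kcal/mol) where the reference
        lies below 8 kT."""
        thermo = ThermoParams()
        mask = np.isfinite(self.combined.values) & (
            self.reference.values < 8 * thermo.kT
        )
        return float(np.abs(self.combined.values - self.reference.values)[mask].max())


def binding_fes_study(
    seeds=(1, 2, 3),
    n_steps: int = N_STEPS,
    landscape: ToyLandscape | None = None,
    thermo: ThermoParams | None = None,
    with_unbiased: bool = True,
    unbiased_steps: int | None = None,
) -> BindingStudyResult:
    """Multi-seed OPES study on the toy landscape, biasing (q, z)."""
    landscape = landscape or ToyLandscape()
    thermo = thermo or ThermoParams()
    geom = FunnelGeometry(r_cyl=R_CYL)
    cvs = [CoordinateCV(1, "q"), CoordinateCV(0, "s_z")]
    curves, crossings, unb_crossings, dgs = [], [], [], []
    for seed in seeds:
        traj, _bias = run_opes(
            landscape, cvs, thermo, start=landscape.minima()[0],
            n_steps=n_steps, seed=int(seed), friction=FRICTION, dt=DT,
            stride=STRIDE, gamma=GAMMA,
        )
        z = traj.cv_values[:, 1]
        crossings.append(count_crossings(z))
        half = len(z) // 2
        w = reweight_weights(traj.bias_energy[half:], thermo)
        curve, dg, err = _delta_g_with_block_error(z[half:], w, thermo, geom)
        curves.append(curve)
        dgs.append((dg, err))
        if with_unbiased:
            unb = langevin_trajectory(
                landscape, landscape.minima()[0], thermo, friction=FRICTION,
                dt=DT, n_steps=unbiased_steps or n_steps, seed=int(seed) + 7_000,
            )
            unb_crossings.append(count_crossings(unb.positions[:, 0]))
    combined = combine_fes_curves(curves)
    grid = combined.grid
    ref_vals = landscape.marginal_free_energy(grid, thermo)
    reference = FESCurve(grid, ref_vals)
    dg_ref = delta_g_standard(reference, BOUND_WINDOW, UNBOUND_WINDOW,
                              FunnelGeometry(r_cyl=R_CYL), thermo)
    return BindingStudyResult(
        curves=curves,
        combined=combined,
        reference=reference,
        crossings=crossings,
        unbiased_crossings=unb_crossings,
        delta_gs=dgs,
        delta_g_combined=combine_replicas(dgs),
        delta_g_reference=dg_ref,
    )


@dataclass
class ReplicaStudyResult:
    models: list[DeepLDAModel]
    heldout_correlations: dict[tuple[int, int], float]
    crossings: list[int]
    delta_gs: list[tuple[float, float]]
    delta_g_combined: tuple[float, float]
    delta_g_reference: float

    @property
    def min_pairwise_correlation(self) -> float:
        return min(abs(v) for v in self.heldout_correlations.values())


def train_basin_models(
    n_models: int = 3,
    n_samples: int = 3000,
    base_seed: int = 0,
    landscape: ToyLandscape | None = None,
    thermo: ThermoParams | None = None,
    hidden=(16, 8),
    epochs: int = 300,
) -> tuple[list[DeepLDAModel], pd.DataFrame]:
    """Deep-LDA CVs trained on bound/unbound basin samples of the toy
    landscape (descriptors d = (z, q)), differing only in initial weights."""
    landscape = landscape or ToyLandscape()
    thermo = thermo or ThermoParams()
    table = pd.concat(
        [
            sample_basin_descriptors(landscape, "B", n_samples, thermo,
                                     seed=base_seed + 9100),
            sample_basin_descriptors(landscape, "U", n_samples, thermo,
                                     seed=base_seed + 9200),
        ],
        ignore_index=True,
    )
    models = [
        train_deep_lda(table, hidden=hidden, epochs=epochs,
                       seed=base_seed + r)
        for r in range(n_models)
    ]
    return models, table


def replica_cv_study(
    base_seed: int = 0,
    n_steps: int = 1_200_000,
    landscape: ToyLandscape | None = None,
    thermo: ThermoParams | None = None,
) -> ReplicaStudyResult:
    """Three-CV robustness protocol: correlations plus per-replica Delta G.

    Each trained CV is exported to a (z, q) grid table and used, together
    with z itself, to bias an OPES run; the s_w bandwidth is set to a
    fraction of the CV's full [-2, 2] range because the classifier is nearly
    constant inside a basin.
    """
    landscape = landscape or ToyLandscape()
    thermo = thermo or ThermoParams()
    geom = FunnelGeometry(r_cyl=R_CYL)
    models, _table = train_basin_models(
        n_models=3, base_seed=base_seed, landscape=landscape, thermo=thermo
    )
    held = pd.concat(
        [
            sample_basin_descriptors(landscape, "B", 1000, thermo,
                                     seed=base_seed + 9300),
            sample_basin_descriptors(landscape, "U", 1000, thermo,
                                     seed=base_seed + 9400),
        ],
        ignore_index=True,
    )
    X = held[["d_1", "d_2"]].to_numpy()
    proj = [m.cv_value(X) for m in models]
    corrs = {
        (i, j): float(np.corrcoef(proj[i], proj[j])[0, 1])
        for i in range(3)
        for j in range(i + 1, 3)
    }
    z_grid = np.linspace(-1.8, 1.8, 181)
    q_grid = np.linspace(-2.0, 6.0, 161)
    crossings, dgs = [], []
    for r, model in enumerate(models):
        cv = GridCV.from_model(model, z_grid, q_grid, name="s_w")
        traj, _bias = run_opes(
            landscape, [cv, CoordinateCV(0, "s_z")], thermo,
            start=landscape.minima()[0], n_steps=n_steps,
            seed=base_seed + 50 + r, friction=FRICTION, dt=DT, stride=STRIDE,
            gamma=GAMMA, sigma0=np.array([0.25, 0.15]),
        )
        z = traj.cv_values[:, 1]
        crossings.append(count_crossings(z))
        half = len(z) // 2
        w = reweight_weights(traj.bias_energy[half:], thermo)
        _curve, dg, err = _delta_g_with_block_error(z[half:], w, thermo, geom)
        dgs.append((dg, err))
    grid = 0.5 * (EDGES[:-1] + EDGES[1:])
    ref = FESCurve(grid, landscape.marginal_free_energy(grid, thermo))
    dg_ref = delta_g_standard(ref, BOUND_WINDOW, UNBOUND_WINDOW, geom, thermo)
    return ReplicaStudyResult(
        models=models,
        heldout_correlations=corrs,
        crossings=crossings,
        delta_gs=dgs,
        delta_g_combined=combine_replicas(dgs),
        delta_g_reference=dg_ref,
    )
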