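"""Two-degree-of-freedom toy binding landscape and overdamped Langevin dynamics.

The landscape couples a binding coordinate ``z`` (double well, minima at
z = -1 bound and z = +1 unbound) to a pocket-hydration coordinate ``q``
restrained around a z-dependent target: the cavity is dry (q near q_B) on the
bound side and filled (q near q_U) on the unbound side,

    U(z, q) = eps*(z^2 - 1)^2 + (kappa/2)*(q - qbar(z))^2,
    qbar(z) = q_B + (q_U - q_B)*(1 + tanh(alpha*z))/2.

Because kappa is constant, the marginal free energy along z is exactly the
double well eps*(z^2 - 1)^2 up to an additive constant, which gives this toy
an analytic reference for every downstream estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .units import ThermoParams

_DEFAULT_KT = ThermoParams().kT  # 300 K


@dataclass(frozen=True)
class ToyLandscape:
    """Parameters of the 2-DOF binding/hydration potential.

    Defaults put the barrier at 5 kT and the hydration stiffness at 10 kT
    (T = 300 K): unbiased barrier crossing is rare while a barrier-capped
    bias crosses frequently.
    """

    epsilon: float = 5.0 * _DEFAULT_KT  # barrier scale, kcal/mol
    kappa: float = 10.0 * _DEFAULT_KT  # hydration stiffness, kcal/mol
    q_bound: float = 0.0
    q_unbound: float = 4.0
    alpha: float = 3.0  # coupling steepness, 1/nm

    def qbar(self, z: float | np.ndarray) -> float | np.ndarray:
        """Equilibrium hydration level at binding coordinate z."""
        return self.q_bound + (self.q_unbound - self.q_bound) * 0.5 * (
            1.0 + np.tanh(self.alpha * np.asarray(z, dtype=float))
        )

    def energy(self, z: float | np.ndarray, q: float | np.ndarray) -> float | np.ndarray:
        z = np.asarray(z, dtype=float)
        q = np.asarray(q, dtype=float)
        out = self.epsilon * (z**2 - 1.0) ** 2 + 0.5 * self.kappa * (q - self.qbar(z)) ** 2
        return float(out) if out.ndim == 0 else out

    def gradient(self, x: np.ndarray) -> np.ndarray:
        """Gradient (dU/dz, dU/dq) at state point x = (z, q)."""
        z, q = float(x[0]), float(x[1])
        span = self.q_unbound - self.q_bound
        t = math.tanh(self.alpha * z)
        qbar = self.q_bound + span * 0.5 * (1.0 + t)
        dqbar_dz = span * 0.5 * self.alpha * (1.0 - t * t)
        dq = self.kappa * (q - qbar)
        dz = 4.0 * self.epsilon * z * (z * z - 1.0) - dq * dqbar_dz
        return np.array([dz, dq])

    def marginal_free_energy(
        self, z_grid: np.ndarray, thermo: ThermoParams, n_q: int = 801
    ) -> np.ndarray:
        """F(z) = -kT log integral_q exp(-beta U) by quadrature, min-shifted to 0."""
        z_grid = np.asarray(z_grid, dtype=float)
        qb = self.qbar(z_grid)
        width = math.sqrt(thermo.kT / self.kappa)
        q = np.linspace(qb.min() - 8 * width, qb.max() + 8 * width, n_q)
        boltz = np.exp(-thermo.beta * self.energy(z_grid[:, None], q[None, :]))
        f = -thermo.kT * np.log(np.trapezoid(boltz, q, axis=1))
        return f - f.min()

    def minima(self) -> tuple[np.ndarray, np.ndarray]:
        """Bound and unbound minima (z, q)."""
        return (
            np.array([-1.0, float(self.qbar(-1.0))]),
            np.array([1.0, float(self.qbar(1.0))]),
        )


@dataclass
class Trajectory:
    """Time series of state points from a (possibly biased) Langevin run."""

    positions: np.ndarray  # (n_steps+1, dim)
    dt: float
    seed: int
    bias_energy: np.ndarray | None = None  # per-step bias at the visited point
    cv_values: np.ndarray | None = None  # (n, n_cv) when run under CV bias
    cv_names: list[str] = field(default_factory=list)

    @property
    def times(self) -> np.ndarray:
        return self.dt * np.arange(len(self.positions))


def langevin_trajectory(
    landscape,
    start: np.ndarray,
    thermo: ThermoParams,
    friction: float = 10.0,
    dt: float = 0.001,
    n_steps: int = 10000,
    seed: int = 0,
    extra_force=None,
    divergence_bound: float = 1e3,
) -> Trajectory:
    """Overdamped Euler-Maruyama dynamics on a landscape (or any object with
    ``gradient(x)``).

    Update: x += -grad(U)/friction * dt + sqrt(2 kT dt / friction) * xi.
    ``extra_force(x) -> (energy, gradient)`` adds a static bias/restraint whose
    per-step energy is recorded. Same seed and inputs give a bit-identical
    trajectory.

    The integrator is accurate when k*dt/friction << 1 for the stiffest
    curvature k; a harmonic well then reproduces its variance kT/k to within
    the O(k*dt/friction) discretisation bias.
    """
    x = np.array(start, dtype=float)
    dim = x.size
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n_steps, dim)) * math.sqrt(
        2.0 * thermo.kT * dt / friction
    )
    inv_gamma_dt = dt / friction
    out = np.empty((n_steps + 1, dim))
    out[0] = x
    bias = np.zeros(n_steps + 1) if extra_force is not None else None
    if extra_force is not None:
        bias[0] = extra_force(x)[0]
    for i in range(n_steps):
        g = landscape.gradient(x)
        if extra_force is not None:
            e_b, g_b = extra_force(x)
            g = g + g_b
        x = x - inv_gamma_dt * g + noise[i]
        if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > divergence_bound:
            raise RuntimeError(
                f"trajectory diverged at step {i + 1}: x={x}; "
                f"reduce dt or increase friction"
            )
        out[i + 1] = x
        if extra_force is not None:
            bias[i + 1] = extra_force(x)[0]
    return Trajectory(positions=out, dt=dt, seed=seed, bias_energy=bias)


def make_gaussian_classes(
    n_per_class: int,
    dim: int,
    mean_B,
    mean_U,
    cov,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-class Gaussian descriptor table with columns d_1..d_dim and 'label'.

    ``cov`` may be a matrix shared by both classes. Non-positive-definite
    covariances are rejected.
    """
    mean_B = np.asarray(mean_B, dtype=float)
    mean_U = np.asarray(mean_U, dtype=float)
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    if mean_B.shape != (dim,) or mean_U.shape != (dim,):
        raise ValueError(f"means must have length dim={dim}")
    if cov.shape != (dim, dim):
        raise ValueError(f"cov must be {dim}x{dim}, got {cov.shape}")
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise ValueError("covariance matrix is not positive definite") from None
    rng = np.random.default_rng(seed)
    xb = mean_B + rng.standard_normal((n_per_class, dim)) @ chol.T
    xu = mean_U + rng.standard_normal((n_per_class, dim)) @ chol.T
    cols = [f"d_{i + 1}" for i in range(dim)]
    df = pd.DataFrame(np.vstack([xb, xu]), columns=cols)
    df["label"] = ["B"] * n_per_class + ["U"] * n_per_class
    return df


def sample_basin_descriptors(
    landscape: ToyLandscape,
    state_label: str,
    n_samples: int,
    thermo: ThermoParams,
    seed: int = 0,
    stride: int = 10,
    friction: float = 10.0,
    dt: float = 0.001,
) -> pd.DataFrame:
    """Short unbiased in-basin run, returning (z, q) descriptor rows.

    Emulates the short unbiased bound/unbound simulations used to train a
    discriminant CV: the default barrier keeps a short run inside its
    starting basin.
    """
    if state_label not in ("B", "U"):
        raise ValueError(f"state_label must be 'B' or 'U', got {state_label!r}")
    start = landscape.minima()[0 if state_label == "B" else 1]
    traj = langevin_trajectory(
        landscape, start, thermo, friction=friction, dt=dt,
        n_steps=n_samples * stride, seed=seed,
    )
    pts = traj.positions[stride::stride][:n_samples]
    df = pd.DataFrame(pts, columns=["d_1", "d_2"])
    df["label"] = state_label
    return df
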