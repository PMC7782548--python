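"""On-the-fly probability-enhanced sampling (OPES) bias.

The bias maintains a weighted kernel-density estimate P~(s) of the CV
distribution and applies

    V(s) = (1 - 1/gamma) * kT * log( P~(s)/Z + eps ),

with bias factor gamma > 1, normalisation Z (the mean of P~ over kernel
centers) and regulariser eps = exp(-beta*dE/(1-1/gamma)), which caps the
total bias range at the barrier parameter dE. Kernels deposited at the
visited CV values carry weights e^{beta*V}, their bandwidth shrinks with the
effective sample size, and a new kernel merges into its nearest neighbour
when closer than one bandwidth, keeping the kernel count compressed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .landscape import Trajectory
from .units import ThermoParams

try:  # numba shaves an order of magnitude off the per-step kernel sums
    from numba import njit

    @njit(cache=False, fastmath=False)
    def _kde_core(s, centers, bandwidths, heights):
        n, d = centers.shape
        p = 0.0
        grad = np.zeros(d)
        wsum = 0.0
        for k in range(n):
            expo = 0.0
            norm = heights[k]
            for j in range(d):
                diff = (s[j] - centers[k, j]) / bandwidths[k, j]
                expo += diff * diff
                norm /= bandwidths[k, j]
            g = norm * math.exp(-0.5 * expo) / (2.0 * math.pi) ** (d / 2.0)
            p += g
            for j in range(d):
                grad[j] -= g * (s[j] - centers[k, j]) / bandwidths[k, j] ** 2
            wsum += heights[k]
        return p / wsum, grad / wsum

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - exercised only without numba
    _HAVE_NUMBA = False


class OPESBias:
    """Kernel store and bias evaluator for 1 or 2 CVs.

    Parameters
    ----------
    sigma0 : array-like
        Initial per-CV bandwidth, conventionally the CV standard deviation
        in a short unbiased run.
    gamma : float
        Bias factor (> 1); gamma == 1 is the unbiased edge case, V = 0.
    barrier : float
        dE, the bias cap, kcal/mol.
    """

    def __init__(
        self,
        sigma0,
        gamma: float = 10.0,
        barrier: float | None = None,
        thermo: ThermoParams = ThermoParams(),
        merge_threshold: float = 1.0,
        z_update_every: int = 10,
        min_bandwidth_factor: float = 0.5,
    ):
        self.sigma0 = np.atleast_1d(np.asarray(sigma0, dtype=float))
        if np.any(self.sigma0 <= 0):
            raise ValueError("sigma0 must be positive")
        if gamma < 1:
            raise ValueError("bias factor gamma must be >= 1")
        self.gamma = gamma
        self.thermo = thermo
        self.barrier = 10.0 * thermo.kT if barrier is None else barrier
        self.merge_threshold = merge_threshold
        self.dim = len(self.sigma0)
        self.centers = np.empty((0, self.dim))
        self.bandwidths = np.empty((0, self.dim))
        self.heights = np.empty(0)
        self.z_update_every = z_update_every
        # floor on the bandwidth shrinkage: keeps the bias curvature bounded
        # (~prefactor/sigma^2), so the overdamped integrator stays in its
        # stability region at the run's dt
        self.min_bandwidth_factor = min_bandwidth_factor
        self.Z = 1.0
        self.sum_w = 0.0
        self.sum_w2 = 0.0
        self.n_deposits = 0

    # -- derived constants -------------------------------------------------
    @property
    def _prefactor(self) -> float:
        return (1.0 - 1.0 / self.gamma) * self.thermo.kT

    @property
    def epsilon(self) -> float:
        """Regulariser keeping the bias below the barrier cap."""
        if self.gamma == 1.0:
            return 1.0
        return math.exp(-self.thermo.beta * self.barrier / (1.0 - 1.0 / self.gamma))

    # -- evaluation --------------------------------------------------------
    def _kde(self, s: np.ndarray) -> tuple[float, np.ndarray]:
        """(P~(s), dP~/ds) of the weighted, normalised kernel estimate."""
        if _HAVE_NUMBA:
            return _kde_core(s, self.centers, self.bandwidths, self.heights)
        diff = (s - self.centers) / self.bandwidths
        norm = self.heights / np.prod(self.bandwidths, axis=1) / (
            (2 * math.pi) ** (self.dim / 2)
        )
        g = norm * np.exp(-0.5 * np.sum(diff * diff, axis=1))
        wsum = self.heights.sum()
        p = g.sum() / wsum
        grad = -(g[:, None] * diff / self.bandwidths).sum(axis=0) / wsum
        return p, grad

    def prob(self, s) -> float:
        s = np.atleast_1d(np.asarray(s, dtype=float))
        if len(self.centers) == 0:
            return 0.0
        return self._kde(s)[0]

    def bias(self, s) -> float:
        """V(s) in kcal/mol; 0 for an empty kernel list or gamma == 1."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        if not np.all(np.isfinite(s)):
            raise FloatingPointError(f"non-finite CV value {s}")
        if len(self.centers) == 0 or self.gamma == 1.0:
            return 0.0
        p, _ = self._kde(s)
        return self._prefactor * math.log(p / self.Z + self.epsilon)

    def bias_and_gradient(self, s) -> tuple[float, np.ndarray]:
        s = np.atleast_1d(np.asarray(s, dtype=float))
        if len(self.centers) == 0 or self.gamma == 1.0:
            return 0.0, np.zeros_like(s)
        p, dp = self._kde(s)
        ratio = p / self.Z + self.epsilon
        v = self._prefactor * math.log(ratio)
        dv = self._prefactor * (dp / self.Z) / ratio
        return v, dv

    # -- deposition --------------------------------------------------------
    def update(self, s_now) -> None:
        """Deposit a kernel at the current CV value (call every stride)."""
        s_now = np.atleast_1d(np.asarray(s_now, dtype=float))
        if not np.all(np.isfinite(s_now)):
            raise FloatingPointError(f"non-finite CV value {s_now}")
        if self.gamma == 1.0:
            return
        weight = math.exp(self.thermo.beta * self.bias(s_now))
        self.sum_w += weight
        self.sum_w2 += weight * weight
        self.n_deposits += 1
        n_eff = self.sum_w**2 / self.sum_w2
        shrink = (n_eff * (self.dim + 2) / 4.0) ** (-1.0 / (self.dim + 4))
        sigma = self.sigma0 * max(shrink, self.min_bandwidth_factor)
        self._add_kernel(s_now, sigma, weight)
        # Z, the mean of the estimate over kernel centers, drifts slowly with
        # n; a periodic full recompute keeps the cost at O(K^2 / z_update_every)
        if self.n_deposits % self.z_update_every == 1 or self.n_deposits < 10:
            wsum = self.heights.sum()
            norm = self.heights / np.prod(self.bandwidths, axis=1) / (
                (2 * math.pi) ** (self.dim / 2)
            )
            diff = (
                self.centers[:, None, :] - self.centers[None, :, :]
            ) / self.bandwidths[None, :, :]
            gmat = norm[None, :] * np.exp(-0.5 * np.sum(diff * diff, axis=2))
            self.Z = float(gmat.sum(axis=1).mean() / wsum)

    def _add_kernel(self, center, sigma, height) -> None:
        if len(self.centers):
            dist = np.sqrt(
                np.sum(((center - self.centers) / self.bandwidths) ** 2, axis=1)
            )
            j = int(np.argmin(dist))
            if dist[j] < self.merge_threshold:
                h = self.heights[j] + height
                c = (self.heights[j] * self.centers[j] + height * center) / h
                var = (
                    self.heights[j] * (self.bandwidths[j] ** 2 + self.centers[j] ** 2)
                    + height * (sigma**2 + center**2)
                ) / h - c**2
                self.centers[j] = c
                self.bandwidths[j] = np.sqrt(np.maximum(var, 1e-300))
                self.heights[j] = h
                return
        self.centers = np.vstack([self.centers, center])
        self.bandwidths = np.vstack([self.bandwidths, sigma])
        self.heights = np.append(self.heights, height)

    # -- persistence -------------------------------------------------------
    def kernel_table(self) -> np.ndarray:
        """Plain restart table: center..., bandwidth..., height per row."""
        return np.column_stack([self.centers, self.bandwidths, self.heights])


@dataclass
class CoordinateCV:
    """CV that picks one coordinate of the state point."""

    index: int
    name: str = ""

    def value(self, x: np.ndarray) -> float:
        return float(x[self.index])

    def gradient(self, x: np.ndarray) -> np.ndarray:
        g = np.zeros_like(x)
        g[self.index] = 1.0
        return g


class GridCV:
    """CV defined by a tabulated function on a regular 2-D grid, evaluated by
    bilinear interpolation.

    This is the consumer side of the exported CV table: a trained model's
    s_w(d) is tabulated once (see :func:`watercv.deeplda.export_cv_table`)
    and then drives the bias at a fraction of a network forward pass per
    step, the same way an external bias engine would use the table.
    """

    def __init__(self, x_grid, y_grid, values, name: str = "s_w"):
        self.x = np.asarray(x_grid, dtype=float)
        self.y = np.asarray(y_grid, dtype=float)
        self.v = np.asarray(values, dtype=float)
        if self.v.shape != (len(self.x), len(self.y)):
            raise ValueError("values must have shape (len(x_grid), len(y_grid))")
        self.name = name

    @classmethod
    def from_model(cls, model, x_grid, y_grid, name: str = "s_w") -> "GridCV":
        xx, yy = np.meshgrid(x_grid, y_grid, indexing="ij")
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        vals = model.cv_value(pts).reshape(len(x_grid), len(y_grid))
        return cls(x_grid, y_grid, vals, name=name)

    def _locate(self, x: float, grid: np.ndarray) -> tuple[int, float]:
        i = int(np.clip(np.searchsorted(grid, x) - 1, 0, len(grid) - 2))
        t = (x - grid[i]) / (grid[i + 1] - grid[i])
        return i, float(np.clip(t, 0.0, 1.0))

    def value(self, p: np.ndarray) -> float:
        i, tx = self._locate(float(p[0]), self.x)
        j, ty = self._locate(float(p[1]), self.y)
        v = self.v
        return float(
            (1 - tx) * (1 - ty) * v[i, j]
            + tx * (1 - ty) * v[i + 1, j]
            + (1 - tx) * ty * v[i, j + 1]
            + tx * ty * v[i + 1, j + 1]
        )

    def gradient(self, p: np.ndarray) -> np.ndarray:
        i, tx = self._locate(float(p[0]), self.x)
        j, ty = self._locate(float(p[1]), self.y)
        v = self.v
        dx = self.x[i + 1] - self.x[i]
        dy = self.y[j + 1] - self.y[j]
        g = np.zeros_like(np.asarray(p, dtype=float))
        g[0] = ((1 - ty) * (v[i + 1, j] - v[i, j]) + ty * (v[i + 1, j + 1] - v[i, j + 1])) / dx
        g[1] = ((1 - tx) * (v[i, j + 1] - v[i, j]) + tx * (v[i + 1, j + 1] - v[i + 1, j])) / dy
        return g


@dataclass
class ModelCV:
    """Deep-LDA CV s_w evaluated on the state point as the descriptor vector."""

    model: object
    name: str = "s_w"

    def value(self, x: np.ndarray) -> float:
        return float(self.model.cv_value(x[None, :])[0])

    def gradient(self, x: np.ndarray) -> np.ndarray:
        return self.model.cv_gradient(x[None, :])[0]


def run_opes(
    landscape,
    cvs: list,
    thermo: ThermoParams,
    start: np.ndarray,
    n_steps: int,
    seed: int = 0,
    friction: float = 10.0,
    dt: float = 0.001,
    stride: int = 500,
    gamma: float = 10.0,
    barrier: float | None = None,
    sigma0=None,
    funnel=None,
    divergence_bound: float = 1e3,
) -> tuple[Trajectory, OPESBias]:
    """Overdamped Langevin dynamics under U + V(CVs) (+ optional restraint).

    ``cvs`` are 1 or 2 objects exposing ``value(x)`` and ``gradient(x)``.
    When ``sigma0`` is None, it is estimated as the CV standard deviation over
    a short unbiased segment (stride steps). Per-step CV values and the bias
    at the visited point are recorded; runs are seed-deterministic.
    """
    if not 1 <= len(cvs) <= 2:
        raise ValueError("run_opes supports 1 or 2 CVs")
    x = np.array(start, dtype=float)
    dim = x.size
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n_steps, dim)) * math.sqrt(
        2.0 * thermo.kT * dt / friction
    )
    if sigma0 is None:
        from .landscape import langevin_trajectory

        # the unbiased segment must cover the slowest CV relaxation time,
        # otherwise the bandwidth is underestimated and the KDE turns spiky
        warm = langevin_trajectory(
            landscape, x, thermo, friction=friction, dt=dt,
            n_steps=max(10 * stride, 2000), seed=seed + 1,
        )
        cv_warm = np.array(
            [[cv.value(p) for cv in cvs] for p in warm.positions]
        )
        half = len(cv_warm) // 2
        sigma0 = np.maximum(cv_warm[half:].std(axis=0, ddof=1), 1e-4)
    bias_state = OPESBias(sigma0, gamma=gamma, barrier=barrier, thermo=thermo)

    inv_gamma_dt = dt / friction
    pos = np.empty((n_steps + 1, dim))
    cv_log = np.empty((n_steps + 1, len(cvs)))
    v_log = np.empty(n_steps + 1)
    pos[0] = x
    s = np.array([cv.value(x) for cv in cvs])
    cv_log[0] = s
    # v_log[i] is the bias in effect at position i when the step leaves it,
    # which is the weight entering the umbrella-like reweighting
    for i in range(n_steps):
        g = landscape.gradient(x)
        v, dv_ds = bias_state.bias_and_gradient(s)
        v_log[i] = v
        if np.any(dv_ds):
            for j, cv in enumerate(cvs):
                g = g + dv_ds[j] * cv.gradient(x)
        if funnel is not None:
            e_f, g_f = funnel.energy_and_gradient(x)
            g = g + g_f
        x = x - inv_gamma_dt * g + noise[i]
        if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > divergence_bound:
            raise RuntimeError(f"biased trajectory diverged at step {i + 1}: x={x}")
        s = np.array([cv.value(x) for cv in cvs])
        if (i + 1) % stride == 0:
            bias_state.update(s)
        pos[i + 1] = x
        cv_log[i + 1] = s
    v_log[n_steps] = bias_state.bias(s)
    traj = Trajectory(
        positions=pos,
        dt=dt,
        seed=seed,
        bias_energy=v_log,
        cv_values=cv_log,
        cv_names=[cv.name or f"cv_{k + 1}" for k, cv in enumerate(cvs)],
    )
    return traj, bias_state
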