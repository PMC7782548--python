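# Methods

This note defines the models implemented in `watercv`, the parameters and
their defaults, what the toy generators emulate, and the numerical choices
made along the way. All energies are in kcal/mol, lengths in nm, times in ps;
`kT ≈ 0.596 kcal/mol` at the default `T = 300 K`
(`k_B = 1.9872041e-3 kcal/mol/K`).

## 1. Toy binding landscape

`ToyLandscape` is a two-dimensional stand-in for funnel-shaped host–guest
binding with hydration gating:

```
U(z, q) = ε (z² − 1)² + (κ/2) (q − q̄(z))²
q̄(z)   = q_B + (q_U − q_B) · (1 + tanh(αz)) / 2
```

* `z` — position along the binding axis; minima at `z = ∓1` play the bound
  (B) and unbound (U) states.
* `q` — a hydration-like coordinate (cavity water occupancy) harmonically
  tethered to a z-dependent target that switches from `q_B = 0` (dry, bound)
  to `q_U = 4` (wet, unbound) across the barrier with steepness `α = 3`.
* Defaults `ε = 5 kT`, `κ = 10 kT`. Because the `q` term is a pure Gaussian
  around `q̄(z)`, the exact marginal along z is
  `F(z) = ε (z² − 1)² + const` — every sampling result in the package can be
  checked against quadrature of this expression.

The coupling reproduces the mechanism the package targets: at fixed `q` the
effective barrier between basins is `κ(q_U − q_B)²/8 ≈ 20 kT` higher than the
marginal barrier, so biasing `z` alone stalls exactly the way water-gated
binding stalls a geometric CV, while biasing `(q, z)` (or a learned CV that
mixes them) succeeds.

Dynamics are overdamped Langevin integrated with Euler–Maruyama,
`x_{t+1} = x_t − (∇U/γ_f) dt + sqrt(2kT dt/γ_f) ξ`, friction
`γ_f = 10 kcal·ps/mol/nm²` and `dt = 0.001 ps` by default. Stability requires
the largest force constant times `dt/γ_f` to stay well below 1; the
integrator aborts with an error on divergence rather than producing NaNs.

## 2. Geometric snapshot generator

`toy_host_guest_frames` emulates the *data* a solvated host–guest simulation
would hand the descriptor code, without simulating one: a cylindrical host
cavity (axis along z, interior `z ∈ [−0.8, 0]`, radius 0.3 nm), a two-bead
guest, and `n_waters` water oxygens placed uniformly in a box. In the bound
state the guest sits inside the cavity and waters are rejection-sampled out
of it plus a 0.3 nm desolvation margin — one switching-function width,
necessary because the rational switching function's long r⁻⁶ tail would
otherwise let points in an exactly water-free cavity read about a third of
the bulk coordination from waters just outside the walls. In the unbound
state the guest sits outside and waters fill everywhere, including the
cavity. "Dry" thus means axial coordination well under a tenth of the
wet-cavity value, not exactly zero. The frames carry the host-axis origin
and direction as extended-XYZ comment metadata so descriptor computation
needs no other input. This gives fixtures whose qualitative hydration
contrast (B dry / U wet) is true by construction.

## 3. Descriptors

Water coordination is counted through the rational switching function

```
s(r) = (1 − (r/r0)^n) / (1 − (r/r0)^m),   r0 = 0.35 nm, n = 6, m = 12
```

evaluated with a series-safe limit at `r = r0`. Two families:

* `L_i` — coordination of water oxygens around each guest bead (ligand
  hydration shell).
* `V_i` — coordination around `n_points = 8` probe points spaced 0.2 nm along
  the host axis starting at `z_start = −0.7` (cavity-interior hydration).

`descriptor_table` also records two geometric CVs (axial guest position
`s_z`, guest orientation `cos θ`) for reference. Descriptors are invariant
under rigid motions and water permutations (tested).

## 4. Deep-LDA collective variable

A feed-forward network `h = f(d)` (default hidden sizes 32-16-8, ELU) is
trained to maximize Fisher's ratio of the bound/unbound classes in feature
space:

```
J* = Δμᵀ (S_w + λI)⁻¹ Δμ,   λ = 0.05
```

where `Δμ` is the class-mean gap and `S_w` the pooled within-class scatter of
`h`. The loss is `−J*`; its gradient with respect to the features exists in
closed form (with `v = (S_w + λI)⁻¹Δμ`:
`∂J*/∂h_k = ±2v/n − (2/(n−1)) (v·(h_k − μ_class)) v`), and standard
backpropagation carries it to the weights. Optimization is full-batch Adam
(lr 1e-3), 80/20 train/validation split, early stopping on validation `J*`
(patience 50); the reported discriminant `w`, the sign convention (bound
projects positive) and the rescaling are fitted on the training split only.

The deployed CV is not the raw projection `s = w·h` but

```
u  = affine rescale of s onto [−1, 1] (training range)
s_w = u + u³
```

The cubic stretch matters: the Fisher objective rewards compressing each
class to a point, which flattens `∂s/∂d` inside the basins — precisely where
a bias needs gradients. `s_w` widens the basins (slope 1 at the centre, 4 at
the edges) while preserving ordering. Empirically the raw `s` correlates
ρ ≈ 0.950 ± 0.005 with the analytic LDA projection on Gaussian classes
(sigmoidal compression is a real effect, not a training failure) while the
deployed `s_w` sits at ρ ≈ 0.97.

torch is deliberately not a dependency: the network is a compact numpy MLP
(`watercv.network`) with hand-written Adam, which keeps training exactly
reproducible (same seed → byte-identical model JSON) and the install light.

## 5. OPES bias

The on-the-fly probability enhanced sampling bias over the CV `s`:

```
V(s) = (1 − 1/γ) kT · ln( P̃(s)/Z + ε ),   ε = exp(−βΔE / (1 − 1/γ))
```

* `P̃` — weighted Gaussian kernel density estimate of the sampled CV
  distribution; each deposition (every `stride` steps, default 500) carries
  weight `e^{βV}` evaluated at deposition time.
* `Z` — mean of `P̃` over the kernel centres, recomputed every 10 deposits
  (an O(K²) sum; the 10-deposit cycle keeps cost negligible at no measurable
  accuracy loss).
* `γ = 10` (bias factor), `ΔE = 10 kT` (barrier parameter). The ε regulariser
  bounds the bias below by `−ΔE` exactly; with `Z` defined as a mean over
  centres, the bias *range* can exceed `ΔE` by
  `(1 − 1/γ) kT ln(max P̃/Z)` (≈ 0.2·ΔE at convergence on the toy) — this is a
  property of the estimator, not a bug, and is tested as such.
* Kernel bandwidths start at `σ0` and shrink as
  `σ0 · [n_eff (d+2)/4]^(−1/(d+4))`; new kernels merge into an existing one
  closer than 1.0 bandwidth (Mahalanobis), so the store stays compact
  (hundreds of kernels for 10⁴ deposits).

Two robustness choices, found necessary in practice and kept as defaults:

* **Warmup length.** `σ0` is estimated from the second half of a short
  unbiased segment of `max(10·stride, 2000)` steps. A one-stride warmup
  underestimates the bandwidth of slowly relaxing CVs (the hydration
  coordinate relaxes over ~1700 steps) by 5–8×, which makes the KDE spiky and
  the bias rough.
* **Bandwidth floor.** Shrinkage is floored at `0.5·σ0`. Unfloored shrinkage
  eventually raises the bias curvature to the Euler–Maruyama stability limit
  of the integrator.

The per-step kernel sums are jitted with numba when available, with a pure
numpy fallback. Biasing accepts one or two CVs, each either a coordinate, a
trained model, or a bilinearly interpolated grid table (`GridCV`, matching
the exported-CV deployment path).

## 6. Free energies, funnel correction, replicas

Reweighting uses `w = e^{βV}` (max-shifted for overflow safety). `F(z) =
−kT ln P(z)` on a fixed grid, minimum-shifted, with standard errors from 5
trajectory blocks. The standard-state binding free energy for a funnel
restraint of cylinder radius `R`:

```
ΔG° = −kT ln( C° π R² ∫_bound e^{−β(F(z) − F_U)} dz ),  C° = 1/1.660 nm⁻³
```

(the unbound plateau `F_U` from the unbound window mean; integral by
trapezoid). The funnel geometry itself (`FunnelGeometry`) applies one-sided
harmonic walls on a cone-plus-cylinder envelope; on the 2-D toy a 1-D axial
cap (`AxialFunnel1D`) plays that role.

Replicas (independent seeds or independently trained CVs) are combined
exactly the way replica tables of binding free energies are: per-bin
inverse-variance averaging of the FES curves (after aligning minima) and
inverse-variance combination of ΔG. This matters on the toy: individual runs
carry a rigid inter-basin offset of a few tenths of kT that block errors
faithfully report, and the three-replica combination reduces it as expected.

## 7. Benchmark metrics and descriptor ranking

`sampl_metrics(calc, exp)` reports RMSE, Pearson r², the OLS slope of *calc
regressed on exp* (the orientation in which a slope > 1 reads "the
calculation exaggerates differences between ligands") and Kendall τ-a. The
built-in `OAME_TABLE` carries six host–guest pairs with calculated errors.

`descriptor_relevance` ranks descriptors by `mean |∂s_w/∂d_i|` over the
samples of a state, normalized to sum 1; `state_ranking_report` averages the
ranking over several trained CVs (replica averaging) before normalizing.
On the geometric fixtures, the aggregate weight of the cavity (`V`-type)
descriptors is higher in the unbound state, where cavity hydration is the
fluctuating, reaction-relevant signal. A caveat worth recording: on *minimal*
low-dimensional Gaussian fixtures the derivative ranking can invert — the
Fisher-trained network places its steep response next to the
low-fluctuation class, inflating that state's gradients. Replica averaging
over independently trained CVs and a realistic descriptor set restore the
physical ordering; single-model rankings on toy fixtures should be read with
care.

## 8. Problem sizes and study conditions

The bundled studies (`watercv.toystudy`) are sized for a single desktop core:

* Binding study: 3 seeds × 2·10⁶ steps, friction 1.5, `dt = 0.002`,
  deposition stride 250, bias on `(q, z)`, first half of each trajectory
  discarded as equilibration, FES on 64 bins over `z ∈ [−1.6, 1.6]`,
  windows B = [−1.4, −0.6], U = [0.6, 1.4], funnel radius 0.3 nm. Typical
  outcome: combined FES within ~0.3 kT of quadrature below 8 kT, ΔG within
  ~0.1 kcal/mol of exact, ≥ 20 transitions per run (unbiased: ~0–2).
* Replica-CV study: 3 Deep-LDA CVs (hidden 16-8, 300 epochs) trained on
  3000 basin samples per class, each exported to a grid and used with `z` to
  bias a 10⁶-step run (`σ0 = (0.25, 0.15)` — set explicitly because a trained
  classifier is nearly constant inside a basin, so warmup-estimated
  bandwidths would be degenerate).

These sizes, the OPES module defaults (`γ = 10`, `ΔE = 10 kT`, stride 500)
versus the study conditions, and the toy parameter values are the package's
own choices, made so that every statistical claim is checkable in minutes
against an exact reference.

## 9. Limitations

* The toy landscape is 2-D and overdamped; there is no explicit solvent,
  no rotational/conformational ligand entropy, and the funnel geometry is
  exercised only through its algebra and wall forces, not a 3-D simulation.
* The OPES bias-range overshoot discussed in §5 means `ΔE` is a soft cap on
  the bias range (exact only in the single-kernel limit).
* Deep-LDA training is full-batch and CPU-only; it is meant for descriptor
  tables of 10³–10⁴ rows, not large datasets.
* The derivative ranking is a local sensitivity measure; see the §7 caveat
  on minimal fixtures.
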