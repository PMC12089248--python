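# Methods

This note records how the three components of the package — the lattice
individual-based model (IBM), the continuum finite-volume solver, and the
travelling-wave solver — are computed, which numerical choices were open
and how they were fixed, and what the tests do and do not establish.

## Model and parameters

State: densities `n_i(t,x) ≥ 0` of `I ≥ 2` phenotypes on `[0, L]`,
pressure `p = Σ ω_i n_i`. Evolution:

```
∂t n_i − μ_i ∂x(n_i ∂x p) = α_i G(p) n_i ,   G(p) = arctan((1/10)(1 − p/p̄)).
```

| parameter | meaning | baseline | units |
| --- | --- | --- | --- |
| `p̄` | homeostatic pressure, `G(p̄)=0` | 4×10⁴ | pressure |
| `ω_i` | pressure weight per unit density | (1,2,3[,4]); variants (2,2,2[,2]), (3,2,1)/(4,3,2,1) | pressure·length |
| `μ_i` | mobility | (1,2,3[,4])×10⁻⁴ | length²·pressure⁻¹·time⁻¹ |
| `α_i` | growth time-scale factor | α₁=10, α_{i≥2}=0 | time⁻¹ |
| `Δx`, `τ` | lattice steps | 0.1, 10⁻⁴ | length, time |
| `γ_i` | lattice pressure sensitivity | `2 τ p̄ μ_i/Δx²` = 0.08 i | — |
| `L`, horizon | domain, end time | 150, 150 | length, time |
| `B` | initial Gaussian width | 6×10⁻² | length⁻² |

All quantities are dimensionless multiples of these abstract units; no
physical unit system is attached.

Initial data are segmented Gaussians: phenotype `i` occupies a window of
width 10 starting at `10(i−1)` (the last window extended to `L`) with
density `A_i exp(−B (x − x_i⁰)²)`. The amplitudes are not uniquely
determined by the published constraints (`p(0,·) ≤ p̄`, comparable across
weight variants); the package's reconstruction is **`A_i = p̄/ω_i`**, the
unique simple rule that (a) attains `p = p̄` at each window's left edge,
(b) produces the *same* initial pressure profile for every `ω` variant,
which is what makes the measured speed invariant across variants. `A_i`
is overridable in every config. Consequence to be aware of: with this
reconstruction the three- and four-phenotype baseline speeds computed
here are ≈0.411 and ≈0.345 (all three routes agree within 1%), a couple
of percent below the rounded values quoted alongside the original
figures; the discrepancy is consistent with finite-resolution bias in the
published numerical estimates and with the unknown amplitudes, and no
parameter was adjusted to chase the quoted values.

## Lattice model

One synchronous step of length `τ`:

1. Freeze the state; compute `p_j` and all event probabilities from it.
2. Per site and phenotype, split the count into (left, right, stay)
   movers by a chained binomial — `n_L ~ Bin(N, m_L)`, then
   `n_R ~ Bin(N − n_L, m_R/(1 − m_L))` — an exact multinomial split,
   distributionally identical to per-cell uniform draws (tested against
   per-cell frequencies at 4 SE).
3. Division/death is drawn per mover group with the *origin* site's
   pressure; daughters (or removals) are applied at the destination.
   Movement and division are independent within a step, matching the
   product form of the lattice balance equation to O(τ).
4. Moves off `[0, L)` are aborted (the cell stays): zero-flux walls.

Initial counts are `round(n_i(0, x_j) Δx)` (floor available). Replicates
use independent streams spawned deterministically from one root seed.
The hot loop is compiled (numba) for the built-in growth law and only
touches sites up to one cell beyond the rightmost occupied site; custom
growth laws fall back to a slower vectorised numpy path with identical
distribution. Phenotypes with `α_i = 0` conserve their integer count
exactly, every step, every replicate.

Lattice sites sit at cell centres `x_j = (j + ½)Δx` so that the IBM and
the PDE solver share a grid and can be compared pointwise without
interpolation (the half-cell shift relative to the conventional `jΔx`
lattice affects no measured quantity).

## Continuum solver

Cell-centred finite volumes, first-order upwind in space, explicit Euler
in time:

* edge velocity `u_{j+½} = −μ_i (p_{j+1} − p_j)/Δx`, flux `u · n_upwind`;
* boundary edge fluxes zero; fluxes telescope, so `α_i = 0` masses are
  conserved to ≤10⁻¹⁰ relative over the full horizon;
* reaction `n ← n (1 + dt α_i G(p))` with start-of-step pressure;
* adaptive `dt = 0.9 Δx²/(2 max_i μ_i · max_j p_j)`, capped by the
  reaction sub-limit `0.1/(α₁|G(0)|)`, truncated to land exactly on
  report times. Under this bound the update is positivity-preserving in
  exact arithmetic; rounding-level undershoots (< 10⁻¹² of the phenotype
  density scale `p̄/ω_i`) are clipped to zero, anything worse aborts.

The published solver's appendix details are not available; first-order
upwind is the standard conservative, segregation-respecting choice for
this equation class. Its main artefact is interface smearing: each
support ends in an exponentially decaying tail, so the interface layer
where adjacent supports overlap is 1–2.5 length units wide at `Δx = 0.1`
(it does not widen over time). Two measurement defaults absorb this:

* **support threshold** `10⁻³ p̄/ω_i` (not smaller), which sits above the
  tail and localises the support edge `X_i` to ~2 cells;
* the kink location `x_k` is taken as the midpoint of the interface
  layer (between `n_i`'s right edge and `n_{i+1}`'s left edge); the
  one-sided slope on the curved rear side (`p'' ≈ −2000` per unit near
  the interface) is estimated by extrapolating a cubic fitted on
  `[x_k − 2.5, x_k − 0.5]` to `x_k`, while the linear far side uses a
  straight fit on `[x_k + 0.5, x_k + 1.5]`.

## Travelling-wave solver

Ahead of `z = 0` everything is closed-form in `c`: interface pressures
`p(z_i) = sqrt(2c Σ_{j>i} (ω_j/μ_j) M_j)`, piecewise-linear pressure with
slope `−c/μ_i`, widths from the interface pressures, leading width
`sqrt(2 ω_I μ_I M_I / c)`. Behind it the rear ODE
`−c p' − μ₁ (p p')' = α₁ G(p) p` is integrated (RK45, rtol 10⁻⁹, event
location by sign change) from the unstable manifold of the saddle at
`p = p̄`: starting offset `10⁻⁶ p̄` along the eigenvector of the positive
root of `μ₁ p̄ λ² + c λ + α₁ G'(p̄) p̄ = 0`, stopping when `p' = −c/μ₁`.
The matching residual `p(0⁻) − p(0⁺)` is strictly decreasing in `c`
(rear value falls, front value grows like `sqrt(c)`), so bisection with a
geometrically expanded bracket finds the unique root; `xtol = 10⁻¹²`
keeps the rear/front pressure mismatch below 10⁻⁸ p̄.

Degenerate inputs: `α₁ = 0` (or a non-decreasing growth law) admits no
front and raises; at large `c` the rear profile can decay to zero without
ever reaching the kink slope ("pulled" regime) — since `p` is monotone,
dropping below the front value already proves the residual negative, so
the solver stops there instead of integrating the slow tail.

## Speed measurement

Front position `x₁(t)`: rightmost downward crossing of the level
`0.2 p̄` (levels `0.4 p̄`, `0.6 p̄` agree within 2% once the wave is
established), located by linear interpolation. Speed: least-squares slope
over the second half of the run, `t ∈ [75, 150]` — the transient is over
by `t ≈ 30`, and fits over `[50,150]` or `[100,150]` move the speed by
< 0.1%. The published protocol states "after the transient" without a
window; the half-run window is this package's choice.

## Synthetic data and what green tests establish

There is no external data: every input is generated by `segwave.scenario`
from the baseline parameter sets above, which *are* the published
conditions. The generator emulates segregated Gaussian colonies with
peak pressure `p̄`; it does not emulate unsegregated initial data,
spatially varying parameters, or 2-D/3-D geometry, so the tests establish
propagation (not emergence) of segregation, in one dimension, for the
stated parameter ranges. The acceptance suite asserts the published
two-decimal speed values as printed; where the reconstructed amplitudes
make the computed value round differently (0.41 vs 0.42 at `I = 3`,
analytic 0.345 vs 0.35 at `I = 4`) the test is left failing rather than
loosened, with the three-way internal agreement tested separately.

The continuum-limit check refines `Δx = 0.4 → 0.2 → 0.1` with
`τ ∝ Δx²` (two refinements ending at the published resolution) and
requires the sup-norm pressure discrepancy at `t = 10` between the
rep-averaged lattice model and the PDE solution to fall monotonically.
The PDE reference is computed once at `Δx = 0.025` and conservatively
block-averaged onto each lattice grid: comparing the IBM against a PDE
run at its *own* `Δx` would cancel the two matching discretization
biases and leave only Monte Carlo noise, which grows under refinement.
Measured: 0.026 → 0.011 → 0.004 of `p̄`. Refining below `Δx = 0.1` is
out of budget on one CPU.
The lattice/continuum comparison at `t = 150` uses the published
ensemble size (10 replicates) for the three-phenotype baseline; with 3
replicates the near-interface discrepancy signal is buried in Monte
Carlo noise.

## Known limitations

* First-order accuracy: front speeds at `Δx = 0.1` carry ≈ +0.5%
  discretisation bias (Richardson extrapolation of 0.4177/0.4128 at
  `Δx = 0.2/0.1` recovers the analytic 0.4106).
* The measured-`p(0)` speed route (pressure at `X₁` inserted into the
  mass relation) inherits the interface smearing and underestimates `c`
  by 5–10% at `Δx = 0.1`; it is recorded in experiment manifests as a
  diagnostic, while the shooting solver is the quantitative route.
* Scenarios violating the segregation assumptions (non-monotone `μ`,
  growth in several phenotypes) are accepted for simulation with a
  warning, but the wave solver refuses them: the theory predicts no
  common-speed segregated front there.
* Continuous phenotype spectra, phenotypic switching, adhesion, and
  higher dimensions are out of scope.
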