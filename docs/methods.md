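# Methods

## Forward model

The oxidized form of a single-electron outer-sphere probe (bulk
concentration c_b, mol/cm³) diffuses one-dimensionally toward a planar
electrode:

    ∂c/∂t = D ∂²c/∂z²,      z ∈ [0, L],  c(z, 0) = c_b,  c(L, t) = c_b.

At the electrode (z = 0) the Butler–Volmer condition ties the diffusive
flux to the instantaneous overpotential of the triangular sweep E(t):

    D ∂c/∂z|₀ = k₀ [ c|₀ e^(−α x) − (c_b − c|₀) e^((1−α) x) ],
    x = F (E − E_f⁰) / (R T).

Only the oxidized species is integrated; the reduced species' surface
concentration is c_b − c|₀, which assumes equal diffusivities of the two
forms and a closed surface mass balance. The Faradaic current is
i = F·ECSA·D·∂c/∂z|₀ with the IUPAC sign convention (anodic positive); the
cathodic first sweep of the default protocol therefore starts negative.
The model is Faradaic-only: no double-layer (capacitive) current, no
uncompensated resistance, no migration or convection, and 1-D planar
geometry. Consequences: simulated background currents are zero, so
background-sensitive data-side quantities (e.g. peak-to-background ratios
of measured voltammograms) are never simulated, only computed from data.

The domain length follows the semi-infinite safety rule
L = 6·√(2·D·|E_R − E_L|/v): six diffusion lengths of the full sweep, so the
far-field Dirichlet node never feeds the depletion layer appreciably.

### Discretization

Space: 500 equally spaced nodes (default), node 0 on the electrode.
Interior nodes use the standard conservative second-difference (on a
uniform grid the finite-volume and finite-difference stencils coincide).
The electrode node is a conservative half-cell balance,

    (Δz/2)·dc₀/dt = D (c₁ − c₀)/Δz − J_BV(c₀, E),

with the Butler–Volmer flux J_BV taken implicitly in the surface
concentration and evaluated at the new-step potential; the far node is
Dirichlet. This keeps every step a single tridiagonal solve (Thomas
algorithm, O(n)) while making the discrete species balance exact: the
change of the trapezoidal concentration integral equals the time integral
of (far-field influx − electrode flux) to round-off, and the test suite
asserts closure to 0.5 % of c_b·L. The half-cell treatment was chosen over
folding the flux condition into an algebraic one-sided-gradient row: the
algebraic variant is O(Δz) at the boundary and changed peak currents by
≈1.1 % between 500 and 1000 nodes, while the half-cell variant changes
them by ≈0.13 % and reproduces the reversible Randles–Ševčík peak to
0.2 %. The reported current is i = −F·ECSA·J_BV, identical to the
discrete D ∂c/∂z|₀ up to the (tiny) half-cell storage term.

Time: backward Euler. The recorded step is E_step/v (0.1 s at the 10 mV /
100 mV/s defaults) and is subdivided into `substeps_per_Estep` implicit
substeps (default 10, i.e. Δt = 10 ms). Backward Euler is
unconditionally stable and first-order; at the default Δt the reversible
peak current is converged to well under 1 %. The dimensionless
overpotential x is clamped to ±50 before exponentiation — e±50 ≈ 5×10²¹
is far beyond any physical overpotential in the ±0.6 V window and the
clamp only guards pathological GA candidates from overflow.

ECSA, not the geometric area A_g, multiplies the current: ECSA is a
decision variable of the inverse problem and must influence the forward
model to be estimable. A_g (default 12.56 mm²) only converts current to
current density (µA/mm²) for reporting.

### Default study conditions

| quantity | default | note |
|---|---|---|
| c_b | 1×10⁻⁵ mol/cm³ (10 mM) | probe concentration of the reference assay |
| E_f⁰ | −0.25 V | midpoint of the observed peak region vs the pseudo-reference; a config input, never fitted |
| window | −0.6 … +0.1 V | simulation window; configurable (measurements are also reported to +0.2 V) |
| v | 0.1 V/s | scan rate |
| E_step | 10 mV | recorded potential increment |
| start | +0.1 V, negative sweep | bulk species is oxidized, so the first sweep is cathodic |
| cycles | 1 | configurable; multi-cycle features are averaged per cycle |
| T | 298 K | room temperature |
| grid | 500 nodes | grid-independence asserted in tests (250→500→1000) |

## Feature extraction

Per cycle, I_ox is the current maximum on the anodic sweep (dE/dt > 0),
I_red the minimum on the cathodic sweep, and E_pp = |E_ox − E_red|.
Features are averaged across cycles when a multi-cycle trace is supplied
(mirroring the usual practice of reporting a mean of three cycles). Each
sampled extremum is refined by the vertex of a parabola through its three
neighbouring samples (`refine_peaks=True` by default): with 10 mV recording
steps the raw peak potentials are quantized to the step, which would make
E_pp a staircase function of the kinetic parameters; the refinement makes
the three features smooth in the parameters at negligible cost. A moving
average (`smooth_window`, in samples) is available for noisy measured
traces; it is off by default and never applied to simulated traces. A
monotonic sweep (no interior extremum) raises an error rather than
returning a boundary value.

Misfit is expressed as signed percent relative errors
ΔX = 100·(X_exp − X_sim)/X_exp for X ∈ {I_ox, I_red, E_pp}, with I_red
compared signed (both values are cathodic-negative, so the sign cancels in
the ratio). All three components use the percent scale so the
multi-objective search treats them commensurately.

## Inverse problem

Minimize (|ΔI_ox|, |ΔI_red|, |ΔE_pp|) over (D, k₀, α, ECSA) within box
bounds. The optimizer is an elitist non-dominated-sorting GA (NSGA-II
style): fast non-dominated sorting, crowding distance, binary tournament,
simulated binary crossover (η = 15, p = 0.9) and polynomial mutation
(η = 20, p = 0.25/variable), population 32, 40 generations — one repeat
completes in seconds to minutes on one CPU depending on grid and step
settings. D, k₀ and ECSA are searched on a log₁₀ scale (they span decades;
default bounds D ∈ [10⁻⁷, 10⁻³] cm²/s, k₀ ∈ [10⁻⁵, 1] cm/s,
ECSA ∈ [0.01, 1] cm²); α is linear in [0.3, 0.7]. A candidate whose forward
simulation fails receives an infinite-penalty error vector and a logged
warning; the run aborts only if an entire generation is penalized.

After the final generation the non-dominated front member with the
smallest Euclidean norm of the three error magnitudes is the *elitist*
(ties: smaller |ΔE_pp|, then smaller D). The search is repeated three
times (repeat r seeded with base seed + r); the headline estimate is the
per-parameter median of the repeats' elitists and the reported dispersion
is the maximum relative deviation from that median. The three errors are
combined unweighted on their common percent scale. Everything is
deterministic for a fixed seed.

### Identifiability — what a single-scan-rate CV can and cannot pin down

For semi-infinite diffusion the forward map has an exact continuous
symmetry: the current of the whole voltammogram is

    i(t) = F·ECSA·c_b·√(π D f v) · χ(ψ, α, θ(t)),   ψ ∝ k₀/√(π D f v),

so the transformation (D, k₀, ECSA) → (s·D, √s·k₀, ECSA/√s) leaves i(t)
*exactly* invariant for every s > 0. The domain rule L = 6√(2D·span/v)
deliberately places the simulation in this regime, and the only symmetry
breaking — the fixed finite domain — perturbs the three features by less
than ~0.2 % even a factor of 3 from the truth. Three features (indeed,
the entire single-scan curve) therefore determine only the combinations

    ECSA·√D,   k₀/√D,   α,

and not D, k₀, ECSA individually. Empirically the GA reproduces exactly
this picture on noise-free synthetic targets with bounds one decade either
side of the truth: elitist error norms reach ~0.2–0.8 % while individual
D estimates scatter by 50–400 % along the valley; the invariant
combinations are recovered to a few percent and α to ~2 %. Increasing the
budget (population 64 × 250 generations) does not collapse the valley —
the objective differences along it are below 10⁻³ % and the crowding
mechanism actively preserves spread there. The corresponding round-trip
acceptance test is therefore expected to fail for the individual
parameters and is kept at face value; the identifiable combinations are
asserted alongside it and do recover. When α and ECSA are fixed, the
(D, k₀) subproblem is well posed and the GA matches an exhaustive 40×40
log-grid search to within one grid cell (tested). Practical remedies —
outside this package's present scope — are joint fitting across several
scan rates with a shared finite film thickness, or constraining ECSA by an
independent measurement.

## Assay statistics

**4PL calibration.** y = d + (a−d)/(1+(x/c)^b), fitted by least squares to
group mean responses with `scipy.optimize.curve_fit` on a log-concentration
axis for conditioning (parameters reported on the natural scale).
Self-start: asymptotes from the responses at the concentration extremes, c
from the concentration nearest the mid-response, b from a logit-linearized
slope regression, with sign restarts on non-convergence. The
parametrization has the exact relabelling symmetry
(a, b, c, d) ↔ (d, −b, c, a); a self-started fit may return either
orientation of the same curve, `FourPLParams.flipped()` converts between
them, and the EC50 c is invariant. Noise-free refit recovery of both
reference parameter sets is asserted to 0.1 % up to this symmetry. R² is
computed on group means. Flat data (a ≈ d) raise an unidentifiable-slope
error; fewer than 4 distinct concentrations are rejected.

**Inverse prediction.** x = c·((a−d)/(y−d) − 1)^(1/b), defined on the open
response interval between the asymptotes, verified against a bisection
oracle.

**Limit of detection (IUPAC).** Concentration groups are scanned in
ascending order and Welch-tested (two-sided, α = 0.05) against the
lowest-concentration group, which serves as the blank/reference; the first
significant group with ≥ 3 replicates supplies the response SD, and
LOD = 3.3·SD/|dy/dx| with the derivative of the fitted 4PL at that
concentration. The slope conversion is what makes the figure comparable in
pg/mL; a zero local slope or an absence of any significant group raises an
error rather than returning a sentinel. The reference group choice (blank
vs lowest spiked level) is a convention; the lowest group is used here.

**SNR.** (I_target − I_background)/(I_interferent − I_background) per
interferent plus the mean across interferents; invariant under common
additive shifts of all three signals, undefined when an interferent equals
the background.

**Brown–Anson surface concentration.** Implemented verbatim as
γ = 4RT·I_ox/(A_g·F²·v·ECSA) with I_ox supplied as a current density in
µA/mm² and converted to total current through A_g (equivalently: the
density reading divides out the same A_g). For the reference inputs
(I_ox = 12.6 µA/mm², v = 0.1 V/s, ECSA = 0.1125 cm², A_g = 12.56 mm²,
T = 298 K) direct substitution gives γ ≈ 119.3 nmol/cm², not the
25.1 nmol/cm² quoted in the biosensing literature for this electrode —
neither unit reading of the printed formula reproduces that figure. The
implementation does not force agreement: the result object carries the
computed value together with an explicit statement of the unit
interpretation used.

## Synthetic data

`generate_synthetic_cv` is the forward simulator plus i.i.d. zero-mean
Gaussian noise on the current only (a fixed seed is bitwise reproducible;
zero noise is bitwise identical to `simulate_cv`). It emulates the
reference measurement conditions listed above. What it does *not* emulate:
capacitive background and its drift, iR drop, potential-dependent noise,
electrode fouling between cycles, temperature fluctuations, or replicate
electrode-to-electrode variability. Passing round-trip tests on these
fixtures therefore demonstrates the correctness of the solver/optimizer
loop under the model's own assumptions, not robustness to the systematic
artefacts of real potentiostat data.

## Problem sizes and tolerances used in the tests

Oracle checks that need unquantized peaks (Randles–Ševčík, √v scaling,
E_pp limits) run at 2 mV recording steps; search-behaviour tests
(determinism, grid-search oracle, budget monotonicity) run on a reduced
model (250 nodes, 5 substeps, the default 10 mV steps) because they compare
the GA against oracles through the *same* forward model, making the
discretization level immaterial. The round-trip acceptance experiment runs
at the full default conditions (500 nodes, 10 mV steps, 10 substeps,
population 32 × 40 generations × 3 repeats per interface). Tridiagonal
solves are compared to dense solves at 10⁻¹² relative; species accounting
at 0.5 % of c_b·L; grid convergence at 1 % of the peak current.

## Known limitations

- Single-species, equal-diffusivity, Faradaic-only 1-D model (see above).
- The GA estimates D, k₀ and ECSA only up to the scaling symmetry of
  single-scan-rate voltammetry; report and interpret ECSA·√D and k₀/√D.
- The 4PL self-start assumes monotone dose-response group means; severely
  non-monotone data will fail the fit rather than be reordered.
- LOD requires replicate-level data (≥ 3 replicates in the significant
  group); it is not defined from group means alone.
- No gradient-based refinement after the GA and no joint multi-trace
  fitting.
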