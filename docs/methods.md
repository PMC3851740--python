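# Methods

This note records the model content, the parameter conventions, and every
numerical or design choice that was genuinely open, in enough detail that a
reader can judge what the package's outputs do and do not show.

## Scaling model

**Taper and tissue laws.** Distance from the apex x (m) maps to diameter
d (mm) through d = γx^δ; each tissue property is a power law of diameter.
The bundled parameter sets (`params.PINE`, `params.ASPEN`) carry the bases
and exponents for xylem area (α₁, β₁), phloem area (α₂, β₂), xylem and
phloem nitrogen mass fractions (α₃, β₃; α₄, β₄), conduit radii
(β₅ = β₆ = 0.25, bases arbitrary) and conduit lumen fractions
(β₇ = β₈ = 0, i.e. size-independent). Conduit bases being arbitrary means
every conductance in the package is a *relative* quantity; only the axial
shape and the height scaling of conductances are meaningful, never their
absolute values (the transport module anchors absolute scales separately,
see below).

**Pipe model and furcation.** Summed sapwood cross-section is conserved
across branching and proportional to leaf area. The furcation number is
n(x) = A_sw(d(L))/A_sw(d(x)); without heartwood this is (L/x)^{δβ₁}
exactly. Note a consequence that is easy to get backwards: capping the
sapwood *reduces* the basal sapwood area and therefore reduces n at every
height above the transition — a capped tree supports fewer unit pipes, less
leaf area, and less total phloem than the no-heartwood tree of the same
height. The tests assert this direction.

**Heartwood.** Sapwood is the outermost annulus of radial depth
`r_sw_max` (default scenario 2 cm) of the *xylem* radius, taken as the
equivalent radius √(A_x/π) rather than half the over-bark diameter so bark
is never counted as wood. For large diameters A_sw → 2π·r_sw_max·r, i.e.
A_sw ∝ d asymptotically. Heartwood nitrogen is a scenario dial
(`hw_nitrogen_fraction` ∈ [0, 1]): 0 and 1 bracket reality; a literature
mean across species is about 0.76.

**Tissue densities.** Nitrogen amounts need mass per volume: wood density
400 kg m⁻³ and living-bark density 1000 kg m⁻³ by default, configurable on
`ScalingParams`. They scale nitrogen totals linearly and cancel from every
fitted exponent.

**Whole-tree totals.** Without heartwood each total is an incomplete power
integral evaluated in closed form (the integrand n·P(d(x)) is a power of
x). The closed forms are re-derived from the integrals and verified against
independent adaptive quadrature to <0.01% in the tests; quantities with
heartwood are integrated by composite trapezoid on a log-spaced grid with
grid-doubling refinement (relative tolerance 1e-4, cap 2¹⁶ points).

## Fitted exponents and sampling conventions

Two conventions matter more than one might expect, because several key
quantities are only *near*-allometric:

- **Axial exponents** (profile fields vs distance from apex) are log–log
  OLS fits on a grid **linear in path length** (200 points by default).
  For pure powers the grid is irrelevant; for the kinked heartwood profiles
  equal-length weighting is the convention that mirrors how a profile
  sampled uniformly along a harvested stem would be fitted, and it is the
  convention under which the capped 10 m pine phloem profile fits to
  ≈ −0.46 (a log-spaced grid overweights the apical decades and gives
  ≈ −0.60 for the same curve).
- **Height-scaling exponents** are log–log OLS over log-spaced height
  grids. The default range is 1–25 m. Capped-sapwood quantities approach
  their asymptote slowly (the annulus correction decays only as 1/r), so
  their exponents are fitted over 20–100 m, where the annulus regime is
  established: there sapwood volume fits L^2.00 and leaf nitrogen L^1.00
  (their analytic asymptotes are δβ₁/2 + 1 and δβ₁/2), while a 5–30 m fit
  of the same sapwood-volume curve gives 2.11. Every `ExponentFit` carries
  its fit range precisely because of this range dependence.
- L₀ = 0.1 m is the apex cutoff below which no measurements exist; tissue
  properties are simply not evaluated closer to the apex. (For aspen phloem
  nitrogen the steep β₄ = −0.80 makes the integral sensitive near the apex
  and a cutoff of 1.0 m is the appropriate choice when that quantity is the
  target.)

## Synthetic measurement data

The generator emulates the harvested-segment tables: diameters log-uniform
on 0.9–276.2 mm (the measured distribution is strongly right-skewed;
median ≪ mean), each response B·d^E times multiplicative lognormal noise
with unit median. Per-response noise CVs (A_x 0.10, A_p 0.30, bark 0.45,
nitrogen 0.35–0.40, distance 0.30) were chosen so ln-scale refits land in
the R² ranges the measured regressions report; measured residual variances
are not published, so R² is the only calibration available. What the
generator does **not** emulate: within-tree topology, per-tree random
effects, correlated responses on the same disk, or periderm structure
(whole-bark nitrogen is mixed from the phloem law and a fixed 0.4%
periderm value — plumbing, not science). Consistency handling: the fitted
whole-bark and phloem laws cross below ~7 mm, so the whole-bark column is
raised to max(A_b, A_p); the under-bark diameter comes from the bark
annulus with a floor. Consequently every scaling-relevant response
round-trips exactly in the noise-free limit, while the descriptive
whole-bark column is slightly biased at the small-diameter end.

Fitting offers the raw-scale nonlinear estimator (the convention for these
allometries, initialized from ln-OLS) and ln-OLS. On wide diameter ranges
the raw estimator is dominated by the largest segments and has visibly
larger small-sample variance under multiplicative noise; the ln estimator
is the one whose consistency the tests quantify. Species comparison is
ANCOVA on the ln scale (single model, species × ln d interaction), with
unadjusted pairwise p-values plus a Holm-adjusted column.

## Transport model

**Structure.** One axis from apex to base; in the pipe-model coordinate
every branch tip sits at the apex distance, so all loading (leaves) is
lumped at the apex node and the distributed-canopy case is out of scope.
The xylem carries the whole transpiration stream (the small phloem
counter-current is neglected in the xylem balance); the phloem carries
sugar basipetally. Water-potential equilibrium P_p − RTc = ψ_x holds at
every node (osmotic coefficient 1, T = 293 K). Gravity enters both columns
(9.81 kPa m⁻¹): it opposes xylem ascent and aids phloem descent.

**Steady-state solution.** With loading and unloading given, the sugar
flux through each segment is fixed by conservation, so the steady state
reduces to one apex-to-base recursion: volumetric flow = flux / upwind
concentration; turgor drop = flow × viscosity-corrected segment resistance
− hydrostatic gain; next concentration from equilibrium. The inner
viscosity fixed point per segment converges in a handful of iterations.
This is mathematically the same steady state an iterative damped-Picard
scheme would find, but direct, deterministic, and with one unambiguous
failure mode: if the recursion drives concentration to zero the imposed
sugar flux is physically unsustainable at that conductance (the viscous
flow would need more pressure than the osmotic column can supply), which
is exactly the "sap viscosity builds up and export fails" regime; the
error reports the node and the concentration maximum.

**Boundary closure and anchors.** The steady state needs one concentration
boundary condition; the package fixes the source (leaf) sieve
concentration. Its default is derived from three physiological anchors
rather than picked directly: sink (root) turgor 0.1 MPa (the classic
near-dissipated Münch sink), the calibrated leaf-root turgor difference
0.7 MPa, and the isohydric leaf water potential −2.0 MPa, giving
RT·c_leaf = 2.8 MPa ⇒ c_leaf ≈ 1.15 kmol m⁻³ (≈ 39% w/w sucrose, ~1.2 MPa
leaf turgor — concentrated but consistent with conifer sieve sap under
such xylem tension). Absolute conductance scales: the xylem scale is set
so the 10 m reference tree transpires 1 kg m⁻² leaf day⁻¹ at the isohydric
potential; the phloem scale is calibrated by log-bisection so the
reference tree under root unloading reaches the 0.7 MPa turgor difference,
separately per heartwood scenario. Dimensionless outputs (allocation
optima, normalized profiles, relative turgor trends) are invariant to both
anchors, and a test asserts the invariance for the allocation optimum.

**Viscosity.** Sap viscosity = water viscosity (Vogel correlation in T)
times exp(2.09·w + 6.14·w²) in sucrose mass fraction w — a two-parameter
fit to tabulated 20 °C sucrose-solution data, good to a few percent up to
w ≈ 0.45 (it underestimates beyond ~50%, a regime the solver only reaches
on the way to a reported failure). Solution density ≈ 997 + 385·w kg m⁻³
converts molarity to mass fraction. The law is monotone and convex, which
is all any qualitative conclusion relies on.

**Unloading.** "root": the full load exits at the basal node. "uniform":
equal flux per unit path length (node weights = half the adjacent segment
lengths, source excluded). Unloading per unit phloem volume is a
conceivable alternative reading of "evenly along the pathway"; it makes
the flux profile depend on the allocation being optimized and degenerates
the allocation search toward the apex, so per-length is implemented.

## The three simulations

1. **Axial gradients** (10 m pine, 2 cm cap by default): the solver output
   is summarized by where the drops sit — with root unloading ~60% of the
   phloem turgor drop occurs in the basal half (71% without heartwood,
   whose phloem conductivity is more apex-concentrated), while the xylem
   potential gradient in the apical tenth is ~4× the basal tenth.
2. **Optimal allocation**: A_p,tot is reshaped to ∝ x^θ at exactly the
   reference tree's phloem volume (trapezoid on the solver grid; conduit
   taper and lumen fraction per unit area are retained), the model re-solved
   per θ over a 13-point grid on [−1, 0.5], and the minimizer refined by
   bounded golden-section to Δθ = 0.005. The turgor-difference curve is
   shallow near its minimum (≈1% over ±0.08 in θ), so reported optima are
   sensitive to model detail at the few-hundredths level. With the default
   anchors the optima are θ ≈ −0.20 (root unloading) and θ ≈ −0.46
   (uniform).
3. **Height sweep** (2–50 m): per height, transpiration follows from the
   isohydric budget E = K_x,tot·(ψ_soil − ψ_leaf − ρgL), assimilation
   A = E/WUE with WUE = 250 mol H₂O per mol CO₂, and sucrose loading
   A/12. The scenario-calibrated phloem scale is multiplied by 0.5/1/2.
   Infeasible heights and failed solves are flagged rows, never dropped.
   With low phloem conductance and no heartwood, export fails above ~15 m;
   doubling conductance restores export everywhere tested.

## Sensitivity sweep

β₁–β₆ and δ are drawn independently, uniformly within ±25% of their base
values, and the sapwood cap log-uniformly on 2–200 cm (a linear draw is
available; the sampling law for the cap is not specified by the study
design, and log-uniform spreads draws evenly across its two decades).
Curves are normalized at the 10 m reference before pointwise min/max
envelopes are taken; the unperturbed curve is included in the envelope by
construction. Library default 1000 draws; the test suite exercises 60.

## Known limitations

- The lumped-apex source is the strongest structural simplification. The
  uniform-unloading allocation optimum is the quantity most sensitive to
  it: distributed unloading removes sugar flux (hence any sensitivity of
  the objective) near the base, pinning the optimum near θ ≈ −0.46 for any
  physiologically plausible parameterization of this structure, whereas
  spreading the source over even ~1 m of crown path moves it to ≈ −0.35.
  Conclusions about that optimum's exact value should be read with this in
  mind; its ordering relative to the root-unloading optimum and to the
  measured allocation is robust.
- Transients, cavitation, starch buffering, active loading, and radial
  membrane resistance are all out of scope; equilibrium coupling is
  instantaneous by assumption.
- Near-allometric height scalings mean every quoted height exponent is a
  (range, convention) pair, not a constant of nature; the package always
  reports the range.
- The synthetic data are a statistical stand-in: passing recovery tests
  demonstrates estimator correctness under the stated noise model, not
  that the noise model captures real segment data.
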