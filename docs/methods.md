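# Methods

## Scope and model reduction

`dissectflow` covers the parts of a 4D-flow-informed dissection-CFD
workflow that do not need patient geometry or a 3D solver: target
derivation, outlet-parameter calibration through a 0D surrogate, inlet
plane processing, and the post-processing metric suite. The 3D
Navier–Stokes solve itself (and everything that depends on the luminal
geometry — segmentation, meshing, FBP localization along a centerline) is
out of scope; where the full workflow would verify calibrated parameters
in 3D, this package verifies them in the same 0D network used for tuning.

## Flow and pressure targets

Measured mean branch flows `Q̄′_B` within an anatomical group Γ define
fractions `φ_B = Q̄′_B / Σ_Γ Q̄′`; targets are `Q̄_B = φ_B · Q̄′_Γ` with
`Q̄′_Γ` the flow loss between aortic planes bracketing the group. Using
the inter-plane loss rather than the raw branch measurements suppresses
per-branch measurement error while preserving the measured split, and
makes the targets conserve mass by construction (`Σ Q̄_B = Q̄′_Γ`
exactly). Minor branches (segmental arteries, IMA) sit below image
resolution; their group targets are sums of per-branch literature
(Doppler) flows shipped as an editable config. Within a group the default
is equal per-branch flow — known left/right and vertebral-level asymmetry
is deliberately not modelled, consistent with the constant-diameter
treatment of these vessels.

Aortic pressure targets come from a single brachial cuff reading through
the empirical peripheral-amplification relation `P_s = 0.83 P′_s +
0.15 P′_d`, `P_d = P′_d`. Values are kept at full precision internally
(138/81 mmHg gives 126.69 mmHg systolic); a presentation helper rounds to
integer mmHg (127/81, pulse 46).

## The 0D network

Each (grouped) outlet is a three-element Windkessel: proximal resistance
`R_p = ρ R_tot` in series with distal `R_d = (1−ρ) R_tot` and compliance
`C` to a venous reference (default 0 mmHg — the calibrated tables are
consistent with `R_tot · Q̄` ≈ one common perfusion pressure, implying a
zero reference). All outlets share a single aortic node fed by the
periodic inflow `Q_in(t)`. States are the capacitor pressures; the node
pressure follows algebraically from flow conservation, so `Σ_i Q_i =
Q_in` holds to machine precision at every step rather than to integrator
tolerance.

The branch ODEs are linear with constant coefficients; they are advanced
with backward Euler (unconditionally stable, first order) at `dt = 1 ms`,
with the step snapped so an integer number of steps tiles the period. The
system matrix is LU-factorized once per simulation. Whole cycles repeat
until systolic and diastolic node pressures both change by less than a
relative threshold between consecutive cycles (default 1%, both in the
same cycle); non-convergence within a configurable cycle budget raises an
error carrying the per-cycle history. Initial capacitor pressures default
to the diastolic target when known, which shortens the transient without
changing the converged cycle.

Units are clinical throughout the 0D side: mmHg, mL/s, mmHg/(mL/s),
mL/mmHg, s.

### Verification

The integrator is checked against the closed-form WK3 input impedance
`Z(ω) = R_p + R_d/(1 + jωR_d C)` on single-harmonic inflows (amplitude
within 0.1%, phase within 1°), against the Ohmic steady state under
constant inflow, and by dt-refinement (halving 1 ms changes the pressure
extrema by <0.1%).

## WK3 calibration

At periodic steady state the capacitor carries no mean current, so each
outlet's cycle-mean flow is `(P̄ − P_ven)/R_tot` — the mean split depends
only on the total resistances, not on ρ, C or waveform shape. The tuner
exploits this structure:

1. `R_tot,i = P̄₀ / Q̄_i` with `P̄₀ = P_d + (P_s − P_d)/3`, so the split
   is satisfied by construction and stays satisfied under the global
   scalings below;
2. total compliance initialized from the two-element estimate `SV / PP`
   and distributed as `C_i ∝ 1/R_tot,i`, giving all outlets one RC time
   constant — the regularity visible in the packaged calibrated tables
   (≈1.35 s for the non-iliac rows);
3. alternating global scalings: all resistances by a common factor to move
   the mean pressure toward the mean implied by matching both extrema, and
   all compliances by a common factor to move pulse pressure toward
   target, re-simulating to periodicity each iteration until systolic and
   diastolic are within tolerance (default 1 mmHg; flows within 3%
   relative). On this linear network both scalings are monotone, and the
   scheme converges in a handful of iterations (≤30 enforced).

ρ is never tuned; it is per-outlet-class config input (0.030 supra-aortic,
0.280 renal, 0.056 elsewhere by default).

Tuning simulations run to a tighter periodicity (0.1% cycle change) than
the production 1% criterion: the mean-flow/resistance identity above holds
only at true periodic steady state, so a loose criterion would alias
residual transient into apparent flow error. With the defaults,
closed-loop recalibration of the full 16-outlet set reproduces all mean
flows and both pressure extrema within ~0.6% (bound used for acceptance:
3%). `wk3_from_anchor` exposes the same structure in closed form: given
one calibrated row, any other outlet's parameters follow from
`R_tot,i = R_a Q̄_a / Q̄_i`, `C_i = C_a R_a / R_tot,i`.

The compliance-distribution rule is an interpretation inferred from the
regularity of the calibrated tables, not a uniquely determined choice;
it is isolated in one place and documented as such. The iliac rows of the
minor-branch case imply a slightly lower perfusion pressure (≈91.9 vs
≈98.6 mmHg) than every other row; consistency checks anchor to the
dominant pattern.

## Inlet plane mapping

The measurement plane moves and tilts over the cycle. Registration maps
each frame rigidly onto the reference: best-fit plane (centroid +
total-least-squares normal via SVD, sign oriented along the stated
normal), minimal rotation aligning the normals, then the residual
in-plane rotation from closed-form 2D orthogonal Procrustes over
corresponding points. Velocities rotate with the points; the transform is
returned for audit. Registration is an isometry (pairwise distances
preserved to 1e−9) and recovers generator-applied motions to 1e−6.
Non-rigid in-plane deformation is not modelled.

Temporal resampling is periodic per-point interpolation (linear default,
periodic cubic spline optional) onto a uniform grid of `ceil(T/dt)`
points; the last-to-first interval wraps with the period. The normal
convention: the reference normal points along bulk systolic flow, and all
sign-dependent quantities (forward/reverse, R/F, FLEF) inherit it.

Plane quantities use mm / m/s / mm²; the through-plane flow
`Q = Σ (v·n̂) A` is numerically in mL/s without conversion factors
(1 m/s · 1 mm² = 1 mL/s). Weak velocity divergence in measured data is
reported by a diagnostic (`net_flux_report`), never corrected.

## Metric suite

- Forward/reverse decomposition: strictly positive projections sum to
  `Q_F`, magnitudes of strictly negative ones to `Q_R`; zero projections
  contribute to neither; `Q = Q_F − Q_R` identically.
- `R/F = Q_R/Q_F` per instant; the cycle value is the trapezoid time
  average over the periodically closed frame grid. Instants with zero
  forward flow are excluded with a warning by default (strict mode
  raises); the average then runs over the valid span. FLEF is the cycle
  R/F across the primary entry tear, in percent.
- TMP: trapezoid mean of `P_TL − P_FL` over one cycle; the peak is the
  instantaneous value of largest magnitude with sign preserved, earliest
  instant winning ties (the tie rule is a package choice; peaks of either
  sign occur in practice). Swapping lumina negates both outputs.
- TAWSS/OSI/ECAP per node from the WSS vector history on a uniform grid
  (default every 5 ms, snapped to tile the cycle), trapezoid with periodic
  closure. Nodes with `∫|τ|dt = 0` are 0/0 in the OSI formula; they are
  reported as OSI = 0, ECAP = 0 with a degenerate flag (a no-shear node is
  not oscillatory). ECAP ≥ 1.4 Pa⁻¹ marks thrombotic susceptibility.
  5 ms vs 1 ms sampling differs by <1% on smooth histories.
- Carreau–Yasuda viscosity with editable constants (defaults are the
  widely used whole-blood set: μ0 = 0.056 Pa·s, μ∞ = 0.0035 Pa·s,
  λ = 3.313 s, a = 2, n = 0.3568; density 1056 kg/m³).
- Turbulence check: `Re_p = ρ V D / μ(γ̇_nom)` with nominal shear rate
  `V/D` (configurable), Womersley number `α = (D/2)√(ωρ/μ)`, and a
  configurable power-law critical Reynolds correlation
  `Re_c = K α^p St^q` (defaults K = 169, p = 0.83, q = −0.27); a
  literature `Re_c` can be supplied directly and overrides the
  correlation. Turbulent iff `Re_p > Re_c`.
- Bland–Altman: bias = mean difference, limits = bias ± 1.96 sample SD.
- Velocity errors: peak and signed mean discrepancy of velocity
  magnitude, normalized by the mean inlet velocity at peak systole and
  expressed in percent. The exact normalization of published error tables
  for this workflow is not uniquely fixed; this definition is isolated in
  one function so alternates can be swapped.

## Synthetic data

Generators emit already-quantified fields (no voxel data) with ground
truth recorded pre-noise:

- Inflow: a systole-dominated shape (sin² lobe over 36% of the cycle, a
  small retrograde valve-closure dip) projected onto a configurable number
  of Fourier harmonics and scaled to cycle mean `SV·HR/60`. Defaults:
  94 bpm, SV 69.9 mL → mean 109.5 mL/s, matching the scale of the
  calibrated outlet tables. Zero harmonics gives constant flow.
- Plane series: equal-area sunflower sampling of a disc (default radius
  15 mm, 400 points, 16 frames); a contiguous angular sector carries
  reverse flow, so per-frame `Q_F`/`Q_R` are exact sums over assigned
  areas, and with equal speeds `R/F = f/(1−f)` for realized fraction `f`.
  Frames are optionally carried through a known rigid motion (sinusoidal
  tilt about an in-plane axis + translation).
- WSS histories mix three archetypes with closed forms: constant direction
  (OSI 0), fully reversing sinusoid (OSI 0.5, TAWSS `(2/π)τ0`), and
  offset sinusoid `(m + o sin ωt)ê` with `o > m > 0`, for which
  `TAWSS = (2/π)(m asin(m/o) + √(o²−m²))` and `OSI = (1 − m/TAWSS)/2`.
- Pressure pairs: luminal difference `d + a sin(2πt/T)` on a pulsatile
  baseline, so `TMP_mean = d` and `TMP_max = sign(d)(|d| + a)` exactly.

What the generators emulate: pulsatility at the study heart rate, the
16-frame acquisition cadence, prescribed retrograde fractions, rigid plane
motion, optional Gaussian noise mimicking poor low-velocity signal. What
they do not: realistic luminal cross-sections, jet/recirculation
structure, spatially correlated noise, non-rigid plane deformation, or any
geometry coupling between planes. Passing the round-trip suites therefore
demonstrates correctness of the numerics and conventions, not clinical
accuracy on real anatomies.

## Problem sizes and tolerances

The shipped configurations are small by nature (11–16 outlets, 400-point
planes, tens of WSS nodes, ≤ a few hundred cycles of a ≤16-state linear
ODE), so every test and the acceptance script run in seconds. Key
numerical tolerances: mass conservation 1e−8 relative (achieved at
machine precision by construction), impedance-oracle agreement 0.1%,
registration round-trip 1e−6, tuning 1 mmHg / 3% with ~0.6% achieved,
trapezoid-vs-closed-form agreement on metric integrals at the documented
grid densities.
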