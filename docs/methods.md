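# Methods

This note documents the models, numerical choices and deliberate
simplifications behind `lcxlc`, in the order the pipeline runs.

## Units and conventions

All quantities are normalized at construction/parse time to minutes, µL,
µL/min, mm (column length and bore), µm (particle size, plate height), bar
and mPa·s. ²D flows given in mL/min in configuration files (`*_ml_min` keys)
are converted on input.

φ always denotes the volume fraction of the *strong* eluting solvent of the
dimension at hand — water for HILIC, acetonitrile for RP-LC. Because the two
strong solvents are opposite, transferring ¹D effluent to the ²D flips the
convention: the ²D-strong fraction of HILIC effluent is 1 − φ₁. This flip is
performed in exactly one place (`sample_solvent_composition`), which also
applies the volume-weighted make-up blend, to prevent silent sign errors.

## Retention and gradients

Two laws are supported: LSS (k = k₀·e^(−Sφ), RP-LC) and adsorption
(k = k₁₀₀·φ^(−n), HILIC). The adsorption law diverges at φ = 0; direct
evaluation there is a domain error, while internal code paths clamp φ at
10⁻⁹, which simply renders the analyte immobile in pure weak solvent.

Gradient retention solves ∫₀^(tR−t₀) dt/(t₀·k(φ_in(t))) = 1, where φ_in is
the programmed linear ramp delayed by the dwell time (dwell volume / flow)
plus any initial hold, and held at the final composition indefinitely
afterwards — analytes still in the column elute under the final isocratic
condition. The integrand is sampled on a grid that always contains the ramp
break-points (no trapezoid cell straddles a kink), the crossing is located by
interpolation of the cumulative integral, and the grid is doubled until the
retention time moves by less than 10⁻⁴ min. Agreement with the closed-form
LSS solution tR = t₀ + (t₀/b)·ln(1 + b·k_init), b = SΔφt₀/t_grad, is at the
10⁻⁵ relative level (checked over k₀ ∈ [5, 500], S ∈ [5, 40],
t_grad ∈ [5, 60] min). If the integral has not reached 1 within the horizon
— default 10 × (t_grad + t₀ + delay) — the analyte is flagged "not eluted"
rather than clipped.

The exit-side local retention factor k_e is the law evaluated at the
composition present at the outlet at elution, i.e. the inlet composition one
unretained traversal (t₀) earlier.

Parameter fitting minimizes the sum of squared retention-time residuals over
3–4 gradients (slopes differing ~3×) with Nelder–Mead simplex on
log-parameters, seeded from the best point of a 12 × 12 log-spaced grid over
(k₀ or k₁₀₀) × (S or n). Noise-free round trips recover parameters to ≪ 1%;
fewer than two distinct gradient slopes is an error (the two parameters are
not identifiable from a single slope).

## Theoretical performance metrics

- **Injection variance**: σ²_v = (V²_inj/δ²_inj)·((1+k_e)/(1+k_ss))², with
  δ²_inj = 8; σ²_t = σ²_v/F². k_ss is evaluated in the blended sample
  solvent. A hook exists to substitute a user-supplied variance function;
  only this equation ships.
- **Column variance**: σ = G·t₀(1+k_e)/√N with the gradient compression
  factor G defaulting to 1 (off). The cited compression correction is not
  printed in our sources, so it ships disabled but configurable; note the
  Craig simulator produces compression naturally (see limitations).
- **Band variances add**: column + injection + extra-column (defaults 17 µL²
  for the ¹D path and 3.8 µL² post-column for the ²D; pre-column ²D
  broadening is assumed nullified by focusing).
- **Peak capacities**: n_c = 1 + (t_last − t_first)/(4σ̄) per dimension, the
  window ending at the *predicted last-eluting analyte*, not the programmed
  gradient end; the ¹D value is divided by the undersampling factor
  β = √(1 + 0.21(t_s/σ₁)²); n_c,2D is the plain product (coverage/
  orthogonality corrections are out of scope). σ̄ is the arithmetic mean of
  per-analyte σ. The ²D window is capped at the cycle time.
- **Dilution**: DF = DF₁·DF_mu·DF₂ per analyte, averaged; DF_i =
  √(2π)·σ_v,i/V_inj,i (peak-maximum dilution in volume units) and DF_mu =
  (F₁+F_mu)/F₁.
- **Pressure**: Darcy ΔP = φ_res·η·L·u/d_p², with a shipped η(φ_ACN, T)
  node table for water/acetonitrile at 30 and 60 °C (linear interpolation;
  values representative of published mixture-viscosity data). Feasibility
  uses the worst-case viscosity over the gradient span.
- **Modulation geometry**: eluent fraction F₁·t_s, total fraction
  (F₁+F_mu)·t_s, loop fill fraction; overfilling the loop is a hard
  infeasibility.

## Craig elution-profile simulator

The ²D column is discretized into N cells, N taken from the van Deemter
plate count at the candidate flow (capped at a configurable `n_max`, default
20 000, with a warning). One transfer step lasts t₀/N and consists of
(1) shifting all mobile contents — analyte mobile fraction *and* solvent
composition — one cell toward the outlet, recording the mass leaving the last
cell, and (2) re-equilibrating each cell to mobile fraction 1/(1+k(φ_cell)).
Solvent propagates unretained (scalar composition per cell, no uptake
isotherm). The inlet is fed first by the injection profile, then by the
dwell-delayed gradient; the gradient clock is additionally offset by the
injection (loop-flush) duration, since the loop contents precede the pump
stream at the column inlet. The run stops early once essentially all
injected mass (1 − 10⁻⁹) has eluted; profiles not fully eluted at the
horizon are returned flagged. The simulator contains no randomness:
identical inputs give bit-identical profiles, whether the inner loop runs
under numba or the NumPy fallback.

For an isocratic column and a unit pulse the cell occupancy after n steps is
exactly binomial, C(n−1, r)p^r(1−p)^(n−1−r) with p = 1/(1+k); the
implementation matches this closed form to machine precision and conserves
mass identically at every step.

**Injection profile model.** The flushed loop is modeled as a sample plug of
volume fill·V_loop at the loop outlet, preceded (for partial fills) by
loop-resident mobile phase — the counter-current, first-in-last-out flush
order. Exponential dispersion with a *volume* constant (default
0.15·V_loop) smears both plug interfaces; this constant is a modeling
choice, explicitly tunable, not a measured value. Measured valve profiles
can be imported from CSV and used verbatim. The solvent track carries the
sample composition inside the plug and the mobile phase elsewhere. Analyte
mass is normalized to exactly 1.

**Profile analytics.** Apex (grid argmax), first/second moments by discrete
quadrature, half-height width by linear interpolation of the 50% crossings
around the *global* apex (converted to σ via 2.355), and a split-peak count:
local maxima with prominence ≥ 5% of the global maximum, where adjacent
maxima are merged unless the valley between them drops to ≤ 80% of the lower
one.

## Optimization

Configurations are the Cartesian product of candidate values, filtered by:
pressure in both dimensions (column and instrument caps), loop capacity
((F₁+F_mu)·t_s ≤ V_loop), and ²D cycle closure (t_s ≥ ²D gradient time +
re-equilibration, default 0.1 min). When no explicit ²D gradient candidates
are given, the ²D gradient fills the cycle (t_grad,2 = t_s − re-equil). No
constraint ties the sampling time to an integer divisor of the ¹D window;
fractions are taken on the fixed t_s grid wherever the peaks fall. An empty
feasible set raises an error reporting per-constraint rejection counts.

Each analyte's ²D evaluation uses the *single* fraction containing its ¹D
apex; V_inj is the total fraction volume. Multi-fraction splitting is
handled only in the chromatogram builder, not the metrics — one ²n_c per
analyte. For simulated evaluations, the ²D retention time is the profile
apex, and the *second-moment* σ enters the capacity/dilution metrics (robust
to deformed peaks), with the half-height σ reported alongside in the
moments; only post-column extra-column variance is added, since column and
injection broadening are intrinsic to the simulation.

Pareto filtering keeps the non-dominated set under (max n_c,2D, min time,
min dilution); exact objective ties are all retained, output sorted by
(time, −n_c,2D). The hybrid algorithm evaluates the full grid theoretically,
simulates only the front (|front| × |analytes| simulations — the entire
computational saving), and re-filters; dropped points are reported, as they
are exactly the configurations whose simulated injection broadening no
longer justifies their theoretical rank.

## Synthetic analytes and what they do not show

`generate_synthetic_analytes` draws log-uniform parameters emulating small
phenolic compounds on amide/C18 sub-2 µm phases: ¹D adsorption k₁₀₀ ∈
[0.1, 2], n ∈ [0.5, 3]; ²D LSS k₀ ∈ [5, 300], S ∈ [8, 30]; van Deemter a ∈
[2, 4] µm, b ∈ [1, 5] µm·mm/s, c ∈ [0.1, 0.5] µm·s/mm. A seed fixes all
randomness; the simulator and optimizer are seed-free. Synthetic sets
reproduce the *structure* of an experimental analyte table, not any specific
measured compound set: passing tests demonstrate the algorithms' contracts
(exactness, conservation, dominance, hybrid agreement), not predictive
accuracy for a particular real sample, which requires measured retention and
plate-height parameters.

## Problem sizes

Default test and acceptance runs use 1000–2000 Craig cells, 3–5 synthetic
analytes and candidate grids of ≤ 27 configurations — sizes chosen so the
full-simulation oracle route stays cheap enough to run alongside the hybrid
route it validates. All contracts are size-stable: the binomial oracle is
exact at any N, and the Gaussian-limit recovery is tested at the N where its
asymptotics (≲ 2% bias at k = 50) are well inside the 5% band.

## Known limitations

- **Craig broadening at low k.** The Craig model's variance for an isocratic
  solute is (tR²/N)·k/(1+k): at k ≳ 20 it matches plate theory to a few
  percent, but weakly retained solutes broaden *less* than van Deemter plate
  counts imply (an unretained solute moves deterministically). Simulated ²D
  peak widths for analytes eluting at low k_e are therefore optimistic
  relative to the theoretical σ = t₀(1+k_e)/√N — one reason the two
  evaluation routes are only compared in regimes chosen to isolate the
  injection effects.
- The simulator naturally includes gradient compression; the theoretical
  route (G = 1) does not. Comparisons between routes are therefore made
  either isocratically or on like-for-like simulated values.
- ¹D peaks are Gaussian (no ¹D overload simulation); only the ²D is
  simulated.
- No axial dispersion beyond intrinsic Craig broadening, no nonlinear
  isotherms, no frictional-heating/radial-temperature modeling.
- Analysis time is the ¹D retention time of the last-eluting analyte,
  including any post-gradient isocratic elution — deliberately not clipped
  to the programmed gradient.
- Fractions render at the midpoint of their sampling window on the ¹D axis
  of predicted chromatograms.
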