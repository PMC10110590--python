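# Methods

## Scope and assumptions

`cowflow` models the cerebral arterial circle as a steady-state resistive
network. The choices behind that reduction:

* **Laminar flow.** Reynolds numbers in the large cerebral arteries sit in
  the 100–500 range; flow is treated as laminar throughout, with the
  tortuosity and entrance corrections capturing the dominant departures
  from fully developed Poiseuille flow.
* **Stationary.** No pulsatility, wall compliance, or inertance. The model
  answers questions about mean flows and pressures; transient phenomena
  (and with them Windkessel-type outlets) are out of scope.
* **Newtonian blood.** Constant dynamic viscosity μ = 3.5 mPa·s — the
  high-shear asymptote of the Carreau–Yasuda law, which is the regime the
  large cerebral arteries operate in. The C-Y law itself
  (η₀ = 0.16 Pa·s, η∞ = 3.5 mPa·s, λ = 8.2 s, a = 0.64, n = 0.2128) ships
  as a utility for shear-dependent viscosity estimates, not in the network
  loop. Density ρ = 1050 kg/m³ enters only through Re.
* **No junction losses.** Energy dissipation in bifurcations and
  confluences (recirculation, impinging jets) is not modelled; it matters
  most when communicating arteries carry large collateral flows, which is
  where the model is least accurate (see Limitations).

## Network

18 named segments (ICA, VA ×2; BA; M1, A1, A2, P1, P2, PCoA ×2; ACoA) with
length, diameter, and bend curvature radius from the bundled reference
geometry; four inlets held at 93 mmHg; six terminal beds. Long curved
segments use the tortuosity correction, the short proximal/communicating
segments (A1, P1, PCoA, ACoA) the entrance correction — the assignment is
per segment, stored in the geometry record. Positive PCoA flow runs
anterior → posterior (ICA terminus toward the posterior junction); signs in
all outputs follow each segment's stored orientation.

Two outlet modes:

* **fixed beds** (CFD-matching mode): terminal resistances 4.22×10⁹ (P2),
  3.52×10⁹ (M1), 7.04×10⁹ (A2) Pa·s/m³ per outlet, draining to 10 mmHg;
* **regulated beds**: the ideal-autoregulation controller below, draining
  to 0 mmHg. The 0 mmHg drain is what makes the tabulated resistance
  bounds consistent with the 50/150 mmHg window (50 mmHg / 162 ml·min⁻¹ ≈
  0.31 ≈ R_min of the middle territory); the 10 mmHg venous offset of the
  fixed-bed mode would shift the saturation point visibly. Both drains are
  configurable per bed.

Stenosis semantics: `apply_stenosis(net, name, s)` scales the whole
segment's diameter by (1−s). The lumped model has no sub-segment
localization, so a focal plaque and a uniform narrowing of the same
diameter fraction are indistinguishable; severity 1 removes the segment
from the circuit entirely (occlusion), rather than leaving a near-singular
resistance in the matrix.

## Solver

Node potential method: pressures at non-fixed nodes are unknowns; each
patent segment and each bed contributes a conductance; inlet and drain
potentials enter the right-hand side. The assembled system is solved with
`numpy.linalg.solve` (≈14 unknowns). Unknown nodes with no conductance
path to any fixed potential are detected before factorization and reported
in a structured error.

Nonlinear mode iterates: solve → per-segment flows and Re → target
resistances from the correction formulas → under-relaxed update
(ω = 0.5) → repeat, until the maximum flow change per iteration falls
below `rel_tolerance` (default 10⁻⁸, relative to the largest network
flow, with an absolute floor of 10⁻¹¹ m³/s ≈ 6×10⁻⁴ ml/min so that
zero-flow configurations terminate). Initialization is the
Hagen–Poiseuille solution; the fixed point is empirically independent of
the start (tested from 2× HP) and matches a brute-force scalar root-find
on series toy networks to better than 10⁻⁸ relative. Default iteration cap
200; on the reference network the solver converges in ~25 iterations,
well under a millisecond of linear algebra per solve.

Re uses |Q|: the corrections are dissipative and direction-symmetric, and
the flow sign is carried separately.

## Autoregulation

Each territory's bed follows the ideal characteristic
`R = clip((P_attach − P_drain)/Q_target, R_min, R_max)` with per-side
targets 111 (anterior), 162 (middle), 120 (posterior) ml/min and bounds
0.46–1.31, 0.32–0.90, 0.44–1.20 mmHg·min/ml respectively; the window
limits are 50 and 150 mmHg for every territory. The bed updates are
interleaved with the segment-resistance updates in the same fixed-point
loop (shared convergence test) rather than nested, which avoids
inner-loop stalls near the saturation boundary. Bed resistances start at
mid-range so that edited anatomies (occlusions, overrides) start inside
the bounds.

Classification recomputes the unclipped required resistance from the
converged perfusion pressure: WITHIN if it lies in [R_min, R_max] (to a
10⁻⁶ relative guard), BELOW_LOWER if dilation has saturated at R_min,
ABOVE_UPPER at R_max. Exit detection in
`find_autoregulation_exit` is therefore resistance-saturation based; the
equivalent pressure-threshold reading is available from the reported
perfusion pressures and APR values. With the bundled middle-territory
numbers the two criteria differ slightly (saturation at
0.32×162 ≈ 51.8 mmHg vs the nominal 50 mmHg limit — the tabulated bounds
are rounded), which moves detected exit severities by a point or two.

APR is evaluated at the bed's attach node — the distal end of M1/A2/P2,
i.e. the pressure the terminal bed actually sees.

`find_autoregulation_exit` scans severity in coarse steps (0.02) and
refines the first WITHIN→exit bracket by bisection to `resolution`
(default 0.001), assuming a monotone exit along the sweep (asserted
separately as the APR-monotonicity property). `None` signals that
regulation holds through complete occlusion.

## Scenario engine and fixtures

Scenarios are declarative (edits + optional sweep + mode + regulation
flag) and round-trip through YAML; runs are deterministic with stable row
and column order, so identical configurations produce byte-identical CSV.
Sweep grids are user-chosen; the CLI default is 34 points over [0, 0.99].

`generate_fixture_networks` produces anatomically plausible variants for
testing: every diameter scaled by an independent uniform factor in
[1−p, 1+p], and with probability 2/5 one communicating vessel (ACoA or a
PCoA) removed — the most common incomplete-circle variants. It emulates
geometric variability only: no noise in lengths/curvatures, no fetal-type
posterior circulation, no measurement error model. Convergence of the
solver across this family is a regression property, not a physiological
claim.

## Validation harness

`validate_against_cfd()` recomputes three benchmark cases and compares the
left-M1 flow against bundled finest-mesh CFD reference values
(161.99 ml/min for the physiological circle, 92.52 ml/min with the left
ICA occluded) under nominal error bounds of 2.6% (nonlinear, reference),
9.9% (nonlinear, ICA-occluded) and 14.4% (linear, reference). With the
as-implemented formulas the ICA-occluded (8.5%) and linear (7.6%) cases
sit inside their bounds while the nonlinear reference case measures 4.8%
and honestly fails its 2.6% bound; the harness and the `cowflow validate`
exit status report this rather than masking it. The corresponding
acceptance tests are left failing by design.

## Known limitations

* The correction formulas assume uniform curvature (tortuosity) or a sharp
  entrance (short segments). Applied to the 250 mm ICA with a 10 mm
  curvature radius the tortuosity term is the single largest arterial
  pressure drop in the network; real carotids are curved only along part
  of their course, so the model is conservative (pessimistic) about distal
  perfusion pressure, increasingly so at high Re — e.g. downstream of a
  whole-segment stenosis. This is the main driver of the nonlinear
  reference case missing its nominal CFD bound above, and it shifts
  detected critical-stenosis severities earlier.
* Junction losses are ignored; errors grow when communicating arteries
  carry large collateral flows (severe occlusion scenarios).
* The ideal autoregulation characteristic is a static clip; no dynamic
  response, CO₂ reactivity, or metabolic feedback, and the parameters are
  population-level, not patient-specific.
* Whole-segment stenosis semantics (above) cannot represent focal lesion
  length or post-stenotic dilation.
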