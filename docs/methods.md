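# Methods

`lvadloop` simulates the closed-loop hemodynamics of a heart-failure
circulation supported by a continuous-flow left-ventricular assist device
(CF-LVAD), with dynamic aortic insufficiency (AI) and a tunable degree of
right-ventricular-to-pulmonary-artery (RV-PA) coupling. This note documents
the model, its assumptions, the calibration procedure, the numerical
choices, and what the shipped tests do and do not establish.

## Model

**Topology.** A minimal closed loop in lumped (0D) form: four time-varying
elastance chambers (LA, LV, RA, RV), four valves (mitral, aortic, tricuspid,
pulmonic), four windkessel compartments (systemic arterial/venous, pulmonary
arterial/venous) and the pump connecting the LV apex to the systemic
arterial node in parallel with the aortic valve. There is no baroreflex, no
heart-rate variability and no 3D vascular geometry. Units are mmHg, ml, s
internally; flows are converted to L/min only at the reporting boundary.

**Chambers.** `P = E(t) (V - V0)` with a squared-sine activation between
`E_min` and `E_max`. Atrial activation (onset 0.03, duration 0.14 of the
cycle) precedes ventricular activation (onset 0.17, duration 0.35). With no
source resistance in the chamber law, the beat maximum of `P/(V - V0)`
recovers `E_max` exactly; this makes the end-systolic elastance estimator
trivially consistent and is a deliberate simplification.

**Valves.** Each valve carries a leaflet angle `theta` in
`[theta_min, theta_max]` obeying a second-order pressure-driven ODE
(Korakianitis-Shi style):

    theta'' = k_p * dP * cos(theta) - k_f * theta'

with `k_p = 3.2e5 deg/(s^2 mmHg)` and `k_f = 50 /s`, chosen so that valves
open and close in 20-50 ms and the per-beat closure backflow is a few ml
(physiological closing volume). The effective orifice area follows the
smooth `(1 - cos theta)^2` mapping, and flow obeys the turbulent
(quadratic, Bernoulli-type) law `dP = B(theta) Q |Q|` with
`B ∝ 1/area^2`. Valve flow inertance is carried as a parameter but set to
zero in the assembled loop; the angle dynamics already regularize
transitions, so flows are algebraic in the state.

**Aortic insufficiency** is imposed by raising the aortic `theta_min` above
zero, leaving a permanent regurgitant orifice; a perfect valve has
`theta_min = 0`. The AI phenotype transform additionally scales systemic
vascular resistance by a calibrated severity-dependent factor, representing
the chronic vasoconstrictive compensation of a hypoperfused circulation.
Without a systemic component the published AI phenotypes (high arterial
pressure at low net flow) cannot exist in any model in which mean systemic
flow equals mean pressure drop over resistance.

**Pump.** Centrifugal H-Q characteristic
`H(Q, w) = a w^2 - b Q|Q| - c w Q` (shut-off head quadratic in speed,
strictly decreasing in flow) behind a cannula resistance and inertance, so
pump flow is a state: `L_c dQ/dt = P_lv - P_ao + H - R_c Q`. The
coefficients are calibrated to the study's operating points, not to a
proprietary device datasheet.

## Calibration

The study this package reproduces reports no parameter values (it defers to
an earlier publication); it describes physiological targets and a +/-40%
sensitivity-guided manual adjustment. `lvadloop` replaces that with a
deterministic two-stage least-squares fit (`scripts/recalibrate.py`):

1. **Baseline stage** — knobs: systemic resistance, pulmonary resistance,
   pump shut-off coefficient, total blood volume, RV diastolic stiffness.
   Targets: net flow 5.4 L/min, MAP 85 mmHg, mean PA pressure 22.5 mmHg,
   RV Ees/Ea 1.01, for the coupled no-AI patient at HR 60 and 5,500 RPM.
2. **Catalogue stage** — knobs: pump flow-sensitivity coefficients (b, c),
   cannula resistance, LV contractility, the two aortic minimum angles, the
   two AI systemic-resistance factors, the BP-control factor (bounded to
   the stated 50-60% band) and the two pulmonary uncoupling factors.
   Targets: the published scenario net flows, pump flow, regurgitant
   fractions, coupling ratios, and the three headline management responses
   (+42% speed augmentation, +81% BP control, +113% combined therapy). The
   pump shut-off coefficient is re-derived at every step to preserve the
   baseline operating head, which keeps the two stages decoupled.

The result is frozen into `src/lvadloop/data/calibrated.yaml` and shipped;
all reported quantities are recomputed by simulation from it at run time.

**A known irreducibility.** The published severe-AI columns are mutually
inconsistent with a fixed linear systemic bed: the baseline cell implies a
systemic resistance of ~2.3 mmHg·s/ml (Psa 92 mmHg at 2.1 L/min), while the
baseline-to-speed-augmentation pair implies an incremental slope of ~0.5.
Mean flow through a resistance is exactly mean pressure drop over R, so no
static parameter set reproduces both. The calibration privileges the
management responses and net flows (the quantities the study's conclusions
rest on) and lets the severe-phenotype arterial pressure fall below the
printed 92 mmHg; the comparison report flags those cells rather than hiding
them.

**Scenario transforms** (applied to the calibrated baseline, in this order:
uncoupling, AI, management):

| transform | parameters |
|---|---|
| uncoupling | pulmonary `C x c_unc`, `R x r_unc` (calibrated; Ees/Ea < 0.7 no-AI) |
| AI (mild/severe) | aortic `theta_min`, systemic `R x f_svr` (calibrated) |
| speed augmentation | pump speed 5,500 -> 6,400 RPM |
| BP control | systemic `R x f_bp`, `f_bp` in [0.5, 0.6] (calibrated) |
| pulmonary vasodilation | pulmonary `C x 10`, `R x 0.8` (stated, fixed) |

BP control and pulmonary vasodilation touch disjoint parameters and
therefore commute; the uncoupling transform is idempotent.

## Energetics

RV pressure-volume analysis of the final periodic beat. End-systole is the
instant of peak RV elastance (unambiguous in an elastance model — not a
dP/dt criterion). `Ees` is the beat maximum of `P/(V - V0)`; `Ea` is the RV
pressure at end-systole over total stroke volume — this convention is
applied uniformly, preserving the semantics of the 0.7 coupling threshold,
since the published data do not pin the convention down. Stroke work is the
shoelace loop area, PE the classical end-systolic triangle
`P_es (V_es - V0) / 2`, and `PVA = SW + PE` by construction.

`MVO2 = alpha PVA + beta` with `(alpha, beta)` obtained by least squares
over the published (PVA, MVO2) pairs (`alpha ≈ 2.1e-5 mlO2/(mmHg·ml)`,
`beta ≈ 1.13e-2 mlO2`); the fit reproduces every published MVO2 cell to
within 5e-4 mlO2, which justifies dropping the contractility-dependent term
of the full Suga relation. Mechanical efficiency converts stroke work to
Joules (`1 mmHg·ml = 1.33322e-4 J`) against the caloric equivalent of
oxygen (20 J/mlO2); these two constants reproduce every published
efficiency cell to within 0.002.

## Hemodynamic metrics

Reporting signs follow the published tables: retrograde aortic flow and
per-beat backward volume are negative, regurgitant fraction
(`RF = max(0, -Qao)/Qlvad`) is a positive fraction. Systole/diastole
boundaries come from the LV activation window, not from pressure
crossings. Cannula velocity is pump flow over outflow-graft area
(1.54 cm^2); the S/D ratio uses peak systolic and end-diastolic velocity,
and the diastolic acceleration is the least-squares slope of velocity over
the second half of diastole (fractions 0.5-0.98 of the diastolic interval,
excluding the isovolumic transition) — a documented, fixed convention.

## Numerics

Fixed-step RK4 at `dt = 1e-3 s` (the cycle is divided into an integer
number of steps), with the valve angles projected onto their admissible
interval after each step; this keeps the formulation event-free. The
volume equations form a linear invariant of the vector field, so RK4
conserves total blood volume to round-off. Initial volumes distribute the
stressed volume over nodes in proportion to compliance times a nominal
pressure profile, which lands close enough to the attractor that every
catalogued scenario reaches a periodicity residual below 1e-3 (normalized
per-signal RMS cycle difference, worst signal) within the default 10
cycles. Halving `dt` moves final-beat metrics by well under 0.5%.

Degenerate inputs: a closed valve carries no flow regardless of gradient;
`Ees` is undefined (error) if volume touches `V0`; S/D is reported as NaN
when end-diastolic velocity is not positive; a failed scenario inside the
matrix runner is flagged and the run continues.

## What the synthetic scenarios do and do not establish

The virtual-patient generator perturbs vascular and elastance parameters by
a uniform +/-20% around the calibrated baseline — it emulates inter-patient
spread in afterload, compliance and contractility, not measurement noise,
valve-geometry variation, reflex control or disease progression. A green
invariant sweep (speed up => pump flow up; wider orifice => higher RF;
stable periodic regime) therefore establishes structural robustness of the
model, not clinical validity for any real patient. Likewise the calibrated
catalogue reproduces the study's scenario table within stated tolerances;
it does not validate the underlying physiology beyond that table.

## Known limitations

* No leaflet-resolved valve geometry, jet eccentricity or commissural
  fusion; regurgitant orifice maps smoothly from a single angle.
* No LV energetics reporting; the analysis focuses on the RV.
* RV `Ees` is fixed across speed changes (no septal-shift effect), so the
  small published drifts of EesRV across management columns (0.364 ->
  0.351 etc.) are not reproduced; Ees/Ea differences across scenarios are
  carried entirely by Ea.
* The published severe-AI arterial pressures are irreducible as described
  above; simulated severe-phenotype Psa is lower than printed.
* Wall shear stress and everything 3D is out of scope.
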