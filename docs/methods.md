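# Methods

`norwoodlpn` is a 0D (lumped-parameter) model of the circulation of an
infant with hypoplastic left heart syndrome (HLHS) after stage-I palliation
— a Norwood reconstruction of the aortic arch onto the right ventricle with
a 3.5 mm modified Blalock–Thomas–Taussig shunt (mBTTs) feeding the
pulmonary arteries — and at pre-stage-II assessment (~5 months, before the
bidirectional Glenn). The model is calibrated entirely against pooled
literature data, so it represents a population-average patient at each
time-point, not an individual.

## 1. Literature pooling

Study-level hemodynamic and morphometric measurements (systemic pressures,
Qp:Qs, mean PA pressure, cardiac index, BSA, vessel diameters) are shipped
as two CSV transcriptions of published study tables and pooled per
parameter and stage with a fixed-effect weighted mean.

*Reporting-format conversion.* Records given as median (range) are
converted with the size-stratified range rules: mean = (low + 2·median +
high)/4; SD from the full range-based variance formula for n ≤ 15,
range/4 for 15 < n ≤ 70 and range/6 for n > 70. A quantile-based
alternative (range / (2·Φ⁻¹((n−0.375)/(n+0.25)))) is available behind
`sd_method="quantile"`.

*Weights.* The default weighting is inverse study variance, w_i = 1/sd_i².
When any record in a pool reports no dispersion at all, the whole pool
falls back to sample-size weights w_i = n_i. This combination reproduces
the published pooled table far more closely than textbook inverse-SE²
weights (pre-S2 Qp:Qs 1.287 and diastolic pressure 40.7 versus the
published 1.28 and 40.98; inverse-SE² gives 1.15 and 37.7), so it is the
default; `weighting="inverse_se2"` and `weighting="n"` remain available,
and the inverse-SE² variant is cross-checked against
`statsmodels.stats.meta_analysis` in the test suite.

*Standard errors.* The pooled SE uses Var(Σwᵢmᵢ/Σwᵢ) = Σwᵢ²SEᵢ²/(Σwᵢ)²
with per-record SEᵢ = sdᵢ/√nᵢ, except for median/range-converted records,
whose mean estimate rides on the sample extremes: there SEᵢ = sdᵢ·√(π/(8n)
+ π²/(48·ln n)), the asymptotic standard deviation of (L + 2M + H)/4 for a
normal sample. Without this correction the pooled SE is badly
anticonservative for large-n median/range studies (coverage of |pooled −
μ| ≤ 3·SE drops to ~93% on synthetic tables; with it, ~99.4%).

*Derived closures.* Mean arterial pressure is composed as (systolic +
2·diastolic)/3 when no direct records exist (pre-S2); pulse pressure is
systolic − diastolic; cardiac output is pooled cardiac index × pooled BSA
when not directly reported. The cardiac index (one study, 5.5 L/min/m²) is
taken as stage-invariant, so post-S1 CO = 5.5 × pooled BSA(0.23 m²) = 1.27
L/min. Note the published pooled table prints post-S1 BSA 0.21 m² while
the only post-S1 BSA study reports 0.23 ± 0.02; the package pools what the
study tables contain.

## 2. Geometry → circuit

The arterial tree is the Norwood template: ascending neo-aorta → arch
(two segments) → descending aorta, with right/left carotid and subclavian
branches, and the shunt leaving the arch at the brachiocephalic origin and
feeding the pulmonary junction with left/right PA branches — one inlet,
seven outlets. Diameters come from the pooled tables (post-S1 uses healthy
neonatal PA/descending-aorta diameters, since those regions are not
reconstructed and have not yet remodelled; the reconstructed
ascending-arch region uses the HLHS arch measurement). Lengths are not
reported in the sources; defaults (AAo 15, arch 25, DAo 40, branches and
PAs 20, shunt 20 mm) grow by √(BSA_pre/BSA_post) = √(0.31/0.23) toward
pre-S2, except the PTFE shunt, which is a fixed prosthesis.

Each compliant segment reduces to a π-element: series Poiseuille
resistance R = 8μL/(πr⁴) and inertance L = ρl/A, with half the tube-law
compliance C = 3πr³L/(2Eh) lumped at each end node. Wall stiffness E
derives from distensibility, E = 2r/(hD) with D = ΔA/(A·ΔP), evaluated at
default regional area excursions (graft-stiff arch 8%, native aorta 20%,
PAs 25%, neck branches 15%) under the post-S1 pressure pair; wall
thickness is 1.5 mm on the aorta and PAs and 15% of the local radius on
the neck branches. Blood is ρ = 1.06 g/cm³, μ = 0.04 P (standard neonatal
values; the sources do not state them).

*Shunt.* The shunt is rigid. Suture-line "pinching" reduces the effective
luminal diameter by a fraction p at each anastomosis: d_eff = 3.5·(1−p)
mm. Its pressure-drop law is ΔP = R_v·Q + K·(ρ/2)·(Q/A_eff)²·sign(Q) with
R_v the Poiseuille resistance at the effective radius and K = 2.0 — one
Borda–Carnot-type dynamic-pressure loss per anastomosis. A purely viscous
law cannot produce the tens-of-mmHg trans-shunt gradient observed at
physiological flow; the quadratic term dominates (at 2.9 mm and 16 cm³/s
it contributes ≈47 of ≈52 mmHg).

## 3. The 0D engine

The netlist (resistors, ground-referenced capacitors, inductors, diode
valves, a time-varying-elastance chamber, pressure and flow sources,
nonlinear shunt resistor) is assembled into an ODE system whose states are
capacitive node pressures, chamber volume and the flows of all inductive
branches; storage-free nodes are eliminated by linear nodal analysis at
each right-hand-side evaluation. Integration uses SciPy's BDF with rtol
10⁻⁶ (3·10⁻⁶ during calibration iterations) and per-state absolute
tolerances, cycle by cycle, until cycle-to-cycle periodicity of every
pressure signal (max |P_k − P_{k−1}| ≤ 1% of that signal's pulse pressure)
or a cycle cap. Output is sampled on a uniform grid of T/1000 (all
headline numbers below are computed at this resolution).

*Heart.* The ventricle is an elastance chamber, E(t) = (E_max −
E_min)·e(t) + E_min, with a normalized double-Hill activation (m₁ = 1.32,
m₂ = 27.4, τ₁ = 0.269T; τ₂ defaults to 0.452T and is a calibration knob,
below). The atrium is a fixed pressure source (5.4 / 7.2 mmHg seeds for
post-S1 / pre-S2); both valves are diodes with series resistance and
inertance (33 and 0.667, 10 and 0.1 CGS — published component values read
in the Pa·mm unit system, used as seeds only). Heart rate defaults: 140
bpm post-S1, 120 bpm pre-S2.

*Valve regularization.* A diode is open (series R_open + L) whenever its
flow is positive or its pressure gradient is forward, and closes through a
smooth switch: R_eff = R_open + R_closed·σ(−ΔP/ε_P)·σ(−q/ε_q) with
R_closed = 10¹⁰ dyn·s/cm⁵, ε_P = 10⁻³ mmHg, ε_q = 10⁻⁵ cm³/s. The closed
state leaks |q| ≈ |ΔP|/R_closed ~ 10⁻⁶ cm³/s, far below the 10⁻⁶-of-peak
one-wayness bound asserted in the tests, and keeps the system smooth
enough for BDF.

*Venous references.* Windkessel distal pressures: systemic outlets return
to the right-atrial pressure, pulmonary outlets to a fixed left-atrial
pressure of 6 mmHg (a required closure the sources do not state).

## 4. Two-step calibration

Targets: per-outlet mean flows (Qp = CO·QpQs/(1+QpQs) split LPA:RPA 45:55;
systemic remainder 55% to the descending aorta, the rest equally across
the four neck vessels — no per-branch measurements exist), systemic
systolic/diastolic/mean/pulse pressure, cardiac output (5% band; all
others 10%).

**Step 1** prescribes a synthetic aortic inflow pulse (C¹-smooth squared
half-sine ejection over 35% of the cycle, scaled so the cycle mean equals
the pooled CO) and tunes Windkessel resistances by a damped multiplicative
fixed point: R_i ← R_i·(Q_i/Q_i*)^α·(MAP*/MAP)^α, α = 0.5, until all mean
flows and MAP match. Seeds: R_i = (MAP* − P_ref,i)/Q_i* with the expected
trans-shunt drop subtracted for the PA outlets; R_p:R_d split 5:95
systemic, 10:90 pulmonary; total compliance = stroke volume / pulse
pressure, distributed ∝ flow but with only 15% of it behind the shunt —
the pulmonary beds are decoupled from the aorta by the shunt resistance,
so aortic pulse buffering is almost entirely systemic (the published tuned
values show the same pattern). Step-1 pulse pressure is deliberately *not*
iterated to target: the synthetic pulse is peakier than a real ejection
and its PP floor sits above the target; compliances keep their seed and
are finished in Step 2.

**Step 2** replaces the inflow with the heart and runs a combined damped
refinement: per iteration the resistance/compliance factors above, E_max ←
E_max·(CO*/CO)^0.7 (P_RA adjusted within 3–10 mmHg when E_max saturates),
and the activation decay time τ₂ steered by the waveform duty shape (MAP −
dia)/PP toward the value the pressure targets imply — the
elastance-function adjustment that closes the systolic/diastolic residuals
which pure R/C scaling cannot reach (near equilibrium PP is almost
insensitive to the compliances because systolic and diastolic move
together; a stalled PP inside half its band is accepted). Working
tolerances are 2% so the final deviations sit well inside the 10%/5%
acceptance bands.

**Pinch inverse problem (pre-S2).** With a mean PA pressure target
available, the required trans-shunt drop is pooled MAP − pooled mean PA
pressure (46.8 mmHg from the packaged tables; 46.3 from the published
pooled values). After each refinement pass the cycle-mean drop is measured
at the calibrated operating point and the effective diameter updated
through the quartic dominant scaling of the loss law, aimed so the
simulated PA mean lands on target even while MAP carries its ≤2% residual;
refinement and pinch updates alternate until both settle. The generic
`solve_pinch` bisection operator (used by the interleaved solver's inner
logic and unit-tested against algebraic inversion of the quadratic law)
exploits the verified monotonicity of the drop in the pinch fraction.
Post-S1 has no PA pressure data, so its pinch is fixed at the reported
immediate suture effect of 10%.

## 5. Indices

All indices are computed on the final periodic cycle: pressure extrema and
time averages, pulse pressure, cycle-mean branch flows, Qp:Qs from the
outlet means, Wood-unit resistances (systemic (MAP − P_RA)/Qs, pulmonary
(mean PA − P_LA)/Qp — the report embeds the definitions because the
reference conventions are not uniquely stated), Reynolds numbers Re =
4ρQ/(πμd) (cycle-mean and peak systolic flow, on the pinched shunt
diameter), and Poiseuille wall shear stress 4μQ/(πr³).

## 6. What the synthetic generators emulate

`generate_study_table` draws raw normal cohorts from a known population
mean/SD and reports them in the real tables' mixed formats (mean ± SD with
the genuine sample SD, median with sample min/max, bare mean), so pooling
can be tested against known truth; it does not emulate between-study
heterogeneity, non-normal skew, or correlated parameters, so passing
recovery tests bound only the within-study sampling behaviour.
`generate_inflow_waveform` is a parameterized ejection pulse, not a
measured velocity-encoded MRI waveform; Step-1 quantities that depend on
waveform *shape* (pulse pressure under prescribed inflow) are therefore
surrogate-limited, which is why the pipeline finishes shape-sensitive
calibration with the heart model. The netlist fixtures provide closed-form
benchmarks (RC charging, three-element Windkessel impedance) and the full
stage templates with literature-style seed values.

## 7. Numerical and design choices

- CGS internally (1 mmHg = 1333.22 dyn/cm², 1 L/min = 16.6667 cm³/s);
  clinical units at every interface.
- Damping α = 0.5 and iteration caps (50 per operator) automate what was
  originally a manual tuning loop; every operator logs its deviation trace.
- Degenerate inputs: zero study SD is floored at 1% of the mean; zero-flow
  outlets are excluded with a warning; a pinch target below the unpinched
  drop returns 0 with a warning, an unreachable one raises.
- Simulations warm-start from the previous iterate's final state (or a
  target-pressure seed state), which keeps periodic convergence to 2–4
  cycles during calibration; a cold start takes ~5 cycles.
- Problem sizes: output grid T/1000, ≤10 cycles per simulate call during
  calibration; the full two-stage pipeline is a few hundred short stiff
  integrations (~1–2 minutes per stage on one core).

## 8. Known limitations

- A 0D network cannot reproduce 3D phenomena: high-frequency flow
  oscillations, spatial wall-shear maps, jet impingement, or
  mesh-converged peak Reynolds numbers. Conduit Re and WSS here are
  Poiseuille estimates on cycle statistics.
- A single, stage-independent loss coefficient K = 2.0 closes the shunt
  law. The two stages' reported operating points imply slightly different
  effective K (~2.1 post-S1, ~1.7 pre-S2), so one constant cannot place
  every shunt-sensitive quantity simultaneously: with K = 2.0 the
  calibrated post-S1 surrogate's peak-systolic shunt Reynolds number comes
  out ≈1.98·10³, grazing the 2·10³ turbulence threshold from below, while
  its PA pressure and the pre-S2 pinch solution sit comfortably in range.
- The solved pre-S2 pinch (≈0.15–0.16) is the 0D-equivalent constriction;
  it is consistent with, but not identical to, the 17% per-anastomosis
  narrowing of the 3D geometry.
- Windkessel compliance identification is a global scale; per-outlet
  compliance distributions are design inputs, not identified quantities.
- The loop is open: atrial and venous pressures are fixed references, and
  systemic/pulmonary venous return is not conserved back to the heart.
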