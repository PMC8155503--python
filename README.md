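# norwoodlpn

Population-calibrated 0D (lumped-parameter) hemodynamics of the Norwood
circulation in hypoplastic left heart syndrome (HLHS).

After stage-I palliation (the Norwood procedure) an HLHS infant lives on a
single right ventricle that supplies the body through a reconstructed
aorta and the lungs through a 3.5 mm modified Blalock–Thomas–Taussig shunt
(mBTTs). Catheterisation data are plentiful at the pre-stage-II assessment
(~5 months) but almost absent in the critical first post-operative week —
in particular pulmonary-artery (PA) pressure, which cannot safely be
measured across the shunt. `norwoodlpn` is for modellers and
physiologists who want a desk-scale, fully reproducible estimate of that
hidden state: it pools the published study-level hemodynamics into
population targets, reduces population-scaled vessel geometry to a circuit,
calibrates a heart + Windkessel network to the targets, and reads the PA
pressures, flows and shunt indices off the calibrated model.

The pieces, in the field's standard notation:

- **Fixed-effect pooling** of study records (mean ± SD, bare means, or
  median (range) converted with size-stratified range rules:
  mean = (low + 2·median + high)/4; SD = range/4 or range/6 by cohort
  size), weighted by inverse study variance with a sample-size fallback.
- **Geometry → circuit**: each vessel contributes R = 8μL/(πr⁴),
  L = ρl/A and tube-law compliance C = 3πr³L/(2Eh) with
  E = 2r/(hD) from distensibility; the rigid shunt carries
  ΔP = R_v·Q + K·(ρ/2)(Q/A_eff)²·sign Q on its pinched effective diameter
  d_eff = 3.5·(1 − p) mm.
- **0D engine**: time-varying-elastance ventricle
  E(t) = (E_max − E_min)·e(t) + E_min with a double-Hill activation,
  diode valves with inertance, three-element Windkessels (R_p, C, R_d) at
  all seven outlets; stiff (BDF) integration cycle by cycle until
  cycle-to-cycle periodicity of the pressure field.
- **Two-step calibration**: prescribed inflow → Windkessel resistances to
  outlet mean flows and MAP; then the heart model → elastance and atrial
  pressure to cardiac output (5%) with refinement of all outflow
  parameters to within the 10% bands.
- **Shunt-pinch inverse problem**: with the pre-S2 PA-pressure target
  known, the anastomotic pinch fraction p is solved so the cycle-mean
  trans-shunt drop matches the population-required MAP − mean PA pressure.

See `docs/methods.md` for the model assumptions, parameter defaults and
limitations.

## Worked example

```python
from norwoodlpn import NorwoodLPN

model = NorwoodLPN.from_literature("pre_s2")   # pools the packaged tables
res = model.fit()                              # two-step calibration + pinch solve
print(res.summary())
```

prints (abridged):

```
Norwood 0D circulation - stage pre_s2
==========================================================
converged: True   max index deviation: 3.78%

index                     target    fitted   dev %
--------------------------------------------------
systolic_pressure            102       103    1.15
diastolic_pressure          40.7      42.2    3.78
mean_pressure               61.2      62.4    1.94
pulse_pressure              61.5      61.1    0.58
cardiac_output              1.71      1.71    0.27
qp_qs                       1.29      1.25    2.85
mean_pa_pressure            14.4        14    2.93

shunt: nominal 3.50 mm, pinch 0.156 -> effective 2.96 mm (K=2.00)
...
shunt Reynolds: Re_avg 1807, Re_max 2505
```

Reading: every pooled target (systemic pressures in mmHg, cardiac output
in L/min, pulmonary-to-systemic flow ratio Qp:Qs) is matched within 3.8%;
the inverse problem finds that a ~16% diameter pinch at the shunt suture
lines (effective lumen 2.96 mm) is required to drop the mean pressure from
62 mmHg in the aorta to 14 mmHg in the PAs; and the peak-systolic shunt
Reynolds number of ~2500 sits in the transitional/turbulent regime. The
post-S1 fit (`from_literature("post_s1")`, where no PA data exist and the
pinch is fixed at the reported 10% suture effect) *predicts* a mean PA
pressure of ≈23 mmHg — the key unmeasurable quantity of the early
post-operative period.

`res.waveforms` holds the periodic pressure/flow traces
(`res.waveforms.to_frame()` for a clinical-unit DataFrame,
`res.plot_waveforms()` for a figure), `res.windkessel_frame` /
`res.heart_frame` the tuned parameters, and `res.report.to_json()` the
full index report.

The same workflow runs from the shell:

```bash
norwood-lpn run --stage pre_s2 --out-dir out/pre_s2
norwood-lpn meta --stage post_s1 --out targets.yaml
norwood-lpn build --stage pre_s2 --pinch 0.17 --out netlist.json
norwood-lpn simulate --netlist netlist.json --period 0.5 --out waves.csv
```

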