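# petquant

Quantification pipeline for dynamic brain PET with arterial blood sampling,
plus whole-body internal dosimetry. It targets studies that estimate the
total distribution volume (V<sub>T</sub>) of a reversibly binding,
F-18-labelled radiotracer from a 120-min dynamic scan with a
radiometabolite-corrected arterial plasma input function, assess test-retest
reliability, and derive organ radiation doses from sequential whole-body
scans. Everything needed to exercise the pipeline without patient data is
included as seeded synthetic-data generators with known ground truth.

## What it computes

**Input function.** Whole-blood and total-plasma samples are fitted with a
linear rise to the peak followed by a tri-exponential decay; the parent
(unmetabolised) fraction of plasma activity is a mono-exponential anchored at
1 at injection. The metabolite-corrected input is
C<sub>p</sub>(t) = plasma(t) · e<sup>−k<sub>m</sub>t</sup>. Running
integrals and exponential convolutions of this input are evaluated in closed
form. A small PET-vs-blood clock shift (±30 s) is estimated from the
composite cortical curve.

**Compartment models.** One- and two-tissue compartment models with a fixed
5% fractional blood volume:

C<sub>model</sub> = (1 − v<sub>B</sub>) · h ⊛ C<sub>p</sub> + v<sub>B</sub> · C<sub>blood</sub>,  h(t) = K₁e<sup>−k₂t</sup> (1TCM) or the two-exponential 2TCM response from K₁, k₂, k₃, k₄.

V<sub>T</sub> = K₁/k₂ (1TCM) or K₁/k₂ · (1 + k₃/k₄) (2TCM). The preferred
model is chosen by the Akaike information criterion, AIC = n ln(RSS/n) + 2k.

**Logan graphical analysis.** The late-time (t ≥ t*, default 40 min) slope
of ∫C<sub>T</sub>/C<sub>T</sub> against ∫C<sub>p</sub>/C<sub>T</sub>
estimates V<sub>T</sub> without compartmental assumptions, regionally or
voxel-wise, over full, shortened or split ("coffee-break", 0–60 plus 90–120
min) acquisition windows.

**Reproducibility statistics.** TRV = 2(V<sub>T</sub><sup>test</sup> −
V<sub>T</sub><sup>retest</sup>)/(V<sub>T</sub><sup>test</sup> +
V<sub>T</sub><sup>retest</sup>), its absolute value aTRV, the one-way
intra-class correlation ICC = (BSMSS − WSMSS)/(BSMSS + WSMSS), inter-subject
%COV, and Bland-Altman agreement.

**Dosimetry.** Organ time-activity curves (fraction of injected activity,
physical decay included) are fitted with half-time-parameterised
bi-exponential, uptake-washout or uptake-plateau forms; normalized cumulated
activities (NCA, MBq·h/MBq) come from the closed-form integral, a trapezoid
rule with a physical-decay tail, or the ICRP-30 gastrointestinal chain
(small → upper large → lower large intestine, transfer coefficients
6/1.8/1 day⁻¹) driven by the fraction entering the small intestine. Organ
doses are a contraction of NCAs with a user-supplied S-value matrix and the
effective dose applies the ICRP-60 tissue weights.

## Worked example

```python
from petquant import (fit_compartment, fit_input_function, logan_vt, select_model)
from petquant.simulate import (REFERENCE_2TCM, brain_schedule,
                               generate_input_function, generate_tissue_tac)

samples, truth = generate_input_function(seed=7)       # arterial samples
inp = fit_input_function(samples)                      # fitted input function
tac, gt = generate_tissue_tac(REFERENCE_2TCM, truth, brain_schedule(),
                              noise_level=0.05, seed=7)
f1 = fit_compartment(tac, inp, "1tcm")
f2 = fit_compartment(tac, inp, "2tcm")
print(select_model(f1, f2).selected, f2.vt, logan_vt(tac, inp, t_star=40.0).vt)
```

prints (formatted):

```
true VT            : 7.000
1TCM  VT=4.888  AIC=201.3
2TCM  VT=6.966  AIC=116.6  K1=0.295 k2=0.142 k3=0.043 k4=0.018
selected model     : 2tcm (delta AIC = -84.8)
Logan VT (t*=40min): 6.345  (r^2 = 0.99884, 10 points)
```

The two-tissue model recovers the generating V<sub>T</sub> = 7 to within the
noise level and is strongly preferred by AIC; the graphical estimate sits a
few percent lower (its slope carries the 5% blood-volume fraction and a
small noise-induced negative bias), mirroring how the two estimators relate
on real data.

A `petquant` console script exposes the same stages from the shell
(`fit-input`, `fit-kinetics`, `logan`, `logan-voxel`, `trt`, `dosimetry`,
`simulate`); see `petquant --help`.

## Layout

- `src/petquant/tac.py` — frame schedules, TACs, decay correction, NIfTI/CSV I/O
- `src/petquant/input_function.py` — arterial fits, metabolite correction, closed-form integrals, delay
- `src/petquant/kinetics.py` — 1TCM/2TCM simulation and fitting, AIC selection
- `src/petquant/logan.py` — Logan transform, acquisition windows, voxel maps, time stability
- `src/petquant/reliability.py` — TRV/aTRV/ICC/%COV/Bland-Altman
- `src/petquant/dosimetry.py` — organ curves, NCAs, ICRP-30 GI chain, effective dose
- `src/petquant/simulate.py` — seeded synthetic generators with ground truth
- `docs/methods.md` — modelling assumptions, defaults and limitations
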