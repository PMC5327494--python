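# ironmap

Quantitative MRI analysis of tissue iron overload in preclinical (mouse)
imaging: T2/T2*/T1 relaxometry, spleen volumetry, left-ventricular cine
function, and the relaxation-rate-to-iron calibration — together with a
digital phantom that simulates all of the underlying acquisitions with
known ground truth.

Paramagnetic iron stores (ferritin, hemosiderin) shorten the MR relaxation
times T1, T2 and T2\*, which makes relaxometry the standard non-invasive
probe of cardiac and hepatic iron in β-thalassemia. Translating it to
mice is hard (600 bpm heart rate, 1 mm myocardium, T2\* below 1 ms in
loaded tissue), and studies in this space rarely deposit raw scans.
`ironmap` is for researchers who need the full analysis chain as tested,
reusable code: it fits the models used in that literature, and its phantom
generates synthetic cohorts at published group means so every stage can be
validated against ground truth.

## Models

* Transverse decay, fitted to ROI-mean signal at each echo time TE by
  Nelder–Mead least squares:

  S(TE) = S₀·exp(−TE/T2) + C      (T2\* substituted on gradient-echo data)

  with C ≥ 0 absorbing the magnitude-noise floor. Cardiac T2\* is fitted
  on the intraseptal region only.

* Look-Locker inversion recovery sampled every RR interval:

  S(TI) = A − B·exp(−TI/T1\*),  corrected by  T1 = T1\*·(B/A − 1).

* Iron calibration (closed-form least squares; τ₀ fixed to the non-loaded
  group mean):

  iron = K_dry·(1/τ − 1/τ₀).

* Motion-ghosted frames are detected from phase-encode background energy
  (median + 5·scaled-MAD rule) and excluded before fitting.

* Cohort statistics: mean ± SEM, KS normality, one-way ANOVA with
  Holm–Šídák-adjusted pairwise contrasts at α = 0.05.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Simulate a healthy-control mouse cross-section, acquire a 15-echo
gradient-echo series at SNR 30, fit septal T2\*, and convert it to a
tissue-iron estimate:

```python
import numpy as np
from ironmap import phantom, relaxometry as rx
from ironmap.core import gradient_echo_protocol
from ironmap.iron import fit_calibration, predict_iron

ph = phantom.build_mouse_phantom({
    "myocardium": {"t1": 928.0, "t2": 18.0, "t2star": 11.5},
    "liver":      {"t1": 929.0, "t2": 13.2, "t2star": 7.6},
    "spleen":     {"t1": 900.0, "t2": 6.2,  "t2star": 1.5},
}, snr=30.0, seed=7)

series = phantom.simulate_multiecho(ph, gradient_echo_protocol(), snr=30.0, seed=7)
sigma = rx.estimate_noise_sigma(series, ph.labels == 0)
heart = ph.mask("myocardium") | ph.mask("septum")
curve = rx.extract_roi_curve(series, heart, restrict=ph.mask("septum"),
                             noise_sigma=sigma)
fit = rx.fit_transverse(curve, "t2star")
print(f"septal T2* = {fit.params[1]:.2f} ms")

cal = fit_calibration([(0.7, 3.4), (1.1, 2.1), (2.4, 1.0),
                       (4.9, 0.45), (8.0, 0.11), (10.1, 0.03)],
                      tau0=11.5, mode="t2star")
print(f"K_dry = {cal.k_dry:.3f} mg/g per ms^-1")
print(f"iron estimate: {predict_iron(cal, fit.params[1]):.3f} mg/g dry")
```

Output:

```
septal T2* = 11.35 ms
K_dry = 2.567 mg/g per ms^-1
iron estimate: 0.003 mg/g dry
```

The fitted 11.35 ms recovers the simulated healthy myocardial truth of
11.5 ms within 1.3%; because that is essentially the zero-iron baseline
τ₀, the predicted iron is ≈ 0 mg/g dry — an unloaded heart. A loaded
heart (T2\* ≈ 0.7 ms) maps to ≈ 3.4 mg/g on the same curve.

The full study runs end to end from the command line:

```bash
ironmap run --out demo_out --seed 11            # 3 groups x 5 animals
ironmap simulate --out sim_out --seed 1         # write NIfTI series + truth
ironmap fit --series sim_out/humanized_control_00/ge_multite.nii.gz \
            --mask sim_out/humanized_control_00/labels.nii.gz --model t2star
```

`ironmap run` writes `cohort.csv` (per-animal fitted relaxation times,
spleen volume ratio, EDV/ESV/SV/EF/CO, predicted iron), the ground-truth
table, the fitted calibration, and a report directory with group summary
tables, pairwise-contrast tables and annotated bar figures.

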