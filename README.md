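# pbifkit

Population-based input functions (PBIFs) and Patlak analysis for abbreviated
dynamic [18F]-FDG PET protocols.

Quantitative FDG kinetic modeling needs the arterial input function (AIF) —
the plasma tracer concentration over the whole scan. Long axial field-of-view
scanners make a non-invasive image-derived input function (IDIF) from the
descending aorta practical, but still require staying on the scanner for the
full ~65 min post-injection. `pbifkit` implements and evaluates the
alternative: replace the early part of the input function with a
population-averaged shape, scaled to each subject using only a late "tail"
window of image data, so that Patlak net-influx (Ki) estimates survive with
as little as 10–20 min of scanning. A synthetic dynamic-PET generator
(Feng-shaped AIFs with inter-subject variability, irreversible
two-tissue-compartment tissue curves, small 4D phantoms) makes the whole
pipeline testable without any patient data.

It is written for PET physicists and kinetic-modeling researchers who want a
scriptable, reproducible implementation of the PBIF/Patlak workflow.

## The model

The arterial input function is Feng's 7-parameter model (delayed gamma
variate plus two exponentials), with t′ = t − τ and Cp(t) = 0 for t ≤ τ:

    Cp(t) = (A1·t′ − A2 − A3)·e^(−λ1·t′) + A2·e^(−λ2·t′) + A3·e^(−λ3·t′)

Tissue curves follow the irreversible two-tissue compartment model with net
influx Ki = K1·k3/(k2+k3). Patlak graphical analysis plots, after an
equilibration time t*,

    Ct(t)/Cp(t)  =  Ki · ∫₀ᵗCp(s)ds / Cp(t)  +  V

so an ordinary least-squares line through the transformed late frames gives
the slope Ki (ml·g⁻¹·min⁻¹) and intercept V (ml·g⁻¹).

The PBIF is built from a generation cohort of IDIFs: AUC-normalize each,
fit Feng's model, align all fits to the population-mean arrival delay,
average the model curves, renormalize to unit area, refit. A scaled PBIF
(sPBIF) for a new subject multiplies that unit-AUC shape by

    s = AUC_IDIF(ta, tb) / AUC_PBIF(ta, tb)

over a late tail window (35–65 … 55–65 min), which requires only late
images. Because the early ∫Cp then comes from the analytic population shape,
Patlak fits no longer need early dynamic frames at all.

## Worked example

`examples/` contains one narrative script per capability. For instance
`python examples/02_build_and_scale_pbif.py` builds a PBIF from 16
simulated subjects and scales it to a held-out subject:

```
PBIF from 16 subjects, mean delay 0.722 min

sPBIF_55-65: scale factor 648.5 kBq.min/ml per unit AUC
tail AUC 55-65 min  IDIF :    63.63 kBq.min/ml
tail AUC 55-65 min  sPBIF:    63.63 kBq.min/ml
full AUC 0-65 min   truth:    596.3 kBq.min/ml
full AUC 0-65 min   sPBIF:    648.4 kBq.min/ml
```

The tail AUCs agree exactly (that is the construction); the full-curve AUC
differs from the subject's true input function only through
population-shape mismatch (here ~9% — this subject's tail decays unusually
fast for the cohort). `python examples/04_factorial_evaluation.py` then
runs the full factorial evaluation (scaling window × Patlak t*) of tumor Ki
against the IDIF/t*=35 reference on an 8-subject validation cohort; its
first and last rows at t*=35:

```
window  t_star tissue mean_bias precision r_squared  n
 35-65    35.0  tumor    -1.47%     2.40%    0.9991 32
 55-65    35.0  tumor    +0.05%     2.52%    0.9987 32
```

i.e. scaling on the last 10 min of data gives the lowest bias, precision
degrades as t* increases (shorter usable scans), and sPBIF and IDIF Ki
values regress with R² > 0.99 — the behavior the abbreviated-protocol
design relies on. The Wilcoxon signed-rank test on full-curve AUCs is
non-significant for every window (p ≥ 0.195 at n = 8).

The other examples cover input-function fitting (01), Patlak fits across
t* for a single lesion (03), and voxel-wise parametric Ki maps on a 4D
phantom with RC/SSIM/PSNR fidelity metrics (05).

A thin CLI wraps the same stages: `pbifkit run-all --seed 1 --out run/`
writes cohort TACs, the PBIF, the factorial table, AUC tests and parametric
maps with a reproducibility manifest; see `pbifkit --help`.

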