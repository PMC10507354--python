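# roqdce — retrospective quantification of multi-phasic DCE-MRI

Clinical abdominal DCE-MRI acquires four breath-hold phases (one
pre-contrast plus arterial, portal-venous and delayed at ~30-s spacing)
— too coarse for tracer-kinetic modeling, so clinical reads stay
qualitative. `roqdce` implements *retrospective quantification* (RoQ): a
pharmacokinetics-informed neural network temporally super-resolves each
voxel's four phase values back to a 2-s-resolution enhancement curve,
and a simulation-pretrained quantification network then estimates the
standard-Tofts parameters, enabling quantitative perfusion mapping from
standard-of-care protocols. The intended users are quantitative-MRI
researchers studying pancreatic perfusion (healthy pancreas, pancreatic
ductal adenocarcinoma, chronic pancreatitis) and methodologists
benchmarking temporal-interpolation strategies.

## Model

Tissue kinetics follow the standard Tofts model

    Ct(t) = Ktrans · Cp(t) ∗ e^(−kep·t),      ve = Ktrans / kep

with Ktrans (volume transfer constant) and kep (back-flux rate) in
1/min, ve the fractional extravascular extracellular volume, and Cp(t) a
population arterial input function (two Gaussians plus a
sigmoid-modulated exponential). The super-resolution network is trained
with the physics-informed cost

    L = ‖Sout − Sref‖² + λ₁‖Sin − Ω Sout‖² + λ₂‖Sout − fTofts(AIFout, kep, Ktrans)‖²

(λ₁ = λ₂ = 0.1), where Ω is the clinical down-sampling operator and the
parameters in the third term come from the frozen quantification
network. The quantification network is pretrained on simulated
(Ct, AIF) pairs with the mixed loss λ·MAE + (1−λ)·MAPE, λ = 0.998.
In-vivo dynamics are emulated by a synthetic phantom cohort (per-subject
AIFs, group-structured Tofts parameters, Gaussian noise); see
`docs/methods.md` for every modeling choice.

## Worked example

```python
import numpy as np
from roqdce import (AIFModelParams, ClinicalProtocol, TimeGrid,
                    downsample, population_aif, tofts_forward, nlls_fit)

grid = TimeGrid()                      # 130 steps x 2 s
aif = population_aif(AIFModelParams(), grid)
ct = tofts_forward(aif, ktrans=0.8, kep=2.5)   # 1/min

# clinical 4-phase sampling, arterial phase at the AIF peak
peak_t = grid.times[np.argmax(aif.values)]
sample = downsample(ct, ClinicalProtocol(), peak_t)
print("phase times [s]:", sample.phase_times_s)
print("phase values:   ", sample.phase_values.round(4))

fit = nlls_fit(ct, aif)
print(f"NLLS: Ktrans={fit.ktrans:.3f} kep={fit.kep:.3f} ve={fit.ve:.3f}")
```

Output:

```
phase times [s]: [ 10.  40.  70. 100.]
phase values:    [0.     0.2903 0.4276 0.3272]
NLLS: Ktrans=0.800 kep=2.500 ve=0.320
```

The four phase values are what a clinical exam measures; the library's
`TemporalSuperResolver` + `QuantNetRegressor` recover the parameters
from those four numbers alone. The full experiment (pre-training,
phantom cohort, ten-fold cross-validation, displacement sweep) runs as

```bash
roq all --seed 1 --out runs/desk      # or: roq validate / simulate / pretrain / fit / ...
```

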