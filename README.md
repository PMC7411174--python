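# cvrquant

Quantitative cerebrovascular reactivity (CVR) from a hypercapnic CO2
breathing challenge, measured three ways in one scan session:

- **ASL CVR** — fractional change of the pCASL perfusion-weighted signal,
  voxel-wise maps plus whole-brain/gray-matter/white-matter ROI values;
- **BOLD CVR** — fractional change of the simultaneously acquired
  second-echo BOLD signal;
- **PC CVR** — fractional change of blood flux through the superior
  sagittal sinus (SSS) measured with 2D phase-contrast MRI, a global but
  confound-poor readout.

The package is aimed at researchers studying vascular reactivity in aging
and cerebrovascular disease who want a tested, scriptable implementation of
this multi-modal quantification — including the ASL-specific preprocessing
(surround subtraction of the control/label alternation), end-tidal CO2
(EtCO2) extraction and lag alignment, flux quantification, basal cerebral
blood flow (CBF), and the cohort statistics. Because raw human data of this
kind are rarely shareable, `cvrquant` ships a synthetic-subject generator
with known ground truth; every processing stage is validated by recovering
the parameters that generated the data.

## The quantities

With `S` an epoch-averaged signal (ASL or BOLD) and `E` the epoch-averaged
end-tidal CO2 in mmHg,

    CVR = 100 * (S_HC - S_RA) / S_RA / (E_HC - E_RA)        [%/mmHg]

where RA/HC are the room-air and hypercapnic epochs (first 4 min and last
4 min of a 10-min scan with a gas switch at 4 min; the middle 2 min are
discarded as non-steady-state). PC CVR applies the same ratio to the SSS
flux, `Flux = ROI area x mean velocity`. Basal CBF comes from the room-air
flux:

    CBF = Flux_RA / (BrainVolume * 1.06) * 100 / 0.46       [ml/100g/min]

with 0.46 the SSS share of whole-brain flow and 1.06 g/ml the brain tissue
density. The EtCO2 trace is peak-picked breath-by-breath and shifted onto
the MRI clock by maximizing its cross-correlation with the whole-brain BOLD
time course (the lung-to-brain transit delay).

## Worked example

```python
from cvrquant import (GroundTruthParams, PipelineConfig, analyze_subject,
                      simulate_subject)

params = GroundTruthParams(cvr_true_gm=5.6, cvr_true_wm=5.1,
                           pc_cvr_true=6.15,
                           noise_sd_asl=0.0, noise_sd_bold=0.0, seed=0)
data = simulate_subject(params, grid_dims=(48, 48, 24), voxel_size=4.0)
res = analyze_subject(data.dual_echo, data.masks, data.trace,
                      data.pc_ra, data.pc_hc, PipelineConfig(fwhm_mm=0.0))
print(f"lag = {res.lag_s:.0f} s")
print(f"ASL CVR  GM {res.cvr['asl'].gm:.3f}  WM {res.cvr['asl'].wm:.3f} %/mmHg")
print(f"PC CVR   WB {res.cvr['pc'].wb:.3f} %/mmHg")
print(f"basal CBF   {res.basal_cbf:.1f} ml/100g/min")
```

prints

```
lag = 12 s
ASL CVR  GM 5.600  WM 5.100 %/mmHg
PC CVR   WB 6.150 %/mmHg
basal CBF   63.7 ml/100g/min
```

i.e. on this noiseless, confound-free subject the full pipeline returns the
generative GM/WM ASL CVR and PC CVR exactly, recovers the injected 12-s
lung-to-brain lag, and converts the 420 ml/min SSS flux into a basal CBF
consistent with the phantom's 1.35-L brain.

The same stages are exposed individually (`surround_subtract`,
`extract_etco2`, `align_etco2`, `compute_flux`, `basal_cbf`,
`group_compare_adjusted`, ...) and through a CLI:

```bash
cvrquant simulate --config sim.yaml --out sub01/ --seed 1
cvrquant analyze  --data sub01/ --out results/
cvrquant report   --cohort cohort.csv --out report/
```

## Layout

- `cvrquant.synthetic` — ground-truth phantom subjects and cohorts
- `cvrquant.timeseries` — smoothing, masking, surround subtraction/addition,
  epoch averaging
- `cvrquant.physio` — EtCO2 extraction, lag alignment, epoch EtCO2
- `cvrquant.cvr` — CVR maps and ROI values
- `cvrquant.pcflow` — vessel ROI, flux, PC CVR, basal CBF
- `cvrquant.stats` — adjusted group contrasts, correlations, paired tests,
  cohort report
- `cvrquant.pipeline` — one-call single-subject analysis
- `docs/methods.md` — models, assumptions, numerical choices
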