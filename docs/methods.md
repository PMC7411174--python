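# Methods

## The measurement model

A hypercapnic challenge raises arterial CO2 by roughly 10 mmHg, dilating
cerebral vessels and raising both perfusion and venous outflow.
Cerebrovascular reactivity (CVR) is the fractional signal change per mmHg of
end-tidal CO2 (EtCO2). Three readouts are quantified from one session:

1. **ASL CVR.** A dual-echo pCASL sequence alternates control and label
   volumes every TR = 4.006 s for 150 volumes (~10 min), with the inspired
   gas switched to a CO2-enriched mixture 4 min in. The first echo is
   perfusion-weighted: surround subtraction (below) converts the
   control/label alternation into a CBF-weighted difference time course
   dM(t). Epoch means over the first 4 min (room air, RA) and last 4 min
   (hypercapnia, HC) enter the ratio
   `100 * (dM_HC - dM_RA) / dM_RA / dEtCO2`.
2. **BOLD CVR.** The second echo is T2*-weighted; surround addition removes
   the residual labeling alternation, and the same ratio is applied.
3. **PC CVR and basal CBF.** 2D phase-contrast scans of the superior
   sagittal sinus (SSS) at each gas state give through-plane velocity maps
   (velocity-encoding limit 80 cm/s). Flux = ROI area x mean ROI velocity,
   in ml/min; the same CVR ratio is applied to the flux pair, and basal CBF
   is `Flux_RA / (V_brain * 1.06) * 100 / 0.46` with V_brain the
   segmentation-derived brain volume in ml.

The middle 2 min around the gas transition are discarded everywhere:
physiology is not at steady state while the inspired gas equilibrates.

### Surround operators

The perfusion series alternates control (C) and label (L) volumes. For
interior index i,

    dM_i = p_i * (s_i - (s_{i-1} + s_{i+1}) / 2),   p_i = +1 on C, -1 on L
    B_i  = (s_i + (s_{i-1} + s_{i+1}) / 2) / 2

and endpoints use the single available neighbour. The symmetric two-neighbour
form is chosen because it cancels any purely linear drift exactly at interior
points (the linear term of `s_i - (s_{i-1}+s_{i+1})/2` vanishes) and keeps
full temporal resolution; the two-point endpoint fallback trades that
cancellation for coverage at the first and last volume. Both operators are
linear, which the tests exploit.

### EtCO2 extraction and alignment

End-tidal values are per-breath maxima of the capnograph waveform: local
maxima separated by at least 2 s and at least 50% of the robust (98th
percentile) trace maximum, rejecting cardiogenic ripples on the expiratory
plateau. Inhaled CO2 reaches the cerebral vasculature seconds after the
valve switches, so the breath series is aligned to the whole-brain BOLD time
course: for each candidate lag in [0, 60] s (step 1 s) the series is shifted,
linearly interpolated onto the BOLD grid (nearest-value edge extension), and
correlated (Pearson, overlapping samples only, requiring >= 50% overlap);
the best-correlated lag wins, ties toward the smaller lag. The search is
one-sided because the physiological lung-to-brain delay is non-negative. We
align the *extracted end-tidal series*, not the raw waveform — the waveform's
within-breath excursions carry no arterial information and would dominate
the correlation.

### Epoch conventions

All windows are half-open `[t0, t1)`; volume i is timestamped `i * TR`
(start of acquisition); a volume or breath exactly at a window's right edge
is excluded. ROI summary values are computed ROI-mean-first (mask-mean time
course, then epoch means, then the CVR ratio); averaging a voxelwise CVR map
instead is also available but differs under noise, because the ratio is
nonlinear in the noisy per-voxel baseline. Map voxels whose room-air
baseline is non-positive (possible in noisy ASL difference data) are masked
out and counted in a QC tally rather than clipped — the ratio is undefined
there.

### Vessel ROI

Manual SSS ROI drawing is replaced by seeded region growing on the
complex-difference image: the connected component around the seed (default:
brightest voxel) above 50% of the seed intensity. A user-supplied mask is
accepted verbatim for the manual workflow. RA and HC ROIs are grown
independently by default (configurable to shared geometry): vessel caliber
changes between states, and the flux integral is robust to modest ROI
dilation because added background voxels carry near-zero velocity.

## The synthetic generator

The generator emulates the acquisition above on a nested-ellipsoid phantom
(whole-brain ellipsoid, GM shell, WM core, a CSF-like rim; default grid
48x48x24 at 4 mm isotropic, ~1.35 L brain — smaller than an acquisition
matrix but volumetrically realistic, and test grids are smaller still).
Signal model:

- Echo 1: control volumes carry the tissue M0 (GM 1000, WM 800, rim 600
  a.u.); label volumes subtract a perfusion difference dM (GM 12, WM 6 a.u.,
  ~1% of M0, GM > WM reflecting higher basal perfusion) scaled by
  `1 + CVR_true * dEtCO2(t) / 100` and multiplied by the hypercapnic
  labeling efficiency as the stimulus arrives.
- Echo 2: tissue baselines (GM 800, WM 700, rim 500 a.u.) scaled by
  `1 + BOLD_CVR_true * dEtCO2(t) / 100`, plus a small (0.3%) control/label
  alternation so surround addition has a labeling residue to cancel. The
  GM > WM BOLD response amplitude stands in for the venous-blood-volume
  contrast of real BOLD; ASL CVR is injected *equal* in GM and WM by
  default, reflecting comparable fractional CBF reactivity across tissue.
- The capnograph trace is a rounded sawtooth per 4-s breath (fast rise,
  expiratory plateau at the end-tidal value, fall to ~2 mmHg inspired);
  only the per-breath maxima are physiological. The end-tidal envelope
  steps +10 mmHg from a 40-mmHg baseline over a 20-s smooth transition *at
  the gas-switch time*; the brain response uses the same envelope delayed
  by the lung-to-brain lag (default 12 s). This reproduces the alignment
  problem with a known answer.
- Phase contrast: an elliptical vessel with a parabolic through-plane
  velocity profile, scaled so the integrated flux equals the generative
  flux exactly (RA: `basal_flux_sss`, default 420 ml/min; HC: scaled by
  `1 + PC_CVR_true * step / 100`); the generator refuses parameter
  combinations whose peak velocity would exceed the 80 cm/s encoding limit.
  Complex-difference magnitude is uniform inside the vessel with low-level
  background noise.
- Optional linear drift on both echoes and seeded Gaussian noise (default
  SD 5 a.u. per raw volume) added last. All randomness derives from the
  single subject seed through named substreams; reruns are byte-identical.

Cohorts draw per-subject parameters from group-level normal distributions
(defaults: an aging contrast with lower PC CVR and basal CBF in the older
group, near-equal ASL CVR, GM > WM BOLD CVR and no BOLD age effect, with
between-subject SDs on the order of the group SE x sqrt(n) of such studies),
assign sex and site labels at random, and record every drawn value in a
truth table.

**What the generator does not emulate** — and what passing tests therefore
do not demonstrate about real data: head motion (the realignment stage is an
identity hook), cardiac/respiratory quasi-periodic noise, bolus-arrival-time
changes, velocity aliasing and phase-offset errors in PC, partial-volume
mixtures beyond hard tissue boundaries, scanner drift nonlinearity, and
multi-vendor differences. Parameter recovery here validates the estimator
chain, not robustness to those artifacts.

## Numerical and design choices

- **Smoothing.** The pipeline default is a 4-mm FWHM Gaussian per volume
  (sigma = FWHM / (2 sqrt(2 ln 2)) per axis, in mm, converted per-axis to
  voxels), applied before masking and time-course extraction. Smoothing
  trades noise for partial-volume mixing at GM/WM boundaries; noiseless
  validation runs disable it (`fwhm_mm=0`), since it is a processing option
  rather than part of the estimand.
- **Whole-brain mask.** Voxels above 0.25 x the 98th-percentile intensity of
  the mean (smoothed) first-echo volume, largest connected component. The
  mask is computed after smoothing; GM/WM masks are inputs.
- **EtCO2 epochs for PC.** The real protocol acquires 30-s PC scans before
  and after the main scan; the synthetic trace covers the main scan only and
  its plateaus equal the PC-scan values, so the PC epochs default to the
  ASL RA/HC windows (configurable via `PipelineConfig.pc_windows`).
- **Statistics.** Group contrasts are OLS with intercept, group, sex and
  site indicator columns; df is reported as n - rank, and constant
  covariates (single-site cohorts) are dropped with a log note, while true
  rank deficiency raises an error naming the collinear column. SE is sample
  SD / sqrt(n) per group. Degenerate paired tests (zero-variance
  differences) return t = 0, p = 1 when the mean difference is zero and an
  infinite-t, p = 0 sentinel otherwise.
- **Units.** Velocity cm/s, area cm^2, flux ml/min, volume ml, CVR %/mmHg,
  CBF ml/100g/min, throughout.

## Known limitations

- The BOLD CVR estimate carries a ~0.15% multiplicative bias from the
  residual labeling dip (the dip shifts the RA baseline by half its
  amplitude); this is far below the sampling variability of any realistic
  acquisition and is visible only in noiseless phantoms.
- Endpoint volumes of the surround operators lose the linear-drift
  cancellation; with 150 volumes their weight in a 60-volume epoch mean is
  negligible.
- The step-stimulus design cannot separate a true BOLD response from slow
  scanner drift; the generator exposes `drift_slope` so users can quantify
  that susceptibility, but the pipeline deliberately applies no drift
  correction.
- PC CVR is global: no map, no regional values.
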