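"""Synthetic CVR subjects with known ground truth.

Emulates a hypercapnic-challenge session: a ~10-min dual-echo pCASL/BOLD
acquisition (TR 4.006 s, control/label alternation, gas switch at 4 min), a
capnograph CO2 trace stepping ~+10 mmHg at the switch, and a pair of 2D
phase-contrast scans of the superior sagittal sinus at normocapnia and
hypercapnia. Every generated quantity is recorded in ``GroundTruthParams`` so
downstream estimators can be validated against the values that produced the
data.

Two deliberate asymmetries reproduce the physiology the analysis must cope
with: the end-tidal trace steps at the gas-switch time while the brain signal
lags behind it by ``lung_to_brain_lag`` (the alignment problem), and
``labeling_efficiency_hc`` < 1 attenuates the hypercapnic ASL difference
signal without touching phase-contrast flux (the ASL-underestimation
confound).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .types import (
    AcquisitionTimeline,
    CapnoTrace,
    DualEchoSeries,
    PCImagePair,
    TissueMasks,
    default_timeline,
)

__all__ = [
    "GroundTruthParams",
    "SubjectData",
    "Cohort",
    "make_phantom_masks",
    "simulate_etco2_trace",
    "etco2_envelope",
    "simulate_dual_echo",
    "simulate_pc_pair",
    "simulate_subject",
    "make_cohort",
    "default_group_effects",
]

# Baseline tissue signal levels, a.u. "other" is intra-cranial tissue that is
# neither GM nor WM (CSF-like): no perfusion difference signal, no CO2 response.
_M0 = {"gm": 1000.0, "wm": 800.0, "other": 600.0}
_DM_RA = {"gm": 12.0, "wm": 6.0, "other": 0.0}  # basal perfusion GM > WM
_BOLD_BASE = {"gm": 800.0, "wm": 700.0, "other": 500.0}
_BOLD_LABEL_DIP_FRAC = 0.003  # residual labeling effect on the second echo
_ETCO2_TRANSITION_S = 20.0  # smooth gas-step transition (<= 30 s)


@dataclass(frozen=True)
class GroundTruthParams:
    """Generative parameters of one synthetic subject.

    CVR values are %/mmHg; ``labeling_efficiency_hc`` multiplies the ASL
    difference signal during hypercapnia (1.0 = no confound); the lag is the
    lung-to-brain transit delay of the CO2 stimulus.
    """

    cvr_true_gm: float = 5.6
    cvr_true_wm: float = 5.6  # equal to GM by default: no GM-WM CBF-CVR contrast
    bold_cvr_true_gm: float = 0.33
    bold_cvr_true_wm: float = 0.19
    pc_cvr_true: float = 6.15
    basal_flux_sss: float = 420.0  # ml/min
    brain_volume: float = 1300.0  # ml; pipeline uses the mask-derived volume
    etco2_baseline: float = 40.0  # mmHg
    etco2_step: float = 10.0  # mmHg
    lung_to_brain_lag: float = 12.0  # s
    labeling_efficiency_hc: float = 1.0
    noise_sd_asl: float = 5.0  # a.u., per raw echo-1 volume
    noise_sd_bold: float = 5.0  # a.u., per raw echo-2 volume
    drift_slope: float = 0.0  # a.u./s, added to both echoes
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "cvr_true_gm",
            "cvr_true_wm",
            "bold_cvr_true_gm",
            "bold_cvr_true_wm",
            "pc_cvr_true",
        ):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not (0.0 < self.labeling_efficiency_hc <= 1.0):
            raise ValueError("labeling_efficiency_hc must lie in (0, 1]")
        if self.etco2_step < 0:
            raise ValueError("etco2_step must be non-negative")
        if self.lung_to_brain_lag < 0:
            raise ValueError("lung_to_brain_lag must be non-negative")
        if self.noise_sd_asl < 0 or self.noise_sd_bold < 0:
            raise ValueError("noise SDs must be non-negative")


def _rng(params: GroundTruthParams, stream: int) -> np.random.Generator:
    # independent streams per component, all derived from the single seed
    return np.random.default_rng([params.seed, stream])


def make_phantom_masks(
    grid_dims: tuple[int, int, int],
    voxel_size: tuple[float, float, float] | float,
) -> TissueMasks:
    """Deterministic nested-ellipsoid phantom: WB ellipsoid, GM shell, WM core.

    Normalized elliptical radius rho (semi-axes 0.9 * dim/2 per axis):
    WB is rho <= 1, WM the core rho <= 0.55, GM the shell 0.55 < rho <= 0.85;
    the outermost WB rim is CSF-like "other" tissue. GM always outnumbers WM.
    """
    if isinstance(voxel_size, (int, float)):
        voxel_size = (float(voxel_size),) * 3
    if any(d < 8 for d in grid_dims):
        raise ValueError("grid_dims must be >= 8 along every axis")
    center = [(d - 1) / 2.0 for d in grid_dims]
    semi = [0.9 * d / 2.0 for d in grid_dims]
    axes = np.ogrid[[slice(0, d) for d in grid_dims]]
    rho2 = sum(((ax - c) / s) ** 2 for ax, c, s in zip(axes, center, semi))
    rho = np.sqrt(rho2)
    wb = rho <= 1.0
    wm = rho <= 0.55
    gm = (rho > 0.55) & (rho <= 0.85)
    return TissueMasks(gm=gm, wm=wm, wb=wb, voxel_size=tuple(voxel_size))


def etco2_envelope(
    t: np.ndarray | float,
    params: GroundTruthParams,
    switch_time: float,
    lag: float = 0.0,
) -> np.ndarray:
    """End-tidal CO2 envelope: baseline, then a smooth +step over ~20 s.

    ``lag`` shifts the step later in time; the capnograph trace uses lag 0
    (the gas arrives at the mouth when the valve turns), the brain response
    uses ``lung_to_brain_lag``.
    """
    u = (np.asarray(t, dtype=float) - switch_time - lag) / _ETCO2_TRANSITION_S
    ramp = np.clip(u, 0.0, 1.0)
    smooth = 0.5 * (1.0 - np.cos(np.pi * ramp))
    return params.etco2_baseline + params.etco2_step * smooth


def simulate_etco2_trace(
    params: GroundTruthParams,
    duration: float,
    sample_rate: float = 10.0,
    breath_period: float = 4.0,
    gas_switch_time: float = 240.0,
    noise_sd: float = 0.0,
) -> CapnoTrace:
    """Periodic capnograph waveform whose per-breath maxima track the gas state.

    Each breath is a rounded sawtooth: fast rise to the end-tidal plateau,
    fast fall at inspiration, near-zero inspired CO2 between breaths. The
    plateau value equals ``etco2_baseline`` before the gas switch and
    ``etco2_baseline + etco2_step`` after it, with a smooth <=30 s transition.
    Only per-breath maxima (the end-tidal values) carry physiological meaning.
    """
    if sample_rate < 4.0:
        raise ValueError("sample_rate must be >= 4 Hz to resolve breaths")
    if breath_period < 2.0:
        raise ValueError("breath_period must be >= 2 s")
    if duration <= gas_switch_time:
        raise ValueError("duration must extend past the gas switch")
    t = np.arange(0.0, duration, 1.0 / sample_rate)
    et = etco2_envelope(t, params, gas_switch_time)
    phase = (t % breath_period) / breath_period
    shape = np.zeros_like(phase)
    rise = phase < 0.15
    plateau = (phase >= 0.15) & (phase < 0.70)
    fall = (phase >= 0.70) & (phase < 0.85)
    shape[rise] = 0.5 * (1.0 - np.cos(np.pi * phase[rise] / 0.15))
    shape[plateau] = 1.0
    shape[fall] = 0.5 * (1.0 + np.cos(np.pi * (phase[fall] - 0.70) / 0.15))
    inspired = 2.0  # mmHg floor between breaths
    co2 = inspired + (et - inspired) * shape
    if noise_sd > 0:
        co2 = co2 + _rng(params, 1).normal(0.0, noise_sd, co2.shape)
        co2 = np.clip(co2, 0.0, None)
    return CapnoTrace(time=t, co2=co2, sample_rate=sample_rate)


def simulate_dual_echo(
    params: GroundTruthParams,
    masks: TissueMasks,
    timeline: AcquisitionTimeline | None = None,
) -> DualEchoSeries:
    """Simulate the 4D dual-echo acquisition on a phantom.

    Echo 1 (ASL-weighted): control volumes carry the M0 map; label volumes
    carry M0 - dM(t), where the perfusion difference dM is tissue-dependent,
    scales as ``1 + cvr_true * dEtCO2(t) / 100``, and is multiplied by
    ``labeling_efficiency_hc`` as the brain enters hypercapnia. Echo 2
    (BOLD-weighted): a tissue-dependent baseline stepping by
    ``bold_cvr_true * dEtCO2(t)`` percent, with a small control/label
    alternation left in (the residual labeling effect surround-addition must
    cancel). The brain's dEtCO2 lags the inhaled gas switch by
    ``lung_to_brain_lag``. An optional linear drift and seeded Gaussian noise
    are added last to both echoes.
    """
    if timeline is None:
        timeline = default_timeline()
    if timeline.duration < timeline.hc_window[1] - 1e-9:
        raise ValueError("timeline windows must fit within the acquisition")
    t = timeline.volume_times
    d_et = (
        etco2_envelope(t, params, timeline.gas_switch_time, params.lung_to_brain_lag)
        - params.etco2_baseline
    )
    if params.etco2_step > 0:
        step_frac = d_et / params.etco2_step  # 0 at RA -> 1 at full hypercapnia
    else:
        step_frac = np.zeros_like(d_et)
    eff = 1.0 + (params.labeling_efficiency_hc - 1.0) * step_frac
    label_flag = (timeline.control_parity < 0).astype(float)

    shape4 = masks.shape + (timeline.n_volumes,)
    echo1 = np.zeros(shape4)
    echo2 = np.zeros(shape4)
    tissue_masks = {
        "gm": masks.gm,
        "wm": masks.wm,
        "other": masks.wb & ~masks.gm & ~masks.wm,
    }
    cvr = {"gm": params.cvr_true_gm, "wm": params.cvr_true_wm, "other": 0.0}
    bold_cvr = {
        "gm": params.bold_cvr_true_gm,
        "wm": params.bold_cvr_true_wm,
        "other": 0.0,
    }
    for tissue, tmask in tissue_masks.items():
        dm_t = _DM_RA[tissue] * (1.0 + cvr[tissue] * d_et / 100.0) * eff
        echo1[tmask] = _M0[tissue] - label_flag * dm_t
        bold_t = _BOLD_BASE[tissue] * (1.0 + bold_cvr[tissue] * d_et / 100.0)
        echo2[tmask] = bold_t - label_flag * _BOLD_LABEL_DIP_FRAC * _BOLD_BASE[tissue]

    if params.drift_slope != 0.0:
        drift = params.drift_slope * t
        echo1[masks.wb] += drift
        echo2[masks.wb] += drift
    if params.noise_sd_asl > 0:
        echo1 += _rng(params, 2).normal(0.0, params.noise_sd_asl, shape4)
    if params.noise_sd_bold > 0:
        echo2 += _rng(params, 3).normal(0.0, params.noise_sd_bold, shape4)
    return DualEchoSeries(echo1=echo1, echo2=echo2, timeline=timeline)


def _pc_single(
    flux: float,
    state: str,
    slice_dims: tuple[int, int],
    voxel_area: float,
    venc: float,
    rng: np.random.Generator,
    background_noise_sd: float,
) -> tuple[PCImagePair, np.ndarray]:
    ny, nx = slice_dims
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    ay, ax = 0.12 * ny, 0.10 * nx  # vessel semi-axes, voxels
    yy, xx = np.ogrid[0:ny, 0:nx]
    rho2 = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2
    vessel = rho2 <= 1.0
    profile = np.where(vessel, 1.0 - rho2, 0.0)  # parabolic, peak 1 at center
    total = profile.sum()
    v_peak = flux / (60.0 * voxel_area * total)  # scale so summed flux == flux
    if v_peak >= venc:
        raise ValueError(
            f"requested flux {flux:.0f} ml/min needs peak velocity "
            f"{v_peak:.1f} cm/s >= venc {venc:.0f} cm/s (would alias)"
        )
    velocity = v_peak * profile
    if background_noise_sd > 0:
        bg = rng.normal(0.0, background_noise_sd, (ny, nx))
        velocity = velocity + np.where(vessel, 0.0, bg)
    cd = np.where(vessel, 100.0, 0.0)
    cd = cd + np.abs(rng.normal(0.0, 2.0, (ny, nx))) * (~vessel)
    pair = PCImagePair(
        cd_magnitude=cd,
        velocity=velocity,
        voxel_area=voxel_area,
        venc=venc,
        state=state,
    )
    return pair, vessel


def simulate_pc_pair(
    params: GroundTruthParams,
    slice_dims: tuple[int, int] = (64, 64),
    voxel_area: float = 0.01,
    venc: float = 80.0,
    background_noise_sd: float = 0.3,
    return_truth_mask: bool = False,
):
    """Phase-contrast pairs at normocapnia and hypercapnia.

    An elliptical vessel (the SSS cross-section) carries a parabolic
    through-plane velocity profile scaled so the integrated flux (sum of
    velocity x voxel_area x 60) equals ``basal_flux_sss`` at RA and
    ``basal_flux_sss * (1 + pc_cvr_true * etco2_step / 100)`` at HC.
    Complex-difference magnitude is high inside the vessel and near zero
    outside; background velocity is small zero-mean noise.
    """
    if params.basal_flux_sss <= 0:
        raise ValueError("basal_flux_sss must be positive")
    rng = _rng(params, 4)
    flux_hc = params.basal_flux_sss * (
        1.0 + params.pc_cvr_true * params.etco2_step / 100.0
    )
    ra, vessel = _pc_single(
        params.basal_flux_sss, "RA", slice_dims, voxel_area, venc, rng,
        background_noise_sd,
    )
    hc, _ = _pc_single(
        flux_hc, "HC", slice_dims, voxel_area, venc, rng, background_noise_sd
    )
    if return_truth_mask:
        return ra, hc, vessel
    return ra, hc


@dataclass(frozen=True)
class SubjectData:
    """Everything acquired for one (synthetic) subject."""

    dual_echo: DualEchoSeries
    masks: TissueMasks
    trace: CapnoTrace
    pc_ra: PCImagePair
    pc_hc: PCImagePair
    truth: GroundTruthParams | None = None


def simulate_subject(
    params: GroundTruthParams,
    grid_dims: tuple[int, int, int] = (48, 48, 24),
    voxel_size: tuple[float, float, float] | float = 4.0,
    timeline: AcquisitionTimeline | None = None,
    pc_slice_dims: tuple[int, int] = (64, 64),
    pc_voxel_area: float = 0.01,
    trace_noise_sd: float = 0.0,
) -> SubjectData:
    """Generate a complete synthetic session: images, physiology, ground truth."""
    if timeline is None:
        timeline = default_timeline()
    masks = make_phantom_masks(grid_dims, voxel_size)
    trace = simulate_etco2_trace(
        params,
        duration=timeline.duration + 40.0,
        gas_switch_time=timeline.gas_switch_time,
        noise_sd=trace_noise_sd,
    )
    dual_echo = simulate_dual_echo(params, masks, timeline)
    pc_ra, pc_hc = simulate_pc_pair(params, pc_slice_dims, pc_voxel_area)
    return SubjectData(
        dual_echo=dual_echo,
        masks=masks,
        trace=trace,
        pc_ra=pc_ra,
        pc_hc=pc_hc,
        truth=params,
    )


def default_group_effects() -> dict:
    """Cohort group means and between-subject SDs emulating an aging study.

    Younger adults have higher PC CVR and basal CBF; CBF-based (ASL) CVR is
    near-equal across tissue and declines only mildly with age; BOLD CVR shows
    a GM > WM contrast but no age effect. SDs are between-subject.
    """
    young = dict(
        pc_cvr_true=6.59,
        cvr_true_gm=5.74,
        cvr_true_wm=5.27,
        bold_cvr_true_gm=0.33,
        bold_cvr_true_wm=0.19,
        basal_cbf=68.2,
    )
    old = dict(
        pc_cvr_true=5.46,
        cvr_true_gm=5.31,
        cvr_true_wm=4.86,
        bold_cvr_true_gm=0.33,
        bold_cvr_true_wm=0.21,
        basal_cbf=51.5,
    )
    between_sd = dict(
        pc_cvr_true=1.9,
        cvr_true_gm=2.0,
        cvr_true_wm=2.4,
        bold_cvr_true_gm=0.06,
        bold_cvr_true_wm=0.06,
        basal_cbf=18.0,
    )
    return {"young": young, "old": old, "between_sd": between_sd}


@dataclass(frozen=True)
class Cohort:
    """Per-subject generative parameters plus demographic labels.

    ``truth`` records every drawn parameter; image data are generated on
    demand with :func:`simulate_subject` using ``params[i]``.
    """

    params: list
    group: list
    sex: list
    site: list
    truth: pd.DataFrame


def make_cohort(
    n_young: int,
    n_old: int,
    effects: dict | None = None,
    seed: int = 0,
    brain_volume: float = 1300.0,
) -> Cohort:
    """Draw a cohort of synthetic subjects from group-level distributions.

    ``effects`` holds ``young`` / ``old`` mean dicts and a ``between_sd``
    dict over any subset of GroundTruthParams fields (plus ``basal_cbf``,
    which is converted to an SSS flux through the basal-CBF relation using
    ``brain_volume``). Sex (M/F) and site (A/B) labels are assigned at
    random; the truth table records every drawn parameter.
    """
    if n_young < 2 or n_old < 2:
        raise ValueError("need at least 2 subjects per group")
    if effects is None:
        effects = default_group_effects()
    sds = effects.get("between_sd", {})
    if any(s < 0 for s in sds.values()):
        raise ValueError("between-subject sd must be non-negative")
    rng = np.random.default_rng([seed, 99])
    params_list, groups, sexes, sites, rows = [], [], [], [], []
    idx = 0
    for group, n in (("young", n_young), ("old", n_old)):
        means = effects[group]
        for _ in range(n):
            drawn = {
                k: float(rng.normal(m, sds.get(k, 0.0))) for k, m in means.items()
            }
            if "basal_cbf" in drawn:
                cbf = max(drawn.pop("basal_cbf"), 5.0)
                # invert Eq-4: flux = CBF * volume * density * ratio / 100
                drawn["basal_flux_sss"] = cbf * brain_volume * 1.06 * 0.46 / 100.0
            drawn["labeling_efficiency_hc"] = float(
                np.clip(drawn.get("labeling_efficiency_hc", 1.0), 0.05, 1.0)
            )
            p = GroundTruthParams(
                brain_volume=brain_volume, seed=int(rng.integers(2**31)), **drawn
            )
            sex = "M" if rng.random() < 0.5 else "F"
            site = "A" if rng.random() < 0.5 else "B"
            params_list.append(p)
            groups.append(group)
            sexes.append(sex)
            sites.append(site)
            rows.append(
                {"subject_id": f"sub-{idx:03d}", "group": group, "sex": sex,
                 "site": site, **asdict(p)}
            )
            idx += 1
    return Cohort(
        params=params_list,
        group=groups,
        sex=sexes,
        site=sites,
        truth=pd.DataFrame(rows),
    )
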