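"""End-to-end single-subject analysis.

Chains the processing stages: (optional motion-correction hook and Gaussian
smoothing) -> surround subtraction/addition -> whole-brain masking and ROI
time courses -> EtCO2 extraction and lag alignment -> epoch averaging -> CVR
per modality and compartment -> phase-contrast flux, PC CVR and basal CBF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import cvr as cvrmod
from . import pcflow, physio, timeseries
from .types import (
    CapnoTrace,
    CvrSummary,
    DualEchoSeries,
    EtCO2Epochs,
    FluxPair,
    PCImagePair,
    TissueMasks,
)

__all__ = ["PipelineConfig", "SubjectResult", "analyze_subject"]


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable processing choices.

    ``fwhm_mm`` trades SNR for partial-volume mixing at tissue boundaries
    (0 disables smoothing); the lag search covers ``[0, max_lag_s]`` in
    ``lag_step_s`` increments; ``pc_windows`` defaults to the ASL epoch
    windows when None (the EtCO2 plateaus coincide).
    """

    fwhm_mm: float = 4.0
    wb_threshold_frac: float = 0.25
    min_breath_interval_s: float = 2.0
    max_lag_s: float = 60.0
    lag_step_s: float = 1.0
    roi_threshold_frac: float = 0.5
    pc_windows: tuple[tuple[float, float], tuple[float, float]] | None = None
    shared_pc_roi: bool = False
    velocity_sign: float = 1.0


@dataclass(frozen=True)
class SubjectResult:
    """CVR values per modality/compartment plus flow quantities and QC."""

    cvr: dict  # modality -> CvrSummary
    flux: FluxPair
    basal_cbf: float
    brain_volume_ml: float
    lag_s: float
    etco2: EtCO2Epochs
    etco2_pc: EtCO2Epochs
    qc: dict


def analyze_subject(
    dual_echo: DualEchoSeries,
    masks: TissueMasks,
    trace: CapnoTrace,
    pc_ra: PCImagePair,
    pc_hc: PCImagePair,
    config: PipelineConfig = PipelineConfig(),
) -> SubjectResult:
    """Run the full quantification chain on one subject's raw data."""
    timeline = dual_echo.timeline
    tr = timeline.tr

    echo1 = timeseries.realign(dual_echo.echo1)
    echo2 = timeseries.realign(dual_echo.echo2)
    if config.fwhm_mm > 0:
        echo1 = timeseries.smooth_gaussian(echo1, config.fwhm_mm, masks.voxel_size)
        echo2 = timeseries.smooth_gaussian(echo2, config.fwhm_mm, masks.voxel_size)

    wb_mask = timeseries.compute_wb_mask(
        echo1.mean(axis=-1), config.wb_threshold_frac
    )
    asl = timeseries.surround_subtract(echo1, timeline.first_volume_type, tr)
    bold = timeseries.surround_add(echo2, tr)

    wb_bold_course = timeseries.roi_time_course(bold, wb_mask)
    etco2_raw = physio.extract_etco2(trace, config.min_breath_interval_s)
    lag, etco2_aligned = physio.align_etco2(
        etco2_raw, wb_bold_course, tr, config.max_lag_s, config.lag_step_s
    )
    epochs = physio.epoch_etco2(
        etco2_aligned, timeline.ra_window, timeline.hc_window
    )
    pc_win = config.pc_windows or (timeline.ra_window, timeline.hc_window)
    epochs_pc = physio.epoch_etco2(etco2_aligned, pc_win[0], pc_win[1])

    rois = {"wb": wb_mask, "gm": masks.gm, "wm": masks.wm}
    summaries: dict[str, CvrSummary] = {}
    for modality, series in (("asl", asl), ("bold", bold)):
        vals = {
            name: cvrmod.roi_cvr(series, roi, timeline, epochs)
            for name, roi in rois.items()
        }
        summaries[modality] = CvrSummary(modality=modality, **vals)

    roi_ra = pcflow.grow_vessel_roi(pc_ra, threshold_frac=config.roi_threshold_frac)
    if config.shared_pc_roi:
        roi_hc = roi_ra
    else:
        roi_hc = pcflow.grow_vessel_roi(
            pc_hc, threshold_frac=config.roi_threshold_frac
        )
    sign = config.velocity_sign
    flux = FluxPair(
        flux_ra=sign * pcflow.compute_flux(pc_ra, roi_ra),
        flux_hc=sign * pcflow.compute_flux(pc_hc, roi_hc),
    )
    pc_value = pcflow.pc_cvr(flux, epochs_pc)
    summaries["pc"] = CvrSummary(modality="pc", wb=pc_value)

    volume = pcflow.brain_volume_from_masks(masks)
    cbf = pcflow.basal_cbf(flux.flux_ra, volume)

    _, n_excluded = cvrmod.make_cvr_map(asl, wb_mask, timeline, epochs, "asl")
    qc = {
        "n_wb_voxels": int(wb_mask.sum()),
        "n_asl_voxels_nonpositive_baseline": n_excluded,
        "pc_roi_voxels_ra": roi_ra.n_voxels,
        "pc_roi_voxels_hc": roi_hc.n_voxels,
    }
    return SubjectResult(
        cvr=summaries,
        flux=flux,
        basal_cbf=cbf,
        brain_volume_ml=volume,
        lag_s=lag,
        etco2=epochs,
        etco2_pc=epochs_pc,
        qc=qc,
    )
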