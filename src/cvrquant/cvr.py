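"""CVR computation: percent signal change per mmHg of end-tidal CO2.

For a signal S and end-tidal values E,

    CVR = 100 * (S_HC - S_RA) / S_RA / (E_HC - E_RA)   [%/mmHg]

applied identically to the perfusion-weighted (ASL) and BOLD series, per voxel
for maps or on an ROI-mean time course for WB/GM/WM summary values. The
canonical ROI value averages the time course first and computes CVR second;
under noise this differs from averaging a voxelwise map, and voxels whose
room-air baseline is non-positive (possible in noisy ASL difference data) are
excluded rather than clipped, since the ratio is undefined there.
"""

from __future__ import annotations

import numpy as np

from .types import (
    AcquisitionTimeline,
    CvrMap,
    EpochMeans,
    EtCO2Epochs,
    ProcessedSeries,
)
from .timeseries import epoch_average, roi_time_course

__all__ = ["cvr_from_epochs", "roi_cvr", "make_cvr_map"]


def cvr_from_epochs(s: EpochMeans, e: EtCO2Epochs):
    """Evaluate the CVR ratio on epoch means (scalar or elementwise).

    Scalars return a float; arrays return (cvr, valid) where ``valid`` flags
    locations with a positive room-air baseline (CVR is NaN elsewhere).
    """
    if e.delta == 0:
        raise ValueError("etco2_hc equals etco2_ra: CVR undefined")
    if np.isscalar(s.s_ra) or np.ndim(s.s_ra) == 0:
        if s.s_ra == 0:
            raise ValueError("zero room-air baseline: CVR undefined")
        return 100.0 * (s.s_hc - s.s_ra) / s.s_ra / e.delta
    s_ra = np.asarray(s.s_ra, dtype=float)
    s_hc = np.asarray(s.s_hc, dtype=float)
    valid = s_ra > 0
    cvr = np.full(s_ra.shape, np.nan)
    cvr[valid] = 100.0 * (s_hc[valid] - s_ra[valid]) / s_ra[valid] / e.delta
    return cvr, valid


def roi_cvr(
    series: ProcessedSeries,
    mask: np.ndarray,
    timeline: AcquisitionTimeline,
    e: EtCO2Epochs,
) -> float:
    """Canonical ROI CVR: mask-mean time course -> epoch means -> CVR."""
    course = roi_time_course(series, mask)
    means = epoch_average(
        ProcessedSeries(
            values=course, kind=series.kind,
            sampling_interval=series.sampling_interval,
        ),
        timeline,
    )
    return float(cvr_from_epochs(means, e))


def make_cvr_map(
    series: ProcessedSeries,
    wb_mask: np.ndarray,
    timeline: AcquisitionTimeline,
    e: EtCO2Epochs,
    modality: str | None = None,
) -> tuple[CvrMap, int]:
    """Voxelwise CVR map inside a whole-brain mask.

    Returns the map and the count of in-mask voxels excluded for a
    non-positive room-air baseline (a QC tally; such voxels are masked out,
    not clipped).
    """
    if modality is None:
        modality = "asl" if series.kind == "perfusion-weighted" else "bold"
    means = epoch_average(series, timeline)
    cvr, valid = cvr_from_epochs(means, e)
    final_mask = wb_mask & valid
    n_excluded = int((wb_mask & ~valid).sum())
    values = np.where(final_mask, cvr, np.nan)
    return CvrMap(values=values, modality=modality, mask=final_mask), n_excluded
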