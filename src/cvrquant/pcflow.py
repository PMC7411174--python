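"""Phase-contrast flux quantification, PC CVR, and basal CBF.

Blood flux through the superior sagittal sinus is the ROI area times the mean
through-plane velocity in the ROI (equivalently the velocity-area integral),
converted to ml/min. PC CVR is the fractional flux change per mmHg of
end-tidal CO2. Basal whole-brain CBF follows from the room-air SSS flux via

    CBF = Flux_RA / (BrainVolume * 1.06) * 100 / 0.46   [ml/100g/min]

where 0.46 is the SSS share of whole-brain flow and 1.06 g/ml the brain
tissue mass density.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .types import (
    EtCO2Epochs,
    FluxPair,
    PCImagePair,
    QuantConstants,
    TissueMasks,
    VesselROI,
)

__all__ = [
    "grow_vessel_roi",
    "compute_flux",
    "pc_cvr",
    "basal_cbf",
    "brain_volume_from_masks",
]


def grow_vessel_roi(
    pair: PCImagePair,
    seed: tuple[int, int] | None = None,
    threshold_frac: float = 0.5,
    mask: np.ndarray | None = None,
) -> VesselROI:
    """Vessel ROI on the complex-difference image by seeded region growing.

    Grows the connected region around ``seed`` containing voxels with
    ``cd_magnitude >= threshold_frac * cd_magnitude[seed]``. ``seed`` defaults
    to the brightest voxel. An externally supplied boolean ``mask`` (the
    manual-ROI workflow) is accepted verbatim instead.
    """
    if mask is not None:
        if mask.shape != pair.cd_magnitude.shape:
            raise ValueError("supplied mask grid mismatch")
        if not mask.any():
            raise ValueError("supplied mask is empty")
        return VesselROI.from_mask(mask.astype(bool), pair.voxel_area)
    cd = pair.cd_magnitude
    if seed is None:
        seed = np.unravel_index(int(np.argmax(cd)), cd.shape)
    seed = tuple(int(i) for i in seed)
    if not all(0 <= i < n for i, n in zip(seed, cd.shape)):
        raise ValueError("seed lies outside the image")
    seed_val = cd[seed]
    if seed_val <= 0 or seed_val < 0.25 * np.percentile(cd, 99):
        raise ValueError("seed intensity too low: appears to be background")
    candidate = cd >= threshold_frac * seed_val
    labels, _ = ndimage.label(candidate)
    region = labels == labels[seed]
    if not region.any():
        raise ValueError("region growing produced an empty ROI")
    edge = np.zeros_like(region)
    edge[0, :] = edge[-1, :] = edge[:, 0] = edge[:, -1] = True
    if (region & edge).any():
        warnings.warn("vessel ROI touches the image border", stacklevel=2)
    return VesselROI.from_mask(region, pair.voxel_area)


def compute_flux(pair: PCImagePair, roi: VesselROI) -> float:
    """Flux in ml/min: ROI area (cm^2) x mean ROI velocity (cm/s) x 60."""
    if roi.n_voxels == 0:
        raise ValueError("empty vessel ROI")
    mean_v = float(pair.velocity[roi.mask].mean())
    if mean_v <= 0:
        warnings.warn(
            "non-positive mean velocity: check flow direction / ROI placement",
            stacklevel=2,
        )
    return roi.area * mean_v * 60.0


def pc_cvr(flux: FluxPair, e: EtCO2Epochs) -> float:
    """PC CVR in %/mmHg from the RA/HC flux pair."""
    if e.delta == 0:
        raise ValueError("etco2_hc equals etco2_ra: CVR undefined")
    return 100.0 * (flux.flux_hc - flux.flux_ra) / flux.flux_ra / e.delta


def basal_cbf(
    flux_ra: float,
    brain_volume: float,
    k: QuantConstants = QuantConstants(),
) -> float:
    """Basal whole-brain CBF (ml/100g/min) from the room-air SSS flux."""
    if brain_volume <= 0:
        raise ValueError("brain_volume must be positive")
    return flux_ra / (brain_volume * k.brain_density) * k.per100 / k.sss_to_wb_ratio


def brain_volume_from_masks(masks: TissueMasks) -> float:
    """Whole-brain volume in ml: WB voxel count x voxel volume."""
    return float(masks.wb.sum()) * masks.voxel_volume_ml
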