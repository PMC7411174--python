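"""Shared domain containers for the CVR quantification pipeline.

Units are fixed package-wide: time in seconds, CO2 partial pressure in mmHg,
velocity in cm/s, areas in cm^2, flux in ml/min, volumes in ml, CVR in %/mmHg,
basal CBF in ml/100g/min. MRI signal values are in arbitrary units (a.u.).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AcquisitionTimeline",
    "TissueMasks",
    "DualEchoSeries",
    "ProcessedSeries",
    "EpochMeans",
    "CapnoTrace",
    "EtCO2Series",
    "EtCO2Epochs",
    "PCImagePair",
    "VesselROI",
    "FluxPair",
    "QuantConstants",
    "CvrMap",
    "CvrSummary",
    "TestResult",
    "default_timeline",
]


@dataclass(frozen=True)
class AcquisitionTimeline:
    """Timing of an alternating control/label acquisition with a mid-scan gas switch.

    Volume ``i`` is assigned the time ``i * tr`` (start of acquisition). Epoch
    windows are half-open ``[t0, t1)``: a volume acquired exactly at ``t1`` is
    excluded.

    Parameters
    ----------
    tr : float
        Repetition time per volume, s.
    n_volumes : int
        Total number of volumes; must be even (control/label pairs).
    gas_switch_time : float
        Time at which inspired gas switches from room air to the CO2 mixture, s.
    ra_window, hc_window : tuple of float
        Half-open room-air and hypercapnic averaging windows, s.
    first_volume_type : {"control", "label"}
        Label sense of volume 0.
    """

    tr: float
    n_volumes: int
    gas_switch_time: float
    ra_window: tuple[float, float]
    hc_window: tuple[float, float]
    first_volume_type: str = "control"

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.n_volumes % 2 != 0:
            raise ValueError("n_volumes must be even (control/label pairs)")
        if self.first_volume_type not in ("control", "label"):
            raise ValueError("first_volume_type must be 'control' or 'label'")
        ra0, ra1 = self.ra_window
        hc0, hc1 = self.hc_window
        if not (ra0 < ra1 and hc0 < hc1):
            raise ValueError("windows must be non-empty intervals [t0, t1)")
        if max(ra0, hc0) < min(ra1, hc1):
            raise ValueError("ra_window and hc_window must be disjoint")
        if hc0 < self.gas_switch_time:
            raise ValueError("hc_window must start at or after gas_switch_time")

    @property
    def duration(self) -> float:
        return self.n_volumes * self.tr

    @property
    def volume_times(self) -> np.ndarray:
        return np.arange(self.n_volumes) * self.tr

    @property
    def control_parity(self) -> np.ndarray:
        """+1 where the volume is a control, -1 where it is a label."""
        sign = np.where(np.arange(self.n_volumes) % 2 == 0, 1, -1)
        return sign if self.first_volume_type == "control" else -sign


def default_timeline() -> AcquisitionTimeline:
    """The 10-min dual-echo protocol: TR 4.006 s, 150 volumes, gas switch at 4 min.

    The first 4 min are averaged as room air, the last 4 min as hypercapnia,
    and the middle 2 min (non-steady-state physiology) are discarded.
    """
    tr = 4.006
    n = 150
    return AcquisitionTimeline(
        tr=tr,
        n_volumes=n,
        gas_switch_time=240.0,
        ra_window=(0.0, 240.0),
        hc_window=(360.0, n * tr),
        first_volume_type="control",
    )


@dataclass(frozen=True)
class TissueMasks:
    """GM/WM/whole-brain masks on a shared voxel grid."""

    gm: np.ndarray
    wm: np.ndarray
    wb: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        for name in ("gm", "wm", "wb"):
            m = getattr(self, name)
            if m.dtype != bool:
                raise ValueError(f"{name} mask must be boolean")
        if not (self.gm.shape == self.wm.shape == self.wb.shape):
            raise ValueError("masks must share one grid")
        if np.any(self.gm & self.wm):
            raise ValueError("gm and wm masks overlap")
        if np.any((self.gm | self.wm) & ~self.wb):
            raise ValueError("gm and wm must be contained in wb")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be strictly positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.wb.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in ml (mm^3 / 1000)."""
        return float(np.prod(self.voxel_size)) / 1000.0


@dataclass(frozen=True)
class DualEchoSeries:
    """Raw 4D dual-echo acquisition: echo 1 is ASL-weighted, echo 2 BOLD-weighted.

    Both echoes are (x, y, z, t) arrays sharing the grid and timeline; volumes
    alternate control/label starting with ``timeline.first_volume_type``.
    """

    echo1: np.ndarray
    echo2: np.ndarray
    timeline: AcquisitionTimeline

    def __post_init__(self) -> None:
        if self.echo1.shape != self.echo2.shape:
            raise ValueError("echo1 and echo2 must share shape")
        if self.echo1.ndim != 4:
            raise ValueError("echoes must be 4D (x, y, z, t)")
        nt = self.echo1.shape[-1]
        if nt != self.timeline.n_volumes:
            raise ValueError("time axis length must equal timeline.n_volumes")
        if nt % 2 != 0:
            raise ValueError("time axis length must be even")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.echo1.shape


@dataclass(frozen=True)
class ProcessedSeries:
    """A perfusion-weighted or BOLD time course (4D voxelwise or 1D ROI).

    The time axis is always the last axis; ``sampling_interval`` is the TR.
    """

    values: np.ndarray
    kind: str  # "perfusion-weighted" | "bold"
    sampling_interval: float

    def __post_init__(self) -> None:
        if self.kind not in ("perfusion-weighted", "bold"):
            raise ValueError("kind must be 'perfusion-weighted' or 'bold'")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[-1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_timepoints) * self.sampling_interval


@dataclass(frozen=True)
class EpochMeans:
    """Room-air and hypercapnic signal means (scalar for ROIs, 3D for maps)."""

    s_ra: np.ndarray | float
    s_hc: np.ndarray | float


@dataclass(frozen=True)
class CapnoTrace:
    """A sampled capnograph CO2 waveform."""

    time: np.ndarray
    co2: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        if self.time.shape != self.co2.shape or self.time.ndim != 1:
            raise ValueError("time and co2 must be congruent 1D arrays")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.co2 < 0):
            raise ValueError("co2 must be non-negative")

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])


@dataclass(frozen=True)
class EtCO2Series:
    """Breath-wise end-tidal CO2 values with an alignment lag.

    ``lag_applied`` is 0 until :func:`cvrquant.physio.align_etco2` shifts the
    breath times onto the MRI clock.
    """

    breath_times: np.ndarray
    etco2: np.ndarray
    lag_applied: float = 0.0

    def __post_init__(self) -> None:
        if self.breath_times.shape != self.etco2.shape or self.etco2.ndim != 1:
            raise ValueError("breath_times and etco2 must be congruent 1D arrays")
        if self.etco2.size and (self.etco2.min() < 5.0 or self.etco2.max() > 100.0):
            warnings.warn(
                "end-tidal values outside the [5, 100] mmHg sanity range",
                stacklevel=2,
            )

    def shifted(self, lag: float) -> "EtCO2Series":
        return EtCO2Series(
            breath_times=self.breath_times + lag,
            etco2=self.etco2,
            lag_applied=self.lag_applied + lag,
        )


@dataclass(frozen=True)
class EtCO2Epochs:
    """Epoch-averaged end-tidal CO2: the denominators of the CVR equations."""

    etco2_ra: float
    etco2_hc: float

    def __post_init__(self) -> None:
        if self.etco2_hc <= self.etco2_ra:
            warnings.warn(
                "etco2_hc <= etco2_ra: not a hypercapnic challenge?", stacklevel=2
            )

    @property
    def delta(self) -> float:
        return self.etco2_hc - self.etco2_ra


@dataclass(frozen=True)
class PCImagePair:
    """One phase-contrast acquisition: complex-difference magnitude + velocity map.

    Velocities are through-plane, cm/s, positive in the venous flow direction;
    magnitudes must not exceed the velocity-encoding limit ``venc`` (values
    above it would alias in a real acquisition).
    """

    cd_magnitude: np.ndarray
    velocity: np.ndarray
    voxel_area: float
    venc: float
    state: str  # "RA" | "HC"

    def __post_init__(self) -> None:
        if self.cd_magnitude.shape != self.velocity.shape or self.velocity.ndim != 2:
            raise ValueError("cd_magnitude and velocity must be congruent 2D arrays")
        if self.voxel_area <= 0:
            raise ValueError("voxel_area must be positive")
        if self.state not in ("RA", "HC"):
            raise ValueError("state must be 'RA' or 'HC'")
        if np.any(np.abs(self.velocity) > self.venc):
            raise ValueError("velocity exceeds venc; acquisition would alias")


@dataclass(frozen=True)
class VesselROI:
    """A connected 2D vessel region with its physical area."""

    mask: np.ndarray
    area: float  # cm^2

    @classmethod
    def from_mask(cls, mask: np.ndarray, voxel_area: float) -> "VesselROI":
        if mask.dtype != bool:
            raise ValueError("mask must be boolean")
        return cls(mask=mask, area=float(mask.sum()) * voxel_area)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class FluxPair:
    """SSS blood flux at normocapnia and hypercapnia, ml/min."""

    flux_ra: float
    flux_hc: float

    def __post_init__(self) -> None:
        if self.flux_ra <= 0 or self.flux_hc <= 0:
            raise ValueError("fluxes must be positive")


@dataclass(frozen=True)
class QuantConstants:
    """Constants of the basal-CBF conversion.

    ``sss_to_wb_ratio`` is the fraction of whole-brain flow drained by the
    superior sagittal sinus; ``brain_density`` converts tissue volume to mass;
    ``per100`` expresses CBF per 100 g of tissue.
    """

    sss_to_wb_ratio: float = 0.46
    brain_density: float = 1.06  # g/ml
    per100: float = 100.0


@dataclass(frozen=True)
class CvrMap:
    """A voxelwise CVR map, defined (finite) only inside its mask."""

    values: np.ndarray
    modality: str  # "asl" | "bold"
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.modality not in ("asl", "bold"):
            raise ValueError("modality must be 'asl' or 'bold'")
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask must share shape")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("CVR values inside the mask must be finite")


@dataclass(frozen=True)
class CvrSummary:
    """ROI CVR values for one modality; PC is global (whole-brain only)."""

    modality: str  # "pc" | "asl" | "bold"
    wb: float
    gm: float | None = None
    wm: float | None = None

    def __post_init__(self) -> None:
        if self.modality not in ("pc", "asl", "bold"):
            raise ValueError("modality must be 'pc', 'asl' or 'bold'")
        if self.modality == "pc" and (self.gm is not None or self.wm is not None):
            raise ValueError("PC CVR is global: no gm/wm entries")


@dataclass(frozen=True)
class TestResult:
    """Outcome of one statistical test."""

    estimate: float
    t_statistic: float
    df: float
    p_value: float
    test_name: str

    def __post_init__(self) -> None:
        if self.df <= 0:
            raise ValueError("df must be positive")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")
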