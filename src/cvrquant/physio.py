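"""End-tidal CO2 extraction and temporal alignment to the BOLD signal.

End-tidal values are the per-breath maxima of the capnograph waveform. Because
inhaled CO2 takes several seconds to reach the cerebral vasculature, the
extracted series is aligned to the whole-brain BOLD time course by scanning
candidate lags and keeping the one maximizing the Pearson correlation.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import find_peaks

from .types import CapnoTrace, EtCO2Epochs, EtCO2Series

__all__ = ["extract_etco2", "align_etco2", "epoch_etco2"]


def extract_etco2(
    trace: CapnoTrace, min_breath_interval: float = 2.0
) -> EtCO2Series:
    """Per-breath end-tidal maxima of a capnograph trace.

    Breath peaks are local maxima separated by at least
    ``min_breath_interval`` and at least 50% of the trace's robust maximum
    (98th percentile), which rejects cardiogenic ripples riding on the
    expiratory plateau.
    """
    robust_max = float(np.percentile(trace.co2, 98))
    distance = max(1, int(round(min_breath_interval * trace.sample_rate)))
    peaks, _ = find_peaks(trace.co2, distance=distance, height=0.5 * robust_max)
    if peaks.size == 0:
        raise ValueError("no breath peaks found in the CO2 trace")
    return EtCO2Series(
        breath_times=trace.time[peaks], etco2=trace.co2[peaks], lag_applied=0.0
    )


def align_etco2(
    etco2: EtCO2Series,
    wb_bold: np.ndarray,
    sampling_interval: float,
    max_lag: float = 60.0,
    lag_step: float = 1.0,
) -> tuple[float, EtCO2Series]:
    """Lag maximizing the EtCO2-vs-BOLD cross-correlation.

    The breath series is linearly interpolated onto the BOLD time grid
    (nearest-value extension at the edges) for each candidate lag in
    ``[0, max_lag]`` with step ``lag_step``; the Pearson correlation is
    computed over the overlapping samples only. The lag search is one-sided
    because the lung-to-brain transit delay is non-negative. Ties break toward
    the smallest lag. Returns the winning lag and the series with its breath
    times shifted by ``+lag``.
    """
    bold = np.asarray(wb_bold, dtype=float)
    if bold.ndim != 1 or bold.size < 3:
        raise ValueError("wb_bold must be a 1D time course with >= 3 samples")
    if np.std(bold) == 0:
        raise ValueError("constant BOLD time course: correlation undefined")
    if np.std(etco2.etco2) == 0:
        raise ValueError("constant EtCO2 series: correlation undefined")
    bold_t = np.arange(bold.size) * sampling_interval
    duration = bold_t[-1] - bold_t[0]
    lags = np.arange(0.0, max_lag + 0.5 * lag_step, lag_step)
    best_lag, best_r = None, -np.inf
    for lag in lags:
        bt = etco2.breath_times + lag
        overlap = (bold_t >= bt[0]) & (bold_t <= bt[-1])
        if duration > 0 and (
            bold_t[overlap].size < 3
            or (bold_t[overlap][-1] - bold_t[overlap][0]) < 0.5 * duration
        ):
            continue
        interp = np.interp(bold_t[overlap], bt, etco2.etco2)
        b = bold[overlap]
        if np.std(interp) == 0 or np.std(b) == 0:
            continue
        r = float(np.corrcoef(interp, b)[0, 1])
        if r > best_r:
            best_r, best_lag = r, float(lag)
    if best_lag is None:
        raise ValueError("no candidate lag gave sufficient overlap")
    return best_lag, etco2.shifted(best_lag)


def epoch_etco2(
    aligned: EtCO2Series,
    window_ra: tuple[float, float],
    window_hc: tuple[float, float],
) -> EtCO2Epochs:
    """Mean end-tidal CO2 per half-open epoch window on the aligned clock.

    The same reduction serves both the 4-min ASL/BOLD epochs and the 30-s
    phase-contrast scan windows.
    """
    bt = aligned.breath_times
    out = []
    for t0, t1 in (window_ra, window_hc):
        sel = (bt >= t0) & (bt < t1)
        if sel.sum() < 2:
            raise ValueError(f"fewer than 2 breaths in window [{t0}, {t1})")
        out.append(float(aligned.etco2[sel].mean()))
    return EtCO2Epochs(etco2_ra=out[0], etco2_hc=out[1])
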