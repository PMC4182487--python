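"""Acoustic quantification of impulse responses.

Three standard room-acoustic measures used to validate the synthetic
filters: the direct-to-reverberant energy ratio (D/R), the Schroeder
backward-integrated reverberation time (RT60), and an early-reflection
census.  Binaural pairs are scored per channel; D/R values of a pair are
averaged in dB so each condition yields one number.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .binaural_synth import FS, _direct_onset

__all__ = [
    "AcousticReport",
    "estimate_drr",
    "estimate_rt60",
    "detect_reflections",
    "acoustic_report",
]


@dataclass
class AcousticReport:
    """Summary acoustics of one impulse response."""

    drr_db: float
    rt60: float
    reflection_times: np.ndarray  # seconds after the direct peak
    direct_onset: float  # seconds


def _channels(ir: np.ndarray) -> np.ndarray:
    ir = np.atleast_2d(np.asarray(ir, float))
    if not np.any(np.abs(ir) > 0):
        raise ValueError("silent impulse response")
    return ir


def _direct_peaks(ir: np.ndarray, fs: int, search: float = 0.0015) -> np.ndarray:
    """Per-channel index of the direct-path peak.

    The direct arrival of a strongly head-shadowed ear can be weaker than
    later reflections, so the per-channel peak is searched only within
    ``search`` seconds of the pair's common direct onset rather than taken
    as the global maximum.
    """
    onset = _direct_onset(ir)
    hi = min(ir.shape[-1], onset + int(round(search * fs)) + 1)
    return onset + np.argmax(np.abs(ir[:, onset:hi]), axis=1)


def estimate_drr(
    ir: np.ndarray, fs: int = FS, direct_window: float = 0.001
) -> float:
    """Direct-to-reverberant energy ratio in dB.

    The direct part is the window [peak - 0.5 ms, peak + ``direct_window``]
    around the main peak of each channel; everything after counts as
    reverberant.  The 1 ms default direct window sits safely inside the
    default room's ~2.6 ms first-reflection gap.  Returns +inf when the
    tail holds less than 1e-12 of the total energy.  Channel values of a
    binaural pair are averaged in dB.
    """
    ir = _channels(ir)
    vals = []
    for ch, peak in zip(ir, _direct_peaks(ir, fs)):
        e = ch**2
        peak = int(peak)
        lo = max(0, peak - int(round(0.0005 * fs)))
        hi = min(ch.size, peak + int(round(direct_window * fs)) + 1)
        direct = e[lo:hi].sum()
        tail = e[hi:].sum()
        if tail < 1e-12 * e.sum():
            vals.append(np.inf)
        else:
            vals.append(10.0 * np.log10(direct / tail))
    return float(np.mean(vals))


def estimate_rt60(ir: np.ndarray, fs: int = FS) -> float:
    """Reverberation time from the Schroeder energy decay curve.

    Backward-integrates the squared response, fits a line to the -5..-35 dB
    span of the decay, and doubles the fitted 30 dB time.  If the response
    never decays 35 dB below its initial level the estimate is flagged with
    a warning and computed on the available span.
    """
    ir = _channels(ir)
    e = np.sum(ir**2, axis=0)
    edc = np.cumsum(e[::-1])[::-1]
    edc /= edc[0]
    db = 10.0 * np.log10(np.maximum(edc, 1e-30))
    t = np.arange(e.size) / fs

    floor = -35.0
    if db.min() > -35.0:
        floor = db.min() + 1.0
        warnings.warn(
            f"impulse response shows only {-db.min():.1f} dB of decay; "
            "RT60 estimate uses a reduced span",
            stacklevel=2,
        )
    span = (db <= -5.0) & (db >= floor)
    if span.sum() < 2:
        raise ValueError("too little decay range for an RT60 estimate")
    slope, _ = np.polyfit(t[span], db[span], 1)
    if slope >= 0:
        raise ValueError("energy decay curve is not decreasing")
    return float(-60.0 / slope)


def detect_reflections(
    ir: np.ndarray, fs: int = FS, rel_threshold_db: float = -20.0
) -> np.ndarray:
    """Times (s after the direct peak) of early reflected arrivals.

    Local maxima of |ir| after the direct peak that exceed
    ``rel_threshold_db`` relative to it, separated from the peak and from
    each other by at least 0.25 ms (to avoid counting filter ringing).
    Binaural pairs are censused per channel against each channel's own
    direct peak -- the contralateral ear's delayed direct arrival is
    binaural structure, not a reflection -- and the merged times are
    returned.
    """
    if rel_threshold_db >= 0:
        raise ValueError("rel_threshold_db must be negative (relative to peak)")
    ir = _channels(ir)
    sep = max(1, int(round(0.00025 * fs)))
    times = []
    for ch, peak in zip(ir, _direct_peaks(ir, fs)):
        env = np.abs(ch)
        peak = int(peak)
        height = env[peak] * 10.0 ** (rel_threshold_db / 20.0)
        tail = env[peak + sep :]
        if tail.size == 0:
            continue
        idx, _ = signal.find_peaks(tail, height=height, distance=sep)
        times.extend((idx + sep) / fs)
    if not times:
        return np.array([])
    # merge channel censuses: collapse arrivals closer than the separation
    times = np.sort(np.asarray(times))
    merged = [times[0]]
    for t in times[1:]:
        if t - merged[-1] >= sep / fs:
            merged.append(t)
    return np.array(merged)


def acoustic_report(
    ir: np.ndarray,
    fs: int = FS,
    direct_window: float = 0.001,
    rel_threshold_db: float = -20.0,
) -> AcousticReport:
    """Bundle D/R, RT60 and the reflection census for one response."""
    ir = _channels(ir)
    env = np.max(np.abs(ir), axis=0)
    onset = _direct_onset(ir) / fs
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            rt60 = estimate_rt60(ir, fs)
        except ValueError:
            rt60 = float("nan")
    return AcousticReport(
        drr_db=estimate_drr(ir, fs, direct_window),
        rt60=rt60,
        reflection_times=detect_reflections(ir, fs, rel_threshold_db),
        direct_onset=onset,
    )
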