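"""Amplitude-modulated noise carrier and quantized auditory motion rendering.

The moving stimulus is built the way discrete virtual-auditory-space motion
is produced in practice: one long noise carrier is cut into per-position
segments whose duration encodes the velocity (dwell = step / velocity), each
segment is convolved with the binaural filter pair of its azimuth, and the
convolution tail of every segment is overlap-added onto the next so the
summed two-channel signal is exactly continuous.  With a constant filter at
all positions the segmented render equals one full convolution sample for
sample, which is the oracle the tests lean on.

Carrier: white noise shaped by a bank of 79 bandpass filters (centres
400..16000 Hz every 200 Hz, nominal 100 Hz bandwidth) under a common 20 Hz
full-depth raised-sine envelope, encouraging a single coherent auditory
object.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal

from .binaural_synth import FS, SpatialFilterSet

__all__ = [
    "VELOCITIES",
    "MotionPath",
    "BinauralStimulus",
    "segment_dwell",
    "carrier_filter_bank",
    "make_carrier",
    "plan_trajectory",
    "render_motion",
    "total_duration",
    "normalize_stimulus",
]

#: study velocities, degrees / s
VELOCITIES = (25.0, 50.0, 100.0)

#: visual trajectory endpoints, degrees
VISUAL_SPAN = (-70.0, 70.0)

CENTER_FREQS = np.arange(400.0, 16000.0 + 1.0, 200.0)
BAND_HALF_WIDTH = 50.0
AM_RATE = 20.0


@dataclass(frozen=True)
class MotionPath:
    """A straight sweep over the azimuth grid at constant velocity.

    ``start_az``/``end_az`` are inclusive endpoints on a grid of spacing
    ``step`` degrees; ``velocity`` is in degrees/s; ``direction`` is
    ``"rightward"`` (increasing azimuth) or ``"leftward"``.
    """

    start_az: float
    end_az: float
    step: float
    velocity: float
    direction: str

    def __post_init__(self) -> None:
        if self.step <= 0 or self.velocity <= 0:
            raise ValueError("step and velocity must be positive")
        if self.direction not in ("leftward", "rightward"):
            raise ValueError(f"unknown direction {self.direction!r}")
        span = self.end_az - self.start_az
        if abs(span / self.step - round(span / self.step)) > 1e-9:
            raise ValueError("(end_az - start_az) must be a multiple of step")
        sign = 1.0 if self.direction == "rightward" else -1.0
        if span * sign < 0:
            raise ValueError("direction inconsistent with start/end azimuths")

    @property
    def n_positions(self) -> int:
        return int(round(abs(self.end_az - self.start_az) / self.step)) + 1

    def positions(self) -> np.ndarray:
        """Occupied azimuths, both endpoints inclusive, in travel order."""
        return np.linspace(self.start_az, self.end_az, self.n_positions)

    def mirrored(self) -> "MotionPath":
        """Left-right reflection of the path."""
        flip = {"leftward": "rightward", "rightward": "leftward"}
        return MotionPath(-self.start_az, -self.end_az, self.step,
                          self.velocity, flip[self.direction])


@dataclass
class BinauralStimulus:
    """Rendered two-channel waveform plus its motion bookkeeping.

    ``segment_boundaries[k]`` is the output sample at which the k-th
    occupied azimuth starts; the final entry is the end of the last dwell
    (the filter tail extends beyond it).
    """

    waveform: np.ndarray  # (2, n)
    fs: int
    path: MotionPath
    segment_boundaries: np.ndarray
    rms: np.ndarray  # per channel


def segment_dwell(velocity: float, step: float) -> float:
    """Seconds spent at each quantized position: step / velocity."""
    if velocity <= 0 or step <= 0:
        raise ValueError("velocity and step must be positive")
    return step / velocity


def total_duration(path: MotionPath) -> float:
    """Stimulus duration: positions (endpoints inclusive) x dwell."""
    return path.n_positions * segment_dwell(path.velocity, path.step)


@lru_cache(maxsize=4)
def carrier_filter_bank(fs: int = FS, numtaps: int = 3501) -> tuple[np.ndarray, ...]:
    """The 79 linear-phase bandpass kernels of the carrier filter bank.

    Kaiser design with ~60 dB stopband; 200 Hz centre spacing with 100 Hz
    nominal bandwidth leaves deliberate spectral gaps between bands.
    """
    return tuple(
        signal.firwin(
            numtaps,
            [fc - BAND_HALF_WIDTH, fc + BAND_HALF_WIDTH],
            fs=fs,
            pass_zero=False,
            window=("kaiser", 5.653),
        )
        for fc in CENTER_FREQS
    )


def make_carrier(
    duration: float, fs: int = FS, seed: int = 0, rms: float = 0.1
) -> np.ndarray:
    """Multiband amplitude-modulated noise carrier.

    White noise is passed through the summed filter bank (equivalent to
    filtering per band and summing, since every band shares the same
    envelope) and multiplied by a full-depth 20 Hz raised-sine envelope
    starting at its minimum.  Output is scaled to ``rms``; the same seed
    yields a bit-identical carrier.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration * fs))
    noise = np.random.default_rng(seed).standard_normal(n)
    kernel = np.sum(carrier_filter_bank(fs), axis=0)
    shaped = signal.fftconvolve(noise, kernel, mode="same")
    t = np.arange(n) / fs
    envelope = 0.5 - 0.5 * np.cos(2.0 * np.pi * AM_RATE * t)
    x = shaped * envelope
    return x * (rms / np.sqrt(np.mean(x**2)))


def plan_trajectory(visual_path: MotionPath, offset: float) -> MotionPath:
    """Auditory path displaced ``offset`` degrees from the visual path.

    Positive offsets are an auditory lag (visual lead): the auditory path
    trails the visual one against the direction of motion.  Negative
    offsets put audition ahead.  The displaced path must stay on the
    measured -90..+90 degree grid.
    """
    if abs(offset) > 20.0 + 1e-9:
        raise ValueError("offsets beyond +-20 degrees are outside the design")
    sign = 1.0 if visual_path.direction == "rightward" else -1.0
    start = visual_path.start_az - sign * offset
    end = visual_path.end_az - sign * offset
    if not (-90.0 <= start <= 90.0 and -90.0 <= end <= 90.0):
        raise ValueError(
            f"auditory path {start:g}..{end:g} leaves the measured -90..+90 grid"
        )
    return MotionPath(start, end, visual_path.step, visual_path.velocity,
                      visual_path.direction)


def _boundaries(n_positions: int, dwell: float, fs: int) -> np.ndarray:
    """Segment start samples; rounding the cumulative clock keeps the
    accumulated drift below one sample over any trajectory."""
    return np.rint(np.arange(n_positions + 1) * dwell * fs).astype(int)


def render_motion(
    carrier: np.ndarray,
    path: MotionPath,
    filters: SpatialFilterSet,
    join: str = "overlap_add",
    xfade: float = 0.002,
) -> BinauralStimulus:
    """Render apparent motion by segment-wise binaural convolution.

    Each consecutive carrier slice of one dwell is convolved with the
    filter pair at its azimuth.  ``join="overlap_add"`` (default) adds
    every segment's convolution tail onto the following segment's output
    -- the exact splice for piecewise time-invariant filtering.
    ``join="crossfade"`` instead renders overlapping slices and linearly
    crossfades them over ``xfade`` seconds.
    """
    if join not in ("overlap_add", "crossfade"):
        raise ValueError(f"unknown join mode {join!r}")
    if not np.isclose(filters.step, path.step):
        raise ValueError(
            f"filter grid step {filters.step:g} != path step {path.step:g}"
        )
    fs = filters.fs
    dwell = segment_dwell(path.velocity, path.step)
    positions = path.positions()
    bounds = _boundaries(len(positions), dwell, fs)
    need = bounds[-1]
    if carrier.shape[-1] < need:
        raise ValueError(
            f"carrier has {carrier.shape[-1]} samples; path needs {need}"
        )
    flen = filters.length
    out = np.zeros((2, need + flen - 1))

    if join == "overlap_add":
        for k, az in enumerate(positions):
            pair = filters.pair_for(az)
            seg = carrier[bounds[k] : bounds[k + 1]]
            out[:, bounds[k] : bounds[k + 1] + flen - 1] += signal.fftconvolve(
                pair, seg[None, :], axes=1
            )
    else:
        # each interior boundary owns a window of nx samples ending at the
        # boundary, shared by complementary linear ramps so the weighted
        # slices sum exactly to the carrier
        nx = max(1, int(round(xfade * fs)))
        w_up = (np.arange(nx) + 0.5) / nx
        for k, az in enumerate(positions):
            pair = filters.pair_for(az)
            lo = bounds[k] - nx if k > 0 else bounds[k]
            lo = max(lo, 0)
            seg = carrier[lo : bounds[k + 1]].copy()
            ramp = bounds[k] - lo
            if ramp:
                seg[:ramp] *= w_up[-ramp:]
            if k < len(positions) - 1 and seg.size >= nx:
                seg[-nx:] *= 1.0 - w_up
            conv = signal.fftconvolve(pair, seg[None, :], axes=1)
            out[:, lo : lo + conv.shape[1]] += conv

    rms = np.sqrt(np.mean(out**2, axis=1))
    return BinauralStimulus(out, fs, path, bounds, rms)


def normalize_stimulus(stim: BinauralStimulus, peak_db: float = -1.0) -> BinauralStimulus:
    """Scale the waveform so its peak sits at ``peak_db`` dBFS."""
    peak = np.max(np.abs(stim.waveform))
    if peak == 0:
        return stim
    scaled = stim.waveform * (10.0 ** (peak_db / 20.0) / peak)
    return BinauralStimulus(scaled, stim.fs, stim.path, stim.segment_boundaries,
                            np.sqrt(np.mean(scaled**2, axis=1)))
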