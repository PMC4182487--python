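"""Synthetic binaural spatial filters.

Stand-ins for measured head-related impulse responses (HRIRs) and binaural
room impulse responses (BRIRs):

* a spherical-head model -- Woodworth interaural time difference plus a
  first-order head-shadow (Duda--Martens style) interaural level filter --
  for the anechoic case;
* a shoebox image-source model, with every reflected arrival spatialized
  through the same spherical-head model, for the reverberant case;
* an exponential sine-sweep (ESS) generate/deconvolve chain emulating the
  impulse-response measurement procedure; and
* the 21 ms BRIR truncation applied before reverberant rendering.

All azimuths are in degrees, 0 straight ahead, positive to the right.
The fixed study sample rate is 48 kHz.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal
from scipy.fft import next_fast_len, rfft, irfft

__all__ = [
    "FS",
    "SPEED_OF_SOUND",
    "DEFAULT_HEAD_RADIUS",
    "BRIR_KEEP_S",
    "RoomSpec",
    "SpatialFilterSet",
    "default_room",
    "woodworth_itd",
    "synth_hrir",
    "sabine_absorption",
    "enumerate_image_sources",
    "image_source_brir",
    "ess_generate",
    "ess_deconvolve",
    "truncate_brir",
    "build_filter_set",
]

log = logging.getLogger(__name__)

FS = 48000
SPEED_OF_SOUND = 343.0
DEFAULT_HEAD_RADIUS = 0.0875
#: seconds of BRIR kept after the direct-path onset when rendering
BRIR_KEEP_S = 0.021

# half-width (samples) of the windowed-sinc fractional-delay kernel
_KHALF = 32


# ---------------------------------------------------------------------------
# room geometry


@dataclass(frozen=True)
class RoomSpec:
    """Shoebox room for image-source BRIR synthesis.

    The default geometry is a small listening room of 17 m^3 with a
    reverberation time target of 200 ms.  The listener sits off-centre so
    that the first reflected path (the ceiling image) trails the direct
    sound by ~2.6 ms at every source azimuth on the frontal arc.

    Parameters
    ----------
    dimensions
        Interior (x, y, z) extents in metres; x is the listener's
        left-right axis, y points straight ahead, z is up.
    listener_position
        Head centre in room coordinates, metres.
    target_rt60
        Desired broadband reverberation time, seconds.
    wall_absorption
        Uniform energy absorption coefficient of all six surfaces in
        (0, 1].  ``None`` means "derive from ``target_rt60`` via Sabine".
    speed_of_sound
        m/s.
    source_radius
        Distance of the loudspeaker arc from the listener, metres.
    """

    dimensions: tuple[float, float, float] = (3.4, 2.5, 2.0)
    listener_position: tuple[float, float, float] = (1.7, 0.8, 1.2)
    target_rt60: float = 0.2
    wall_absorption: float | None = None
    speed_of_sound: float = SPEED_OF_SOUND
    source_radius: float = 1.0

    def __post_init__(self) -> None:
        dims = np.asarray(self.dimensions, float)
        pos = np.asarray(self.listener_position, float)
        if dims.shape != (3,) or np.any(dims <= 0):
            raise ValueError("dimensions must be three positive lengths")
        if self.wall_absorption is not None and not (0.0 < self.wall_absorption <= 1.0):
            raise ValueError("wall_absorption must lie in (0, 1]")
        if self.target_rt60 <= 0:
            raise ValueError("target_rt60 must be positive")
        if self.source_radius <= 0:
            raise ValueError("source_radius must be positive")
        if np.any(pos <= 0) or np.any(pos >= dims):
            raise ValueError("listener must be strictly inside the room")
        # the whole frontal source arc must fit inside the room
        r = self.source_radius
        lo = pos - np.array([r, 0.0, 0.0])
        hi = pos + np.array([r, r, 0.0])
        if np.any(lo <= 0) or np.any(hi >= dims):
            raise ValueError("source arc extends outside the room")

    @property
    def volume(self) -> float:
        return float(np.prod(self.dimensions))

    @property
    def surface_area(self) -> float:
        lx, ly, lz = self.dimensions
        return 2.0 * (lx * ly + lx * lz + ly * lz)

    def absorption(self) -> float:
        """Energy absorption coefficient, explicit or Sabine-derived."""
        if self.wall_absorption is not None:
            return self.wall_absorption
        return sabine_absorption(self)

    def source_position(self, azimuth: float) -> np.ndarray:
        """Loudspeaker position at ``azimuth`` degrees on the frontal arc."""
        if not -90.0 <= azimuth <= 90.0:
            raise ValueError(f"azimuth {azimuth:g} outside [-90, 90]")
        th = np.radians(azimuth)
        pos = np.asarray(self.listener_position, float) + self.source_radius * np.array(
            [np.sin(th), np.cos(th), 0.0]
        )
        dims = np.asarray(self.dimensions, float)
        if np.any(pos <= 0) or np.any(pos >= dims):
            raise ValueError("source position outside the room")
        return pos


def default_room(target_rt60: float = 0.2) -> RoomSpec:
    """The study's default 17 m^3 listening room."""
    return RoomSpec(target_rt60=target_rt60)


def sabine_absorption(room: RoomSpec) -> float:
    """Uniform absorption coefficient hitting ``room.target_rt60`` (Sabine).

    alpha = 0.161 V / (S RT60).  Raises if the requested RT60 is so short
    that the room cannot physically provide it (alpha would exceed 1).
    """
    alpha = 0.161 * room.volume / (room.surface_area * room.target_rt60)
    if alpha > 1.0:
        raise ValueError(
            f"infeasible room: Sabine absorption {alpha:.3f} > 1; "
            "shrink target_rt60 or grow the room"
        )
    return float(alpha)


# ---------------------------------------------------------------------------
# spherical-head anechoic model


def woodworth_itd(
    azimuth: float | np.ndarray,
    head_radius: float = DEFAULT_HEAD_RADIUS,
    speed_of_sound: float = SPEED_OF_SOUND,
):
    """Signed interaural time difference (s) of a rigid spherical head.

    ITD(theta) = a/c (theta + sin theta), theta in radians; positive for
    sources to the right (left ear lags).  Antisymmetric in azimuth and
    strictly increasing on [0, 90] degrees.
    """
    th = np.radians(azimuth)
    return head_radius / speed_of_sound * (th + np.sin(th))


def _windowed_sinc(length: int, delay: float) -> np.ndarray:
    """Unit impulse at fractional ``delay`` samples (Hann-windowed sinc)."""
    x = np.arange(length) - delay
    out = np.zeros(length)
    m = np.abs(x) <= _KHALF
    out[m] = np.sinc(x[m]) * (0.5 * (1.0 + np.cos(np.pi * x[m] / _KHALF)))
    return out


def _shadow_coeffs(theta_inc_deg: float, head_radius: float, speed_of_sound: float, fs: int):
    """First-order head-shadow filter for an ear at incidence ``theta_inc_deg``.

    Single pole/zero spherical-head approximation: H(s) =
    (1 + alpha s / (2 w0)) / (1 + s / (2 w0)) with w0 = c/a; alpha runs from
    2 (bright side, +6 dB high shelf) to 0.1 (deep shadow near 150 deg).
    """
    w0 = speed_of_sound / head_radius
    alpha = 1.05 + 0.95 * np.cos(np.radians(theta_inc_deg * 180.0 / 150.0))
    return signal.bilinear([alpha / (2.0 * w0), 1.0], [1.0 / (2.0 * w0), 1.0], fs)


def _spatial_ir(
    azimuth: float,
    fs: int,
    head_radius: float,
    speed_of_sound: float,
    length: int,
    base_delay: float,
) -> np.ndarray:
    """(left, right) impulse responses with Woodworth ITD + head shadow.

    ``base_delay`` (samples, may be fractional) is the arrival time of the
    interaural midpoint; each ear is offset by +-ITD/2 around it.
    """
    itd = woodworth_itd(azimuth, head_radius, speed_of_sound)
    half = 0.5 * itd * fs
    ears = (
        (base_delay + half, abs(azimuth + 90.0)),  # left ear at -90 deg
        (base_delay - half, abs(azimuth - 90.0)),  # right ear at +90 deg
    )
    out = np.empty((2, length))
    for ch, (dly, inc) in enumerate(ears):
        b, a = _shadow_coeffs(inc, head_radius, speed_of_sound, fs)
        out[ch] = signal.lfilter(b, a, _windowed_sinc(length, dly))
    return out


def _base_delay(fs: int) -> float:
    """Causal headroom for the fractional-delay kernel and the ITD."""
    return max(_KHALF + 24, round(0.002 * fs))


def synth_hrir(
    azimuth: float,
    head_radius: float = DEFAULT_HEAD_RADIUS,
    fs: int = FS,
    length: int = 256,
) -> np.ndarray:
    """Anechoic spherical-head HRIR pair at ``azimuth`` degrees.

    Returns an array of shape (2, length): (left, right).  The
    contralateral ear is delayed by the Woodworth ITD and low-pass
    shadowed by a first-order filter; at the midline the two ears are
    identical.
    """
    if not -90.0 <= azimuth <= 90.0:
        raise ValueError(f"azimuth {azimuth:g} outside [-90, 90]")
    if head_radius <= 0:
        raise ValueError("head_radius must be positive")
    return _spatial_ir(azimuth, fs, head_radius, SPEED_OF_SOUND, length, _base_delay(fs))


# ---------------------------------------------------------------------------
# image-source reverberant model


def enumerate_image_sources(
    room: RoomSpec, source: Sequence[float], max_order: int
) -> tuple[np.ndarray, np.ndarray]:
    """All image-source positions with total reflection order <= max_order.

    Returns (positions (m, 3), orders (m,)); the order-0 entry is the
    source itself.  Along each axis of a wall pair at 0 and L the images
    of a source at s lie at 2 m L + eps s with eps = +-1, accumulating
    |2m| (eps=+1) or |2m - 1| (eps=-1) reflections.
    """
    if max_order < 0:
        raise ValueError("max_order must be >= 0")
    axes_coord, axes_order = [], []
    mmax = max_order // 2 + 1
    for length, s in zip(room.dimensions, np.asarray(source, float)):
        coord, order = [], []
        for m in range(-mmax, mmax + 1):
            for eps in (1, -1):
                n = abs(2 * m) if eps == 1 else abs(2 * m - 1)
                if n <= max_order:
                    coord.append(2.0 * m * length + eps * s)
                    order.append(n)
        axes_coord.append(np.array(coord))
        axes_order.append(np.array(order))
    ox, oy, oz = np.meshgrid(*axes_order, indexing="ij")
    total = ox + oy + oz
    keep = total <= max_order
    cx, cy, cz = np.meshgrid(*axes_coord, indexing="ij")
    positions = np.stack([cx[keep], cy[keep], cz[keep]], axis=1)
    return positions, total[keep]


def _fold_azimuth(az: np.ndarray) -> np.ndarray:
    """Map arrival azimuths in (-180, 180] onto the frontal [-90, 90] grid.

    The spherical-head model is front-back symmetric, so rear arrivals are
    mirrored about the interaural axis.
    """
    az = np.where(az > 90.0, 180.0 - az, az)
    return np.where(az < -90.0, -180.0 - az, az)


def image_source_brir(
    room: RoomSpec,
    azimuth: float,
    max_order: int = 3,
    fs: int = FS,
    head_radius: float = DEFAULT_HEAD_RADIUS,
    ir_length: int | None = None,
    exact_order: int = 1,
) -> np.ndarray:
    """Binaural room impulse response via the image-source method.

    Each image arrival is spatialized through the spherical-head model at
    its (front-back folded) arrival azimuth, delayed by distance/c,
    scaled by 1/distance, and attenuated in ENERGY by (1 - alpha) per
    wall bounce (amplitude sqrt(1 - alpha)^order), consistent with the
    Sabine absorption used to size alpha.  Returns shape (2, n); time
    zero is the emission instant, so the direct path peaks near
    source_radius / c.

    The direct path and reflections up to ``exact_order`` are rendered
    with exact fractional delays; higher-order arrivals reuse cached head
    filters on a 1 degree azimuth grid and nearest-sample delays (a
    <= 10.4 us timing quantization, irrelevant for decay statistics but
    much faster for the dense late field).
    """
    src = room.source_position(azimuth)
    listener = np.asarray(room.listener_position, float)
    alpha = room.absorption()
    refl = np.sqrt(max(0.0, 1.0 - alpha))

    positions, orders = enumerate_image_sources(room, src, max_order)
    vec = positions - listener
    dist = np.linalg.norm(vec, axis=1)
    az_arr = _fold_azimuth(np.degrees(np.arctan2(vec[:, 0], vec[:, 1])))
    amp = refl ** orders / dist
    delay = dist / room.speed_of_sound * fs  # samples, fractional

    base = _base_delay(fs)
    local_len = int(base) + 160
    n = ir_length or int(np.ceil(delay.max())) + local_len + 8
    out = np.zeros((2, n))
    cache: dict[int, np.ndarray] = {}
    for a_i, amp_i, d_i, o_i in zip(az_arr, amp, delay, orders):
        k0 = int(np.floor(d_i)) - int(base)
        if k0 < 0:
            raise ValueError("room too small for the synthesis pre-delay")
        if o_i <= exact_order:
            frac = d_i - np.floor(d_i)
            pair = _spatial_ir(float(a_i), fs, head_radius,
                               room.speed_of_sound, local_len, base + frac)
        else:
            key = int(round(a_i))
            if key not in cache:
                cache[key] = _spatial_ir(float(key), fs, head_radius,
                                         room.speed_of_sound, local_len,
                                         float(base))
            pair = cache[key]
            k0 = int(round(d_i)) - int(base)
        hi = min(n, k0 + local_len)
        out[:, k0:hi] += amp_i * pair[:, : hi - k0]
    log.debug(
        "image_source_brir az=%g order<=%d images=%d alpha=%.3f",
        azimuth, max_order, len(orders), alpha,
    )
    return out


# ---------------------------------------------------------------------------
# exponential sine-sweep measurement chain


def ess_generate(
    f1: float, f2: float, duration: float, fs: int = FS
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential sine sweep and its deconvolution inverse filter.

    The sweep is the standard log sweep x(t) = sin(2 pi f1 L (e^{t/L}-1)),
    L = T / ln(f2/f1).  The inverse is the amplitude-compensated
    time-reversed sweep, realized by regularized spectral inversion with
    raised-cosine skirts outside [f1, f2], so that
    ``sweep * inverse`` is a band-limited unit delta at lag
    ``len(inverse) // 2`` (the convention :func:`ess_deconvolve` assumes).
    """
    if not 0.0 < f1 < f2 < fs / 2.0:
        raise ValueError("need 0 < f1 < f2 < fs/2")
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    rate = np.log(f2 / f1)
    sweep_len_s = n / fs
    ell = sweep_len_s / rate
    sweep = np.sin(2.0 * np.pi * f1 * ell * (np.exp(t / ell) - 1.0))

    # centre the design delay with enough headroom that the band-limited
    # delta's ringing never wraps: the linear and circular convolutions
    # then agree exactly
    ring = int(round(0.25 * fs))
    mfft = next_fast_len(2 * (n + ring))
    spec = rfft(sweep, mfft)
    freqs = np.arange(spec.size) * fs / mfft

    # flat inside [f1, f2]; half-cosine skirts one third of an octave wide
    lo = f1 * 2.0 ** (-1.0 / 3.0)
    hi = min(f2 * 2.0 ** (1.0 / 3.0), 0.4999 * fs)
    w = np.zeros_like(freqs)
    w[(freqs >= f1) & (freqs <= f2)] = 1.0
    ramp = (freqs > lo) & (freqs < f1)
    w[ramp] = 0.5 - 0.5 * np.cos(np.pi * (freqs[ramp] - lo) / (f1 - lo))
    if hi > f2:
        ramp = (freqs > f2) & (freqs < hi)
        w[ramp] = 0.5 + 0.5 * np.cos(np.pi * (freqs[ramp] - f2) / (hi - f2))

    delay = mfft // 2
    phase = np.exp(-2j * np.pi * np.arange(spec.size) * delay / mfft)
    denom = np.abs(spec) ** 2 + 1e-10 * np.max(np.abs(spec) ** 2)
    # unit in-band gain by construction: sweep * inverse has spectrum
    # w |S|^2 / (|S|^2 + delta) ~= w
    inverse = irfft(np.conj(spec) * w * phase / denom, mfft)
    return sweep, inverse


def ess_deconvolve(
    recording: np.ndarray, inverse: np.ndarray, ir_length: int,
    pre_roll: int = 0,
) -> np.ndarray:
    """Recover an impulse response from a sweep recording.

    ``recording`` is the ESS played through a linear system (possibly
    multichannel, shape (..., n)); lag zero of the recovered response sits
    at index ``len(inverse) // 2`` of the full convolution.  ``pre_roll``
    shifts the capture window ``pre_roll`` samples before lag zero --- as a
    real measurement records ahead of the direct arrival --- so the
    band-limitation pre-ring of an early onset is kept rather than cut.
    """
    recording = np.atleast_2d(recording)
    z = inverse.size // 2 - pre_roll
    if z < 0:
        raise ValueError("pre_roll longer than the inverse filter")
    full = signal.fftconvolve(recording, inverse[None, :], axes=1)
    out = np.zeros((recording.shape[0], ir_length))
    avail = min(ir_length, full.shape[1] - z)
    out[:, :avail] = full[:, z : z + avail]
    return out[0] if out.shape[0] == 1 else out


# ---------------------------------------------------------------------------
# truncation and filter-set assembly


def _direct_onset(ir: np.ndarray, rel_db: float = -20.0) -> int:
    """First sample within ``rel_db`` of the global peak (direct onset)."""
    env = np.max(np.abs(np.atleast_2d(ir)), axis=0)
    if not np.any(env > 0):
        raise ValueError("silent impulse response")
    thresh = env.max() * 10.0 ** (rel_db / 20.0)
    return int(np.argmax(env >= thresh))


def truncate_brir(ir: np.ndarray, keep: float = BRIR_KEEP_S, fs: int = FS) -> np.ndarray:
    """Keep ``keep`` seconds after the direct-path onset, fade the cut.

    A 1 ms raised-cosine tail avoids a spectral splatter click at the cut.
    Responses already shorter than the window are returned unchanged.
    """
    if keep <= 0:
        raise ValueError("keep must be positive")
    n = ir.shape[-1]
    end = _direct_onset(ir) + int(round(keep * fs))
    if n <= end:
        return ir
    out = np.array(ir[..., :end], copy=True)
    fade = min(int(round(0.001 * fs)), end)
    ramp = 0.5 * (1.0 + np.cos(np.pi * np.arange(1, fade + 1) / fade))
    out[..., end - fade :] *= ramp
    return out


@dataclass
class SpatialFilterSet:
    """Grid of binaural impulse-response pairs over frontal azimuth.

    ``pairs`` has shape (n_azimuths, 2, length); row order matches
    ``azimuths`` (uniform, sorted, covering -90..+90 inclusive).
    """

    azimuths: np.ndarray
    step: float
    fs: int
    pairs: np.ndarray
    condition: str

    def __post_init__(self) -> None:
        self.azimuths = np.asarray(self.azimuths, float)
        self.pairs = np.asarray(self.pairs, float)
        az = self.azimuths
        if az.ndim != 1 or az.size < 2:
            raise ValueError("need at least two azimuths")
        if not (np.isclose(az[0], -90.0) and np.isclose(az[-1], 90.0)):
            raise ValueError("grid must cover -90..+90 inclusive")
        if not np.allclose(np.diff(az), self.step):
            raise ValueError("grid must be uniform with the stated step")
        if self.pairs.shape[:2] != (az.size, 2):
            raise ValueError("pairs must be (n_azimuths, 2, length)")
        if not np.all(np.isfinite(self.pairs)):
            raise ValueError("impulse responses must be finite")
        self._index = {round(float(a), 6): i for i, a in enumerate(az)}

    @property
    def length(self) -> int:
        return self.pairs.shape[-1]

    def pair_for(self, azimuth: float) -> np.ndarray:
        """(left, right) impulse responses at ``azimuth``; KeyError if absent."""
        key = round(float(azimuth), 6)
        if key not in self._index:
            raise KeyError(f"azimuth {azimuth:g} not in the {self.condition} filter grid")
        return self.pairs[self._index[key]]


def build_filter_set(
    mode: str,
    step: float | None = None,
    room: RoomSpec | None = None,
    fs: int = FS,
    max_order: int = 3,
    ess_roundtrip: bool = False,
    head_radius: float = DEFAULT_HEAD_RADIUS,
    hrir_length: int = 256,
    keep: float = BRIR_KEEP_S,
) -> SpatialFilterSet:
    """Assemble the -90..+90 degree filter grid for one acoustic condition.

    ``mode`` is ``"anechoic"`` (default 1 degree step) or ``"reverberant"``
    (default 5 degree step; requires a :class:`RoomSpec`).  Reverberant
    filters are image-source BRIRs, optionally passed through the simulated
    ESS measure/deconvolve chain, then truncated to ``keep`` seconds after
    onset.
    """
    if mode not in ("anechoic", "reverberant"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "reverberant" and room is None:
        raise ValueError("reverberant mode requires a RoomSpec")
    if step is None:
        step = 1.0 if mode == "anechoic" else 5.0
    azimuths = np.arange(-90.0, 90.0 + 0.5 * step, step)

    sweep = inverse = None
    if ess_roundtrip:
        sweep, inverse = ess_generate(200.0, 20000.0, 1.0, fs)

    pairs = []
    for az in azimuths:
        if mode == "anechoic":
            ir = synth_hrir(az, head_radius, fs, hrir_length)
        else:
            ir = image_source_brir(room, az, max_order, fs, head_radius)
        if ess_roundtrip:
            rec = signal.fftconvolve(ir, sweep[None, :], axes=1)
            ir = ess_deconvolve(rec, inverse, ir.shape[-1])
        if mode == "reverberant":
            ir = truncate_brir(ir, keep, fs)
        pairs.append(np.atleast_2d(ir))

    length = max(p.shape[-1] for p in pairs)
    stacked = np.zeros((len(pairs), 2, length))
    for i, p in enumerate(pairs):
        stacked[i, :, : p.shape[-1]] = p
    fset = SpatialFilterSet(azimuths, float(step), fs, stacked, mode)
    if room is not None and mode == "reverberant":
        log.info(
            "filter set: %s step=%g deg, alpha=%.3f, length=%d samples",
            mode, step, room.absorption(), length,
        )
    return fset
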