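"""File interfaces: WAV impulse responses and stimuli, CSV tables, JSON configs.

WAV files are 48 kHz float32; filter sets are directories of per-azimuth
stereo files named ``az{+DDD}.wav`` beside a ``meta.json`` describing the
grid.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .binaural_synth import RoomSpec, SpatialFilterSet

__all__ = [
    "write_wav",
    "read_wav",
    "save_filter_set",
    "load_filter_set",
    "room_to_json",
    "room_from_json",
]


def write_wav(path, data: np.ndarray, fs: int) -> None:
    """Write mono (n,) or stereo (2, n) float audio."""
    data = np.asarray(data, np.float32)
    if data.ndim == 2:
        data = data.T  # wavfile expects (n, channels)
    wavfile.write(str(path), fs, data)


def read_wav(path) -> tuple[np.ndarray, int]:
    """Read audio as float (channels-first for stereo)."""
    fs, data = wavfile.read(str(path))
    data = np.asarray(data)
    if data.dtype.kind == "i":
        data = data / float(np.iinfo(data.dtype).max)
    data = data.astype(float)
    if data.ndim == 2:
        data = data.T
    return data, fs


def _az_name(az: float) -> str:
    return f"az{int(round(az)):+04d}.wav"


def save_filter_set(fset: SpatialFilterSet, out_dir) -> Path:
    """Write one stereo WAV per azimuth plus a meta.json of the grid."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for az, pair in zip(fset.azimuths, fset.pairs):
        write_wav(out / _az_name(az), pair, fset.fs)
    meta = dict(
        condition=fset.condition,
        step=fset.step,
        fs=fset.fs,
        azimuths=[float(a) for a in fset.azimuths],
    )
    (out / "meta.json").write_text(json.dumps(meta, indent=2))
    return out


def load_filter_set(in_dir) -> SpatialFilterSet:
    src = Path(in_dir)
    meta = json.loads((src / "meta.json").read_text())
    pairs = []
    for az in meta["azimuths"]:
        data, fs = read_wav(src / _az_name(az))
        if fs != meta["fs"]:
            raise ValueError(f"sample-rate mismatch in {_az_name(az)}")
        pairs.append(np.atleast_2d(data))
    length = max(p.shape[-1] for p in pairs)
    stacked = np.zeros((len(pairs), 2, length))
    for i, p in enumerate(pairs):
        stacked[i, :, : p.shape[-1]] = p
    return SpatialFilterSet(
        np.array(meta["azimuths"]), meta["step"], meta["fs"], stacked,
        meta["condition"],
    )


def room_to_json(room: RoomSpec, path) -> None:
    Path(path).write_text(
        json.dumps(
            dict(
                dimensions=list(room.dimensions),
                listener_position=list(room.listener_position),
                target_rt60=room.target_rt60,
                wall_absorption=room.wall_absorption,
                speed_of_sound=room.speed_of_sound,
                source_radius=room.source_radius,
            ),
            indent=2,
        )
    )


def room_from_json(path) -> RoomSpec:
    cfg = json.loads(Path(path).read_text())
    return RoomSpec(
        dimensions=tuple(cfg["dimensions"]),
        listener_position=tuple(cfg["listener_position"]),
        target_rt60=cfg.get("target_rt60", 0.2),
        wall_absorption=cfg.get("wall_absorption"),
        speed_of_sound=cfg.get("speed_of_sound", 343.0),
        source_radius=cfg.get("source_radius", 1.0),
    )
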