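#!/usr/bin/env python
"""Render example moving stimuli at the three study velocities.

Uses the reverberant 5-degree filter library (built by 01, or rebuilt on
the fly) to render one rightward sweep per velocity at a +5 degree
auditory lag, verifying the printed stimulus durations, and writes the
stereo WAVs plus their segment-boundary tables under results/stimuli/.
"""

import sys
from pathlib import Path

import pandas as pd

from vasmotion import binaural_synth as bs
from vasmotion import io as vio
from vasmotion import renderer as vr

OUT = Path("results/stimuli")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    filters_dir = Path("results/filters/reverberant5")
    if filters_dir.exists():
        fset = vio.load_filter_set(filters_dir)
    else:
        fset = bs.build_filter_set("reverberant", room=bs.default_room())

    for velocity in vr.VELOCITIES:
        visual = vr.MotionPath(-70.0, 70.0, 5.0, velocity, "rightward")
        path = vr.plan_trajectory(visual, offset=5.0)
        duration = vr.total_duration(path)
        carrier = vr.make_carrier(duration + 0.05, fset.fs, seed=int(velocity))
        stim = vr.normalize_stimulus(vr.render_motion(carrier, path, fset))
        name = OUT / f"sweep_{velocity:g}degps.wav"
        vio.write_wav(name, stim.waveform, stim.fs)
        bounds = stim.segment_boundaries
        pd.DataFrame(dict(azimuth=path.positions(),
                          start_sample=bounds[:-1],
                          end_sample=bounds[1:])).to_csv(
            name.with_suffix(".segments.csv"), index=False)
        print(f"{velocity:g} deg/s: {duration:.2f} s over "
              f"{path.n_positions} positions -> {name.name} "
              f"(rms L/R {stim.rms[0]:.3f}/{stim.rms[1]:.3f})")


if __name__ == "__main__":
    sys.exit(main())
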