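#!/usr/bin/env python
"""Repeated-measures ANOVAs on the fitted PSEs and slopes.

Reads results/fits.csv (from 04) and runs the two within-subject 2 x 3
(condition x velocity) decompositions the study design calls for: the
spatial-quantization contrast (anechoic 1 deg vs anechoic 5 deg) and the
reverberation contrast (anechoic 5 deg vs reverberant 5 deg), on both the
PSE and the slope beta.  Under the simulated null configuration both
contrasts should be non-significant at the nominal rate.
"""

import sys
from pathlib import Path

import pandas as pd

from vasmotion.psychometrics import rm_anova

OUT = Path("results")

CONTRASTS = {
    "quantization": ("anechoic1", "anechoic5"),
    "reverberation": ("anechoic5", "reverberant5"),
}


def main() -> None:
    fits = pd.read_csv(OUT / "fits.csv")
    rows = []
    for contrast, conditions in CONTRASTS.items():
        subset = fits[fits.condition.isin(conditions)]
        for measure in ("pse", "beta"):
            table = rm_anova(subset, "condition", "velocity", measure, "subject")
            table.insert(0, "measure", measure)
            table.insert(0, "contrast", contrast)
            rows.append(table)
            line = ", ".join(
                f"{r.effect}: F={r.F:.2f}, p={r.p:.3f}"
                for r in table.itertuples()
            )
            print(f"{contrast} / {measure}: {line}")
    out = pd.concat(rows, ignore_index=True)
    out.to_csv(OUT / "anova.csv", index=False)
    print(f"wrote {OUT / 'anova.csv'}")


if __name__ == "__main__":
    sys.exit(main())
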