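#!/usr/bin/env python
"""Stimulus design from pRF model parameters.

Builds a small synthetic table of candidate pRFs, applies the vertex-selection
rules (eccentricity band 1.5-3 dva, >= 1 dva from the vertical meridian,
r2 > 0.55, sigma1 > 0.50 dva), and, for the selected pRF, derives the
size-tuning curve and the participant-specific stimulus set: the center disc
at the tuning-curve maximum, the largest non-occluded 2-dva annulus, and the
medium annulus halfway in between.

Writes results/stimulus_design.tsv and results/size_tuning.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from lamline.prf import (
    PRFParams,
    ScreenGeometry,
    design_stimulus_set,
    filter_prf_candidates,
    size_tuning_curve,
    spatial_profile_markers,
)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

screen = ScreenGeometry(half_width=8.0, half_height=4.5, pixels_per_dva=20.0)

# synthetic candidate table (id, position, DN parameters, fit quality)
candidates = pd.DataFrame(
    {
        "id": ["v01", "v02", "v03", "v04", "v05"],
        "x": [1.8, 0.4, 2.6, -1.9, 1.2],
        "y": [0.9, 0.2, -1.0, 0.8, 3.2],
        "sigma1": [0.8, 0.7, 0.45, 0.9, 0.8],
        "sigma2": [2.4, 2.1, 1.4, 2.7, 2.4],
        "amp_act": [1.0] * 5,
        "amp_norm": [0.02] * 5,
        "b": [0.0] * 5,
        "d": [0.5] * 5,
        "r2": [0.72, 0.58, 0.80, 0.50, 0.68],
        "merid_dist": [1.8, 0.4, 2.6, 1.9, 1.2],
    }
)
candidates["eccentricity"] = np.hypot(candidates.x, candidates.y)

surviving = filter_prf_candidates(candidates)
print(f"{len(surviving)} / {len(candidates)} candidate pRFs survive selection")
row = surviving.iloc[0]
prf = PRFParams(
    x=row.x, y=row.y, sigma1=row.sigma1, sigma2=row.sigma2,
    amp_act=row.amp_act, amp_norm=row.amp_norm, b=row.b, d=row.d, r2=row.r2,
)

curve = size_tuning_curve(prf, screen)
pd.DataFrame({"radius_dva": curve.radii, "response": curve.responses}).to_csv(
    OUT / "size_tuning.tsv", sep="\t", index=False
)

stimuli = design_stimulus_set(prf, screen)
(fwhm_lo, fwhm_hi), zc = spatial_profile_markers(prf)
rows = [
    {
        "kind": s.kind,
        "inner_radius_dva": s.inner_radius,
        "outer_radius_dva": s.outer_radius,
    }
    for s in stimuli.values()
]
design = pd.DataFrame(rows)
design.to_csv(OUT / "stimulus_design.tsv", sep="\t", index=False)

print(f"selected pRF {row.id}: (x, y) = ({prf.x}, {prf.y}), sigma1 = {prf.sigma1}")
print(f"spatial profile FWHM = {fwhm_hi - fwhm_lo:.2f} dva, zero crossing at "
      f"{'none' if zc is None else f'{zc[1]:.2f} dva'}")
print(design.to_string(index=False))
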