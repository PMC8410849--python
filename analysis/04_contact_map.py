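#!/usr/bin/env python
"""Contact-map layer: masking, SCN normalization, decay and dispersion.

Normalizes the simulated raw map, verifies the decay exponent, and computes
the dispersion index I(s) = var(s)/P(s) per compartment: long-range
(> 100 kb) contacts are substantially more variable in the terminal arms
than in the central compartment, as planted.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from strepfold import contacts
from strepfold.io import read_matrix_tsv, write_matrix_tsv

DATA = Path("results/data")
OUT = Path("results")

cmap_raw = read_matrix_tsv("scratch/matrix_raw.tsv")
truth = json.loads((DATA / "truth.json").read_text())
regions = {name: np.arange(lo, hi + 1)
           for name, (lo, hi) in truth["compartment_bins"].items()}

masked = contacts.mask_low_coverage(cmap_raw)
scn = contacts.scn_normalize(masked)
write_matrix_tsv(scn, "scratch/matrix_scn.tsv")
norms = np.sqrt((scn.matrix ** 2).sum(axis=1))[scn.unmasked()]
print(f"SCN: {len(scn.masked_bins)} bins masked, "
      f"max |row norm - 1| = {np.abs(norms - 1).max():.2e}")

dec = contacts.contact_probability(cmap_raw)
sel = dec[(dec.s_bins >= 1) & (dec.s_bins <= 60)]
slope = np.polyfit(np.log(sel["s_bins"] + 1), np.log(sel["P"]), 1)[0]
print(f"apparent distance-decay exponent (log-log fit, s <= 600 kb): {slope:.2f} "
      "(steeper than the planted alpha = -1 because intra-domain enrichment "
      "boosts short-range contacts)")

rows = []
for name, region in regions.items():
    d = contacts.dispersion_index(contacts.contact_probability(cmap_raw, region))
    d.insert(0, "region", name)
    rows.append(d)
pd.concat(rows).to_csv(OUT / "dispersion.tsv", sep="\t", index=False)

lr = contacts.long_range_dispersion(cmap_raw, regions)
ratio = 0.5 * (lr["left"] + lr["right"]) / lr["central"]
print("long-range (> 100 kb) dispersion index: "
      + ", ".join(f"{k} {v:.1f}" for k, v in lr.items()))
print(f"arm/center dispersion ratio: {ratio:.1f} "
      "(terminal contacts are more variable, as planted at 3x)")
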