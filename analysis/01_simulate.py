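#!/usr/bin/env python
"""Generate the synthetic study bundle: annotation, orthologs, counts, 3C map.

Emulates the data structure of the real study — a ~6.7 Mb TIR-trimmed linear
chromosome whose central compartment (delimited by the outermost rDNA operons
at ~1.47 and ~5.80 Mb) is conserved and highly expressed while the terminal
arms are variable and quiescent in exponential phase — and writes the tables
the downstream analysis steps read.  The planted truth (islands, boundaries,
compartments) goes to results/data/truth.json.
"""

import json
from pathlib import Path

import numpy as np

from strepfold import synthdata
from strepfold.genome import genes_to_frame
from strepfold.io import write_matrix_tsv

SEED = 1
OUT = Path("results/data")
OUT.mkdir(parents=True, exist_ok=True)

print("## simulating annotation (2000 genes, rDNA-partitioned chromosome)")
genes, partition = synthdata.synth_genome(n_genes=2000, seed=SEED)
genes_to_frame(genes).to_csv(OUT / "genes.tsv", sep="\t", index=False)

print("## simulating orthologs across 8 genomes with one planted 20-CDS island")
island_spec = [{"ref_start": 150, "n_cds": 20, "side": "reference"}]
table, island_truth = synthdata.synth_orthologs(
    genes, partition, n_genomes=8, island_spec=island_spec, seed=SEED + 1
)
rows = []
for name in table.presence:
    tidx = table.target_index[name]
    for i in np.flatnonzero(table.presence[name]):
        rows.append((name, int(i), int(tidx[i])))
with open(OUT / "orthologs.tsv", "w") as fh:
    fh.write("genome\tref_index\ttarget_index\n")
    for r in rows:
        fh.write("\t".join(map(str, r)) + "\n")

print("## simulating stranded counts (3 conditions x 3 replicates)")
raw_s, raw_a, reps = synthdata.synth_counts(genes, partition, seed=SEED + 2)
raw_s.to_csv(OUT / "counts_sense.tsv", sep="\t")
raw_a.to_csv(OUT / "counts_antisense.tsv", sep="\t")
with open(OUT / "samples.tsv", "w") as fh:
    fh.write("sample\tcondition\n")
    for cond, samples in reps.items():
        for s in samples:
            fh.write(f"{s}\t{cond}\n")

print("## simulating 10-kb contact map (670 bins, 2e6 pairs, 16 boundaries)")
boundaries = list(range(40, 670, 40))
cmap, truth = synthdata.synth_contact_map(
    n_bins=670, boundaries=boundaries, boundary_strength=3.0,
    arm_noise_mult=3.0, n_pairs=2_000_000, seed=SEED + 3,
)
Path("scratch").mkdir(exist_ok=True)
write_matrix_tsv(cmap, "scratch/matrix_raw.tsv")

(OUT / "truth.json").write_text(json.dumps({
    "seed": SEED,
    "islands": island_truth,
    "boundaries": truth.boundaries,
    "compartment_bins": truth.compartment_bins,
    "arm_noise_mult": truth.arm_noise_mult,
    "n_pairs": truth.n_pairs,
}, indent=2))

print(f"wrote {len(genes)} genes, {len(rows)} ortholog assignments, "
      f"{raw_s.to_numpy().sum():,} sense reads, "
      f"{int(np.triu(cmap.matrix, 1).sum() + np.diag(cmap.matrix).sum()):,} "
      "contact pairs")
print("raw contact matrix -> scratch/matrix_raw.tsv (large, regenerable)")
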