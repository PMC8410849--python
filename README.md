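# strepfold

Analysis pipeline linking **genetic compartmentalization, transcription and
3D folding** of a linear *Streptomyces*-type bacterial chromosome.
The chromosome is partitioned by its outermost rDNA operons into a conserved,
highly expressed central compartment and two variable, quiescent terminal
arms; `strepfold` quantifies that organisation in three layers and ties them
together at chromosome-interacting-domain (CID) boundaries:

1. **Conservation** — reciprocal-best-hit orthologs, the persistence index
   `N_orth / N` (fraction of surveyed genomes carrying an ortholog), the
   gene-order-conservation index GOC (orthologs in conserved adjacencies over
   orthologs, sliding window of 8 CDSs), genomic-island calling from synteny
   breaks (≥ 15 CDSs between same-direction blocks), and two-sided Fisher
   enrichment of features per compartment.
2. **Expression** — median-of-ratios size factors, antisense-aware
   normalization (the raw antisense percentage applied to normalized sense
   counts), `normRPK = normalized counts / gene length × 1000`, expression
   categories CAT_0..CAT_4, switch-ON genes (CAT_0 in one condition, ≥ CAT_3
   in another), and the antisense index `AS = ΣAS / (ΣS + ΣAS)`.
3. **Folding** — 3C contact maps (in-silico digestion, event filtering,
   10-kb binning), sequential component normalization (SCN: alternate
   column/row division by the Euclidean norm until convergence), the
   **frontier index**: with `L(i,j) = log(M(i,j) − P(|i−j|) + m/20)`,
   directional derivatives of `L` clipped at zero and summed over partners
   within 600 kb give per-bin upstream/downstream profiles; peaks above
   `median + 2·1.48·MAD` (per compartment) that co-occur on one bin or two
   consecutive bins are CID boundaries. The **dispersion index**
   `I(s) = var(s)/P(s)` measures contact variability per compartment.

Every layer has a seeded synthetic generator (`strepfold.synthdata`) that
plants ground truth — islands, boundaries, compartment parameters — so the
whole pipeline is testable end to end without any downloads.

Intended for microbial genomics / chromosome-biology researchers analysing
bacterial 3C/Hi-C data together with comparative genomics and stranded
RNA-seq counts.

## Worked example

```sh
python analysis/01_simulate.py      # synthetic bundle -> results/data/
python analysis/02_conservation.py
python analysis/03_expression.py
python analysis/04_contact_map.py
python analysis/05_frontiers.py
```

Output of the conservation and frontier steps on the default seed:

```
mean persistence: central 0.92 vs arms 0.34 (conserved backbone sits in the central compartment)
mean GOC: central 0.97 vs arms 0.42
5 genomic island(s) called; planted 20-CDS island recovered
SMBGC: odds ratio 19.6 toward arms (two-sided Fisher p = 1.04e-68)
...
11 boundaries called, 15 orphan peaks removed
planted-boundary recovery: 11/16 within +/- 2 bins; 0 false positives (0.00 per Mb)
central domains: 10, sizes 400-400 kb
median persistence of boundary environments: 1.00 (chromosome-wide median 0.88)
```

The central compartment carries the persistent, co-linear backbone; islands
and SMBGCs are enriched in the arms (odds ratio ≫ 1); the frontier index
recovers the planted central boundaries exactly (arm boundaries are partly
hidden by the planted 3× arm noise, mirroring the higher long-range
variability of terminal compartments); and boundary environments are
enriched in persistent genes.

The same run as a single command:

```sh
strepfold run-all --out-dir my_run --seed 1
```

## Layout

```
src/strepfold/      library: genome, conservation, expression, contacts,
                    frontiers, synthdata, io, pipeline, cli
analysis/           numbered narrative drivers over the library
tests/              pytest suite (unit, property and validation tests)
scripts/            acceptance recomputation
docs/methods.md     models, parameters, numerical choices, limitations
```
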