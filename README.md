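# clcrep

Characterization of the antibody repertoire of a **common-light-chain (cLC)
mouse** — an engineered strain whose kappa J locus is replaced by a single
prearranged IGKV10-96/IGKJ1 segment (with the CDR-L3 tryptophan at Chothia
position 96 replaced by leucine), so that every B cell expresses the same
germline light chain. Such animals are a discovery platform for
common-light-chain bispecific antibodies, and the central analytical
question is whether restricting the light chain costs repertoire quality:
heavy-chain diversity, clonal diversity, mutation load, epitope coverage.

`clcrep` is a library plus CLI for the analyses that answer that question
from annotated single-cell V(D)J tables:

- **Pairing filter** — keep cells with exactly one productive heavy and one
  productive light chain.
- **Clonotyping** — greedy CD-HIT-style clustering: cells share a clonotype
  iff they share the heavy V gene, the CDR-H3 length, and ≥ 80% CDR-H3
  amino-acid identity to the cluster representative. Consensus sequences,
  hamming distances, CDR liability flags (N-X-[S/T] sequons, unpaired
  cysteines) and a deterministic clone-selection ranking follow.
- **Diversity** — Gini coefficient G = Σᵢⱼ|xᵢ−xⱼ|/(2n²μ) on a count vector,
  D50 (smallest number of clonotypes holding ≥ 50% of the repertoire),
  top-N rank occupancy, seeded down-sampling, V-gene usage tables,
  chi-squared usage comparison, Wilcoxon rank-sum with BH adjustment.
- **SHM profiling** — per-Chothia-position amino-acid mutation frequencies
  of light chains against the prearranged germline, region summaries
  (CDR-L1/2/3, frameworks) and hotspot reports.
- **Epitope binning** — net flow-cytometry geomean (total geomean of
  reference + panel antibody minus the reference-alone geomean), Pearson
  correlation of competition profiles, single-linkage bin assignment, and
  benchmark matching with novel-bin flagging.
- **Structure mapping** — Shrake–Rupley relative solvent accessibility
  (rSASA) per residue and projection of mutation frequencies onto a Fab
  structure's temperature-factor column.
- **Synthetic repertoire generator** — plants clone-size laws, SHM hotspot
  rates, isotype mixes, dual-allele light chains, multiplets and epitope-bin
  structure, so every stage is benchmarked against known ground truth
  without any data download.

## Worked example

```python
from clcrep import simulate, io, clonotyping, diversity

config = simulate.clcm_like_config(seed=1)          # 2884 cells, 515 planted clonotypes
records, truth = simulate.generate_repertoire(config)
paired, report = io.pair_cells(io.normalize_records(records))
clonotypes, membership = clonotyping.assign_clonotypes(paired, threshold=0.8)
summary = diversity.summarize(clonotypes["size"].to_numpy())
print(report.n_paired, len(clonotypes), summary.d50,
      round(summary.topn_fractions[(1, 10)], 3))
```

prints

```
2395 510 64 0.259
```

meaning: of 2884 simulated cells, 2395 passed the exactly-one-heavy/
one-light filter (the rest were multiplets or dropped light chains); they
cluster into 510 clonotypes (five planted singleton clones lost their only
cell to dropout); the 64 largest clonotypes hold half the repertoire; and
the ten largest hold 25.9% — the skewed occupancy the cLC-mouse-like
conditions plant. The equivalent wildtype-like conditions
(`simulate.wildtype_like_config`) give a flatter repertoire (D50 ≈ 149,
top-10 ≈ 14.6%), reproducing the expected diversity ordering.

The same stages are available as a CLI:

```sh
clcrep simulate repertoire --preset clcm --seed 1 --out sim/
clcrep clonotype sim/rearrangements.tsv --threshold 0.8 --out clono/
clcrep diversity clono/clonotypes.tsv
clcrep run --config pipeline.yaml     # full pipeline with MANIFEST + JSON report
```

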