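# Methods

## The analysis

The package implements the repertoire-characterization workflow used to
evaluate a common-light-chain mouse: single-cell V(D)J annotation tables go
through a pairing filter, heavy-chain clonotype clustering, diversity
statistics, light-chain somatic-hypermutation (SHM) profiling, clone
selection, competitive epitope binning, and structural mapping of mutation
hotspots. Each stage is a library function with a deterministic contract;
the CLI and `run_pipeline` compose them.

### Pairing

A cell is retained iff it carries exactly one productive IGH record and
exactly one productive IGK/IGL record. Non-productive chains are excluded
*before* counting (the analysis concerns expressed BCRs), and a cell with
one kappa plus one lambda chain counts as multi-light. The pairing report
partitions all input cells into paired / multi / unpaired, so
`n_paired + n_dropped_multi + n_dropped_unpaired = n_cells_in` always
holds. Gene calls are compared at gene level (allele suffixes `*01`
stripped, raw calls retained), because usage and clonotype definitions in
this setting are gene-level.

### Clonotyping

Two cells share a clonotype iff they share the heavy V gene, the CDR-H3
length, and ≥ 0.8 CDR-H3 amino-acid identity to the cluster
representative. ">80%" is implemented as ≥ 0.8 (greedy-clustering
semantics use inclusive thresholds; the choice is visible here to avoid
off-by-epsilon surprises). Clustering is greedy and incremental within
each (V gene, CDR-H3 length) block: unique CDR-H3s are processed in
descending multiplicity, ties broken lexicographically; a sequence joins
the first existing cluster whose *founder* it matches at threshold,
otherwise it founds a new cluster. Length is constant inside a block, so
multiplicity is the natural abundance analogue of the usual greedy
seed-ordering; the tie-break makes output deterministic and
permutation-invariant.

Consensus sequences are computed for clonotypes with ≥ 5 members
(per-position modal residue; ties go to the lexicographically smallest
residue). Consensus and hamming distance use the full heavy V-domain when
all members share one length, else the clonotype falls back to CDR-H3 with
a logged downgrade — the strict full-VH reading is preferred, but
indel-bearing clonotypes need a defined behaviour. Liability flags scan
the CDR strings as annotated (no junction re-derivation): `nglyc_cdr` for
an N-X-[S/T] sequon with X ≠ P (also across the CDR3's two-residue right
flank when supplied) and `unpaired_cys_cdr` for any CDR cysteine. Note
that CDR-3 annotations that include the conserved junction cysteine will
always flag; the scan operates on whatever CDR boundaries the annotation
provides.

Clone selection ranks liability-free members of consensus-bearing
clonotypes: clonotypes by size descending (ties: id), one member per
clonotype per round (within a clonotype: hamming to consensus ascending,
then sequence id), so clonotype coverage is exhausted before any clonotype
contributes twice.

### Diversity

- Gini: population mean-absolute-difference form,
  G = Σᵢⱼ|xᵢ−xⱼ| / (2 n² μ), zeros included, no small-sample correction —
  the common default of R inequality packages. A one-hot vector scores
  (n−1)/n.
- D50: smallest k whose k largest counts reach ≥ 50% of the total
  (inclusive reading of "occupy 50%").
- Top-N occupancy: fractions over inclusive 1-based rank intervals
  (defaults 1–10, 11–50, 51–500); ranks beyond the table contribute 0.
- Down-sampling is uniform without replacement, requires an explicit seed,
  and drops any clonotype labels so the caller re-clusters the subsample.
- Usage comparison: Pearson chi-squared without continuity correction on
  the 2×K table after zero-filling both vectors onto their label union and
  dropping pooled-zero categories.
- Group comparison: two-sided Wilcoxon rank-sum (exact for small tie-free
  samples, tie-corrected normal otherwise; two fully tied samples return
  p = 1 by policy), Benjamini–Hochberg adjustment across a batch. BH is a
  declared choice — the protocol this mirrors says only "adjusted
  p-values".

### SHM profile

Each kappa light chain assigned to the prearranged germline is compared
position-by-position: equal lengths give a direct comparison, otherwise a
global alignment (match +2, mismatch −1, gap open −8, gap extend −0.5 —
values chosen so isolated substitutions are never absorbed into gaps at
V-domain length scales). Gap columns are flagged indels and excluded from
substitution counting; records with aligned identity < 50% are rejected
with a logged reason. Frequencies are reported per Chothia label with
per-label denominators (records covering the label), region summaries over
the packaged label ranges (CDR-L1 24–34, CDR-L2 50–56, CDR-L3 89–97,
FR-L1–L4), and hotspot reports rank labels by frequency with ties broken
in numbering order. Dual-allele mixtures are profiled as-is — the
homozygous animal expresses both prearranged alleles and sequencing cannot
separate them, so no deconvolution is attempted.

The numbering for the packaged germline is a static index→label table
(labels "1"–"107", no insertions). This is deliberate: the analysis needs
a handful of positions on one fixed chain, not a general antibody
numbering engine; user-supplied chains bring their own table.

### Epitope binning

The competition statistic is the net geomean,
`net[r, p] = total_geomean[r, p] − reference_alone[r]`; negative values
are retained (clipping would distort correlations) and logged. Panel
profiles (columns over the reference axis) are compared by Pearson
correlation — the spreadsheet correlation coefficient of the original
protocol; zero-variance profiles have no defined correlation and are
excluded with a flag. Bins are single-linkage components of the graph with
edges at r ≥ 0.8 (threshold configurable and echoed in output); labels
A, B, … are assigned by decreasing bin size, ties by first member, making
output permutation-invariant up to renaming. Raising the threshold can
only refine bins.

Benchmark matching assigns a panel antibody to a benchmark's bin iff
(a) the antibody's profile shows genuine competition — its minimum net
geomean is below 0.5× its maximum, the "dark cell" a binning heatmap is
read by — and (b) its correlation with that benchmark is ≥ threshold
(best benchmark wins); otherwise it is novel. The competition gate exists
because a flat, non-competing profile measured over only ~7 references
can correlate with a benchmark through measurement noise alone (with
7-point profiles, noise correlations reach 0.8 a few percent of the
time); requiring observable suppression removes that failure mode without
touching genuinely competing antibodies.

### Structure mapping

Absolute per-residue SASA uses the Shrake–Rupley rolling-probe algorithm
(probe 1.4 Å, Fibonacci meshes, default 1000 points/atom) summed over
heavy atoms; relative SASA divides by the residue type's theoretical
Gly-X-Gly maximum (Tien et al. 2013). Relative values are *uncapped*:
termini and isolated residues can exceed 1 because the reference includes
neighbour occlusion. Chothia-label → PDB-residue maps are explicit inputs.
By default the full deposited assembly is used (a `chains` filter is
available) since the original report does not state whether its rSASA was
computed on the Fab alone.

## The synthetic generator

The generator emulates the *post-annotation* output of a single-cell BCR
experiment on the two pools the analysis contrasts. Defaults are the study
conditions, chosen once:

| parameter | default | rationale |
|---|---|---|
| `n_cells` | 2884 | the paired-cell count both pools are analysed at |
| clone-size law | ranked Zipf, 515 clonotypes, exponent 0.85 (cLC-like); 704 / 0.70 (wildtype-like) | exponents set so the planted top-10 occupancy matches the reported ~26% / ~14% shapes; the true clone-size law of real repertoires is unknown, so the family is configurable and no inference is implied |
| `shm_rates` | hotspots 30/31 = 0.40, 32 = 0.25, 92/93 = 0.50, 94 = 0.25, 83 = 0.30; flat background so Σ = 4.9 | hotspot positions CDR-L1 30–32, CDR-L3 92–94, framework 83; mean amino-acid mutation load 4.9 per light chain (wildtype-like preset scales rates to mean 6.4) |
| `heavy_shm_rate` | 2.0 Poisson substitutions per VH | realistic post-immunization framework load; not analysed downstream |
| `cdrh3_shm_rate` | 0.005 per position | keeps within-clone CDR-H3 identity far above the 0.8 clustering threshold |
| `dual_allele_fraction` | 0.5 | homozygous animals express both alleles; the reported chain is drawn from one of two independently mutated lineages, never both |
| `isotype_probs` | IgG2B 0.35, IgG2C 0.33, IgG1 0.10, IgM 0.09, IgA 0.07, IgD 0.06 | IgG-dominated OVA+ pools with ~10% IgG1 |
| `lambda_fraction` / `editing_fraction` | 0.0002 / 0.0028 (cLC-like) | yields ~99.7% dominant-germline usage with a ~0.02% lambda remainder — the receptor-editing floor the model design aims for; wildtype-like uses 0.02 / 0.60 |
| `multiplet_rate` / `light_dropout_rate` | 0.08 / 0.10 | reproduce the observed ~74–83% pairing survival of real cell-calling |

Planted clonotypes draw a V gene from the usage vector and a random CDR-H3
(length 10–18), rejecting candidates ≥ 50% identical to an earlier
clonotype of the same (gene, length) block, so planted clonotypes are
separable by construction. Nucleotide sequences are deterministic
one-codon-per-residue reverse translations — sufficient for format
round-trips; the generator makes no claim about codon usage or
nucleotide-level SHM targeting (no WRCY motifs, no VDJ machinery, no
class-switch dynamics).

What passing the recovery tests shows: the pipeline correctly inverts this
generative model (clonotype partition, rate vector, clone-size profile,
bin structure) at realistic sizes and noise. What it does not show:
robustness to annotation errors, allele-collapsing artifacts, indel-rich
real SHM, or clone-size laws outside the configured families — real data
keeps those caveats.

The bead-panel generator plants bin labels on references and panel
antibodies; a well's total geomean is the reference baseline plus the
panel antibody's signal, suppressed by `competition_factor` (default 0.05)
for same-bin pairs, under mean-preserving log-normal noise of CV
`noise_cv` (default 0.10; recovery checks use 0.05, a realistic
plate-reader CV).

## Problem sizes and runtime

Recovery checks run at the study scale (2884 cells; 5000 light chains for
SHM expectation checks; 20 replicate pairs for the diversity-ordering
check; 10 seeds × 18-antibody panels for binning), keeping the full suite
around a minute and the acceptance script a few seconds.

## Known limitations

- The greedy clustering depends on its documented seed order; a different
  order can split near-threshold clusters differently (inherent to all
  CD-HIT-style methods). The exhaustive-reference test pins the
  implemented order.
- Liability scanning trusts the annotation's CDR boundaries; junction
  cysteines inside an annotated CDR3 flag as unpaired cysteines.
- The bundled germlines are synthetic stand-ins; analyses of real data
  should supply IMGT references and a matching numbering table.
- rSASA on user structures requires an explicit label→residue map; no
  antibody-numbering engine is included.
- Consensus fallback to CDR-H3 discards framework information for
  indel-bearing clonotypes.
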