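# Methods note

Algorithms, default parameters and data provenance for the hipsurvey
package. Every default below is a configuration key, not a constant:
`SurveySettings`, `GeneratorConfig` and the per-function keyword
arguments expose them all.

## Coordinates and distances

All gene coordinates are GFF3-native: 1-based, inclusive on both ends.
The intergenic distance between genes *a* and *b* on one contig is
`start(b) − end(a) − 1` with the smaller-start gene treated as upstream,
so 0 means abutting genes and negative values mean overlapping genes
(e.g. −20 for a 20-nt overlap). GFF3/FASTA parsing is strict: malformed
lines fail with their line number, duplicate gene IDs fail, and a CDS
without a matching protein record fails naming the gene — features are
never silently dropped.

## Motif models (kinase motifs and domain profiles)

Motifs and domains are scored with log-odds position weight matrices
built from ungapped seed-alignment blocks:

```
entry[i][aa] = log2(((count + pseudocount·bg) / (N + pseudocount)) / bg)
```

with pseudocount 1.0 and a uniform background (bg = 0.05) by default;
scores are in bits and `X` scores a column's mean. A window scan reports
the best-scoring window (leftmost on ties) and calls a hit when it
reaches the model threshold.

Four kinase motifs are scanned in canonical order — Gly-rich loop,
activation loop, catalytic motif, Mg²⁺-binding motif — each with
threshold 10 bits. A protein is a *full-length kinase* when all four are
present and their starts strictly increase. A Ser/Thr within 5 residues
downstream of the Gly-rich loop is flagged as an autophosphorylation
candidate.

The packaged seed blocks are **synthetic stand-ins** assembled from the
standard protein-kinase motif vocabulary (file names end in
`.synthetic.tsv` and say so in their headers). They exist so the
pipeline is runnable and testable offline; real analyses should supply
seed blocks extracted from a curated kinase alignment.

## Domain detection

- **HTH**: a 22-position weight matrix scanned over every window,
  following the classic weight-matrix approach for helix-turn-helix
  prediction. The matrix is calibrated on 5,000 random 22-mers (seeded),
  and a call requires the best window to score at least
  `call_sd` (default 5.0) standard deviations above the calibration
  mean.
- **HipS-like, Stl-like, γδ-resolvase-like, HIRAN**: 30-position
  log-odds profiles, call threshold 45 bits.
- Overlapping calls on one protein are resolved greedily by score.
- The DNA-binding domain set is {HTH, Stl-like, resolvase-like, HIRAN}.
- **HIRAN conservation matrix**: group members are projected onto a
  packaged 100-residue synthetic HIRAN reference by global alignment;
  a member conserves a motif window when ≥ 50% of its positions match
  the reference; a group shows the motif as present (+) at ≥ 70%
  conserving members, partial (±) at ≥ 40%, absent (−) below. The
  NAF-motif Phe is retained when ≥ 50% of members keep F at the
  reference position; a Phe-retaining group is never shown as lacking
  the NAF motif entirely (absent is promoted to partial).

## Operon context and layout classification

Operon neighbors are collected by walking outward from the kinase on the
same strand, nearest first, while the intergenic gap is ≤ 150 nt
(overlaps always qualify), up to 2 genes per side; an opposite-strand
gene stops the walk. Upstream/downstream are relative to the kinase's
reading direction.

Layout rules, first match wins:

1. upstream HipS-like gene with an HTH gene beyond it → `hipBST`;
2. upstream Stl-like gene → `hipRF` if the kinase has ≥ 70 residues
   before its Gly-rich loop (an N-subdomain-1 proxy), else `hipRG`;
3. upstream HTH gene → `hipBA`;
4. downstream HipS-like + HIRAN → `hipIN`; HipS-like only → `hipJS`;
   resolvase-like → `hipMP`; HTH → `hipEB` or `hipAB`, decided by which
   family profile (HipE vs HipA) the kinase matches best by global
   identity (tie → unclassified);
5. no context gene: kinase HTH starting within the first 60 residues →
   `hipH_mono`; internal HipS-like plus a HIRAN ending in the C-terminal
   40% → `hipL_mono`;
6. otherwise `unclassified`.

The layout forces the family (`hipBA`/`hipAB` → HipA, eleven layouts →
ten families); `hipAB` and `hipEB` are the reversed-gene-order layouts.
Frequency reports give exact counts plus integer percentages (rounded
half-up) per layout, family and phylum, and a reversed-order total.

## Curation

Retention criteria, applied in order; each rejection records the first
failed criterion:

1. `not_full_length` — the four-motif test above;
2. `no_adjacent_antitoxin` — an operon partner exists, or the kinase is
   monocistronic with the compensating internal domain (HTH for
   `hipH_mono`; HipS-like + HIRAN for `hipL_mono`);
3. `antitoxin_not_dna_binding` — some operon partner carries a
   DNA-binding domain; waived for `hipJS`, whose HipS antitoxin
   neutralizes the kinase without binding DNA;
4. `redundant_ge_95pct` — greedy deduplication: survivors are processed
   longest-first (ties by ID) and kept only if < 95% identical to every
   already-kept sequence.

Global identity is the number of identical aligned residue pairs over
`min(len(a), len(b))` after affine-gap global alignment (BLOSUM62, gap
open 10, extend 1, so a length-k gap costs 10 + (k−1)); the min-length
denominator makes a perfect substring 100% identical to its
superstring, the conservative convention for duplicate removal. The pair
is canonically ordered before alignment so identity is exactly
symmetric.

## Alignment, trees, statistics

Pairwise global alignment uses an affine-gap Needleman–Wunsch/Gotoh
(Biopython's PairwiseAligner engine). Multiple alignment uses the
center-star heuristic ("once a gap, always a gap"), with the center
chosen to maximize the summed pairwise score — adequate at the
dozens-of-sequences scale this package targets; externally produced
aligned FASTA is accepted everywhere an alignment is.

Alignment statistics classify each column as constant (≤ 1 residue type
among non-gap cells), parsimony-informative (≥ 2 types each occurring
≥ 2 times) or singleton (the rest); the three classes partition the
columns exactly. p-distances use pairwise gap deletion; a pair with no
comparable columns is an error (or distance 1.0 inside the bootstrap,
where resampling can drop all shared columns).

Trees are Saitou–Nei neighbor joining on p-distances. Q-matrix ties
break to the smallest (i, j) pair in the current working order; negative
branch lengths are clamped to zero and the clamped total is recorded on
the tree. Bootstrap resamples alignment columns with replacement;
supports (percent of replicates containing each internal bipartition)
are stored as internal node labels. A tip set is monophyletic when one
edge of the unrooted tree separates exactly that set. The in-house NJ is
cross-checked against scikit-bio's implementation in the test suite.

## Indel and divergence mapping

Given reference and query member sets on one alignment, per-column
non-gap occupancy defines the calls: a Δ deletion is a maximal run of
≥ 3 columns with reference occupancy ≥ 0.8 and query occupancy ≤ 0.2; an
ω insertion is the converse. Events are labeled Δ1…/ω1… left to right
and mapped to the residue numbering of an ungapped reference row; events
falling entirely in reference-gap columns (typical for insertions) carry
the preceding reference residue as an anchor and an `in_ref_gap` flag.
High-divergence regions are maximal merged windows (width 10) where the
between-group consensus identity falls below 0.3.

## Synthetic data generator

Family templates are deterministic scaffolds seeded by
`crc32(label) XOR template_seed`: the four kinase motif consensuses in
canonical order with random spacers, plus family extras (a 90-residue
N-terminal extension for the long families HipA/HipE/HipF; an N-terminal
HTH for HipH; an internal HipS-like plus C-terminal HIRAN for HipL; no
autophosphorylation Ser/Thr for HipG). The packaged family profiles are
the templates at template_seed 0. Instances are derived by i.i.d.
substitution at the configured divergence; indels are never introduced,
so indel tests plant their own gaps with exact truth. Gene placement
draws intergenic distances from a mixture of an overlap component
(default −20…−1 nt, probability 0.25) and a gap component (1…120 nt),
places minus-strand modules right-to-left, separates modules by 400 nt
(beyond the operon gap limit) and emits a complete truth table plus
optional decoy genes (motif-less proteins and orphan kinases).

## Packaged data provenance

| file | content | provenance |
|---|---|---|
| `kinase_motif_seeds.synthetic.tsv` | seed blocks for the 4 kinase motifs | synthetic, standard kinase-motif vocabulary |
| `domain_profile_seeds.synthetic.tsv` | seed blocks for HipS-like, Stl-like, resolvase-like, HIRAN | synthetic |
| `hth_seed.synthetic.tsv` | 22-mer HTH seed block + calibration seed | synthetic |
| `hiran_reference.synthetic.tsv` | 100-aa HIRAN reference with motif windows and NAF-Phe position | synthetic |
| `clade_sizes.tsv` | published per-clade kinase counts (total 1,239) | survey literature summary |

## Reproducibility

Every stochastic step takes an explicit seed (`SurveySettings.seed`,
`GeneratorConfig.seed`, bootstrap seed, HTH calibration seed); reruns
with the same seed and inputs produce byte-identical output tables. The
`run_manifest.json` written with each survey bundle records the package
version and the full settings.
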