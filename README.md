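# hipsurvey

Genetic-context classification, curation, phylogeny and indel mapping for
HipA-homologous serine/threonine kinase toxin–antitoxin (TA) modules.

HipA-like kinase toxins are encoded by TA operons in eleven distinct
genetic layouts (antitoxin-first `hipBA`, reversed `hipAB`/`hipEB`,
tricistronic `hipBST`, monocistronic `hipH`/`hipL`, and the
`hipRF`/`hipRG`/`hipMP`/`hipIN`/`hipJS` operons), which map onto ten
kinase families. This package implements the desk-scale survey workflow
around that observation:

- **genome_io** — validated GFF3 + protein FASTA reading, intergenic
  distances (negative = overlapping genes), locus-table round-trips;
- **kinase motifs** — log-odds PSSM scanning for the four canonical
  kinase motifs (Gly-rich loop, activation loop, catalytic motif,
  Mg²⁺-binding motif) and the full-length-kinase test;
- **antitoxin domains** — HTH detection via a 22-position weight-matrix
  scan calibrated on random windows, plus profile scans for HipS-like,
  Stl-like, γδ-resolvase-like and HIRAN domains, and a HIRAN
  DNA-binding-motif conservation matrix;
- **neighborhood** — same-strand operon-context extraction and
  layout/family classification with frequency reports;
- **curation** — the three retention criteria (full-length kinase,
  adjacent antitoxin or compensating internal domain, DNA-binding
  partner — waived for `hipJS`) followed by greedy <95%-identity
  deduplication;
- **align_phylo** — pairwise global alignment (affine gaps, BLOSUM62),
  center-star multiple alignment, alignment statistics, p-distances,
  neighbor-joining trees with column bootstrap and monophyly tests;
- **indel_map** — clade-relative ω-insertion / Δ-deletion calls from gap
  occupancy, mapped to reference-sequence numbering, plus
  consensus-vs-consensus divergence regions;
- **synthetic data** — a seeded generator that plants modules of every
  layout (with truth tables) so the whole pipeline is testable offline.

All packaged motif/domain models are clearly labelled synthetic
stand-ins (`src/hipsurvey/data/*.synthetic.tsv`) and can be replaced
with user-supplied seed alignments.

## Worked example

`examples/01_generate_and_classify.py` plants one module of every layout
at zero divergence and classifies the genome end to end:

```sh
$ python examples/01_generate_and_classify.py
synthetic genome: 23 genes, 11 planted modules

kinase            layout      family  antitoxin  dist(nt)  truth
hipAB_1_g1_kinase               hipAB       HipA    hipAB_1    -3        ok
hipBA_1_g2_kinase               hipBA       HipA    hipBA_1    52        ok
hipBST_1_g3_kinase              hipBST      HipT    hipBST_1   -5        ok
hipEB_1_g1_kinase               hipEB       HipE    hipEB_1    22        ok
hipH_mono_1_g1_kinase           hipH_mono   HipH    -                    ok
hipIN_1_g1_kinase               hipIN       HipI    hipIN_1    54        ok
hipJS_1_g1_kinase               hipJS       HipJ    hipJS_1    -3        ok
hipL_mono_1_g1_kinase           hipL_mono   HipL    -                    ok
hipMP_1_g1_kinase               hipMP       HipM    hipMP_1    100       ok
hipRF_1_g2_kinase               hipRF       HipF    hipRF_1    -2        ok
hipRG_1_g2_kinase               hipRG       HipG    hipRG_1    -3        ok

distinct families after curation: 10
HipA, HipE, HipF, HipG, HipH, HipI, HipJ, HipL, HipM, HipT
```

The other examples walk curation and deduplication (`02`), tree building
with bootstrap and per-family monophyly (`03`), and clade-relative indel
mapping plus the HIRAN conservation matrix (`04`).

## Command-line interface

```sh
# plant a synthetic dataset (GFF3 + FASTA + truth table)
hipsurvey generate --out data/ --seed 42 --divergence 0.05

# run the full survey bundle: locus table, curation report, frequency
# tables, alignment, bootstrapped NJ tree, monophyly, indels, HIRAN matrix
hipsurvey survey --genomes data/ --out results/ --seed 42

# individual stages
hipsurvey scan     --genomes data/            # motif hits per protein
hipsurvey classify --genomes data/            # locus table to stdout
hipsurvey curate   --genomes data/            # curation report
hipsurvey tree     --genomes data/ --out kinases.nwk --replicates 100
```

Exit codes: 0 ok, 1 user error, 2 internal error. A flat YAML config
(`--config`) supplies defaults; any flag overrides its config key.

## Testing

```sh
python -m pytest -q tests/           # full suite (~6 s)
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`scripts/acceptance.py` recomputes two headline quantities from scratch:
the number of distinct family labels on a one-module-per-layout fixture
(exactly 10) and the maximum pairwise identity retained after greedy
deduplication on a 50-sequence panel (must stay ≤ 95%).

## Layout

```
src/hipsurvey/        library (genome_io, pssm, motifs, domains,
                      neighborhood, curation, align, phylo, indels,
                      synth, pipeline, cli)
src/hipsurvey/data/   packaged synthetic model fixtures + published
                      clade-size reference table
examples/             narrative walkthroughs of each capability
scripts/acceptance.py headline-quantity recomputation
docs/methods.md       methods note: algorithms, defaults, provenance
tests/                pytest suite incl. acceptance criteria
```

See `docs/methods.md` for the algorithmic choices, default thresholds
and the provenance of every packaged data file.
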