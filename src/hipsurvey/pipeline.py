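"""End-to-end survey pipeline.

Chains the stages: motif/domain scanning -> operon-context classification
-> curation -> frequency tables -> alignment + NJ tree with bootstrap and
per-family monophyly -> clade-relative indel/divergence mapping -> HIRAN
motif-conservation matrix.

Candidate selection: every gene passing the four-motif test is a kinase
candidate; genes accounted for as operon partners of a candidate are not
re-screened; every remaining gene is screened as a candidate too, so that
motif-less genes surface in the curation report as ``not_full_length``
rather than vanishing silently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

from . import __version__
from .align import Msa, center_star_msa
from .curation import CurationReport, curate, global_identity
from .domains import (
    HiranMotifMatrix,
    annotate_protein,
    default_hiran_reference,
    hiran_motif_matrix,
)
from .genome_io import GeneRecord, LocusRow, LocusTable, write_locus_table
from .indels import DivergenceRegion, IndelEvent, call_indels, divergence_regions, to_reference_coords
from .motifs import autophosphorylation_flag, is_candidate_kinase, scan_motifs
from .neighborhood import (
    TAModule,
    assign_family,
    classify_layout,
    frequency_report,
    operon_context,
    pick_antitoxin,
)
from .phylo import bootstrap_support, is_monophyletic
from .synth import family_profiles

__all__ = ["SurveySettings", "SurveyResult", "run_survey"]


@dataclass
class SurveySettings:
    """Pipeline thresholds; defaults documented in the methods note."""

    max_gap: int = 150
    max_genes: int = 2
    identity_threshold: float = 0.95
    call_sd: float = 5.0
    extension_min: int = 70
    bootstrap_replicates: int = 100
    seed: int = 0
    template_seed: int = 0
    reference_family: str = "HipA"
    indel_occ_high: float = 0.8
    indel_occ_low: float = 0.2
    indel_min_len: int = 3
    divergence_window: int = 10
    divergence_cutoff: float = 0.3


@dataclass
class SurveyResult:
    modules: list[TAModule]
    curation: CurationReport
    kept_modules: list[TAModule]
    frequencies: dict
    msa: Msa | None
    tree: object | None
    monophyly: dict[str, bool]
    indel_events: dict[str, list[IndelEvent]]
    divergence: dict[str, list[DivergenceRegion]]
    hiran: HiranMotifMatrix | None
    settings: SurveySettings

    def distinct_families(self) -> set[str]:
        return {m.family for m in self.kept_modules}

    def locus_table(self) -> LocusTable:
        rows = []
        for m in self.kept_modules:
            at = m.antitoxin
            at_calls = m.context_domains.get(at.gene_id, []) if at else []
            rows.append(
                LocusRow(
                    kinase_id=m.kinase.gene_id,
                    length_codons=m.kinase.length_codons,
                    organism="synthetic",
                    phylum="synthetic",
                    kinase_seq=m.kinase.protein,
                    distance_nt=m.antitoxin_distance,
                    organization=m.organization,
                    antitoxin_id=at.gene_id if at else "",
                    antitoxin_len=at.length_codons if at else None,
                    antitoxin_seq=at.protein if at else "",
                    hips_seq=at.protein if at and m.organization in ("hipBST", "hipJS") else "",
                    antitoxin_domains=",".join(sorted({c.domain for c in at_calls})),
                    notes=f"family={m.family}",
                )
            )
        return LocusTable(rows=rows)

    def write_outputs(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "locus_table.tsv", "w") as fh:
            write_locus_table(self.locus_table(), fh)
        with open(outdir / "curation.tsv", "w") as fh:
            self.curation.to_tsv(fh)
        for name, df in self.frequencies.items():
            df.to_csv(outdir / f"freq_{name}.tsv", sep="\t")
        if self.msa is not None:
            with open(outdir / "kinases.aln.fasta", "w") as fh:
                self.msa.to_fasta(fh)
        if self.tree is not None:
            self.tree.write(str(outdir / "kinases.nwk"))
        with open(outdir / "monophyly.tsv", "w") as fh:
            fh.write("family\tmonophyletic\n")
            for fam, verdict in sorted(self.monophyly.items()):
                fh.write(f"{fam}\t{verdict}\n")
        with open(outdir / "indels.tsv", "w") as fh:
            fh.write(
                "query_family\tkind\tlabel\tmsa_start\tmsa_end\t"
                "ref_start\tref_end\tref_anchor\n"
            )
            for fam, events in self.indel_events.items():
                for ev in events:
                    fh.write(
                        f"{fam}\t{ev.kind}\t{ev.label}\t{ev.msa_start}\t"
                        f"{ev.msa_end}\t{ev.ref_start or ''}\t{ev.ref_end or ''}\t"
                        f"{ev.ref_anchor or ''}\n"
                    )
        if self.hiran is not None:
            with open(outdir / "hiran_matrix.tsv", "w") as fh:
                cols = self.hiran.motif_names
                fh.write("group\t" + "\t".join(cols) + "\tnaf_phe\n")
                for group, cells in self.hiran.cells.items():
                    vals = "\t".join(cells[c] for c in cols)
                    fh.write(f"{group}\t{vals}\t{self.hiran.naf_phe[group]}\n")
        with open(outdir / "run_manifest.json", "w") as fh:
            json.dump(
                {"package_version": __version__, "settings": asdict(self.settings)},
                fh,
                indent=2,
            )


def _build_module(
    kinase: GeneRecord,
    genes: Sequence[GeneRecord],
    hits_cache: dict,
    domains_cache: dict,
    settings: SurveySettings,
) -> TAModule:
    up, down = operon_context(kinase, genes, settings.max_gap, settings.max_genes)
    context_domains = {
        c.gene.gene_id: domains_cache[c.gene.gene_id] for c in up + down
    }
    return TAModule(
        kinase=kinase,
        upstream=up,
        downstream=down,
        kinase_hits=hits_cache[kinase.gene_id],
        kinase_domains=domains_cache[kinase.gene_id],
        context_domains=context_domains,
    )


def run_survey(
    genes: Sequence[GeneRecord], settings: SurveySettings | None = None
) -> SurveyResult:
    """Run the full comparative survey on an annotated gene set."""
    settings = settings or SurveySettings()
    profiles = family_profiles(settings.template_seed)

    hits_cache = {g.gene_id: scan_motifs(g.protein) for g in genes}
    domains_cache = {
        g.gene_id: annotate_protein(g.protein, call_sd=settings.call_sd)
        for g in genes
    }

    def decide_reversed_family(kinase_seq: str) -> str | None:
        # kinase-then-HTH split: nearest family profile decides HipE vs HipA
        id_a = global_identity(kinase_seq, profiles["HipA"])
        id_e = global_identity(kinase_seq, profiles["HipE"])
        if id_a == id_e:
            return None
        return "HipE" if id_e > id_a else "HipA"

    full_kinases = [
        g for g in genes if is_candidate_kinase(hits_cache[g.gene_id])[0]
    ]
    modules: list[TAModule] = []
    used_ids: set[str] = set()
    for kinase in full_kinases:
        module = _build_module(kinase, genes, hits_cache, domains_cache, settings)
        module.organization = classify_layout(
            module,
            family_decider=decide_reversed_family,
            extension_min=settings.extension_min,
        )
        module.family = assign_family(module.organization)
        module.antitoxin = pick_antitoxin(module)
        modules.append(module)
        used_ids.update(module.context_domains)

    full_ids = {g.gene_id for g in full_kinases}
    for gene in genes:
        if gene.gene_id in full_ids or gene.gene_id in used_ids:
            continue
        modules.append(
            _build_module(gene, genes, hits_cache, domains_cache, settings)
        )

    curation = curate(modules, identity_threshold=settings.identity_threshold)
    kept_set = set(curation.kept)
    kept_modules = [m for m in modules if m.kinase.gene_id in kept_set]
    frequencies = frequency_report(kept_modules)

    msa = tree = None
    monophyly: dict[str, bool] = {}
    indel_events: dict[str, list[IndelEvent]] = {}
    divergence: dict[str, list[DivergenceRegion]] = {}
    if len(kept_modules) >= 3:
        msa = center_star_msa(
            [(m.kinase.gene_id, m.kinase.protein) for m in kept_modules]
        )
        tree = bootstrap_support(
            msa, replicates=settings.bootstrap_replicates, seed=settings.seed
        )
        by_family: dict[str, list[str]] = {}
        for m in kept_modules:
            by_family.setdefault(m.family, []).append(m.kinase.gene_id)
        for fam, members in by_family.items():
            monophyly[fam] = is_monophyletic(tree, members)

        ref_members = by_family.get(settings.reference_family, [])
        if ref_members:
            for fam, members in by_family.items():
                if fam == settings.reference_family:
                    continue
                events = call_indels(
                    msa,
                    ref_members,
                    members,
                    occ_high=settings.indel_occ_high,
                    occ_low=settings.indel_occ_low,
                    min_len=settings.indel_min_len,
                )
                indel_events[fam] = to_reference_coords(events, msa, ref_members[0])
                divergence[fam] = divergence_regions(
                    msa,
                    ref_members,
                    members,
                    window=settings.divergence_window,
                    cutoff=settings.divergence_cutoff,
                )

    hiran = _hiran_matrix(kept_modules)
    return SurveyResult(
        modules=modules,
        curation=curation,
        kept_modules=kept_modules,
        frequencies=frequencies,
        msa=msa,
        tree=tree,
        monophyly=monophyly,
        indel_events=indel_events,
        divergence=divergence,
        hiran=hiran,
        settings=settings,
    )


def _hiran_matrix(kept_modules: Sequence[TAModule]) -> HiranMotifMatrix | None:
    """Group HIRAN-carrying proteins by family and score motif conservation.

    HIRAN call windows are projected onto the reference coordinate system
    positionally (the packaged HIRAN profile occupies reference residues
    9-38; planted domains carry no indels), padding with gaps where the
    protein ends inside the reference span.
    """
    reference = default_hiran_reference()
    profile_start_on_ref = 9  # where the HIRAN profile consensus sits
    groups: dict[str, list[str]] = {}
    for m in kept_modules:
        carriers = [(m.kinase.protein, m.kinase_domains, f"{m.family}_kinase")]
        if m.antitoxin is not None:
            carriers.append(
                (
                    m.antitoxin.protein,
                    m.context_domains.get(m.antitoxin.gene_id, []),
                    f"{m.family}_antitoxin",
                )
            )
        for protein, calls, group in carriers:
            call = next((c for c in calls if c.domain == "HIRAN"), None)
            if call is None:
                continue
            seg_start = call.start - profile_start_on_ref  # 0-based
            chars = []
            for k in range(len(reference.sequence)):
                idx = seg_start + k
                chars.append(protein[idx] if 0 <= idx < len(protein) else "-")
            groups.setdefault(group, []).append("".join(chars))
    if not groups:
        return None
    return hiran_motif_matrix(groups, reference)
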