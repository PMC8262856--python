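"""Operon-context extraction and genetic-organization classification.

The central procedure of the survey: each candidate kinase gene is
classified by the domain content and placement of its same-strand operon
neighbors into one of eleven genetic layouts, and each layout maps onto
one of ten kinase families (the two reversed-order layouts hipBA/hipAB
both encode HipA kinases).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import pandas as pd

from .domains import DomainCall
from .genome_io import GeneRecord, intergenic_distance
from .pssm import MotifHit

LAYOUTS = [
    "hipBA",
    "hipAB",
    "hipBST",
    "hipEB",
    "hipH_mono",
    "hipL_mono",
    "hipRF",
    "hipRG",
    "hipMP",
    "hipIN",
    "hipJS",
    "unclassified",
]

REVERSED_LAYOUTS = {"hipAB", "hipEB"}

LAYOUT_TO_FAMILY = {
    "hipBA": "HipA",
    "hipAB": "HipA",
    "hipBST": "HipT",
    "hipEB": "HipE",
    "hipH_mono": "HipH",
    "hipL_mono": "HipL",
    "hipRF": "HipF",
    "hipRG": "HipG",
    "hipMP": "HipM",
    "hipIN": "HipI",
    "hipJS": "HipJ",
    "unclassified": "unknown",
}

__all__ = [
    "LAYOUTS",
    "REVERSED_LAYOUTS",
    "LAYOUT_TO_FAMILY",
    "ContextGene",
    "TAModule",
    "is_reversed",
    "operon_context",
    "classify_layout",
    "assign_family",
    "frequency_report",
]


def is_reversed(layout: str) -> bool:
    """Kinase-before-antitoxin layouts (reversed relative to hipBA)."""
    return layout in REVERSED_LAYOUTS


@dataclass(frozen=True)
class ContextGene:
    gene: GeneRecord
    distance: int  # signed nt to the previous gene walking outward
    same_strand: bool


@dataclass
class TAModule:
    """A kinase gene with its classified neighborhood."""

    kinase: GeneRecord
    upstream: list[ContextGene] = field(default_factory=list)    # nearest first
    downstream: list[ContextGene] = field(default_factory=list)  # nearest first
    organization: str = "unclassified"
    family: str = "unknown"
    antitoxin: GeneRecord | None = None
    kinase_hits: list[MotifHit] = field(default_factory=list)
    kinase_domains: list[DomainCall] = field(default_factory=list)
    context_domains: dict[str, list[DomainCall]] = field(default_factory=dict)

    @property
    def reversed(self) -> bool:
        return is_reversed(self.organization)

    @property
    def antitoxin_distance(self) -> int | None:
        if self.antitoxin is None:
            return None
        return intergenic_distance(self.kinase, self.antitoxin)


def operon_context(
    kinase: GeneRecord,
    genes: Sequence[GeneRecord],
    max_gap: int = 150,
    max_genes: int = 2,
) -> tuple[list[ContextGene], list[ContextGene]]:
    """Same-strand operon neighbors of a kinase gene.

    Walks outward from the kinase in both directions, adding genes while
    the intergenic gap is at most ``max_gap`` nt (overlaps always
    qualify), up to ``max_genes`` per side; an opposite-strand gene stops
    the walk.  Returns ``(upstream, downstream)`` relative to the
    kinase's reading direction, nearest gene first.
    """
    contig_genes = sorted(
        (g for g in genes if g.contig == kinase.contig), key=lambda g: g.start
    )
    try:
        idx = next(
            i for i, g in enumerate(contig_genes) if g.gene_id == kinase.gene_id
        )
    except StopIteration:
        raise ValueError(f"kinase {kinase.gene_id!r} not in gene list") from None

    def walk(step: int) -> list[ContextGene]:
        out: list[ContextGene] = []
        prev = kinase
        i = idx + step
        while 0 <= i < len(contig_genes) and len(out) < max_genes:
            gene = contig_genes[i]
            gap = intergenic_distance(prev, gene)
            if gap > max_gap:
                break
            if gene.strand != kinase.strand:
                break
            out.append(ContextGene(gene=gene, distance=gap, same_strand=True))
            prev = gene
            i += step
        return out

    left, right = walk(-1), walk(+1)
    if kinase.strand == "+":
        return left, right
    return right, left


def _has(calls: Sequence[DomainCall], domain: str) -> bool:
    return any(c.domain == domain for c in calls)


def classify_layout(
    module: TAModule,
    family_decider: Callable[[str], str | None] | None = None,
    extension_min: int = 70,
    hth_n_terminal: int = 60,
) -> str:
    """Classify a kinase neighborhood into a genetic layout.

    Decision rules are applied in order, first match wins:

    1. upstream HTH gene with an upstream-adjacent HipS-like gene between
       it and the kinase -> hipBST (tricistronic);
    2. upstream Stl-like(+HTH) gene -> hipRF when the kinase has an
       N-terminal extension of at least ``extension_min`` residues before
       the Gly-rich loop (the N-subdomain-1 proxy), else hipRG;
    3. upstream HTH gene -> hipBA;
    4. downstream HipS-like + HIRAN -> hipIN; downstream HipS-like only
       -> hipJS; downstream resolvase-like -> hipMP; downstream HTH ->
       hipEB or hipAB, decided by ``family_decider`` on the kinase
       sequence (unresolvable -> unclassified);
    5. no context gene: kinase HTH call starting within the first
       ``hth_n_terminal`` residues -> hipH_mono; internal HipS-like plus
       C-terminal HIRAN -> hipL_mono;
    6. otherwise unclassified.
    """
    up = [module.context_domains.get(c.gene.gene_id, []) for c in module.upstream]
    down = [module.context_domains.get(c.gene.gene_id, []) for c in module.downstream]

    # (1) tricistronic: HTH gene, then HipS-like gene, then the kinase
    if len(module.upstream) >= 2 and _has(up[0], "HipS_like") and _has(up[1], "HTH"):
        return "hipBST"
    if module.upstream:
        nearest = up[0]
        # (2) Stl-like (two-domain repressor) antitoxin upstream
        if _has(nearest, "Stl_like"):
            gly = next(
                (h for h in module.kinase_hits if h.motif == "gly_rich_loop"), None
            )
            if gly is not None and gly.start - 1 >= extension_min:
                return "hipRF"
            return "hipRG"
        # (3) plain HTH antitoxin upstream
        if _has(nearest, "HTH"):
            return "hipBA"
    if module.downstream:
        nearest = down[0]
        if _has(nearest, "HipS_like") and _has(nearest, "HIRAN"):
            return "hipIN"
        if _has(nearest, "HipS_like"):
            return "hipJS"
        if _has(nearest, "resolvase_like"):
            return "hipMP"
        if _has(nearest, "HTH"):
            if family_decider is not None:
                family = family_decider(module.kinase.protein)
                if family == "HipE":
                    return "hipEB"
                if family == "HipA":
                    return "hipAB"
                return "unclassified"
            return "hipAB"
    if not module.upstream and not module.downstream:
        # (5) monocistronic layouts with a compensating internal domain
        hth = next((c for c in module.kinase_domains if c.domain == "HTH"), None)
        if hth is not None and hth.start <= hth_n_terminal:
            return "hipH_mono"
        hiran = next(
            (c for c in module.kinase_domains if c.domain == "HIRAN"), None
        )
        if (
            _has(module.kinase_domains, "HipS_like")
            and hiran is not None
            and hiran.end > 0.6 * len(module.kinase.protein)
        ):
            return "hipL_mono"
    return "unclassified"


def assign_family(layout: str) -> str:
    """Family label forced by the layout (the hipBA/hipAB pair both map
    to HipA, giving ten families for eleven layouts)."""
    if layout not in LAYOUT_TO_FAMILY:
        raise ValueError(f"unknown layout {layout!r}")
    return LAYOUT_TO_FAMILY[layout]


def pick_antitoxin(module: TAModule) -> GeneRecord | None:
    """The cognate antitoxin gene of a classified module.

    hipBA/hipRF/hipRG: the nearest upstream gene; hipBST: the nearest
    upstream gene (HipS; the HTH gene beyond it is a context gene);
    hipAB/hipEB/hipMP/hipIN/hipJS: the nearest downstream gene;
    monocistronic layouts: none.
    """
    layout = module.organization
    if layout in {"hipBA", "hipBST", "hipRF", "hipRG"}:
        return module.upstream[0].gene if module.upstream else None
    if layout in {"hipAB", "hipEB", "hipMP", "hipIN", "hipJS"}:
        return module.downstream[0].gene if module.downstream else None
    return None


def _percent(count: int, total: int) -> int:
    if total == 0:
        return 0
    # round half-up to integer percent
    return int(100 * count / total + 0.5)


def frequency_report(
    modules: Sequence[TAModule],
    phyla: Mapping[str, str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Counts and integer percentages per layout, family and phylum.

    Returns a dict of DataFrames ("layout", "family", "phylum",
    "summary"); the summary table carries the total and the
    reversed-gene-order count.
    """
    total = len(modules)

    def table(labels: Sequence[str], order: Sequence[str] | None = None) -> pd.DataFrame:
        counts: dict[str, int] = {}
        for lab in labels:
            counts[lab] = counts.get(lab, 0) + 1
        if order is not None:
            counts = {k: counts.get(k, 0) for k in order}
        df = pd.DataFrame(
            {
                "count": list(counts.values()),
                "percent": [_percent(c, total) for c in counts.values()],
            },
            index=list(counts.keys()),
        )
        df.index.name = "label"
        return df

    layout_df = table([m.organization for m in modules], order=LAYOUTS)
    family_df = table([m.family for m in modules])
    if phyla is not None:
        phylum_df = table(
            [phyla.get(m.kinase.gene_id, "unknown") for m in modules]
        )
    else:
        phylum_df = table([])
    reversed_count = sum(1 for m in modules if m.reversed)
    summary = pd.DataFrame(
        {"value": [total, reversed_count]}, index=["total_modules", "reversed_order"]
    )
    summary.index.name = "quantity"
    return {
        "layout": layout_df,
        "family": family_df,
        "phylum": phylum_df,
        "summary": summary,
    }
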