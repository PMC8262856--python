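"""Curation of the candidate kinase set.

Three retention criteria are applied in order, then a greedy <95%-identity
deduplication:

(i)   full-length kinase: all four canonical motifs, in canonical order;
(ii)  an adjacent putative antitoxin gene — or, for monocistronic
      layouts, a compensating internal domain (an N-terminal HTH for
      hipH-type kinases; HipS-like plus HIRAN for hipL-type kinases);
(iii) a DNA-binding protein in the operon (waived for hipJS modules,
      whose HipS antitoxins bind the kinase, not DNA).

Every rejection records the first failed criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .align import needleman_wunsch
from .domains import DNA_BINDING_DOMAINS
from .motifs import is_candidate_kinase
from .neighborhood import TAModule

REASONS = (
    "not_full_length",
    "no_adjacent_antitoxin",
    "antitoxin_not_dna_binding",
    "redundant_ge_95pct",
)

__all__ = ["CurationReport", "global_identity", "greedy_dedup", "curate"]


@dataclass
class CurationReport:
    kept: list[str] = field(default_factory=list)
    rejected: list[tuple[str, str]] = field(default_factory=list)
    parameters: dict = field(default_factory=dict)

    def reason(self, kinase_id: str) -> str | None:
        for kid, why in self.rejected:
            if kid == kinase_id:
                return why
        return None

    def to_tsv(self, stream) -> None:
        stream.write("kinase_id\tstatus\treason\n")
        for kid in self.kept:
            stream.write(f"{kid}\tkept\t\n")
        for kid, why in self.rejected:
            stream.write(f"{kid}\trejected\t{why}\n")


def global_identity(
    a: str,
    b: str,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
    substitution_matrix: str | object | None = "BLOSUM62",
    match: float = 1.0,
    mismatch: float = -1.0,
) -> float:
    """Fraction of identical aligned residue pairs over min(len(a), len(b)).

    The denominator makes a perfect substring 100% identical to its
    superstring, the conservative convention for near-duplicate removal.
    Symmetric in its arguments (the pair is canonically ordered before
    alignment so traceback ties cannot break symmetry).
    """
    if not a or not b:
        raise ValueError("empty sequence")
    x, y = (a, b) if a <= b else (b, a)
    xa, ya, _ = needleman_wunsch(
        x, y, substitution_matrix, gap_open, gap_extend, match, mismatch
    )
    identical = sum(1 for p, q in zip(xa, ya) if p == q and p != "-")
    return identical / min(len(a), len(b))


def greedy_dedup(
    seqs: Sequence[tuple[str, str]],
    threshold: float = 0.95,
    **identity_kwargs,
) -> list[str]:
    """Greedy longest-first deduplication.

    Sequences are processed sorted by (length descending, id ascending);
    a sequence is kept iff its identity to every already-kept sequence is
    below ``threshold``.  Returns kept ids in processing order.
    """
    ids = [i for i, _ in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence IDs")
    by_id = dict(seqs)
    order = sorted(ids, key=lambda i: (-len(by_id[i]), i))
    kept: list[str] = []
    for sid in order:
        seq = by_id[sid]
        if all(
            global_identity(seq, by_id[k], **identity_kwargs) < threshold
            for k in kept
        ):
            kept.append(sid)
    return kept


def _passes_adjacency(module: TAModule) -> bool:
    if module.upstream or module.downstream:
        return True
    # monocistronic layouts: the kinase itself carries the compensating domain
    domains = {c.domain for c in module.kinase_domains}
    if module.organization == "hipH_mono" and "HTH" in domains:
        return True
    if module.organization == "hipL_mono" and {"HipS_like", "HIRAN"} <= domains:
        return True
    return False


def _passes_dna_binding(module: TAModule) -> bool:
    if module.organization == "hipJS":
        return True  # explicit waiver: HipS antitoxins are not DNA binders
    if not module.upstream and not module.downstream:
        return True  # monocistronic; handled by the adjacency criterion
    for calls in module.context_domains.values():
        if any(c.domain in DNA_BINDING_DOMAINS for c in calls):
            return True
    return False


def curate(
    modules: Sequence[TAModule],
    identity_threshold: float = 0.95,
    **identity_kwargs,
) -> CurationReport:
    """Apply retention criteria (i)-(iii) in order, then greedy dedup.

    Deterministic and independent of input ordering: criteria are
    per-module, and the dedup processing order is (length desc, id asc).
    """
    report = CurationReport(
        parameters={"identity_threshold": identity_threshold, **identity_kwargs}
    )
    survivors: list[TAModule] = []
    for module in sorted(modules, key=lambda m: m.kinase.gene_id):
        kid = module.kinase.gene_id
        ok, _why = is_candidate_kinase(module.kinase_hits)
        if not ok:
            report.rejected.append((kid, "not_full_length"))
            continue
        if not _passes_adjacency(module):
            report.rejected.append((kid, "no_adjacent_antitoxin"))
            continue
        if not _passes_dna_binding(module):
            report.rejected.append((kid, "antitoxin_not_dna_binding"))
            continue
        survivors.append(module)

    kept_ids = greedy_dedup(
        [(m.kinase.gene_id, m.kinase.protein) for m in survivors],
        threshold=identity_threshold,
        **identity_kwargs,
    )
    kept_set = set(kept_ids)
    report.kept = kept_ids
    for m in survivors:
        if m.kinase.gene_id not in kept_set:
            report.rejected.append((m.kinase.gene_id, "redundant_ge_95pct"))
    return report
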