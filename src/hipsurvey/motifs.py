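"""Detection of the four canonical Hip/Hanks kinase motifs.

A protein counts as a full-length kinase candidate when all four motifs —
Gly-rich loop, activation loop, catalytic motif and Mg2+-binding motif —
are present and occur in that N-to-C order.  Motif models are log-odds
matrices built from seed-alignment blocks; the packaged defaults are
synthetic fixtures (see ``data/kinase_motif_seeds.synthetic.tsv``) and can
be replaced by user-supplied seed blocks.
"""

from __future__ import annotations

import functools
from importlib import resources
from typing import Sequence, TextIO

from .pssm import MotifModel, MotifHit, best_window, build_pssm

MOTIF_ORDER = [
    "gly_rich_loop",
    "activation_loop",
    "catalytic_motif",
    "mg_binding_motif",
]

__all__ = [
    "MOTIF_ORDER",
    "default_motif_models",
    "load_motif_seeds",
    "scan_motifs",
    "is_candidate_kinase",
    "autophosphorylation_flag",
]


def load_motif_seeds(stream: TextIO) -> list[MotifModel]:
    """Build one PSSM per motif from a seed-block TSV.

    File format: ``name<TAB>sequence`` data lines grouped by motif name,
    plus ``!threshold<TAB>name<TAB>bits`` lines.
    """
    blocks: dict[str, list[str]] = {}
    thresholds: dict[str, float] = {}
    for raw in stream:
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0] == "!threshold":
            thresholds[parts[1]] = float(parts[2])
            continue
        if parts[0].startswith("!"):
            continue
        blocks.setdefault(parts[0], []).append(parts[1])
    models = []
    for name, seqs in blocks.items():
        models.append(
            build_pssm(seqs, name=name, threshold=thresholds.get(name, 0.0))
        )
    return models


@functools.cache
def default_motif_models() -> list[MotifModel]:
    """The packaged synthetic motif models, in canonical motif order."""
    ref = resources.files("hipsurvey.data") / "kinase_motif_seeds.synthetic.tsv"
    with ref.open() as fh:
        models = load_motif_seeds(fh)
    by_name = {m.name: m for m in models}
    missing = [n for n in MOTIF_ORDER if n not in by_name]
    if missing:
        raise ValueError(f"packaged seeds missing motifs: {missing}")
    return [by_name[n] for n in MOTIF_ORDER]


def scan_motifs(
    protein: str, models: Sequence[MotifModel] | None = None
) -> list[MotifHit]:
    """Best above-threshold window per motif (at most one hit per motif).

    Motifs whose model is longer than the protein are simply absent.
    Hits are returned in the models' order with 1-based coordinates.
    """
    if models is None:
        models = default_motif_models()
    hits: list[MotifHit] = []
    for model in models:
        hit = best_window(protein, model)
        if hit is not None:
            hits.append(hit)
    return hits


def is_candidate_kinase(hits: Sequence[MotifHit]) -> tuple[bool, str]:
    """Full-length-kinase test: all four motifs, in canonical order.

    Returns ``(ok, reason)``; the reason names the first violated
    condition (a missing motif, or "order violation").
    """
    by_name = {h.motif: h for h in hits}
    for name in MOTIF_ORDER:
        if name not in by_name:
            return False, f"missing {name}"
    starts = [by_name[n].start for n in MOTIF_ORDER]
    if any(a >= b for a, b in zip(starts, starts[1:])):
        return False, "order violation"
    return True, "full-length kinase with four motifs in canonical order"


def autophosphorylation_flag(
    protein: str, hits: Sequence[MotifHit], window: int = 5
) -> bool:
    """Ser/Thr adjacent to the Gly-rich loop (autophosphorylation candidate).

    True iff any S or T occurs within ``window`` residues downstream of the
    Gly-rich loop hit.
    """
    gly = next((h for h in hits if h.motif == "gly_rich_loop"), None)
    if gly is None:
        return False
    segment = protein[gly.end : gly.end + window]
    return any(aa in "ST" for aa in segment)
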