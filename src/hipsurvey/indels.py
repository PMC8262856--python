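"""Clade-relative indel and divergence mapping on a protein MSA.

Insertions (ω) and deletions (Δ) in a query subclade are called relative
to a reference subclade from per-column gap occupancy, then mapped to the
residue numbering of an ungapped reference sequence so they can annotate
a structure.  High-divergence regions come from a sliding-window
consensus-versus-consensus identity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .align import GAP, Msa

__all__ = [
    "IndelEvent",
    "DivergenceRegion",
    "occupancy_profile",
    "call_indels",
    "divergence_regions",
    "to_reference_coords",
]


@dataclass(frozen=True)
class IndelEvent:
    kind: str  # "omega_insertion" (query has extra columns) or "delta_deletion"
    label: str  # ω1..., Δ1... in reference-coordinate order
    msa_start: int  # 1-based column
    msa_end: int    # 1-based column, inclusive
    ref_start: int | None = None  # 1-based reference residue
    ref_end: int | None = None
    ref_anchor: int | None = None  # preceding reference residue for insertions
    in_ref_gap: bool = False

    @property
    def length(self) -> int:
        return self.msa_end - self.msa_start + 1


@dataclass(frozen=True)
class DivergenceRegion:
    msa_start: int
    msa_end: int
    mean_identity: float
    ref_start: int | None = None
    ref_end: int | None = None


def occupancy_profile(msa: Msa, members: Sequence[str]) -> np.ndarray:
    """Per-column fraction of non-gap cells among the given rows."""
    if not members:
        raise ValueError("empty member set")
    rows = [np.frombuffer(msa.row(m).encode(), dtype="S1") for m in members]
    stack = np.vstack(rows)
    return (stack != GAP.encode()).mean(axis=0)


def _runs(mask: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """Maximal runs of True of length >= min_len, as 0-based [start, end]."""
    out = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            if i - start >= min_len:
                out.append((start, i - 1))
            start = None
    if start is not None and len(mask) - start >= min_len:
        out.append((start, len(mask) - 1))
    return out


def call_indels(
    msa: Msa,
    ref_members: Sequence[str],
    query_members: Sequence[str],
    occ_high: float = 0.8,
    occ_low: float = 0.2,
    min_len: int = 3,
) -> list[IndelEvent]:
    """Call Δ (deletion) and ω (insertion) events in the query subclade
    relative to the reference subclade.

    Δ: maximal runs of at least ``min_len`` columns where reference
    occupancy is >= ``occ_high`` and query occupancy is <= ``occ_low``.
    ω: the converse.  Events are labeled Δ1.../ω1... left to right
    (reference-coordinate order).
    """
    if set(ref_members) & set(query_members):
        raise ValueError("reference and query member sets overlap")
    ref_occ = occupancy_profile(msa, ref_members)
    query_occ = occupancy_profile(msa, query_members)

    events: list[IndelEvent] = []
    delta_mask = (ref_occ >= occ_high) & (query_occ <= occ_low)
    omega_mask = (query_occ >= occ_high) & (ref_occ <= occ_low)
    for n, (s, e) in enumerate(_runs(delta_mask, min_len), start=1):
        events.append(
            IndelEvent(
                kind="delta_deletion", label=f"Δ{n}", msa_start=s + 1, msa_end=e + 1
            )
        )
    for n, (s, e) in enumerate(_runs(omega_mask, min_len), start=1):
        events.append(
            IndelEvent(
                kind="omega_insertion", label=f"ω{n}", msa_start=s + 1, msa_end=e + 1
            )
        )
    return sorted(events, key=lambda ev: (ev.msa_start, ev.kind))


def _consensus(msa: Msa, members: Sequence[str]) -> list[str | None]:
    """Majority non-gap residue per column; None where all members gap."""
    rows = [msa.row(m) for m in members]
    out: list[str | None] = []
    for j in range(msa.ncols):
        counts: dict[str, int] = {}
        for r in rows:
            aa = r[j]
            if aa != GAP:
                counts[aa] = counts.get(aa, 0) + 1
        if not counts:
            out.append(None)
        else:
            best = max(counts.items(), key=lambda kv: (kv[1], -ord(kv[0])))
            out.append(best[0])
    return out


def divergence_regions(
    msa: Msa,
    ref_members: Sequence[str],
    query_members: Sequence[str],
    window: int = 10,
    cutoff: float = 0.3,
) -> list[DivergenceRegion]:
    """Sliding-window between-group consensus identity; merged maximal
    windows with mean identity below ``cutoff`` are reported."""
    if set(ref_members) & set(query_members):
        raise ValueError("reference and query member sets overlap")
    if window > msa.ncols:
        raise ValueError("window larger than alignment")
    ref_cons = _consensus(msa, ref_members)
    query_cons = _consensus(msa, query_members)

    flagged = np.zeros(msa.ncols, dtype=bool)
    for s in range(msa.ncols - window + 1):
        comparable = matches = 0
        for j in range(s, s + window):
            a, b = ref_cons[j], query_cons[j]
            if a is not None and b is not None:
                comparable += 1
                if a == b:
                    matches += 1
        identity = matches / comparable if comparable else 1.0
        if identity < cutoff:
            flagged[s : s + window] = True

    regions: list[DivergenceRegion] = []
    for s, e in _runs(flagged, 1):
        comparable = matches = 0
        for j in range(s, e + 1):
            a, b = ref_cons[j], query_cons[j]
            if a is not None and b is not None:
                comparable += 1
                if a == b:
                    matches += 1
        identity = matches / comparable if comparable else 1.0
        regions.append(
            DivergenceRegion(msa_start=s + 1, msa_end=e + 1, mean_identity=identity)
        )
    return regions


def _column_to_residue(msa: Msa, reference_row_id: str) -> list[int]:
    """1-based residue number per column (0 for reference-gap columns)."""
    row = msa.row(reference_row_id)
    mapping = []
    res = 0
    for aa in row:
        if aa != GAP:
            res += 1
            mapping.append(res)
        else:
            mapping.append(0)
    return mapping


def to_reference_coords(
    events: Sequence[IndelEvent], msa: Msa, reference_row_id: str
) -> list[IndelEvent]:
    """Fill reference-residue spans for indel events.

    Events covering reference residues get a closed residue span; events
    falling entirely within reference gap columns (typical for ω
    insertions) carry the preceding reference residue as anchor and are
    flagged ``in_ref_gap``.
    """
    mapping = _column_to_residue(msa, reference_row_id)
    out: list[IndelEvent] = []
    for ev in events:
        cols = mapping[ev.msa_start - 1 : ev.msa_end]
        residues = [c for c in cols if c > 0]
        if residues:
            out.append(
                replace(ev, ref_start=residues[0], ref_end=residues[-1])
            )
        else:
            preceding = [c for c in mapping[: ev.msa_start - 1] if c > 0]
            anchor = preceding[-1] if preceding else 0
            out.append(replace(ev, ref_anchor=anchor, in_ref_gap=True))
    return out
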