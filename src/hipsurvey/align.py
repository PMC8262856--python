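"""Desk-scale protein alignment: pairwise global alignment, center-star
multiple alignment, alignment statistics and p-distances.

Pairwise alignment is affine-gap global (Needleman–Wunsch/Gotoh), executed
by Biopython's PairwiseAligner.  The center-star heuristic replaces a full
progressive aligner at the problem sizes this package targets; externally
produced aligned FASTA is accepted everywhere an ``Msa`` is.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import numpy as np
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"

__all__ = [
    "Msa",
    "needleman_wunsch",
    "center_star_msa",
    "alignment_stats",
    "p_distance_matrix",
]


@dataclass
class Msa:
    """A gapped protein alignment: parallel lists of names and rows."""

    names: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise ValueError("names and rows differ in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate sequence names")
        if self.rows:
            width = len(self.rows[0])
            if any(len(r) != width for r in self.rows):
                raise ValueError("alignment rows differ in length")

    @property
    def ncols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.rows)

    def row(self, name: str) -> str:
        return self.rows[self.names.index(name)]

    def ungapped(self, name: str) -> str:
        return self.row(name).replace(GAP, "")

    def subset(self, names: Sequence[str]) -> "Msa":
        return Msa(names=list(names), rows=[self.row(n) for n in names])

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)

    @classmethod
    def from_fasta(cls, stream: TextIO | str) -> "Msa":
        if isinstance(stream, str):
            stream = io.StringIO(stream)
        names, rows = [], []
        for rec in SeqIO.parse(stream, "fasta"):
            names.append(rec.id)
            rows.append(str(rec.seq))
        return cls(names=names, rows=rows)

    def to_fasta(self, stream: TextIO) -> None:
        SeqIO.write(
            (SeqRecord(Seq(r), id=n, description="") for n, r in zip(self.names, self.rows)),
            stream,
            "fasta",
        )


def _make_aligner(
    substitution_matrix: str | object | None,
    gap_open: float,
    gap_extend: float,
    match: float,
    mismatch: float,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if substitution_matrix is None:
        aligner.match_score = match
        aligner.mismatch_score = mismatch
    else:
        if isinstance(substitution_matrix, str):
            substitution_matrix = substitution_matrices.load(substitution_matrix)
        aligner.substitution_matrix = substitution_matrix
    # length-k gap costs gap_open + (k-1) * gap_extend
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def needleman_wunsch(
    a: str,
    b: str,
    substitution_matrix: str | object | None = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
    match: float = 1.0,
    mismatch: float = -1.0,
) -> tuple[str, str, float]:
    """Optimal global alignment with affine gaps.

    Returns ``(aligned_a, aligned_b, score)``.  With
    ``substitution_matrix=None``, simple match/mismatch scores are used
    instead.  Ties are resolved by the aligner's deterministic traceback
    enumeration (first alignment).
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = _make_aligner(substitution_matrix, gap_open, gap_extend, match, mismatch)
    if aligner.substitution_matrix is not None:
        alphabet = set(str(aligner.substitution_matrix.alphabet))
        unknown = (set(a) | set(b)) - alphabet
        if unknown:
            raise ValueError(f"residues not in substitution matrix: {sorted(unknown)}")
    alignments = aligner.align(a, b)
    best = alignments[0]
    aligned_a, aligned_b = str(best[0]), str(best[1])
    return aligned_a, aligned_b, float(best.score)


def _merge_into_master(
    master: str, center_aligned: str
) -> tuple[str, list[int] | None, list[int]]:
    """Map columns of a new center/sequence pairwise alignment into the
    running master alignment, inserting new gap columns where needed.

    Returns (new_master, insert_positions, column_of_new_row) where
    insert_positions are master indices (pre-insertion, ascending) at which
    a gap column must be spliced into every existing row.
    """
    out_master: list[str] = []
    inserts: list[int] = []  # positions in the OLD master before which to insert
    new_row_cols: list[int] = []  # for each column of center_aligned, its out index
    i = j = 0
    while i < len(master) or j < len(center_aligned):
        if j < len(center_aligned) and center_aligned[j] == GAP:
            # new sequence induced a gap in the center: new column
            inserts.append(i)
            out_master.append(GAP)
            new_row_cols.append(len(out_master) - 1)
            j += 1
        elif i < len(master) and master[i] == GAP:
            # pre-existing gap column; the new row gets a gap here
            out_master.append(GAP)
            i += 1
        else:
            out_master.append(master[i])
            new_row_cols.append(len(out_master) - 1)
            i += 1
            j += 1
    return "".join(out_master), inserts, new_row_cols


def center_star_msa(
    seqs: Sequence[tuple[str, str]],
    substitution_matrix: str | object | None = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> Msa:
    """Center-star multiple alignment ("once a gap, always a gap").

    The center is the sequence maximizing the summed pairwise alignment
    score against all others (ties: first in input order).
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    names = [n for n, _ in seqs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate sequence names")

    n = len(seqs)
    scores = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, _, s = needleman_wunsch(
                seqs[i][1], seqs[j][1], substitution_matrix, gap_open, gap_extend
            )
            scores[i, j] = scores[j, i] = s
    center_idx = int(scores.sum(axis=1).argmax())
    center_name, center_seq = seqs[center_idx]

    master = center_seq
    aligned_rows: dict[str, str] = {center_name: center_seq}
    order = [center_name]
    for idx, (name, seq) in enumerate(seqs):
        if idx == center_idx:
            continue
        ca, sa, _ = needleman_wunsch(
            center_seq, seq, substitution_matrix, gap_open, gap_extend
        )
        new_master, inserts, new_cols = _merge_into_master(master, ca)
        if inserts:
            for row_name, row in aligned_rows.items():
                chars = list(row)
                for offset, pos in enumerate(inserts):
                    chars.insert(pos + offset, GAP)
                aligned_rows[row_name] = "".join(chars)
        new_row = [GAP] * len(new_master)
        for col, aa in zip(new_cols, sa):
            new_row[col] = aa
        aligned_rows[name] = "".join(new_row)
        master = new_master
        order.append(name)

    # restore input order
    final_names = [n for n, _ in seqs]
    return Msa(names=final_names, rows=[aligned_rows[n] for n in final_names])


def alignment_stats(msa: Msa) -> dict[str, int]:
    """Column classification of an alignment.

    Returns columns, distinct_patterns, parsimony_informative, singleton
    and constant counts.  A column is constant when at most one residue
    type occurs among its non-gap cells (an all-gap column counts as
    constant); parsimony-informative when at least two residue types each
    occur at least twice (gaps ignored); singleton otherwise.  The three
    classes partition the columns.
    """
    ncols = msa.ncols
    patterns = set()
    constant = informative = 0
    for j in range(ncols):
        col = msa.column(j)
        patterns.add(col)
        counts: dict[str, int] = {}
        for aa in col:
            if aa != GAP:
                counts[aa] = counts.get(aa, 0) + 1
        if len(counts) <= 1:
            constant += 1
        elif sum(1 for c in counts.values() if c >= 2) >= 2:
            informative += 1
    singleton = ncols - constant - informative
    return {
        "columns": ncols,
        "distinct_patterns": len(patterns),
        "parsimony_informative": informative,
        "singleton": singleton,
        "constant": constant,
    }


def p_distance_matrix(msa: Msa, on_zero_overlap: str = "error") -> np.ndarray:
    """Pairwise p-distances with pairwise gap deletion.

    d(i, j) = mismatches / columns where both rows are non-gap.  A pair
    with no comparable column raises an error naming the pair, or scores
    the maximum distance 1.0 when ``on_zero_overlap="max"`` (used by the
    bootstrap, where resampling can drop all shared columns).
    """
    if len(msa) < 2:
        raise ValueError("need at least 2 rows")
    arrs = [np.frombuffer(r.encode(), dtype="S1") for r in msa.rows]
    gap = GAP.encode()
    n = len(arrs)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = (arrs[i] != gap) & (arrs[j] != gap)
            comparable = int(both.sum())
            if comparable == 0:
                if on_zero_overlap == "max":
                    d = 1.0
                else:
                    raise ValueError(
                        f"no comparable columns between {msa.names[i]!r} "
                        f"and {msa.names[j]!r}"
                    )
            else:
                mism = int((arrs[i][both] != arrs[j][both]).sum())
                d = mism / comparable
            dist[i, j] = dist[j, i] = d
    return dist
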