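"""Antitoxin and kinase-internal domain annotation.

Five domains are annotated: helix-turn-helix (HTH, via a Dodd & Egan
style 22-position weight-matrix scan), HipS-like, Stl-like,
gamma-delta-resolvase-like and HIRAN (via log-odds profile scans).  The
packaged matrices are synthetic stand-ins (``data/*.synthetic.tsv``) and
are user-replaceable.

The HIRAN conservation matrix summarizes, per group of HIRAN-domain
sequences aligned to a reference coordinate system, which of the four
DNA-binding sequence motifs of the reference domain are conserved, and
whether the duplex-DNA-stacking Phe of the NAF motif is retained.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence, TextIO

import numpy as np

from .align import needleman_wunsch
from .motifs import load_motif_seeds
from .pssm import AMINO_ACIDS, MotifModel, best_window, build_pssm

HTH_WINDOW = 22
DNA_BINDING_DOMAINS = {"HTH", "Stl_like", "resolvase_like", "HIRAN"}

__all__ = [
    "DomainCall",
    "HthMatrix",
    "HiranReference",
    "HiranMotifMatrix",
    "default_domain_profiles",
    "default_hth_matrix",
    "default_hiran_reference",
    "hth_scan",
    "profile_match",
    "annotate_protein",
    "align_to_reference",
    "hiran_motif_matrix",
]


@dataclass(frozen=True)
class DomainCall:
    domain: str
    start: int  # 1-based
    end: int    # 1-based inclusive
    score: float
    method: str  # "dodd_egan" or "profile"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start must be <= end")

    def overlaps(self, other: "DomainCall") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass(frozen=True)
class HthMatrix:
    """22-position HTH weight matrix with its calibration distribution."""

    model: MotifModel
    calibration_mean: float
    calibration_sd: float

    def call_threshold(self, call_sd: float) -> float:
        return self.calibration_mean + call_sd * self.calibration_sd


@functools.cache
def default_domain_profiles() -> dict[str, MotifModel]:
    ref = resources.files("hipsurvey.data") / "domain_profile_seeds.synthetic.tsv"
    with ref.open() as fh:
        return {m.name: m for m in load_motif_seeds(fh)}


@functools.cache
def default_hth_matrix() -> HthMatrix:
    ref = resources.files("hipsurvey.data") / "hth_seed.synthetic.tsv"
    seqs: list[str] = []
    cal_seed, cal_n = 20210, 5000
    with ref.open() as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "!calibration_seed":
                cal_seed = int(parts[1])
            elif parts[0] == "!calibration_n":
                cal_n = int(parts[1])
            elif not parts[0].startswith("!"):
                seqs.append(parts[1])
    # the model threshold is unused for HTH (calibration decides calls);
    # keep it low enough that best_window always reports the best window
    model = build_pssm(seqs, name="HTH", threshold=-1e9)
    rng = np.random.default_rng(cal_seed)
    aas = np.array(list(AMINO_ACIDS))
    scores = np.empty(cal_n)
    for k in range(cal_n):
        window = "".join(rng.choice(aas, size=HTH_WINDOW))
        scores[k] = model.score(window)
    return HthMatrix(
        model=model,
        calibration_mean=float(scores.mean()),
        calibration_sd=float(scores.std(ddof=1)),
    )


def hth_scan(
    protein: str, matrix: HthMatrix | None = None, call_sd: float = 5.0
) -> DomainCall | None:
    """Dodd–Egan style HTH scan: score every 22-residue window; call the
    best window iff its score is at least ``call_sd`` standard deviations
    above the calibration mean."""
    if matrix is None:
        matrix = default_hth_matrix()
    if len(protein) < HTH_WINDOW:
        return None
    hit = best_window(protein, matrix.model)  # model threshold is -inf
    assert hit is not None
    if hit.score < matrix.call_threshold(call_sd):
        return None
    return DomainCall(
        domain="HTH", start=hit.start, end=hit.end, score=hit.score, method="dodd_egan"
    )


def profile_match(
    protein: str, profile: MotifModel, threshold: float | None = None
) -> DomainCall | None:
    """Best-window log-odds score against a domain profile; call iff the
    score reaches the threshold (profile default unless overridden)."""
    if len(protein) < len(profile):
        return None
    thr = profile.threshold if threshold is None else threshold
    hit = best_window(
        protein, MotifModel(name=profile.name, matrix=profile.matrix, threshold=thr)
    )
    if hit is None:
        return None
    return DomainCall(
        domain=profile.name, start=hit.start, end=hit.end, score=hit.score,
        method="profile",
    )


def annotate_protein(
    protein: str,
    profile_set: Mapping[str, MotifModel] | None = None,
    hth_matrix: HthMatrix | None = None,
    call_sd: float = 5.0,
) -> list[DomainCall]:
    """All non-overlapping domain calls on one protein, ordered by start.

    Overlapping calls are resolved in favor of the higher score.
    """
    if profile_set is None:
        profile_set = default_domain_profiles()
    calls: list[DomainCall] = []
    hth = hth_scan(protein, hth_matrix, call_sd)
    if hth is not None:
        calls.append(hth)
    for profile in profile_set.values():
        call = profile_match(protein, profile)
        if call is not None:
            calls.append(call)
    kept: list[DomainCall] = []
    for call in sorted(calls, key=lambda c: (-c.score, c.start)):
        if not any(call.overlaps(k) for k in kept):
            kept.append(call)
    return sorted(kept, key=lambda c: c.start)


@dataclass(frozen=True)
class HiranReference:
    """Reference HIRAN domain defining the motif coordinate system."""

    name: str
    sequence: str
    motif_windows: tuple[tuple[str, int, int], ...]  # (name, start, end) 1-based
    naf_phe_position: int


@functools.cache
def default_hiran_reference() -> HiranReference:
    ref = resources.files("hipsurvey.data") / "hiran_reference.synthetic.tsv"
    name = sequence = None
    windows: list[tuple[str, int, int]] = []
    naf_phe = None
    with ref.open() as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "!reference":
                name = parts[1]
            elif parts[0] == "!sequence":
                sequence = parts[1]
            elif parts[0] == "!motif":
                windows.append((parts[1], int(parts[2]), int(parts[3])))
            elif parts[0] == "!naf_phe":
                naf_phe = int(parts[1])
    assert name and sequence and windows and naf_phe
    return HiranReference(
        name=name,
        sequence=sequence,
        motif_windows=tuple(windows),
        naf_phe_position=naf_phe,
    )


def align_to_reference(seq: str, reference: str) -> str:
    """Project a sequence onto reference coordinates by global alignment.

    Returns a string of length ``len(reference)``: for each reference
    residue, the aligned residue of ``seq`` (or ``-``).  Residues of
    ``seq`` inserted relative to the reference are dropped.
    """
    ra, sa, _ = needleman_wunsch(reference, seq)
    out = []
    for r, s in zip(ra, sa):
        if r != "-":
            out.append(s)
    return "".join(out)


@dataclass
class HiranMotifMatrix:
    """Per-group presence (+), partial conservation (±) or absence (−)
    of the reference HIRAN DNA-binding motifs, plus NAF-Phe retention."""

    motif_names: list[str]
    cells: dict[str, dict[str, str]]  # group -> motif -> "+"/"±"/"−"
    naf_phe: dict[str, bool]

    def to_rows(self) -> list[dict[str, object]]:
        rows = []
        for group, motifs in self.cells.items():
            row: dict[str, object] = {"group": group}
            row.update(motifs)
            row["naf_phe"] = self.naf_phe[group]
            rows.append(row)
        return rows


def hiran_motif_matrix(
    groups: Mapping[str, Sequence[str]],
    reference: HiranReference | None = None,
    present_frac: float = 0.7,
    partial_frac: float = 0.4,
    position_frac: float = 0.5,
    naf_frac: float = 0.5,
) -> HiranMotifMatrix:
    """Score motif conservation of HIRAN-domain groups.

    Each group member must already be projected onto the reference
    coordinate system (length equal to the reference; see
    :func:`align_to_reference`).  A member "conserves" a motif when at
    least ``position_frac`` of the motif's positions match the reference
    residue; a motif is present (+) in a group when at least
    ``present_frac`` of members conserve it, partial (±) above
    ``partial_frac``, absent (−) below.  ``naf_phe`` is true when at
    least ``naf_frac`` of members retain F at the reference NAF-Phe
    position; a group retaining the Phe is never reported as lacking the
    NAF motif entirely (an absent cell is promoted to partial).
    """
    if reference is None:
        reference = default_hiran_reference()
    L = len(reference.sequence)
    cells: dict[str, dict[str, str]] = {}
    naf_flags: dict[str, bool] = {}
    for group, members in groups.items():
        if not members:
            raise ValueError(f"empty group {group!r}")
        for m in members:
            if len(m) != L:
                raise ValueError(
                    f"group {group!r}: sequence length {len(m)} != reference "
                    f"length {L}; align to the reference first"
                )
        row: dict[str, str] = {}
        for motif, start, end in reference.motif_windows:
            ref_window = reference.sequence[start - 1 : end]
            conserving = 0
            for m in members:
                window = m[start - 1 : end]
                matches = sum(1 for a, b in zip(window, ref_window) if a == b)
                if matches / len(ref_window) >= position_frac:
                    conserving += 1
            frac = conserving / len(members)
            if frac >= present_frac:
                row[motif] = "+"
            elif frac >= partial_frac:
                row[motif] = "±"
            else:
                row[motif] = "−"
        phe_col = reference.naf_phe_position - 1
        n_phe = sum(1 for m in members if m[phe_col] == "F")
        has_phe = n_phe / len(members) >= naf_frac
        if has_phe and row.get("naf") == "−":
            row["naf"] = "±"
        cells[group] = row
        naf_flags[group] = has_phe
    return HiranMotifMatrix(
        motif_names=[w[0] for w in reference.motif_windows],
        cells=cells,
        naf_phe=naf_flags,
    )
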