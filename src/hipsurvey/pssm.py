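"""Log-odds position weight matrices for short protein motifs.

A :class:`MotifModel` is a plain log-odds matrix built from an ungapped
seed-alignment block.  Both the kinase-motif scanner and the domain
annotators score candidate windows with these matrices; anything that
clears the model threshold (in bits) is a hit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
UNIFORM_BACKGROUND = np.full(20, 0.05)

__all__ = [
    "AMINO_ACIDS",
    "MotifModel",
    "MotifHit",
    "build_pssm",
    "best_window",
    "write_models",
    "read_models",
]


@dataclass(frozen=True)
class MotifModel:
    """Log-odds matrix over the 20 amino acids with a bit-score threshold."""

    name: str
    matrix: np.ndarray  # shape (L, 20), bits
    threshold: float

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 20:
            raise ValueError("matrix must have shape (L, 20)")
        if self.matrix.shape[0] < 4:
            raise ValueError("motif length must be >= 4")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def score(self, window: str) -> float:
        """Score one window of length ``len(self)``; X scores the column mean."""
        if len(window) != len(self):
            raise ValueError(
                f"window length {len(window)} != model length {len(self)}"
            )
        total = 0.0
        for pos, aa in enumerate(window):
            idx = AA_INDEX.get(aa)
            if idx is None:
                total += float(self.matrix[pos].mean())
            else:
                total += float(self.matrix[pos, idx])
        return total

    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.matrix.argmax(axis=1))

    def max_score(self) -> float:
        return float(self.matrix.max(axis=1).sum())


@dataclass(frozen=True)
class MotifHit:
    motif: str
    start: int  # 1-based residue
    end: int    # 1-based inclusive
    score: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start must be <= end")


def build_pssm(
    aligned_block: Sequence[str],
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
    name: str = "motif",
    threshold: float = 0.0,
) -> MotifModel:
    """Build a log-odds matrix from an ungapped seed-alignment block.

    Entry[i][aa] = log2(((count + pseudocount*bg) / (N + pseudocount)) / bg),
    where N is the number of sequences and bg the background frequency.
    """
    if len(aligned_block) < 2:
        raise ValueError("need at least 2 seed sequences")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    length = len(aligned_block[0])
    if any(len(s) != length for s in aligned_block):
        raise ValueError("ragged seed block: sequences differ in length")
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    if bg.shape != (20,) or not np.isclose(bg.sum(), 1.0):
        raise ValueError("background must be 20 frequencies summing to 1")
    if (bg <= 0).any():
        raise ValueError("zero background frequency")

    n = len(aligned_block)
    counts = np.zeros((length, 20))
    for seq in aligned_block:
        for pos, aa in enumerate(seq):
            if aa == "-":
                continue
            idx = AA_INDEX.get(aa)
            if idx is None:
                raise ValueError(f"unknown residue {aa!r} in seed block")
            counts[pos, idx] += 1
    if (counts.sum(axis=1) == 0).any():
        raise ValueError("seed block contains an all-gap column")

    freqs = (counts + pseudocount * bg) / (n + pseudocount)
    matrix = np.log2(freqs / bg)
    return MotifModel(name=name, matrix=matrix, threshold=threshold)


def best_window(protein: str, model: MotifModel) -> MotifHit | None:
    """Best-scoring window of ``model`` in ``protein`` (ties: leftmost).

    Returns None when the protein is shorter than the model or the best
    score is below the model threshold.
    """
    L = len(model)
    if len(protein) < L:
        return None
    best_score = -np.inf
    best_start = 0
    for start in range(len(protein) - L + 1):
        s = model.score(protein[start : start + L])
        if s > best_score:
            best_score = s
            best_start = start
    if best_score < model.threshold:
        return None
    return MotifHit(
        motif=model.name,
        start=best_start + 1,
        end=best_start + L,
        score=best_score,
    )


def write_models(models: Iterable[MotifModel], stream: TextIO) -> None:
    """Serialize models as a tab-separated matrix file."""
    stream.write("# motif models: name\tposition\t" + "\t".join(AMINO_ACIDS) + "\n")
    for model in models:
        stream.write(f">{model.name}\tthreshold={model.threshold:.6g}\n")
        for pos in range(len(model)):
            vals = "\t".join(f"{v:.6f}" for v in model.matrix[pos])
            stream.write(f"{model.name}\t{pos + 1}\t{vals}\n")


def read_models(stream: TextIO) -> list[MotifModel]:
    models: list[MotifModel] = []
    name = None
    threshold = 0.0
    rows: list[list[float]] = []

    def flush() -> None:
        if name is not None:
            models.append(
                MotifModel(name=name, matrix=np.array(rows), threshold=threshold)
            )

    for line in stream:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            flush()
            head, _, thr = line[1:].partition("\t")
            name = head
            threshold = float(thr.split("=", 1)[1]) if "=" in thr else 0.0
            rows = []
        else:
            parts = line.split("\t")
            rows.append([float(v) for v in parts[2:22]])
    flush()
    return models
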