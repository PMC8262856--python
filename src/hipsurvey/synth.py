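"""Synthetic annotated genomes with planted toxin-antitoxin modules.

The generator emits GFF3 + protein FASTA contigs containing TA modules of
every genetic layout the survey describes, with planted kinase motifs,
planted antitoxin domains, configurable intergenic distances (including
negative overlaps), mixed strands, decoy genes and per-family sequence
divergence — together with a complete truth table, so every pipeline
stage can be validated without downloading anything.

Family templates are deterministic scaffolds: the four kinase motifs in
canonical order plus family-specific extras (an N-subdomain-1-like
N-terminal extension for the long kinases HipA/HipE/HipF; motifs close to
the N terminus for the short kinases; an N-terminal HTH for HipH; an
internal HipS-like domain plus a C-terminal HIRAN domain for HipL).
Divergence is applied to instances by i.i.d. substitution; indels are
never introduced here, so indel tests plant their own gaps with exact
truth.
"""

from __future__ import annotations

import io
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .domains import default_domain_profiles, default_hth_matrix
from .genome_io import GeneRecord, write_genome
from .motifs import default_motif_models
from .pssm import AMINO_ACIDS

FAMILIES = [
    "HipA", "HipT", "HipH", "HipE", "HipF",
    "HipG", "HipM", "HipI", "HipJ", "HipL",
]

# gene order (5' to 3'): (role, template) — kinase templates are family
# names, antitoxin/context templates are lowercase operon-part names
LAYOUT_GENES: dict[str, list[tuple[str, str]]] = {
    "hipBA": [("antitoxin", "hipB"), ("kinase", "HipA")],
    "hipAB": [("kinase", "HipA"), ("antitoxin", "hipB")],
    "hipBST": [("context", "hipB"), ("antitoxin", "hipS"), ("kinase", "HipT")],
    "hipEB": [("kinase", "HipE"), ("antitoxin", "hipB")],
    "hipH_mono": [("kinase", "HipH")],
    "hipL_mono": [("kinase", "HipL")],
    "hipRF": [("antitoxin", "hipR"), ("kinase", "HipF")],
    "hipRG": [("antitoxin", "hipR"), ("kinase", "HipG")],
    "hipMP": [("kinase", "HipM"), ("antitoxin", "hipP")],
    "hipIN": [("kinase", "HipI"), ("antitoxin", "hipN")],
    "hipJS": [("kinase", "HipJ"), ("antitoxin", "hipS")],
}

LAYOUT_TO_FAMILY = {
    layout: next(t for role, t in genes if role == "kinase")
    for layout, genes in LAYOUT_GENES.items()
}

# families without an N-subdomain-1-like extension have no conserved
# Ser/Thr next to the Gly-rich loop only in HipG (autophosphorylation
# marker, used by downstream annotation)
NO_AUTOPHOSPHO = {"HipG"}
LONG_FAMILIES = {"HipA", "HipE", "HipF"}

__all__ = [
    "FAMILIES",
    "LAYOUT_GENES",
    "LAYOUT_TO_FAMILY",
    "GeneratorConfig",
    "ModuleTruth",
    "SyntheticTruth",
    "make_family_template",
    "make_antitoxin_template",
    "family_profiles",
    "mutate",
    "random_protein",
    "generate_genome",
    "near_duplicate_panel",
]


def _rng_for(label: str, seed: int) -> np.random.Generator:
    return np.random.default_rng((zlib.crc32(label.encode()) ^ seed) & 0x7FFFFFFF)


def random_protein(length: int, rng: np.random.Generator, alphabet: str = AMINO_ACIDS) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def _filler(rng: np.random.Generator, length: int, exclude: str = "") -> str:
    alphabet = [a for a in AMINO_ACIDS if a not in exclude]
    return "".join(rng.choice(alphabet, size=length))


def _consensuses() -> dict[str, str]:
    out = {m.name: m.consensus() for m in default_motif_models()}
    out.update({name: p.consensus() for name, p in default_domain_profiles().items()})
    out["HTH"] = default_hth_matrix().model.consensus()
    return out


def _kinase_core(
    rng: np.random.Generator, cons: dict[str, str], autophospho: bool
) -> tuple[str, dict[str, tuple[int, int]]]:
    """Core kinase domain: the four motifs, in order, with random spacers."""
    parts: list[str] = []
    coords: dict[str, tuple[int, int]] = {}

    def add(segment: str, name: str | None = None) -> None:
        start = sum(len(p) for p in parts) + 1
        parts.append(segment)
        if name is not None:
            coords[name] = (start, start + len(segment) - 1)

    add(_filler(rng, 5))
    add(cons["gly_rich_loop"], "gly_rich_loop")
    if autophospho:
        add("S" + _filler(rng, 1, exclude="ST"))
    else:
        add(_filler(rng, 2, exclude="ST"))
    add(_filler(rng, 16, exclude="ST" if not autophospho else ""))
    add(cons["activation_loop"], "activation_loop")
    add(_filler(rng, 18))
    add(cons["catalytic_motif"], "catalytic_motif")
    add(_filler(rng, 18))
    add(cons["mg_binding_motif"], "mg_binding_motif")
    add(_filler(rng, 25))
    return "".join(parts), coords


def make_family_template(
    family: str, seed: int = 0
) -> tuple[str, dict[str, tuple[int, int]]]:
    """Deterministic template protein for a kinase family.

    Returns (protein, feature map of 1-based inclusive spans) covering the
    four planted motifs and any planted domains.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    rng = _rng_for(f"template:{family}", seed)
    cons = _consensuses()
    autophospho = family not in NO_AUTOPHOSPHO

    prefix = ""
    features: dict[str, tuple[int, int]] = {}
    if family in LONG_FAMILIES:
        prefix = _filler(rng, 90)
        features["n_extension"] = (1, 90)
    elif family == "HipH":
        # HTH near the N terminus (starts at residue 15)
        prefix = _filler(rng, 14) + cons["HTH"] + _filler(rng, 40)
        features["HTH"] = (15, 15 + len(cons["HTH"]) - 1)

    core, core_coords = _kinase_core(rng, cons, autophospho)
    offset = len(prefix)
    for name, (s, e) in core_coords.items():
        features[name] = (s + offset, e + offset)
    protein = prefix + core

    if family == "HipL":
        # internal HipS-like domain, then a C-terminal HIRAN domain
        mid = _filler(rng, 10)
        hips = cons["HipS_like"]
        tail = _filler(rng, 10)
        hiran = cons["HIRAN"]
        start = len(protein) + len(mid) + 1
        features["HipS_like"] = (start, start + len(hips) - 1)
        start2 = start + len(hips) + len(tail)
        features["HIRAN"] = (start2, start2 + len(hiran) - 1)
        protein = protein + mid + hips + tail + hiran
    return protein, features


def make_antitoxin_template(
    kind: str, seed: int = 0
) -> tuple[str, dict[str, tuple[int, int]]]:
    """Deterministic template for an operon partner gene.

    Kinds: hipB (HTH antitoxin), hipS (HipS-like), hipR (Stl-like + HTH),
    hipN (HipS-like + C-terminal HIRAN), hipP (resolvase-like).
    """
    rng = _rng_for(f"antitoxin:{kind}", seed)
    cons = _consensuses()
    features: dict[str, tuple[int, int]] = {}

    def build(parts: list[tuple[str, str | None]]) -> str:
        segments = []
        pos = 0
        for segment, name in parts:
            if name is not None:
                features[name] = (pos + 1, pos + len(segment))
            segments.append(segment)
            pos += len(segment)
        return "".join(segments)

    if kind == "hipB":
        protein = build(
            [(_filler(rng, 20), None), (cons["HTH"], "HTH"), (_filler(rng, 38), None)]
        )
    elif kind == "hipS":
        protein = build(
            [(_filler(rng, 10), None), (cons["HipS_like"], "HipS_like"),
             (_filler(rng, 25), None)]
        )
    elif kind == "hipR":
        protein = build(
            [(_filler(rng, 8), None), (cons["Stl_like"], "Stl_like"),
             (_filler(rng, 8), None), (cons["HTH"], "HTH"), (_filler(rng, 12), None)]
        )
    elif kind == "hipN":
        protein = build(
            [(_filler(rng, 5), None), (cons["HipS_like"], "HipS_like"),
             (_filler(rng, 15), None), (cons["HIRAN"], "HIRAN"),
             (_filler(rng, 5), None)]
        )
    elif kind == "hipP":
        protein = build(
            [(_filler(rng, 10), None), (cons["resolvase_like"], "resolvase_like"),
             (_filler(rng, 20), None)]
        )
    else:
        raise ValueError(f"unknown antitoxin kind {kind!r}")
    return protein, features


def family_profiles(template_seed: int = 0) -> dict[str, str]:
    """One reference sequence per family (the templates themselves)."""
    return {fam: make_family_template(fam, template_seed)[0] for fam in FAMILIES}


def mutate(seq: str, divergence: float, seed: int | np.random.Generator) -> str:
    """I.i.d. substitutions at the given per-site rate (uniform over the
    other 19 residues); deterministic under a seed."""
    if not 0 <= divergence < 1:
        raise ValueError("divergence must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if divergence == 0:
        return seq
    out = list(seq)
    hits = rng.random(len(seq)) < divergence
    for i in np.nonzero(hits)[0]:
        alternatives = [a for a in AMINO_ACIDS if a != out[i]]
        out[i] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(out)


@dataclass
class GeneratorConfig:
    """Study conditions for a synthetic survey genome."""

    seed: int
    layout_counts: dict[str, int] = field(
        default_factory=lambda: {layout: 1 for layout in LAYOUT_GENES}
    )
    divergence: float = 0.1            # within-family, substitutions/site
    template_seed: int = 0             # scaffold seed; 0 matches the packaged profiles
    overlap_prob: float = 0.25         # mass of the negative-distance component
    overlap_range: tuple[int, int] = (-20, -1)
    gap_range: tuple[int, int] = (1, 120)
    decoys_no_motif: int = 0
    decoys_orphan: int = 0
    strand_mix: bool = True
    module_spacing: int = 400          # nt between modules, > operon max_gap
    modules_per_contig: int = 6

    def validate(self) -> None:
        if any(c < 0 for c in self.layout_counts.values()):
            raise ValueError("negative layout count")
        unknown = set(self.layout_counts) - set(LAYOUT_GENES)
        if unknown:
            raise ValueError(f"unknown layouts: {sorted(unknown)}")
        if not 0 <= self.divergence < 1:
            raise ValueError("divergence must be in [0, 1)")
        if self.decoys_no_motif < 0 or self.decoys_orphan < 0:
            raise ValueError("negative decoy count")
        if self.module_spacing <= 150:
            raise ValueError("module_spacing must exceed the operon gap limit")


@dataclass
class ModuleTruth:
    module_id: str
    layout: str
    family: str
    kinase_id: str
    antitoxin_id: str | None
    context_ids: list[str]
    distances: list[int]           # intergenic distances between adjacent genes, 5'->3'
    kinase_antitoxin_distance: int | None
    strand: str
    kinase_features: dict[str, tuple[int, int]]
    antitoxin_features: dict[str, tuple[int, int]]


@dataclass
class SyntheticTruth:
    modules: list[ModuleTruth] = field(default_factory=list)
    decoys: list[tuple[str, str]] = field(default_factory=list)  # (gene_id, class)

    def gene_ids(self) -> set[str]:
        ids = {d[0] for d in self.decoys}
        for m in self.modules:
            ids.add(m.kinase_id)
            if m.antitoxin_id:
                ids.add(m.antitoxin_id)
            ids.update(m.context_ids)
        return ids

    def layout_of_kinase(self) -> dict[str, str]:
        return {m.kinase_id: m.layout for m in self.modules}

    def family_of_kinase(self) -> dict[str, str]:
        return {m.kinase_id: m.family for m in self.modules}

    def to_tsv(self, stream) -> None:
        stream.write(
            "record\tmodule_id\tlayout\tfamily\tkinase_id\tantitoxin_id\t"
            "context_ids\tdistances\tka_distance\tstrand\tdecoy_class\n"
        )
        for m in self.modules:
            stream.write(
                f"module\t{m.module_id}\t{m.layout}\t{m.family}\t{m.kinase_id}\t"
                f"{m.antitoxin_id or ''}\t{','.join(m.context_ids)}\t"
                f"{','.join(map(str, m.distances))}\t"
                f"{'' if m.kinase_antitoxin_distance is None else m.kinase_antitoxin_distance}\t"
                f"{m.strand}\t\n"
            )
        for gene_id, klass in self.decoys:
            stream.write(f"decoy\t\t\t\t{gene_id}\t\t\t\t\t\t{klass}\n")


def _draw_distance(cfg: GeneratorConfig, rng: np.random.Generator) -> int:
    if rng.random() < cfg.overlap_prob:
        lo, hi = cfg.overlap_range
    else:
        lo, hi = cfg.gap_range
    return int(rng.integers(lo, hi + 1))


def generate_genome(
    config: GeneratorConfig,
) -> tuple[str, str, SyntheticTruth]:
    """Emit (GFF3 text, protein FASTA text, truth) for a synthetic genome."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes: list[GeneRecord] = []
    truth = SyntheticTruth()

    # deterministic module order: spec order of layouts, then replicate index
    jobs: list[tuple[str, int]] = []
    for layout in LAYOUT_GENES:
        for rep in range(config.layout_counts.get(layout, 0)):
            jobs.append((layout, rep))

    contig_idx = 1
    cursor = 1
    modules_on_contig = 0
    for layout, rep in jobs:
        if modules_on_contig >= config.modules_per_contig:
            contig_idx += 1
            cursor = 1
            modules_on_contig = 0
        contig = f"ctg{contig_idx}"
        module_id = f"{layout}_{rep + 1}"
        strand = "+"
        if config.strand_mix and rng.random() < 0.5:
            strand = "-"

        parts = LAYOUT_GENES[layout]
        proteins: list[tuple[str, str, str]] = []  # (gene_id, role, protein)
        kin_feat: dict[str, tuple[int, int]] = {}
        at_feat: dict[str, tuple[int, int]] = {}
        for gi, (role, template) in enumerate(parts):
            gene_id = f"{module_id}_g{gi + 1}_{role}"
            if role == "kinase":
                template_seq, feats = make_family_template(
                    template, config.template_seed
                )
                kin_feat = feats
            else:
                template_seq, feats = make_antitoxin_template(
                    template, config.template_seed
                )
                if role == "antitoxin":
                    at_feat = feats
            protein = mutate(template_seq, config.divergence, rng)
            proteins.append((gene_id, role, protein))

        distances = [_draw_distance(config, rng) for _ in range(len(parts) - 1)]

        # genome placement: for '-' strand modules the 5'->3' gene order
        # runs right-to-left on the contig
        module_genes: list[GeneRecord] = []
        pos = cursor
        if strand == "+":
            seq_iter = list(zip(proteins, [0] + distances))
        else:
            rev_dists = distances[::-1]
            seq_iter = list(zip(proteins[::-1], [0] + rev_dists))
        for k, ((gene_id, role, protein), dist) in enumerate(seq_iter):
            if k > 0:
                pos = module_genes[-1].end + 1 + dist
            length_nt = 3 * (len(protein) + 1)
            start = max(1, pos)
            gene = GeneRecord(
                gene_id=gene_id,
                contig=contig,
                start=start,
                end=start + length_nt - 1,
                strand=strand,
                protein=protein,
                product=f"synthetic {role}",
            )
            module_genes.append(gene)
        genes.extend(module_genes)
        cursor = max(g.end for g in module_genes) + config.module_spacing
        modules_on_contig += 1

        kinase_id = next(g for g, r, _ in proteins if r == "kinase")
        antitoxin_id = next((g for g, r, _ in proteins if r == "antitoxin"), None)
        context_ids = [g for g, r, _ in proteins if r == "context"]
        ka_dist = None
        if antitoxin_id is not None:
            by_id = {g.gene_id: g for g in module_genes}
            a, b = by_id[kinase_id], by_id[antitoxin_id]
            first, second = (a, b) if a.start <= b.start else (b, a)
            ka_dist = second.start - first.end - 1
        truth.modules.append(
            ModuleTruth(
                module_id=module_id,
                layout=layout,
                family=LAYOUT_TO_FAMILY[layout],
                kinase_id=kinase_id,
                antitoxin_id=antitoxin_id,
                context_ids=context_ids,
                distances=distances,
                kinase_antitoxin_distance=ka_dist,
                strand=strand,
                kinase_features=kin_feat,
                antitoxin_features=at_feat,
            )
        )

    # decoys on their own contig region, well separated
    for d in range(config.decoys_no_motif):
        gene_id = f"decoy_nomotif_{d + 1}"
        protein = _filler(rng, 120)
        length_nt = 3 * (len(protein) + 1)
        genes.append(
            GeneRecord(
                gene_id=gene_id, contig=f"ctg{contig_idx}", start=cursor,
                end=cursor + length_nt - 1, strand="+", protein=protein,
                product="synthetic decoy",
            )
        )
        cursor += length_nt + config.module_spacing
        truth.decoys.append((gene_id, "no_motifs"))
    for d in range(config.decoys_orphan):
        gene_id = f"decoy_orphan_{d + 1}"
        template_seq, _ = make_family_template("HipA", config.template_seed)
        protein = mutate(template_seq, config.divergence, rng)
        length_nt = 3 * (len(protein) + 1)
        genes.append(
            GeneRecord(
                gene_id=gene_id, contig=f"ctg{contig_idx}", start=cursor,
                end=cursor + length_nt - 1, strand="+", protein=protein,
                product="synthetic orphan kinase",
            )
        )
        cursor += length_nt + config.module_spacing
        truth.decoys.append((gene_id, "orphan_kinase"))

    gff_buf, fasta_buf = io.StringIO(), io.StringIO()
    write_genome(genes, gff_buf, fasta_buf)
    return gff_buf.getvalue(), fasta_buf.getvalue(), truth


def near_duplicate_panel(
    n: int = 50, seed: int = 0, template_seed: int = 0,
    near_divergence: float = 0.02, far_divergence: float = 0.25,
    near_pairs: int = 8,
) -> list[tuple[str, str]]:
    """A seeded panel of kinase sequences containing near-duplicate pairs.

    Members are drawn from the family templates at ``far_divergence``;
    ``near_pairs`` of them get a partner at ``near_divergence`` (expected
    identity well above 95%), exercising the deduplication rule.
    """
    rng = np.random.default_rng(seed)
    base: list[tuple[str, str]] = []
    k = 0
    while len(base) < n - near_pairs:
        fam = FAMILIES[k % len(FAMILIES)]
        template, _ = make_family_template(fam, template_seed)
        base.append((f"kin{len(base) + 1:03d}", mutate(template, far_divergence, rng)))
        k += 1
    panel = list(base)
    for p in range(near_pairs):
        src_id, src_seq = base[p]
        panel.append((f"{src_id}_dup", mutate(src_seq, near_divergence, rng)))
    return panel[:n]
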