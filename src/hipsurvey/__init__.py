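"""hipsurvey: comparative genomics of HipA-homologous kinase
toxin-antitoxin modules.

Motif-based kinase detection, genetic-context (operon layout)
classification into kinase families, antitoxin domain annotation,
curation with near-duplicate removal, neighbor-joining phylogeny with
bootstrap and monophyly tests, and clade-relative indel/divergence
mapping — all exercisable on synthetic genomes with planted truth.
"""

__version__ = "0.1.0"

from importlib import resources as _resources

import pandas as _pd


def load_reference_clade_sizes() -> "_pd.DataFrame":
    """The published clade summary of the 1,239-kinase Hip tree
    (clade, number of kinase genes, TA gene organizations)."""
    ref = _resources.files("hipsurvey.data") / "clade_sizes.tsv"
    with ref.open() as fh:
        return _pd.read_csv(fh, sep="\t", comment="#")


from .genome_io import (  # noqa: E402
    GeneRecord,
    LocusRow,
    LocusTable,
    intergenic_distance,
    parse_genome,
    parse_locus_table,
    write_locus_table,
)
from .motifs import is_candidate_kinase, scan_motifs  # noqa: E402
from .curation import curate, global_identity, greedy_dedup  # noqa: E402
from .domains import annotate_protein, hiran_motif_matrix, hth_scan, profile_match  # noqa: E402
from .neighborhood import (  # noqa: E402
    TAModule,
    assign_family,
    classify_layout,
    frequency_report,
    operon_context,
)
from .align import (  # noqa: E402
    Msa,
    alignment_stats,
    center_star_msa,
    needleman_wunsch,
    p_distance_matrix,
)
from .phylo import bootstrap_support, is_monophyletic, nj_tree  # noqa: E402
from .indels import call_indels, divergence_regions, occupancy_profile, to_reference_coords  # noqa: E402
from .synth import GeneratorConfig, generate_genome, make_family_template, mutate  # noqa: E402
from .pipeline import SurveySettings, run_survey  # noqa: E402
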