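import pytest

from hipsurvey.curation import global_identity
from hipsurvey.domains import annotate_protein
from hipsurvey.genome_io import GeneRecord
from hipsurvey.motifs import scan_motifs
from hipsurvey.neighborhood import (
    LAYOUTS,
    LAYOUT_TO_FAMILY,
    REVERSED_LAYOUTS,
    TAModule,
    assign_family,
    classify_layout,
    frequency_report,
    is_reversed,
    operon_context,
    pick_antitoxin,
)
from hipsurvey.synth import family_profiles, make_antitoxin_template, make_family_template


def _gene(gid, start, length_nt, strand="+", protein="MKV", contig="c1"):
    return GeneRecord(gid, contig, start, start + length_nt - 1, strand, protein)


def test_operon_context_upstream_antitoxin():
    b = _gene("B", 100, 200)
    a = _gene("A", 320, 600)  # gap 20
    up, down = operon_context(a, [b, a])
    assert [c.gene.gene_id for c in up] == ["B"]
    assert up[0].distance == 20 and up[0].same_strand
    assert down == []


def test_operon_context_tricistronic_nearest_first():
    b = _gene("B", 100, 150)
    s = _gene("S", 300, 150)  # gap 49 to B
    t = _gene("T", 500, 600)  # gap 49 to S
    up, down = operon_context(t, [b, s, t])
    assert [c.gene.gene_id for c in up] == ["S", "B"]
    assert down == []


def test_operon_context_opposite_strand_stops_walk():
    b = _gene("B", 100, 200, strand="-")
    a = _gene("A", 320, 600)
    up, down = operon_context(a, [b, a])
    assert up == [] and down == []


def test_operon_context_gap_limit_stops_walk():
    b = _gene("B", 100, 200)
    a = _gene("A", 500, 600)  # gap 199 > 150
    up, _ = operon_context(a, [b, a])
    assert up == []
    up, _ = operon_context(a, [b, a], max_gap=250)
    assert [c.gene.gene_id for c in up] == ["B"]


def test_operon_context_minus_strand_orientation():
    # on the minus strand, upstream genes lie to the right on the contig
    a = _gene("A", 100, 200, strand="-")
    b = _gene("B", 320, 150, strand="-")
    up, down = operon_context(a, [a, b])
    assert [c.gene.gene_id for c in up] == ["B"]
    assert down == []


def test_operon_context_unknown_kinase_error():
    a = _gene("A", 100, 200)
    with pytest.raises(ValueError, match="ghost"):
        operon_context(_gene("ghost", 500, 100), [a])


def _module(kinase, genes):
    up, down = operon_context(kinase, genes)
    return TAModule(
        kinase=kinase,
        upstream=up,
        downstream=down,
        kinase_hits=scan_motifs(kinase.protein),
        kinase_domains=annotate_protein(kinase.protein),
        context_domains={
            c.gene.gene_id: annotate_protein(c.gene.protein) for c in up + down
        },
    )


def _profile_decider():
    profiles = family_profiles()

    def decide(seq):
        id_a = global_identity(seq, profiles["HipA"])
        id_e = global_identity(seq, profiles["HipE"])
        if id_a == id_e:
            return None
        return "HipE" if id_e > id_a else "HipA"

    return decide


def test_reversal_mirror_flips_hipba_to_hipab():
    kin, _ = make_family_template("HipA")
    at, _ = make_antitoxin_template("hipB")
    kin_nt, at_nt = 3 * (len(kin) + 1), 3 * (len(at) + 1)
    decider = _profile_decider()

    # antitoxin-first: hipBA, not reversed
    b = _gene("at", 100, at_nt, protein=at)
    a = _gene("kin", b.end + 6, kin_nt, protein=kin)
    module = _module(a, [b, a])
    module.organization = classify_layout(module, family_decider=decider)
    assert module.organization == "hipBA"
    assert not module.reversed

    # mirrored gene order, nothing else changed: hipAB, reversed
    a2 = _gene("kin", 100, kin_nt, protein=kin)
    b2 = _gene("at", a2.end + 6, at_nt, protein=at)
    module2 = _module(a2, [a2, b2])
    module2.organization = classify_layout(module2, family_decider=decider)
    assert module2.organization == "hipAB"
    assert module2.reversed


def test_kinase_then_hth_hipe_template_classified_hipeb():
    kin, _ = make_family_template("HipE")
    at, _ = make_antitoxin_template("hipB")
    a = _gene("kin", 100, 3 * (len(kin) + 1), protein=kin)
    b = _gene("at", a.end + 6, 3 * (len(at) + 1), protein=at)
    module = _module(a, [a, b])
    layout = classify_layout(module, family_decider=_profile_decider())
    assert layout == "hipEB"
    assert assign_family(layout) == "HipE"


def test_classified_layouts_match_truth(zero_div_survey):
    result, truth = zero_div_survey
    layout_truth = truth.layout_of_kinase()
    family_truth = truth.family_of_kinase()
    by_id = {m.kinase.gene_id: m for m in result.modules}
    for kid, layout in layout_truth.items():
        assert by_id[kid].organization == layout
        assert by_id[kid].family == family_truth[kid]


def test_reversed_flag_matches_layout_set():
    assert REVERSED_LAYOUTS == {"hipAB", "hipEB"}
    for layout in LAYOUTS:
        assert is_reversed(layout) == (layout in {"hipAB", "hipEB"})


def test_assign_family_exhaustive_mapping():
    expected = {
        "hipBA": "HipA", "hipAB": "HipA", "hipBST": "HipT", "hipEB": "HipE",
        "hipH_mono": "HipH", "hipL_mono": "HipL", "hipRF": "HipF",
        "hipRG": "HipG", "hipMP": "HipM", "hipIN": "HipI", "hipJS": "HipJ",
        "unclassified": "unknown",
    }
    assert {lay: assign_family(lay) for lay in LAYOUTS} == expected
    families = {assign_family(lay) for lay in LAYOUTS if lay != "unclassified"}
    assert len(families) == 10
    with pytest.raises(ValueError, match="unknown layout"):
        assign_family("hipXX")


def test_pick_antitoxin_sides(zero_div_survey):
    result, truth = zero_div_survey
    at_truth = {m.kinase_id: m.antitoxin_id for m in truth.modules}
    for m in result.kept_modules:
        expected = at_truth[m.kinase.gene_id]
        got = m.antitoxin.gene_id if m.antitoxin else None
        assert got == expected


def _bare_module(layout, idx=0):
    kinase = _gene(f"k{layout}{idx}", 100 + 1000 * idx, 300)
    m = TAModule(kinase=kinase)
    m.organization = layout
    m.family = LAYOUT_TO_FAMILY[layout]
    return m


def test_frequency_report_counts_and_percent():
    modules = [_bare_module("hipBA", 0), _bare_module("hipBA", 1), _bare_module("hipBST", 2)]
    report = frequency_report(modules)
    layout = report["layout"]
    assert layout.loc["hipBA", "count"] == 2
    assert layout.loc["hipBA", "percent"] == 67
    assert layout.loc["hipBST", "count"] == 1
    assert layout.loc["hipBST", "percent"] == 33
    assert layout.loc["hipJS", "count"] == 0
    assert report["summary"].loc["total_modules", "value"] == 3
    assert report["summary"].loc["reversed_order", "value"] == 0


def test_frequency_report_empty_all_zero():
    report = frequency_report([])
    assert (report["layout"]["count"] == 0).all()
    assert (report["layout"]["percent"] == 0).all()
    assert report["summary"].loc["total_modules", "value"] == 0


def test_frequency_report_one_per_layout_ten_families():
    modules = [
        _bare_module(lay, i)
        for i, lay in enumerate(LAYOUTS)
        if lay != "unclassified"
    ]
    report = frequency_report(modules)
    assert len(report["family"]) == 10
    assert report["summary"].loc["reversed_order", "value"] == 2
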