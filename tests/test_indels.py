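import numpy as np
import pytest

from hipsurvey.align import Msa
from hipsurvey.indels import (
    call_indels,
    divergence_regions,
    occupancy_profile,
    to_reference_coords,
)


def _msa(rows):
    return Msa(names=[f"s{i}" for i in range(len(rows))], rows=rows)


def test_occupancy_profile_basic():
    msa = _msa(["ACDE", "AC-E", "A--E", "A-DE"])
    occ = occupancy_profile(msa, msa.names)
    assert np.allclose(occ, [1.0, 0.5, 0.5, 1.0])
    with pytest.raises(ValueError, match="empty"):
        occupancy_profile(msa, [])


def test_occupancy_profile_random_matches_direct_tally():
    rng = np.random.default_rng(41)
    chars = list("ACD-")
    rows = ["".join(rng.choice(chars, size=30)) for _ in range(5)]
    msa = _msa(rows)
    occ = occupancy_profile(msa, msa.names)
    for j in range(30):
        direct = sum(1 for r in rows if r[j] != "-") / 5
        assert occ[j] == pytest.approx(direct)


def _planted_msa():
    """4 ref + 4 query rows, width 40: query gapped at columns 11-15 (Δ),
    ref gapped at columns 25-28 (ω)."""
    base = "MKVAGTWEHDLYNRCPQISFMKVAGTWEHDLYNRCPQISF"
    assert len(base) == 40
    ref_row = base[:24] + "----" + base[28:]   # ref rows gapped at 25-28
    query_row = base[:10] + "-----" + base[15:]  # query rows gapped at 11-15
    rows = [ref_row] * 4 + [query_row] * 4
    names = [f"ref{i}" for i in range(4)] + [f"q{i}" for i in range(4)]
    return Msa(names=names, rows=rows), [n for n in names if n.startswith("ref")], [
        n for n in names if n.startswith("q")
    ]


def test_planted_indels_exact_recall_and_precision():
    msa, ref, query = _planted_msa()
    events = call_indels(msa, ref, query)
    # exactly the two planted events, nothing else
    assert len(events) == 2
    delta = next(e for e in events if e.kind == "delta_deletion")
    omega = next(e for e in events if e.kind == "omega_insertion")
    assert (delta.msa_start, delta.msa_end, delta.label) == (11, 15, "Δ1")
    assert (omega.msa_start, omega.msa_end, omega.label) == (25, 28, "ω1")
    assert delta.length == 5 and omega.length == 4


def test_omega_delta_duality_under_group_swap():
    msa, ref, query = _planted_msa()
    fwd = call_indels(msa, ref, query)
    rev = call_indels(msa, query, ref)
    assert len(fwd) == len(rev)
    spans_fwd = {(e.msa_start, e.msa_end): e.kind for e in fwd}
    spans_rev = {(e.msa_start, e.msa_end): e.kind for e in rev}
    assert set(spans_fwd) == set(spans_rev)
    swap = {"delta_deletion": "omega_insertion", "omega_insertion": "delta_deletion"}
    for span, kind in spans_fwd.items():
        assert spans_rev[span] == swap[kind]


def test_two_deletions_labeled_left_to_right():
    base = "MKVAGTWEHDLYNRCPQISF"  # 20 cols
    query = "---" + base[3:8] + "----" + base[12:]
    msa = Msa(names=["r0", "r1", "q0", "q1"], rows=[base, base, query, query])
    events = call_indels(msa, ["r0", "r1"], ["q0", "q1"], min_len=3)
    deltas = [e for e in events if e.kind == "delta_deletion"]
    assert [(e.label, e.msa_start, e.msa_end) for e in deltas] == [
        ("Δ1", 1, 3),
        ("Δ2", 9, 12),
    ]


def test_min_len_filters_short_runs():
    base = "MKVAGTWEHDLYNRCPQISF"
    query = base[:5] + "--" + base[7:]  # run of 2 < min_len 3
    msa = Msa(names=["r", "q"], rows=[base, query])
    assert call_indels(msa, ["r"], ["q"], min_len=3) == []
    assert len(call_indels(msa, ["r"], ["q"], min_len=2)) == 1


def test_overlapping_groups_rejected():
    msa = _msa(["ACDE", "ACDE"])
    with pytest.raises(ValueError, match="overlap"):
        call_indels(msa, ["s0"], ["s0", "s1"])


def test_divergence_regions_identical_groups_none():
    base = "MKVAGTWEHDLYNRCPQISFMKVAGTWEHD"
    msa = Msa(names=["r", "q"], rows=[base, base])
    assert divergence_regions(msa, ["r"], ["q"]) == []


def test_divergence_regions_planted_block():
    rng = np.random.default_rng(53)
    base = "MKVAGTWEHDLYNRCPQISF" * 3  # 60 cols
    chars = [c for c in "ACDEFGHIKLMNPQRSTVWY"]
    block_start, block_end = 20, 39  # 0-based, 20 columns
    q = list(base)
    for j in range(block_start, block_end + 1):
        alternatives = [c for c in chars if c != q[j]]
        q[j] = alternatives[int(rng.integers(len(alternatives)))]
    query = "".join(q)
    msa = Msa(names=["r", "q"], rows=[base, query])
    regions = divergence_regions(msa, ["r"], ["q"], window=10, cutoff=0.3)
    assert len(regions) == 1
    region = regions[0]
    # flagged windows can extend at most window-1 columns past the block
    assert region.msa_start >= block_start + 1 - 9
    assert region.msa_end <= block_end + 1 + 9
    assert region.msa_start <= block_start + 1
    assert region.msa_end >= block_end + 1
    assert region.mean_identity < 0.3 + 0.2  # merged-run mean stays low
    # cutoff 0 can never flag anything (identity < 0 is impossible)
    assert divergence_regions(msa, ["r"], ["q"], cutoff=0.0) == []
    with pytest.raises(ValueError, match="window"):
        divergence_regions(msa, ["r"], ["q"], window=1000)


def test_reference_coords_gap_free_reference():
    msa, ref, query = _planted_msa()
    # make a gap-free reference row for mapping
    base = "MKVAGTWEHDLYNRCPQISFMKVAGTWEHDLYNRCPQISF"
    msa2 = Msa(names=msa.names + ["anchor"], rows=msa.rows + [base])
    events = call_indels(msa2, ref + ["anchor"], query)
    mapped = to_reference_coords(events, msa2, "anchor")
    for ev in mapped:
        assert (ev.ref_start, ev.ref_end) == (ev.msa_start, ev.msa_end)
        assert not ev.in_ref_gap


def test_reference_coords_leading_gaps_shift():
    ref_row = "--MKVAGTWEHD"
    q_row = "--MKV-----HD"
    msa = Msa(names=["r", "q"], rows=[ref_row, q_row])
    events = call_indels(msa, ["r"], ["q"])
    mapped = to_reference_coords(events, msa, "r")
    assert len(mapped) == 1
    ev = mapped[0]
    assert (ev.msa_start, ev.msa_end) == (6, 10)
    # reference residue numbers are shifted by the 2 leading gap columns
    assert (ev.ref_start, ev.ref_end) == (4, 8)


def test_reference_coords_insertion_in_ref_gap_anchored():
    ref_row = "MKVAG-----WEHD"
    q_row = "MKVAGTTTTTWEHD"
    msa = Msa(names=["r", "q"], rows=[ref_row, q_row])
    events = call_indels(msa, ["r"], ["q"])
    assert len(events) == 1 and events[0].kind == "omega_insertion"
    mapped = to_reference_coords(events, msa, "r")
    ev = mapped[0]
    assert ev.in_ref_gap
    assert ev.ref_anchor == 5  # preceding reference residue
    assert ev.ref_start is None and ev.ref_end is None


def test_reference_coords_hand_built_mapping():
    from hipsurvey.indels import _column_to_residue

    msa = Msa(names=["r"], rows=["-AB-C-"])
    # manual column-to-residue table: gap columns 0, residues count up
    assert _column_to_residue(msa, "r") == [0, 1, 2, 0, 3, 0]
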