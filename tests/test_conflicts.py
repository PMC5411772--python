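import pytest

from hybridscaf.alignment import AlignmentParams, MapAlignment, align_maps
from hybridscaf.conflicts import (
    Breakpoint,
    ConflictParams,
    ConflictRecord,
    Junction,
    arbitrate_conflict,
    break_objects,
    detect_conflicts,
    place_breakpoints,
)
from hybridscaf.digestion import RestrictionMap


def _map(map_id, sites, length=None, source="consensus"):
    return RestrictionMap(map_id, length or sites[-1] + 5_000, list(sites), source=source)


def _grid(n, spacing=8_000, start=8_000):
    return [start + k * spacing for k in range(n)]


LOW = {"strict": 10.0, "relaxed": 5.0}


def _align(query, ref):
    params = AlignmentParams(tier_thresholds=dict(LOW))
    alns = align_maps(query, ref, params, max_alignments=1)
    assert alns, "constructed instance must align"
    return alns[0]


def test_full_containment_is_not_a_conflict():
    ref = _map("cmap", _grid(20))
    # query = interior slice of ref: overhangs exist on ref only
    q_sites = [s - 40_000 for s in _grid(20)[6:14]]
    query = _map("ctg", q_sites, source="insilico_contig")
    aln = _align(query, ref)
    assert detect_conflicts([aln], {"cmap": ref}, {"ctg": query}) == []


def _chimera_instance():
    """Contig whose left half matches the map, right half does not.

    Map: 24 sites at 8 kb spacing.  Contig: the first 10 map intervals then a
    divergent tail (different spacing), so the alignment ends internally on
    both objects with >= 5 unaligned labels each.
    """
    ref = _map("cmap", _grid(24))
    left = _grid(10)
    tail = [left[-1] + 3_000 + k * 5_500 for k in range(8)]
    query = _map("ctg", left + tail, source="insilico_contig")
    aln = _align(query, ref)
    return ref, query, aln


def test_conflict_requires_overhang_on_both_objects():
    ref, query, aln = _chimera_instance()
    conflicts = detect_conflicts([aln], {"cmap": ref}, {"ctg": query})
    assert len(conflicts) == 1
    c = conflicts[0]
    assert c.contig_id == "ctg" and c.map_id == "cmap"
    # hand count: pairs cover query sites 0..9 and ref sites 0..9, leaving 8
    # query and 14 ref labels beyond the terminus
    assert c.junction_side == "ref_right"
    assert detect_conflicts([aln], {"cmap": ref}, {"ctg": query}, min_overhang_sites=9) == []


def test_two_maps_conflicting_at_same_region():
    """Two different maps disagreeing over one contig region -> two
    conflicts naming the same contig junction; arbitration blames the contig."""
    ref1, query, aln1 = _chimera_instance()
    ref2 = _map("cmap2", _grid(24, spacing=8_000, start=4_000))
    aln2 = _align(query, ref2)
    maps = {"cmap": ref1, "cmap2": ref2}
    conflicts = detect_conflicts([aln1, aln2], maps, {"ctg": query})
    on_ctg = [c for c in conflicts if c.contig_id == "ctg"]
    assert len(on_ctg) == 2
    mids = [c.contig_junction.midpoint for c in on_ctg]
    assert abs(mids[0] - mids[1]) < 20_000
    verdict = arbitrate_conflict(on_ctg[0], conflicts, conflicts)
    assert verdict == "contig_error"
    assert "second conflict on contig" in on_ctg[0].evidence


def test_alt_assembly_supports_map_over_contig():
    """A map fully aligned across its junction by an alternate-assembly
    contig convicts the focal contig."""
    ref, query, aln = _chimera_instance()
    conflicts = detect_conflicts([aln], {"cmap": ref}, {"ctg": query})
    c = conflicts[0]
    alt_full = MapAlignment(
        query_id="alt_ctg", ref_id="cmap", orientation="+",
        pairs=[(i, i) for i in range(24)], score=72.0, tier="strict",
        query_span=(8_000, 8_000 + 23 * 8_000), ref_span=(8_000, 8_000 + 23 * 8_000),
    )
    assert arbitrate_conflict(c, [c], [c], alt_assembly_alignments=[alt_full]) == "contig_error"


def test_no_evidence_falls_back_to_cutting_both():
    ref, query, aln = _chimera_instance()
    c = detect_conflicts([aln], {"cmap": ref}, {"ctg": query})[0]
    assert arbitrate_conflict(c, [c], [c]) == "both"
    assert "fallback" in c.evidence


def _conflict_with_junction(verdict, contig_junction, aln, contig, cmap):
    c = ConflictRecord(
        contig_id=contig.map_id, map_id=cmap.map_id, alignment=aln,
        junction_side="ref_right", contig_junction=contig_junction,
        map_junction=Junction(cmap.sites[-1], cmap.sites[-1]),
    )
    c.verdict = verdict
    return c


def test_breakpoint_is_floor_midpoint():
    contig = _map("ctg", [50_000, 100_000, 110_000, 150_000, 200_000], length=260_000)
    cmap = _map("cmap", _grid(6))
    aln = MapAlignment("ctg", "cmap", "+", [(0, 0), (1, 1)], 6.0, "strict",
                       (50_000, 100_000), (8_000, 16_000))
    c = _conflict_with_junction("contig_error", Junction(100_000, 110_000), aln, contig, cmap)
    bps = place_breakpoints(c, {"cmap": cmap}, {"ctg": contig})
    assert [(b.object_kind, b.position_bp) for b in bps] == [("contig", 105_000)]


def test_breakpoint_moves_to_nearby_indel_block():
    """An unmatched 2-label block at 118/126 kb pulls the cut to 122 kb."""
    contig = _map(
        "ctg", [50_000, 100_000, 118_000, 126_000, 150_000, 200_000], length=260_000
    )
    cmap = _map("cmap", _grid(8))
    # pairs skip contig labels 2 and 3 (the indel block) between matches
    aln = MapAlignment("ctg", "cmap", "+", [(0, 0), (1, 1), (4, 2), (5, 3)], 12.0,
                       "strict", (50_000, 200_000), (8_000, 32_000))
    c = _conflict_with_junction("contig_error", Junction(100_000, 110_000), aln, contig, cmap)
    bps = place_breakpoints(c, {"cmap": cmap}, {"ctg": contig})
    assert bps[0].position_bp == 122_000


def test_both_verdict_places_two_breakpoints():
    ref, query, aln = _chimera_instance()
    c = detect_conflicts([aln], {"cmap": ref}, {"ctg": query})[0]
    arbitrate_conflict(c, [c], [c])
    bps = place_breakpoints(c, {"cmap": ref}, {"ctg": query})
    assert sorted(b.object_kind for b in bps) == ["contig", "map"]


def test_unresolved_conflict_cannot_be_cut():
    ref, query, aln = _chimera_instance()
    c = detect_conflicts([aln], {"cmap": ref}, {"ctg": query})[0]
    with pytest.raises(ValueError):
        place_breakpoints(c, {"cmap": ref}, {"ctg": query})


def test_break_objects_conserves_sequence_and_sites():
    seq = "ACGT" * 250_000  # 1 Mb
    bps = [Breakpoint("ctg", "contig", 300_000), Breakpoint("ctg", "contig", 700_000)]
    new, lineage = break_objects({"ctg": seq}, bps)
    assert [len(new[f"ctg.{k}"]) for k in (1, 2, 3)] == [300_000, 400_000, 300_000]
    assert new["ctg.1"] + new["ctg.2"] + new["ctg.3"] == seq
    assert [(l[1], l[2], l[3]) for l in lineage] == [
        ("ctg", 0, 300_000), ("ctg", 300_000, 700_000), ("ctg", 700_000, 1_000_000)
    ]


def test_break_objects_partitions_map_sites():
    sites = [50_000 * k for k in range(1, 11)]  # 10 sites, 50k..500k
    m = RestrictionMap("m", 600_000, sites, source="consensus")
    new, _ = break_objects({"m": m}, [Breakpoint("m", "map", 275_000)])
    assert new["m.1"].sites == [50_000, 100_000, 150_000, 200_000, 250_000]
    assert new["m.2"].sites == [s - 275_000 for s in sites[5:]]
    assert new["m.1"].length_bp + new["m.2"].length_bp == 600_000
    assert new["m.1"].n_sites + new["m.2"].n_sites == 10


def test_break_objects_passthrough_and_validation():
    objs = {"a": "ACGT" * 10_000}
    new, lineage = break_objects(objs, [])
    assert new == objs
    with pytest.raises(ValueError):
        break_objects(objs, [Breakpoint("a", "contig", 40_000)])
    with pytest.raises(KeyError):
        break_objects(objs, [Breakpoint("zzz", "contig", 10)])


def test_close_breakpoints_deduplicated():
    seq = "A" * 200_000
    bps = [
        Breakpoint("c", "contig", 100_000),
        Breakpoint("c", "contig", 105_000),  # within min_fragment_bp of the first
    ]
    new, _ = break_objects({"c": seq}, bps, ConflictParams(min_fragment_bp=20_000))
    assert sorted(new) == ["c.1", "c.2"]


def test_dominated_chance_alignments_are_filtered():
    """A weak alignment of a contig region that aligns elsewhere with a far
    higher score is a chance/repeat hit and must not seed conflicts; peer
    alignments of comparable score survive."""
    from hybridscaf.conflicts import filter_dominated_alignments

    strong = MapAlignment("ctg", "cmapA", "+", [(0, 0)], 60.0, "strict", (1_000, 50_000), (1, 2))
    peer = MapAlignment("ctg", "cmapB", "+", [(0, 0)], 55.0, "strict", (1_000, 50_000), (1, 2))
    chance = MapAlignment("ctg", "cmapC", "+", [(0, 0)], 20.0, "strict", (2_000, 18_000), (1, 2))
    elsewhere = MapAlignment("ctg2", "cmapC", "+", [(0, 0)], 20.0, "strict", (2_000, 18_000), (1, 2))
    kept = filter_dominated_alignments([strong, peer, chance, elsewhere])
    assert not any(k is chance for k in kept)
    for survivor in (strong, peer, elsewhere):
        assert any(k is survivor for k in kept)


def test_arbitration_is_order_independent():
    ref1, query, aln1 = _chimera_instance()
    ref2 = _map("cmap2", _grid(24, start=4_000))
    aln2 = _align(query, ref2)
    maps = {"cmap": ref1, "cmap2": ref2}
    conflicts = detect_conflicts([aln1, aln2], maps, {"ctg": query})
    forward = [arbitrate_conflict(c, conflicts, conflicts) for c in conflicts]
    for c in conflicts:
        c.verdict, c.evidence = "unresolved", ""
    rev = list(reversed(conflicts))
    backward = [arbitrate_conflict(c, rev, rev) for c in rev]
    assert forward == list(reversed(backward))
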