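import numpy as np
import pytest

from hybridscaf import simulate as sim
from hybridscaf.digestion import DigestionParams, digest_sequence


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


def test_genome_length_contract_and_determinism():
    g1, t1 = sim.simulate_genome(n_chrom=2, chrom_length_bp=200_000, seed=5)
    g2, _ = sim.simulate_genome(n_chrom=2, chrom_length_bp=200_000, seed=5)
    assert sorted(g1) == ["chr1", "chr2"]
    assert all(len(s) == 200_000 for s in g1.values())
    assert g1 == g2  # byte-identical per seed
    g3, _ = sim.simulate_genome(n_chrom=2, chrom_length_bp=200_000, seed=6)
    assert g1 != g3


def test_repeat_copies_are_near_identical(small_genome):
    genome, truth = small_genome
    by_family = {}
    for family, chrom, start, end in truth.repeats:
        by_family.setdefault(family, []).append(genome[chrom][start:end])
    assert by_family
    for family, copies in by_family.items():
        a, b = copies[0], copies[1]
        mismatch = sum(x != y for x, y in zip(a, b)) / len(a)
        # two copies each diverged 2% from consensus: <= ~4% apart (plus
        # planted label sites overwriting a few bases)
        assert mismatch < 0.08, family


def test_infeasible_repeat_spec_rejected():
    with pytest.raises(ValueError, match="infeasible"):
        sim.simulate_genome(
            n_chrom=1, chrom_length_bp=100_000, repeat_family_count=5,
            repeat_copy_number=10, repeat_length_bp=5_000,
        )


def test_planted_label_density(small_genome):
    genome, _ = small_genome
    m = digest_sequence(genome["chr1"])
    # ~1 site / 2 kb planted
    assert 100 < m.n_sites < 250


# ---------------------------------------------------------------------------
# contigs
# ---------------------------------------------------------------------------


def test_clean_contigs_reconstruct_chromosomes(small_genome):
    genome, gtruth = small_genome
    contigs, ct = sim.simulate_contigs(genome, gtruth, n_breaks=8, n_misjoins=0, seed=3)
    assert not ct.misjoins
    for cid, segs in ct.segments.items():
        assert len(segs) == 1
        seg = segs[0]
        assert contigs[cid] == genome[seg.chrom][seg.start : seg.end]
    # genome order: per-chromosome layout is contiguous and non-overlapping
    for chrom, layout in ct.layout.items():
        ends = [seg.end for _, seg in layout]
        starts = [seg.start for _, seg in layout]
        assert all(e <= s for e, s in zip(ends, starts[1:]))
    # every adjacency's gap is positive (dropped sequence)
    assert all(gap > 0 for *_, gap in ct.adjacencies)


def test_misjoin_junctions_inside_their_contigs(small_genome):
    genome, gtruth = small_genome
    contigs, ct = sim.simulate_contigs(genome, gtruth, n_breaks=10, n_misjoins=3,
                                       min_chimera_fragment_bp=20_000, seed=4)
    assert len(ct.misjoins) == 3
    for mj in ct.misjoins:
        assert 0 < mj.junction_bp < len(contigs[mj.contig_id])
        segs = ct.segments[mj.contig_id]
        assert len(segs) == 2
        # joined loci are unlinked
        assert segs[0].chrom != segs[1].chrom or abs(segs[0].start - segs[1].start) > 200_000


def test_every_genome_base_in_exactly_one_contig(small_genome):
    genome, gtruth = small_genome
    contigs, ct = sim.simulate_contigs(genome, gtruth, n_breaks=8, n_misjoins=2,
                                       min_chimera_fragment_bp=20_000, seed=5)
    total_contig = sum(len(s) for s in contigs.values())
    total_segments = sum(seg.length for segs in ct.segments.values() for seg in segs)
    assert total_contig == total_segments
    assert total_contig < sum(gtruth.chrom_lengths.values())  # gaps dropped


# ---------------------------------------------------------------------------
# consensus maps
# ---------------------------------------------------------------------------


def test_noiseless_maps_equal_window_digests(small_genome):
    genome, _ = small_genome
    maps, truth = sim.simulate_consensus_maps(genome, flip_prob=0.0, seed=6)
    chrom_sites = {c: np.asarray(digest_sequence(s, map_id=c).sites) for c, s in genome.items()}
    for m in maps:
        info = truth[m.map_id]
        sites = chrom_sites[info["chrom"]]
        expected = sites[(sites > info["start"]) & (sites <= info["end"])] - info["start"]
        assert m.sites == [int(s) for s in expected]


def test_map_generation_deterministic(small_genome):
    genome, _ = small_genome
    kw = dict(sizing_sd_coeff=0.5, missing_rate=0.1, false_rate=0.05, seed=8)
    m1, _ = sim.simulate_consensus_maps(genome, **kw)
    m2, _ = sim.simulate_consensus_maps(genome, **kw)
    assert [(m.map_id, m.sites) for m in m1] == [(m.map_id, m.sites) for m in m2]


def test_all_chimeric_maps_record_junctions(small_genome):
    genome, _ = small_genome
    maps, truth = sim.simulate_consensus_maps(genome, chimera_rate=0.999, seed=9)
    chimeric = [truth[m.map_id]["chimera"] for m in maps[:-1]]
    assert all(c is not None for c in chimeric)
    assert all(0 < c["junction_bp"] for c in chimeric if c)


def test_interval_noise_is_centred(small_genome):
    """Monte-Carlo recount: mean interval error ~ 0 within 3 standard errors."""
    genome, _ = small_genome
    coeff = 0.9
    maps, truth = sim.simulate_consensus_maps(
        genome, sizing_sd_coeff=coeff, flip_prob=0.0, coverage=8.0,
        fragment_mean_bp=150_000, seed=10,
    )
    chrom_sites = {c: np.asarray(digest_sequence(s, map_id=c).sites) for c, s in genome.items()}
    errors = []
    for m in maps:
        info = truth[m.map_id]
        sites = chrom_sites[info["chrom"]]
        expected = sites[(sites > info["start"]) & (sites <= info["end"])] - info["start"]
        if len(expected) != m.n_sites:
            continue
        errors.extend(np.diff(m.sites) - np.diff(expected))
    errors = np.asarray(errors, dtype=float)
    assert len(errors) > 2_000
    se = errors.std() / np.sqrt(len(errors))
    assert abs(errors.mean()) < 3 * se + 1.0  # +1 bp for integer rounding


def test_bad_rates_rejected(small_genome):
    genome, _ = small_genome
    with pytest.raises(ValueError):
        sim.simulate_consensus_maps(genome, missing_rate=1.5)


# ---------------------------------------------------------------------------
# pairs and markers
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def chimeric_assembly(small_genome):
    genome, gtruth = small_genome
    contigs, ct = sim.simulate_contigs(genome, gtruth, n_breaks=10, n_misjoins=2,
                                       min_chimera_fragment_bp=20_000, seed=11)
    return genome, gtruth, contigs, ct


def test_pairs_deterministic(chimeric_assembly):
    genome, gtruth, contigs, ct = chimeric_assembly
    p1 = sim.simulate_pairs(ct.segments, gtruth.chrom_lengths, depth=5, seed=12)
    p2 = sim.simulate_pairs(ct.segments, gtruth.chrom_lengths, depth=5, seed=12)
    assert p1.equals(p2)


def test_misjoins_accumulate_cross_contig_support(chimeric_assembly):
    genome, gtruth, contigs, ct = chimeric_assembly
    pairs = sim.simulate_pairs(ct.segments, gtruth.chrom_lengths, depth=30, seed=13)
    cross = pairs[pairs.contig_a != pairs.contig_b]
    for mj in ct.misjoins:
        near = cross[
            ((cross.contig_a == mj.contig_id) & ((cross.pos_a - mj.junction_bp).abs() < 12_000))
            | ((cross.contig_b == mj.contig_id) & ((cross.pos_b - mj.junction_bp).abs() < 12_000))
        ]
        assert len(near) >= 15  # >= depth/2 supporting pairs at 30x


def test_clean_assembly_has_no_inner_cross_pairs(small_genome):
    genome, gtruth = small_genome
    contigs, ct = sim.simulate_contigs(genome, gtruth, n_breaks=6, n_misjoins=0, seed=14)
    pairs = sim.simulate_pairs(
        ct.segments, gtruth.chrom_lengths, depth=10, noise_fraction=0.0,
        libraries=(("mp5k", 5000.0, 500.0),), seed=15,
    )
    cross = pairs[pairs.contig_a != pairs.contig_b]
    lengths = {c: len(s) for c, s in contigs.items()}
    margin = 5000 + 3 * 500 + 3000  # insert + 3 sd + dropped gap
    inner = cross[
        cross.apply(
            lambda r: margin < r.pos_a < lengths[r.contig_a] - margin
            and margin < r.pos_b < lengths[r.contig_b] - margin,
            axis=1,
        )
    ]
    assert len(inner) == 0


def test_proximity_tail_fraction(small_genome):
    """~1.3% of proximity pairs separated by > 25 kb (genomic distance)."""
    genome, gtruth = small_genome
    # whole chromosomes as objects, so object separation == genome separation
    whole = {
        f"obj_{c}": [sim.Segment(c, 0, L)] for c, L in gtruth.chrom_lengths.items()
    }
    pairs = sim.simulate_pairs(
        whole, gtruth.chrom_lengths, kind="proximity", n_pairs=40_000,
        noise_fraction=0.0, seed=16,
    )
    sep = (pairs.pos_b - pairs.pos_a).abs()
    frac = (sep > 25_000).sum() / len(pairs)
    assert 0.008 < frac < 0.020  # ~1.3% of pairs beyond 25 kb separation


def test_marker_counts_and_linkage_groups(chimeric_assembly):
    genome, gtruth, contigs, ct = chimeric_assembly
    markers = sim.simulate_markers(gtruth.chrom_lengths, ct.segments,
                                   markers_per_chrom=40, seed=17)
    assert len(markers) == 2 * 40
    chimeric = {m.contig_id for m in ct.misjoins}
    by_contig = markers.groupby("contig_id")["linkage_group"].nunique()
    for cid, n_lg in by_contig.items():
        if cid not in chimeric:
            assert n_lg == 1
    # chimeric contigs joining different chromosomes carry two linkage groups
    for mj in ct.misjoins:
        segs = ct.segments[mj.contig_id]
        if segs[0].chrom != segs[1].chrom and mj.contig_id in by_contig.index:
            counts = markers[markers.contig_id == mj.contig_id]
            if len(counts) >= 2 and counts.position_bp.min() < mj.junction_bp < counts.position_bp.max():
                assert counts.linkage_group.nunique() == 2
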