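import numpy as np
import pandas as pd
import pytest

from hybridscaf.qc import (
    LibraryModel,
    PAIR_COLUMNS,
    QcParams,
    detect_geneticmap_misassemblies,
    detect_matepair_misassemblies,
    estimate_error_rate,
    fit_library_model,
    pairs_from_sam,
    spanning_signal_breaks,
)


def _pairs(rows):
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def _pair_row(i, ca, pa, cb, pb, lib="lib1", mapq=60, ed=0):
    return [f"r{i}", ca, pa, "+", cb, pb, "-", mapq, mapq, ed, ed, lib]


# ---------------------------------------------------------------------------
# insert-size model
# ---------------------------------------------------------------------------


def test_constant_inserts_give_zero_sd():
    rows = [_pair_row(i, "c1", 1000 + i, "c1", 6000 + i) for i in range(200)]
    model = fit_library_model(_pairs(rows), "lib1")
    assert model.insert_mean_bp == pytest.approx(5000)
    assert model.insert_sd_bp == 0.0


def test_normal_inserts_recovered_within_tolerance(rng):
    """Normal(7000, 700) inserts, n=10,000: mean and sd within +/- 25."""
    inserts = rng.normal(7000, 700, size=10_000)
    rows = [_pair_row(i, "c1", 1000, "c1", 1000 + ins) for i, ins in enumerate(inserts)]
    model = fit_library_model(_pairs(rows), "lib1")
    assert model.insert_mean_bp == pytest.approx(7000, abs=25)
    assert model.insert_sd_bp == pytest.approx(700, abs=25)


def test_two_libraries_fit_independently(rng):
    rows = [_pair_row(i, "c1", 1000, "c1", 6000, "libA") for i in range(150)]
    rows += [_pair_row(1000 + i, "c1", 1000, "c1", 11_000, "libB") for i in range(150)]
    df = _pairs(rows)
    assert fit_library_model(df, "libA").insert_mean_bp == pytest.approx(5000)
    assert fit_library_model(df, "libB").insert_mean_bp == pytest.approx(10_000)


def test_too_few_pairs_is_an_error():
    rows = [_pair_row(i, "c1", 1000, "c1", 6000) for i in range(10)]
    with pytest.raises(ValueError, match="same-contig"):
        fit_library_model(_pairs(rows), "lib1")


# ---------------------------------------------------------------------------
# mate-pair cluster detection
# ---------------------------------------------------------------------------

MODEL = {"lib1": LibraryModel("lib1", 5000.0, 500.0)}
LENGTHS = {"cA": 100_000, "cB": 100_000}


def _cluster_rows(n, pa=50_000, pb=50_000, mapq=60, ed=0, jitter=100):
    return [
        _pair_row(i, "cA", pa + i * jitter, "cB", pb + i * jitter, mapq=mapq, ed=ed)
        for i in range(n)
    ]


def test_no_cross_contig_pairs_after_filters_is_empty():
    rows = _cluster_rows(20, mapq=30)  # mapq must be strictly > 30
    rows += _cluster_rows(20, ed=1)  # any mismatch disqualifies
    assert detect_matepair_misassemblies(_pairs(rows), MODEL, LENGTHS) == []


def test_cluster_of_exactly_five_is_not_reported():
    assert detect_matepair_misassemblies(_pairs(_cluster_rows(5)), MODEL, LENGTHS) == []


def test_cluster_of_six_inner_pairs_is_reported():
    regions = detect_matepair_misassemblies(_pairs(_cluster_rows(6)), MODEL, LENGTHS)
    assert len(regions) == 2  # both sides sit in their contig's inner part
    assert {r.contig_id for r in regions} == {"cA", "cB"}
    r = next(r for r in regions if r.contig_id == "cA")
    assert r.support_count == 6 and r.evidence == "matepair"
    assert r.start <= 50_000 <= r.end + 1


def test_end_anchored_clusters_are_legitimate_joins():
    """Both read clusters near contig ends: a normal spanning pair pattern."""
    rows = [_pair_row(i, "cA", 98_000 + i, "cB", 1_500 + i) for i in range(10)]
    assert detect_matepair_misassemblies(_pairs(rows), MODEL, LENGTHS) == []


def test_output_invariant_under_row_permutation(rng):
    rows = _cluster_rows(8) + [
        _pair_row(100 + i, "cA", 20_000 + i * 50, "cB", 70_000 + i * 50) for i in range(7)
    ]
    df = _pairs(rows)
    base = detect_matepair_misassemblies(df, MODEL, LENGTHS)
    shuffled = df.sample(frac=1.0, random_state=3).reset_index(drop=True)
    perm = detect_matepair_misassemblies(shuffled, MODEL, LENGTHS)
    assert [(r.contig_id, r.start, r.end, r.support_count) for r in base] == [
        (r.contig_id, r.start, r.end, r.support_count) for r in perm
    ]


def test_unknown_library_is_an_error():
    with pytest.raises(KeyError):
        detect_matepair_misassemblies(_pairs(_cluster_rows(6)), {}, LENGTHS)


def test_regions_merge_across_libraries():
    rows = _cluster_rows(6)
    rows += [
        _pair_row(50 + i, "cA", 50_200 + i * 100, "cB", 50_200 + i * 100, lib="lib2")
        for i in range(6)
    ]
    models = dict(MODEL, lib2=LibraryModel("lib2", 7000.0, 700.0))
    regions = detect_matepair_misassemblies(_pairs(rows), models, LENGTHS)
    on_a = [r for r in regions if r.contig_id == "cA"]
    assert len(on_a) == 1  # overlapping regions union-merged
    assert on_a[0].support_count == 12
    assert on_a[0].groups == ["lib1", "lib2"]


# ---------------------------------------------------------------------------
# genetic-map screening
# ---------------------------------------------------------------------------


def _markers(rows):
    return pd.DataFrame(rows, columns=["marker_id", "linkage_group", "contig_id", "position_bp"])


def test_single_linkage_group_not_flagged():
    rows = [[f"m{i}", "LG1", "c1", 10_000 * (i + 1)] for i in range(6)]
    assert detect_geneticmap_misassemblies(_markers(rows)) == []


def test_two_marker_blocks_flag_transition():
    rows = [[f"m{i}", "LG1", "c1", 10_000 * (i + 1)] for i in range(3)]
    rows += [[f"n{i}", "LG3", "c1", 60_000 + 10_000 * i] for i in range(3)]
    regions = detect_geneticmap_misassemblies(_markers(rows))
    assert len(regions) == 1
    r = regions[0]
    assert (r.start, r.end) == (30_000, 60_000)
    assert r.groups == ["LG1", "LG3"] and r.evidence == "genetic_map"


def test_single_stray_marker_not_flagged():
    rows = [[f"m{i}", "LG1", "c1", 10_000 * (i + 1)] for i in range(3)]
    rows += [["stray", "LG2", "c1", 70_000]]
    assert detect_geneticmap_misassemblies(_markers(rows)) == []


# ---------------------------------------------------------------------------
# spanning signal
# ---------------------------------------------------------------------------


def _proximity_rows(rng, length, n, forbid=None):
    rows = []
    for i in range(n):
        sep = float(rng.uniform(20_000, 60_000))
        lo = float(rng.uniform(0, length - sep))
        if forbid is not None and lo < forbid < lo + sep:
            continue
        rows.append(_pair_row(i, "scaf", int(lo), "scaf", int(lo + sep), lib="hic"))
    return rows


def test_uniform_coverage_has_no_breaks(rng):
    rows = _proximity_rows(rng, 600_000, 3_000)
    assert spanning_signal_breaks(_pairs(rows), "scaf", 600_000, 20_000, 3) == []


def test_junction_without_spanning_pairs_is_detected(rng):
    """No pair straddles 410 kb of a 600 kb scaffold -> one region there."""
    rows = _proximity_rows(rng, 600_000, 3_000, forbid=410_000)
    regions = spanning_signal_breaks(_pairs(rows), "scaf", 600_000, 20_000, 3)
    assert len(regions) == 1
    assert regions[0].start <= 410_000 <= regions[0].end


def test_zero_min_span_is_vacuous(rng):
    rows = _proximity_rows(rng, 600_000, 50, forbid=410_000)
    assert spanning_signal_breaks(_pairs(rows), "scaf", 600_000, 20_000, 0) == []


# ---------------------------------------------------------------------------
# error rate
# ---------------------------------------------------------------------------


def _coverage(rows):
    return pd.DataFrame(rows, columns=["contig", "start", "end", "mapq", "depth"])


def _variants(rows):
    return pd.DataFrame(rows, columns=["contig", "pos", "kind", "zygosity"])


def test_zero_variants_give_zero_rate():
    cov = _coverage([["c1", 1, 1_000_000, 60, 30]])
    assert estimate_error_rate(_variants([]), cov) == 0.0


def test_error_rate_arithmetic():
    """3 homozygous SNPs + 2 homozygous indels over 100 kb -> 5e-5."""
    cov = _coverage([["c1", 1, 100_000, 60, 30]])
    var = _variants(
        [["c1", p, "snp", "hom"] for p in (10, 20, 30)]
        + [["c1", p, "indel", "hom"] for p in (40, 50)]
    )
    assert estimate_error_rate(var, cov) == pytest.approx(5e-5)


def test_heterozygous_variants_excluded():
    cov = _coverage([["c1", 1, 100_000, 60, 30]])
    var = _variants([["c1", p, "snp", "het"] for p in (10, 20)])
    assert estimate_error_rate(var, cov) == 0.0


def test_low_mapq_or_coverage_regions_ineligible():
    cov = _coverage([["c1", 1, 50_000, 25, 30], ["c1", 50_001, 100_000, 60, 5]])
    with pytest.raises(ValueError, match="empty eligible"):
        estimate_error_rate(_variants([]), cov)


def test_error_rate_is_scale_invariant():
    cov1 = _coverage([["c1", 1, 100_000, 60, 30]])
    var1 = _variants([["c1", 10, "snp", "hom"]])
    cov2 = _coverage([["c1", 1, 100_000, 60, 30], ["c2", 1, 100_000, 60, 30]])
    var2 = _variants([["c1", 10, "snp", "hom"], ["c2", 10, "snp", "hom"]])
    assert estimate_error_rate(var1, cov1) == estimate_error_rate(var2, cov2)


# ---------------------------------------------------------------------------
# SAM adapter
# ---------------------------------------------------------------------------


def test_pairs_from_sam_round_trip(tmp_path):
    sam = tmp_path / "pairs.sam"
    sam.write_text(
        "@HD\tVN:1.6\tSO:unsorted\n"
        "@SQ\tSN:cA\tLN:100000\n"
        "@SQ\tSN:cB\tLN:100000\n"
        "r1\t0\tcA\t5000\t60\t50M\t*\t0\t0\t" + "A" * 50 + "\t*\tNM:i:0\n"
        "r1\t16\tcB\t7000\t55\t50M\t*\t0\t0\t" + "A" * 50 + "\t*\tNM:i:2\n"
    )
    df = pairs_from_sam(sam, "libX")
    assert len(df) == 1
    row = df.iloc[0]
    assert (row.contig_a, row.pos_a, row.mapq_a, row.edit_distance_a) == ("cA", 5000, 60, 0)
    assert (row.contig_b, row.pos_b, row.mapq_b, row.edit_distance_b) == ("cB", 7000, 55, 2)
    assert row.library_id == "libX"
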