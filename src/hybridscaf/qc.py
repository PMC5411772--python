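"""Independent misassembly evidence and nucleotide error-rate estimation.

Four evidence channels flag suspicious regions of an assembly:

* **mate pairs** — clusters of large-insert read pairs whose two reads land on
  two different contigs, with at least one read cluster deep inside a contig
  where a legitimate pair could not cross a contig boundary;
* **genetic map** — contigs carrying markers from two different linkage
  groups (inter-chromosomal misjoins);
* **spanning signal** — windows of a proximity-ligation library with a sudden
  absence of read pairs spanning across them;
* **map conflicts** — produced by the conflict-resolution stage and carried
  in the same MisassemblyRegion currency.

The per-base error rate divides homozygous SNP + indel counts by the total
length of well-covered, confidently mapped sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "PAIR_COLUMNS",
    "LibraryModel",
    "MisassemblyRegion",
    "QcParams",
    "fit_library_model",
    "detect_matepair_misassemblies",
    "detect_geneticmap_misassemblies",
    "spanning_signal_breaks",
    "estimate_error_rate",
    "pairs_from_sam",
]

#: columns of the tabular pair format (one row per read pair)
PAIR_COLUMNS = [
    "read_id",
    "contig_a", "pos_a", "strand_a",
    "contig_b", "pos_b", "strand_b",
    "mapq_a", "mapq_b",
    "edit_distance_a", "edit_distance_b",
    "library_id",
]

MARKER_COLUMNS = ["marker_id", "linkage_group", "contig_id", "position_bp"]


@dataclass
class LibraryModel:
    library_id: str
    insert_mean_bp: float
    insert_sd_bp: float

    def __post_init__(self) -> None:
        if self.insert_mean_bp <= 0 or self.insert_sd_bp < 0:
            raise ValueError("insert mean must be > 0 and sd >= 0")


@dataclass
class MisassemblyRegion:
    contig_id: str
    start: int
    end: int
    evidence: str  # matepair | genetic_map | map_conflict | spanning_signal
    support_count: int = 1
    groups: list[str] = field(default_factory=list)  # libraries / linkage groups

    def __post_init__(self) -> None:
        if self.support_count < 1:
            raise ValueError("support_count must be >= 1")

    def overlaps(self, other: "MisassemblyRegion") -> bool:
        return self.contig_id == other.contig_id and not (
            self.end < other.start or other.end < self.start
        )


@dataclass
class QcParams:
    min_mapq: int = 30            # strictly greater than this is kept
    max_edit_distance: int = 0    # "without any mismatches or indels"
    min_cluster_pairs: int = 6    # "more than five read pairs", read strictly
    cluster_sd_mult: float = 3.0  # reads co-cluster within this many insert sds
    min_markers_per_group: int = 2
    trim_fraction: float = 0.01   # total mass trimmed from the insert tails


def fit_library_model(
    pairs: pd.DataFrame, library_id: str, trim_fraction: float = 0.01, min_pairs: int = 100
) -> LibraryModel:
    """Insert-size distribution of one library from same-contig pairs.

    The insert is the separation of the two read positions.  The extreme
    tails (``trim_fraction`` total mass, split symmetrically) are trimmed
    before taking mean and sd; the sd is then rescaled by the truncated-
    normal consistency factor so it is unbiased for Gaussian inserts while
    staying robust to gross outliers.  Deterministic.
    """
    same = pairs[
        (pairs["library_id"] == library_id) & (pairs["contig_a"] == pairs["contig_b"])
    ]
    inserts = (same["pos_b"] - same["pos_a"]).abs().to_numpy(dtype=float)
    if len(inserts) < min_pairs:
        raise ValueError(
            f"library {library_id}: only {len(inserts)} same-contig pairs (< {min_pairs})"
        )
    alpha = trim_fraction / 2.0
    lo, hi = np.quantile(inserts, [alpha, 1 - alpha])
    kept = inserts[(inserts >= lo) & (inserts <= hi)]
    mean = float(kept.mean())
    sd = float(kept.std(ddof=1))
    if sd > 0 and alpha > 0:
        c = norm.ppf(1 - alpha)
        shrink = 1.0 - 2.0 * c * norm.pdf(c) / (2.0 * norm.cdf(c) - 1.0)
        sd /= float(np.sqrt(shrink))
    return LibraryModel(library_id, mean, sd)


def _single_linkage_2d(pos_a: np.ndarray, pos_b: np.ndarray, radius: float) -> list[np.ndarray]:
    """Single-linkage clusters: records link when close on BOTH sides."""
    n = len(pos_a)
    parent = np.arange(n)

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    order = np.argsort(pos_a, kind="stable")
    pa, pb = pos_a[order], pos_b[order]
    for i in range(n):
        for j in range(i + 1, n):
            if pa[j] - pa[i] >= radius:
                break
            if abs(pb[j] - pb[i]) < radius:
                ri, rj = find(order[i]), find(order[j])
                if ri != rj:
                    parent[ri] = rj
    roots = np.array([find(i) for i in range(n)])
    return [np.nonzero(roots == r)[0] for r in np.unique(roots)]


def _merge_regions(regions: list[MisassemblyRegion]) -> list[MisassemblyRegion]:
    """Union-merge overlapping regions on the same contig."""
    out: list[MisassemblyRegion] = []
    for reg in sorted(regions, key=lambda r: (r.contig_id, r.start, r.end)):
        if out and out[-1].overlaps(reg):
            last = out[-1]
            last.end = max(last.end, reg.end)
            last.support_count += reg.support_count
            last.groups = sorted(set(last.groups) | set(reg.groups))
        else:
            out.append(reg)
    return out


def detect_matepair_misassemblies(
    pairs: pd.DataFrame,
    models: dict[str, LibraryModel],
    contig_lengths: dict[str, int],
    params: QcParams = QcParams(),
) -> list[MisassemblyRegion]:
    """Cross-contig mate-pair clusters flagging misassembled regions.

    Pipeline: keep confidently, perfectly aligned records (mapq strictly
    above ``min_mapq`` on both reads, zero edit distance); group cross-contig
    pairs by unordered contig pair; single-linkage cluster within a group at
    ``cluster_sd_mult`` insert sds per side; keep clusters with strictly more
    than five pairs; require at least one side's read cluster to sit in the
    *inner part* of its contig (farther than mean + 3 sd from both ends);
    emit that side's interval; finally union-merge regions across libraries.
    """
    missing = set(pairs["library_id"].unique()) - set(models)
    if missing:
        raise KeyError(f"no insert model for libraries: {sorted(missing)}")
    regions: list[MisassemblyRegion] = []
    clean = pairs[
        (pairs["mapq_a"] > params.min_mapq)
        & (pairs["mapq_b"] > params.min_mapq)
        & (pairs["edit_distance_a"] <= params.max_edit_distance)
        & (pairs["edit_distance_b"] <= params.max_edit_distance)
        & (pairs["contig_a"] != pairs["contig_b"])
    ]
    for lib_id, lib_pairs in clean.groupby("library_id", sort=True):
        model = models[lib_id]
        radius = params.cluster_sd_mult * model.insert_sd_bp
        inner_margin = model.insert_mean_bp + 3.0 * model.insert_sd_bp
        # canonical unordered contig pair: a <= b lexicographically
        swap = lib_pairs["contig_a"] > lib_pairs["contig_b"]
        ca = lib_pairs["contig_a"].where(~swap, lib_pairs["contig_b"])
        cb = lib_pairs["contig_b"].where(~swap, lib_pairs["contig_a"])
        pa = lib_pairs["pos_a"].where(~swap, lib_pairs["pos_b"])
        pb = lib_pairs["pos_b"].where(~swap, lib_pairs["pos_a"])
        df = pd.DataFrame({"ca": ca, "cb": cb, "pa": pa, "pb": pb})
        for (contig_a, contig_b), group in df.groupby(["ca", "cb"], sort=True):
            pos_a = group["pa"].to_numpy(dtype=float)
            pos_b = group["pb"].to_numpy(dtype=float)
            for idx in _single_linkage_2d(pos_a, pos_b, radius):
                if len(idx) < params.min_cluster_pairs:
                    continue
                sides = [
                    (contig_a, pos_a[idx]),
                    (contig_b, pos_b[idx]),
                ]
                inner = []
                for contig, positions in sides:
                    lo, hi = positions.min(), positions.max()
                    length = contig_lengths[contig]
                    if lo > inner_margin and hi < length - inner_margin:
                        inner.append((contig, int(lo), int(hi)))
                if not inner:
                    continue
                for contig, lo, hi in inner:
                    regions.append(
                        MisassemblyRegion(
                            contig, lo, hi, "matepair",
                            support_count=len(idx), groups=[str(lib_id)],
                        )
                    )
    return _merge_regions(regions)


def detect_geneticmap_misassemblies(
    markers: pd.DataFrame, params: QcParams = QcParams()
) -> list[MisassemblyRegion]:
    """Contigs carrying markers of two or more linkage groups.

    A contig is flagged when at least ``min_markers_per_group`` markers from
    each of two or more linkage groups map to it; the emitted interval spans
    the transition between consecutive markers of different (qualifying)
    linkage groups.
    """
    regions: list[MisassemblyRegion] = []
    for contig_id, group in markers.groupby("contig_id", sort=True):
        counts = group["linkage_group"].value_counts()
        qualifying = set(counts[counts >= params.min_markers_per_group].index)
        if len(qualifying) < 2:
            continue
        block = group[group["linkage_group"].isin(qualifying)].sort_values("position_bp")
        lgs = block["linkage_group"].to_numpy()
        pos = block["position_bp"].to_numpy()
        for k in range(1, len(block)):
            if lgs[k] != lgs[k - 1]:
                regions.append(
                    MisassemblyRegion(
                        str(contig_id), int(pos[k - 1]), int(pos[k]), "genetic_map",
                        support_count=int(counts[lgs[k - 1]] + counts[lgs[k]]),
                        groups=sorted({str(lgs[k - 1]), str(lgs[k])}),
                    )
                )
    return _merge_regions(regions)


def spanning_signal_breaks(
    pairs: pd.DataFrame,
    scaffold_id: str,
    scaffold_length: int,
    window_bp: int = 20_000,
    min_span: int = 3,
    step_bp: int | None = None,
) -> list[MisassemblyRegion]:
    """Windows with a sudden absence of long-range spanning pairs.

    For each window midpoint, counts same-scaffold proximity-ligation pairs
    whose reads straddle the midpoint with separation at least ``window_bp``.
    Midpoints closer than ``window_bp`` to either scaffold end are excluded
    (spanning there is impossible).  Runs of windows with fewer than
    ``min_span`` spanning pairs merge into candidate misassembly regions.
    """
    if min_span <= 0:
        return []
    step = step_bp or max(window_bp // 2, 1)
    same = pairs[(pairs["contig_a"] == scaffold_id) & (pairs["contig_b"] == scaffold_id)]
    lo = np.minimum(same["pos_a"].to_numpy(), same["pos_b"].to_numpy())
    hi = np.maximum(same["pos_a"].to_numpy(), same["pos_b"].to_numpy())
    keep = (hi - lo) >= window_bp
    lo, hi = np.sort(lo[keep]), np.sort(hi[keep])
    mids = np.arange(window_bp, scaffold_length - window_bp + 1, step)
    if len(mids) == 0:
        return []
    counts = np.searchsorted(lo, mids, side="right") - np.searchsorted(hi, mids, side="left")
    regions: list[MisassemblyRegion] = []
    run_start = None
    for m, c in zip(mids, counts):
        if c < min_span:
            if run_start is None:
                run_start = m
            run_end = m
        elif run_start is not None:
            regions.append(
                MisassemblyRegion(
                    scaffold_id,
                    int(run_start - step // 2),
                    int(run_end + step // 2),
                    "spanning_signal",
                )
            )
            run_start = None
    if run_start is not None:
        regions.append(
            MisassemblyRegion(
                scaffold_id, int(run_start - step // 2), int(run_end + step // 2),
                "spanning_signal",
            )
        )
    return regions


def estimate_error_rate(variant_table: pd.DataFrame, coverage_mask: pd.DataFrame) -> float:
    """Homozygous SNP+indel events per eligible base.

    ``variant_table`` columns: contig, pos, kind (snp|indel), zygosity
    (hom|het).  ``coverage_mask`` columns: contig, start, end (1-based
    inclusive), mapq, depth; only intervals with mapq strictly above 25 and
    depth strictly above 5 are eligible.  Returns numerator/denominator;
    raises on an empty eligible region.
    """
    eligible = coverage_mask[(coverage_mask["mapq"] > 25) & (coverage_mask["depth"] > 5)]
    denominator = 0
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for contig, group in eligible.groupby("contig", sort=True):
        ivs = sorted(zip(group["start"], group["end"]))
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        by_contig[contig] = [(s, e) for s, e in merged]
        denominator += sum(e - s + 1 for s, e in merged)
    if denominator == 0:
        raise ValueError("empty eligible region")
    hom = variant_table[variant_table["zygosity"] == "hom"]
    numerator = 0
    for contig, group in hom.groupby("contig", sort=True):
        ivs = by_contig.get(contig, [])
        if not ivs:
            continue
        starts = np.array([s for s, _ in ivs])
        ends = np.array([e for _, e in ivs])
        pos = group["pos"].to_numpy()
        k = np.searchsorted(starts, pos, side="right") - 1
        ok = (k >= 0) & (pos <= ends[np.clip(k, 0, None)])
        numerator += int(ok.sum())
    return numerator / denominator


def pairs_from_sam(path, library_id: str) -> pd.DataFrame:
    """Convert name-paired SAM alignments to the tabular pair format.

    Primary alignments only; the edit distance is taken from the NM tag.
    """
    import pysam

    ends: dict[str, list] = {}
    rows = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            entry = [
                rec.reference_name,
                rec.reference_start + 1,
                "-" if rec.is_reverse else "+",
                rec.mapping_quality,
                int(nm),
            ]
            if rec.query_name in ends:
                other = ends.pop(rec.query_name)
                rows.append(
                    [rec.query_name, *other[:3], *entry[:3], other[3], entry[3],
                     other[4], entry[4], library_id]
                )
            else:
                ends[rec.query_name] = entry
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)
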