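"""Synthetic genomes, assemblies, maps, read pairs and markers with truth.

Every pipeline stage is testable without downloads: this module fabricates a
repeat-bearing multi-chromosome genome, cuts it into contigs (optionally
planting chimeric misjoins that splice unlinked loci, the signature artifact
of repeat-confused long-read assembly), simulates optical consensus maps
with the platform's error modes (sizing noise growing as sqrt(interval),
missing and false labels, chimeric joins, arbitrary orientation), draws
mate-pair and proximity-ligation read pairs on the *true* genome and reports
them in contig coordinates (so planted misjoins produce exactly the
cross-contig patterns the QC stage looks for), and places genetic markers
whose linkage group is their chromosome of origin.

All generators are pure functions of their parameters and seed.  Ground
truth (fragment layout, misjoin junctions, true adjacencies and gaps, map
loci) is returned alongside every artifact, and evaluation helpers score a
pipeline result against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .digestion import BSPQI_MOTIF, DigestionParams, RestrictionMap, digest_sequence, reverse_complement
from .qc import PAIR_COLUMNS, MARKER_COLUMNS

__all__ = [
    "GenomeTruth",
    "ContigTruth",
    "Segment",
    "simulate_genome",
    "simulate_contigs",
    "simulate_consensus_maps",
    "simulate_pairs",
    "simulate_markers",
    "evaluate_misjoin_repair",
    "adjacency_recovery",
    "fragment_genome_segments",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class Segment:
    """A contig (or fragment) interval on the true genome, 0-based half-open."""

    chrom: str
    start: int
    end: int
    orient: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeTruth:
    chrom_lengths: dict[str, int]
    repeats: list[tuple[str, str, int, int]] = field(default_factory=list)  # family, chrom, start, end


@dataclass
class Misjoin:
    contig_id: str
    junction_bp: int  # 0-based offset of the junction within the contig
    left: Segment = None
    right: Segment = None


@dataclass
class ContigTruth:
    #: contig -> ordered genome segments (chimeric contigs have two)
    segments: dict[str, list[Segment]]
    misjoins: list[Misjoin]
    #: per-chromosome ordered (contig_id, Segment) in genome order
    layout: dict[str, list[tuple[str, Segment]]]
    #: true adjacencies: (left contig, right contig, chrom, left genome end,
    #: right genome start, gap_bp)
    adjacencies: list[tuple[str, str, str, int, int, int]]


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p)


def _mutate(rng: np.random.Generator, arr: np.ndarray, rate: float) -> np.ndarray:
    out = arr.copy()
    k = rng.binomial(len(arr), rate)
    if k:
        idx = rng.choice(len(arr), size=k, replace=False)
        out[idx] = rng.choice(_BASES, size=k)
    return out


def simulate_genome(
    n_chrom: int = 2,
    chrom_length_bp: int = 1_000_000,
    repeat_family_count: int = 2,
    repeat_copy_number: int = 6,
    repeat_length_bp: int = 5_000,
    repeat_divergence: float = 0.02,
    tandem_array_spec: list[dict] | None = None,
    gc: float = 0.36,
    site_spacing_bp: int = 2_000,
    seed: int = 0,
) -> tuple[dict[str, str], GenomeTruth]:
    """Random genome with interspersed repeats, tandem arrays and nick labels.

    Chromosomes are i.i.d. background sequence at the given GC content with
    ``repeat_copy_number`` near-identical copies (divergence per-base
    substitutions) of each of ``repeat_family_count`` repeat families, plus
    optional tandem arrays (spec entries: monomer_bp, copies, arrays).  With
    ``site_spacing_bp > 0`` the nicking motif is additionally planted at that
    jittered spacing so desk-scale fragments carry enough labels to be
    alignable; set 0 for raw-sequence motif density.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    total_repeat = repeat_family_count * repeat_copy_number * repeat_length_bp
    if tandem_array_spec:
        total_repeat += sum(s["monomer_bp"] * s["copies"] * s.get("arrays", 1) for s in tandem_array_spec)
    if total_repeat > 0.5 * n_chrom * chrom_length_bp:
        raise ValueError("repeat content exceeds half the genome; infeasible spec")

    chroms = {f"chr{i + 1}": _random_seq(rng, chrom_length_bp, gc) for i in range(n_chrom)}
    names = list(chroms)
    truth = GenomeTruth(chrom_lengths={c: chrom_length_bp for c in names})

    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in names}

    def _place(block: np.ndarray, family: str) -> None:
        for _ in range(200):
            chrom = names[rng.integers(len(names))]
            start = int(rng.integers(0, chrom_length_bp - len(block)))
            end = start + len(block)
            if all(end <= s or start >= e for s, e in occupied[chrom]):
                chroms[chrom][start:end] = block
                occupied[chrom].append((start, end))
                truth.repeats.append((family, chrom, start, end))
                return
        raise ValueError("could not place repeat copy; genome too crowded")

    for fam in range(repeat_family_count):
        consensus = _random_seq(rng, repeat_length_bp, gc)
        for _ in range(repeat_copy_number):
            _place(_mutate(rng, consensus, repeat_divergence), f"family_{fam}")
    for t, spec in enumerate(tandem_array_spec or []):
        monomer = _random_seq(rng, spec["monomer_bp"], gc)
        array = np.tile(monomer, spec["copies"])
        for _ in range(spec.get("arrays", 1)):
            _place(array.copy(), f"tandem_{t}")

    if site_spacing_bp > 0:
        motif_f = np.frombuffer(BSPQI_MOTIF.encode(), dtype="S1")
        motif_r = np.frombuffer(reverse_complement(BSPQI_MOTIF).encode(), dtype="S1")
        for chrom in names:
            pos = 0
            while True:
                # genomic nick sites are approximately a Poisson process;
                # exponential spacings keep interval patterns distinctive
                # (regular spacing would make unrelated loci look alike).
                # A floor keeps neighbouring labels resolvable.
                pos += max(int(rng.exponential(site_spacing_bp)), 600)
                if pos + 7 >= chrom_length_bp:
                    break
                chroms[chrom][pos : pos + 7] = motif_f if rng.random() < 0.5 else motif_r

    seqs = {c: arr.tobytes().decode() for c, arr in chroms.items()}
    return seqs, truth


def _jittered_breaks(rng, length: int, n: int, min_fragment: int) -> list[int]:
    """n internal cut positions, roughly evenly spaced with jitter."""
    if n <= 0:
        return []
    spacing = length / (n + 1)
    jitter = min(0.3 * spacing, max(0.0, (spacing - min_fragment) / 2))
    return sorted(
        int((k + 1) * spacing + rng.uniform(-jitter, jitter)) for k in range(n)
    )


def simulate_contigs(
    genome: dict[str, str],
    truth: GenomeTruth,
    n_breaks: int = 40,
    n_misjoins: int = 0,
    misjoin_at_repeats: bool = False,
    dropped_gap_mean_bp: int = 3_000,
    min_chimera_fragment_bp: int = 30_000,
    seed: int = 0,
) -> tuple[dict[str, str], ContigTruth]:
    """Cut the genome into contigs; optionally splice chimeric misjoins.

    The genome is cut at ``n_breaks`` jittered positions (distributed over
    chromosomes by length); at each junction a short unassembled stretch of
    mean ``dropped_gap_mean_bp`` is discarded, so true inter-contig gaps are
    positive and recorded.  ``n_misjoins`` chimeric contigs are then formed
    by joining pairs of fragments from unlinked loci (different chromosomes,
    or loci > 200 kb apart); with ``misjoin_at_repeats`` the joined fragment
    ends are preferentially those abutting a planted repeat copy.  The truth
    table records every fragment's genome interval, every junction, and the
    fragment-level adjacency list with true gaps.
    """
    rng = np.random.default_rng(seed)
    total = sum(truth.chrom_lengths.values())
    fragments: list[tuple[str, Segment]] = []  # (fragment key, segment)
    layout: dict[str, list[tuple[str, Segment]]] = {}
    adjacencies: list[tuple[str, str, str, int, int, int]] = []

    frag_counter = 0
    per_chrom_frags: dict[str, list[str]] = {}
    frag_segment: dict[str, Segment] = {}
    for chrom, seq in genome.items():
        length = truth.chrom_lengths[chrom]
        n_c = max(1, round(n_breaks * length / total))
        cuts = _jittered_breaks(rng, length, n_c, min_chimera_fragment_bp)
        bounds = [0] + cuts + [length]
        chrom_frags = []
        prev_end = 0
        for lo, hi in zip(bounds, bounds[1:]):
            # dropped stretches stay below typical mate-pair inserts so that
            # jumping libraries can span assembly gaps
            gap = (
                int(min(rng.exponential(dropped_gap_mean_bp) + 200, (hi - lo) / 3,
                        2 * dropped_gap_mean_bp))
                if lo > 0
                else 0
            )
            start = lo + gap
            frag_id = f"frag_{frag_counter:04d}"
            frag_counter += 1
            seg = Segment(chrom, start, hi)
            frag_segment[frag_id] = seg
            chrom_frags.append(frag_id)
        per_chrom_frags[chrom] = chrom_frags

    # choose chimera partners among sufficiently long, unlinked fragments
    all_frags = sorted(frag_segment)
    big = [f for f in all_frags if frag_segment[f].length >= min_chimera_fragment_bp]
    if misjoin_at_repeats:
        repeat_hits = set()
        for _, chrom, rs, re_ in truth.repeats:
            for f in big:
                seg = frag_segment[f]
                if seg.chrom == chrom and not (re_ <= seg.start or rs >= seg.end):
                    repeat_hits.add(f)
        cand = sorted(repeat_hits)
    else:
        cand = big
    rng.shuffle(cand := list(cand))

    def _compatible(a: str, b: str) -> bool:
        sa, sb = frag_segment[a], frag_segment[b]
        unlinked = sa.chrom != sb.chrom or abs(sa.start - sb.start) > 200_000
        # both junction-adjacent loci must continue somewhere in the genome,
        # else the misjoin leaves no mate-pair signal
        interior = sa.end < truth.chrom_lengths[sa.chrom] and sb.start > 0
        return unlinked and interior

    chimera_pairs: list[tuple[str, str]] = []
    used: set[str] = set()
    for a in cand:
        if len(chimera_pairs) >= n_misjoins or a in used:
            continue
        for b in cand:
            if b is a or b in used:
                continue
            if _compatible(a, b):
                chimera_pairs.append((a, b))
                used.update((a, b))
                break
            if _compatible(b, a):
                chimera_pairs.append((b, a))
                used.update((a, b))
                break
    if len(chimera_pairs) < n_misjoins:
        raise ValueError(
            f"only {len(chimera_pairs)} unlinked fragment pairs available for {n_misjoins} misjoins"
        )

    contigs: dict[str, str] = {}
    segments: dict[str, list[Segment]] = {}
    misjoins: list[Misjoin] = []
    frag_to_contig: dict[str, str] = {}
    counter = 0

    def _next_id() -> str:
        nonlocal counter
        counter += 1
        return f"ctg{counter:04d}"

    for a, b in chimera_pairs:
        cid = _next_id()
        sa, sb = frag_segment[a], frag_segment[b]
        seq = genome[sa.chrom][sa.start : sa.end] + genome[sb.chrom][sb.start : sb.end]
        contigs[cid] = seq
        segments[cid] = [sa, sb]
        misjoins.append(Misjoin(cid, sa.length, sa, sb))
        frag_to_contig[a] = cid
        frag_to_contig[b] = cid

    for f in all_frags:
        if f in frag_to_contig:
            continue
        cid = _next_id()
        seg = frag_segment[f]
        contigs[cid] = genome[seg.chrom][seg.start : seg.end]
        segments[cid] = [seg]
        frag_to_contig[f] = cid

    for chrom, frags in per_chrom_frags.items():
        layout[chrom] = [(frag_to_contig[f], frag_segment[f]) for f in frags]
        for fa, fb in zip(frags, frags[1:]):
            sa, sb = frag_segment[fa], frag_segment[fb]
            adjacencies.append(
                (frag_to_contig[fa], frag_to_contig[fb], chrom, sa.end, sb.start, sb.start - sa.end)
            )

    return contigs, ContigTruth(
        segments=segments, misjoins=misjoins, layout=layout, adjacencies=adjacencies
    )


def simulate_consensus_maps(
    genome: dict[str, str],
    digestion_params: DigestionParams = DigestionParams(),
    fragment_mean_bp: int = 350_000,
    coverage: float = 3.0,
    sizing_sd_coeff: float = 0.0,
    missing_rate: float = 0.0,
    false_rate: float = 0.0,
    chimera_rate: float = 0.0,
    flip_prob: float = 0.5,
    seed: int = 0,
) -> tuple[list[RestrictionMap], dict[str, dict]]:
    """Optical consensus maps as noisy digests of tiled genomic windows.

    Windows of mean length ``fragment_mean_bp`` tile each chromosome with a
    step of ``fragment_mean_bp / coverage``.  Real consensus maps overlap
    heavily; the default 3x tiling keeps every locus on several maps (with
    margin past window edges), which downstream arbitration relies on.  Each inter-label
    interval is perturbed by Gaussian noise with sd ``coeff*sqrt(interval)``;
    labels are dropped at ``missing_rate``; false labels arrive as a Poisson
    process at ``false_rate`` per true label; with probability
    ``chimera_rate`` a map is a splice of two unlinked half-windows; maps are
    mirrored with probability ``flip_prob`` (consensus maps have no intrinsic
    orientation).  Truth records each map's locus and error realization.
    """
    for rate in (missing_rate, false_rate, chimera_rate):
        if not (0 <= rate < 1):
            raise ValueError("rates must be in [0, 1)")
    rng = np.random.default_rng(seed)
    chrom_sites = {
        c: np.asarray(digest_sequence(seq, digestion_params, c).sites) for c, seq in genome.items()
    }
    windows: list[tuple[str, int, int]] = []
    step = max(int(fragment_mean_bp / max(coverage, 0.1)), 10_000)
    for chrom, seq in genome.items():
        length = len(seq)
        start = 0
        while start < length - step // 2:
            wlen = int(fragment_mean_bp * rng.uniform(0.85, 1.15))
            windows.append((chrom, start, min(start + wlen, length)))
            start += int(step * rng.uniform(0.9, 1.1))

    def _window_map(chrom: str, lo: int, hi: int):
        sites = chrom_sites[chrom]
        rel = sites[(sites > lo) & (sites <= hi)] - lo
        if len(rel) == 0:
            return np.array([], dtype=int), hi - lo
        deltas = np.diff(np.concatenate([[0], rel])).astype(float)
        if sizing_sd_coeff > 0:
            deltas = deltas + rng.normal(0, sizing_sd_coeff * np.sqrt(deltas))
            deltas = np.maximum(deltas, 1.0)
        noisy = np.cumsum(deltas)
        length = int(max(noisy[-1] + (hi - lo - rel[-1]), noisy[-1] + 1))
        if missing_rate > 0:
            keep = rng.random(len(noisy)) >= missing_rate
            noisy = noisy[keep]
        if false_rate > 0 and len(noisy):
            n_false = rng.poisson(false_rate * len(noisy))
            if n_false:
                noisy = np.concatenate([noisy, rng.uniform(1, length, n_false)])
        sites_out = np.unique(np.round(noisy).astype(int))
        sites_out = sites_out[(sites_out >= 1) & (sites_out <= length)]
        return sites_out, length

    maps: list[RestrictionMap] = []
    truth: dict[str, dict] = {}
    i = 0
    w = 0
    while w < len(windows):
        chrom, lo, hi = windows[w]
        w += 1
        i += 1
        map_id = f"cmap_{i:04d}"
        info: dict = {"chrom": chrom, "start": lo, "end": hi, "flipped": False, "chimera": None}
        sites, length = _window_map(chrom, lo, hi)
        if chimera_rate > 0 and rng.random() < chimera_rate and w < len(windows):
            chrom2, lo2, hi2 = windows[w]
            w += 1
            mid1 = (lo + hi) // 2
            mid2 = (lo2 + hi2) // 2
            s1, l1 = _window_map(chrom, lo, mid1)
            s2, l2 = _window_map(chrom2, mid2, hi2)
            sites = np.concatenate([s1, s2 + l1])
            length = l1 + l2
            info.update(
                chimera={"junction_bp": l1, "left": (chrom, lo, mid1), "right": (chrom2, mid2, hi2)},
                end=mid1,
            )
        rmap = RestrictionMap(map_id, int(length), [int(s) for s in sites], source="consensus")
        if rng.random() < flip_prob:
            rmap = rmap.reversed()
            rmap.map_id = map_id
            info["flipped"] = True
        maps.append(rmap)
        truth[map_id] = info
    return maps, truth


# ---------------------------------------------------------------------------
# read pairs and markers
# ---------------------------------------------------------------------------


@dataclass
class ProximityParams:
    """Separation model for proximity-ligation pairs.

    A short-insert bulk (Normal) plus a long-range fraction following a
    power-law decay with exponent -1 truncated at ``max_sep_bp``; the default
    long fraction of 2.5% over [1 kb, 1 Mb] puts ~1.3% of all pairs beyond
    25 kb separation.
    """

    short_mean_bp: float = 500.0
    short_sd_bp: float = 150.0
    long_fraction: float = 0.025
    min_long_sep_bp: float = 1_000.0
    max_sep_bp: float = 1_000_000.0


DEFAULT_LIBRARIES = (("mp5k", 5000.0, 500.0), ("mp7k", 7000.0, 700.0), ("mp10k", 10000.0, 1000.0))


class _GenomeIndex:
    """Lift true-genome coordinates onto contig/scaffold coordinates."""

    def __init__(self, segments: dict[str, list[Segment]]):
        self.by_chrom: dict[str, list[tuple[int, int, str, int, str]]] = {}
        for obj_id, segs in segments.items():
            offset = 0
            for seg in segs:
                self.by_chrom.setdefault(seg.chrom, []).append(
                    (seg.start, seg.end, obj_id, offset, seg.orient)
                )
                offset += seg.length
        self.starts = {}
        for chrom in self.by_chrom:
            self.by_chrom[chrom].sort()
            self.starts[chrom] = np.array([s for s, *_ in self.by_chrom[chrom]])

    def lift(self, chrom: str, gpos: int):
        """(object_id, 1-based position) or None if in a dropped gap."""
        entries = self.by_chrom.get(chrom)
        if not entries:
            return None
        k = int(np.searchsorted(self.starts[chrom], gpos, side="right")) - 1
        if k < 0:
            return None
        start, end, obj_id, offset, orient = entries[k]
        if gpos >= end:
            return None
        rel = gpos - start
        if orient == "-":
            rel = (end - start - 1) - rel
        return obj_id, offset + rel + 1


def simulate_pairs(
    segments: dict[str, list[Segment]],
    genome_lengths: dict[str, int],
    kind: str = "matepair",
    libraries: tuple = DEFAULT_LIBRARIES,
    depth: float = 30.0,
    noise_fraction: float = 0.05,
    proximity: ProximityParams = ProximityParams(),
    n_pairs: int | None = None,
    library_id: str = "hic",
    seed: int = 0,
) -> pd.DataFrame:
    """Read pairs drawn on the true genome, reported in object coordinates.

    ``matepair``: inserts are Normal per library; ``depth`` is the physical
    (insert) coverage of EACH library, so misjoin-free objects show
    cross-object pairs only at their boundaries while planted misjoins
    accumulate inner-locus cross-object clusters.  ``proximity``: separations
    follow :class:`ProximityParams`.  A ``noise_fraction`` of records gets a
    low mapping quality or a positive edit distance to exercise QC filters.
    Pairs with a read in a dropped (unassembled) region are not reported.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng(seed)
    index = _GenomeIndex(segments)
    chroms = sorted(genome_lengths)
    lens = np.array([genome_lengths[c] for c in chroms], dtype=float)
    probs = lens / lens.sum()
    total = lens.sum()
    rows: list[list] = []
    rid = 0

    def _emit(chrom, g_left, g_right, lib):
        nonlocal rid
        a = index.lift(chrom, int(g_left))
        b = index.lift(chrom, int(g_right))
        if a is None or b is None:
            return
        mapq_a = mapq_b = 60
        ed_a = ed_b = 0
        if noise_fraction > 0 and rng.random() < noise_fraction:
            if rng.random() < 0.5:
                mapq_a = int(rng.integers(0, 31))
            else:
                ed_b = int(rng.integers(1, 4))
        rid += 1
        rows.append(
            [f"pair_{rid:07d}", a[0], a[1], "+", b[0], b[1], "-", mapq_a, mapq_b, ed_a, ed_b, lib]
        )

    if kind == "matepair":
        for lib_id, mean, sd in libraries:
            n = n_pairs or int(depth * total / mean)
            ci = rng.choice(len(chroms), size=n, p=probs)
            inserts = rng.normal(mean, sd, size=n)
            for k in range(n):
                chrom = chroms[ci[k]]
                ins = max(inserts[k], 100.0)
                left = rng.uniform(0, genome_lengths[chrom] - ins)
                _emit(chrom, left, left + ins, lib_id)
    elif kind == "proximity":
        n = n_pairs or int(depth * total / proximity.short_mean_bp / 10)
        ci = rng.choice(len(chroms), size=n, p=probs)
        is_long = rng.random(n) < proximity.long_fraction
        u = rng.random(n)
        seps = np.where(
            is_long,
            proximity.min_long_sep_bp
            * (proximity.max_sep_bp / proximity.min_long_sep_bp) ** u,
            np.maximum(np.abs(rng.normal(proximity.short_mean_bp, proximity.short_sd_bp, n)), 50.0),
        )
        for k in range(n):
            chrom = chroms[ci[k]]
            sep = min(seps[k], genome_lengths[chrom] - 1)
            left = rng.uniform(0, genome_lengths[chrom] - sep)
            _emit(chrom, left, left + sep, library_id)
    else:
        raise ValueError(f"unknown pair kind {kind!r}")
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def simulate_markers(
    genome_lengths: dict[str, int],
    segments: dict[str, list[Segment]],
    markers_per_chrom: int = 30,
    seed: int = 0,
) -> pd.DataFrame:
    """Genetic markers per chromosome, lifted onto contig coordinates.

    Linkage group equals the chromosome of origin.  Positions are resampled
    until they fall inside an assembled contig, so the emitted count is
    exactly ``n_chrom * markers_per_chrom``.
    """
    if markers_per_chrom < 1:
        raise ValueError("markers_per_chrom must be >= 1")
    rng = np.random.default_rng(seed)
    index = _GenomeIndex(segments)
    rows = []
    k = 0
    for chrom in sorted(genome_lengths):
        placed = 0
        attempts = 0
        while placed < markers_per_chrom:
            attempts += 1
            if attempts > 10_000 * markers_per_chrom:
                raise RuntimeError(f"cannot place markers on {chrom}")
            gpos = int(rng.integers(0, genome_lengths[chrom]))
            hit = index.lift(chrom, gpos)
            if hit is None:
                continue
            k += 1
            placed += 1
            rows.append([f"marker_{k:04d}", chrom, hit[0], hit[1]])
    return pd.DataFrame(rows, columns=MARKER_COLUMNS)


# ---------------------------------------------------------------------------
# truth-aware evaluation
# ---------------------------------------------------------------------------


#: placeholder chromosome name for N-gap stretches inside scaffold sequences
GAP_CHROM = "__gap__"


def fragment_genome_segments(
    fragment_id: str,
    lineage: list[tuple[str, str, int, int]],
    truth: ContigTruth,
) -> list[Segment]:
    """Genome segments of a (possibly broken) contig/scaffold fragment."""
    entry = next((l for l in lineage if l[0] == fragment_id), None)
    if entry is None:
        parent, lo, hi = fragment_id, 0, None
    else:
        _, parent, lo, hi = entry
    segs = truth.segments[parent]
    if hi is None:
        hi = sum(s.length for s in segs)
    out: list[Segment] = []
    offset = 0
    for seg in segs:
        s_lo, s_hi = offset, offset + seg.length
        inter_lo, inter_hi = max(lo, s_lo), min(hi, s_hi)
        if inter_lo < inter_hi:
            if seg.orient == "+" or seg.chrom == GAP_CHROM:
                g_lo = seg.start + (inter_lo - s_lo)
                g_hi = seg.start + (inter_hi - s_lo)
            else:  # mirrored segment: object left end is the genome right end
                g_lo = seg.start + (s_hi - inter_hi)
                g_hi = seg.start + (s_hi - inter_lo)
            out.append(Segment(seg.chrom, g_lo, g_hi, seg.orient))
        offset = s_hi
    return out


def _flip_orient(o: str) -> str:
    return "-" if o == "+" else "+"


def scaffold_truth_segments(scaffolds, lineage, truth: ContigTruth) -> dict[str, list[Segment]]:
    """Genome segments of each scaffold's sequence, gap runs included.

    Enables a scaffolding result to serve as the input "assembly" of a later
    integration stage while keeping evaluation anchored to the original
    genome: the returned dict plugs into a new :class:`ContigTruth`.
    """
    from .scaffolding import ContigPart

    out: dict[str, list[Segment]] = {}
    for scaf in scaffolds:
        segs: list[Segment] = []
        for part in scaf.parts:
            if not isinstance(part, ContigPart):
                segs.append(Segment(GAP_CHROM, 0, part.gap_bp))
                continue
            frag_segs = fragment_genome_segments(part.contig_id, lineage, truth)
            if part.orientation == "-":
                frag_segs = [
                    Segment(s.chrom, s.start, s.end, _flip_orient(s.orient))
                    for s in reversed(frag_segs)
                ]
            segs.extend(frag_segs)
        out[scaf.scaffold_id] = segs
    return out


def _segment_endpoints(seg: Segment):
    """((chrom,pos,kind) at the object-left end, same at the object-right end)."""
    if seg.orient == "+":
        return (seg.chrom, seg.start, "start"), (seg.chrom, seg.end, "end")
    return (seg.chrom, seg.end, "end"), (seg.chrom, seg.start, "start")


def evaluate_misjoin_repair(
    lineage: list[tuple[str, str, int, int]],
    truth: ContigTruth,
    tol_bp: int | dict[str, int],
) -> dict:
    """Score contig cuts against planted misjoin junctions.

    A misjoin counts as repaired when its contig was cut within tolerance of
    the junction; ``tol_bp`` is either one distance or a per-contig dict
    (conflict breakpoints are defined between labels, so the natural
    tolerance is the junction's local inter-label interval).  A false break
    is a cut on a clean contig, or a cut beyond tolerance from every
    junction of a chimeric contig.
    """
    cuts: dict[str, list[int]] = {}
    for frag, parent, lo, hi in lineage:
        if frag != parent and lo > 0:
            cuts.setdefault(parent, []).append(lo)
    junctions = {m.contig_id: m.junction_bp for m in truth.misjoins}

    def _tol(cid: str) -> int:
        return tol_bp[cid] if isinstance(tol_bp, dict) else tol_bp

    repaired = sum(
        1
        for cid, j in junctions.items()
        if any(abs(c - j) <= _tol(cid) for c in cuts.get(cid, []))
    )
    false_breaks = 0
    clean_broken = set()
    for cid, positions in cuts.items():
        j = junctions.get(cid)
        for c in positions:
            if j is None or abs(c - j) > _tol(cid):
                false_breaks += 1
                if j is None:
                    clean_broken.add(cid)
    return {
        "n_misjoins": len(junctions),
        "n_repaired": repaired,
        "false_breaks": false_breaks,
        "clean_contigs_broken": sorted(clean_broken),
    }


def junction_interval_tolerances(
    contigs: dict[str, str], truth: ContigTruth, floor_bp: int = 1_000
) -> dict[str, int]:
    """Per-misjoin tolerance: the inter-label interval spanning the junction."""
    from .digestion import digest_sequence

    out: dict[str, int] = {}
    for mj in truth.misjoins:
        sites = digest_sequence(contigs[mj.contig_id]).sites
        left = max((s for s in sites if s <= mj.junction_bp), default=0)
        right = min(
            (s for s in sites if s > mj.junction_bp), default=len(contigs[mj.contig_id])
        )
        out[mj.contig_id] = max(right - left, floor_bp)
    return out


def adjacency_recovery(
    scaffolds,
    lineage: list[tuple[str, str, int, int]],
    truth: ContigTruth,
    tol_bp: int = 10_000,
) -> dict:
    """Fraction of true fragment adjacencies realised inside scaffolds.

    Each scaffold is unrolled into its ordered chain of genome segments
    (gap runs and sub-``tol_bp`` slivers dropped — breakpoints are accurate
    only to one label interval, so repaired fragments may keep a sliver of
    the wrong locus at a cut end).  A true adjacency is recovered when some
    chain holds its two flanking loci consecutively, in either overall
    direction.  Composable across stages: feed a truth whose "contigs" are
    a previous stage's scaffolds (see :func:`scaffold_truth_segments`).
    """
    chains = scaffold_truth_segments(scaffolds, lineage, truth)
    junctions = []
    for chain in chains.values():
        segs = [s for s in chain if s.chrom != GAP_CHROM and s.length >= tol_bp]
        for a, b in zip(segs, segs[1:]):
            junctions.append((_segment_endpoints(a)[1], _segment_endpoints(b)[0]))

    def _match(true_adj, junc) -> bool:
        _, _, chrom, g_end, g_start, _ = true_adj
        (c1, p1, k1), (c2, p2, k2) = junc
        fwd = (
            c1 == chrom and c2 == chrom and k1 == "end" and k2 == "start"
            and abs(p1 - g_end) <= tol_bp and abs(p2 - g_start) <= tol_bp
        )
        rev = (
            c1 == chrom and c2 == chrom and k1 == "start" and k2 == "end"
            and abs(p1 - g_start) <= tol_bp and abs(p2 - g_end) <= tol_bp
        )
        return fwd or rev

    recovered = sum(1 for adj in truth.adjacencies if any(_match(adj, j) for j in junctions))
    return {
        "n_true": len(truth.adjacencies),
        "n_recovered": recovered,
        "recovery": recovered / len(truth.adjacencies) if truth.adjacencies else 1.0,
        "n_scaffold_junctions": len(junctions),
    }
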