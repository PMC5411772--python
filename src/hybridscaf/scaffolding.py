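"""Hybrid scaffolding: ordering and orienting contigs along consensus maps.

Each consensus map acts as a backbone: contigs whose in-silico maps align to
it (strict tier, post conflict-resolution) are ordered by their implied
position on the map and oriented by their alignment orientation.  Gaps
between neighbours are estimated from the map distance between the flanking
matched labels minus the contig tails beyond them.  A contig that aligns to
two maps with its two ends stitches those maps' layouts into one scaffold;
layouts are merged on their shared contig overlap like reads in an
overlap-layout assembler.

Scaffolds can be emitted as FASTA (gaps as N runs; proximity-ligation joins
use a fixed 100 N convention) and as AGP v2.1 component tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .alignment import AlignmentParams, MapAlignment, align_all
from .conflicts import (
    ConflictParams,
    break_objects,
    detect_conflicts,
    arbitrate_conflict,
    filter_dominated_alignments,
    place_breakpoints,
)
from .digestion import DigestionParams, RestrictionMap, digest_sequence, reverse_complement

log = logging.getLogger(__name__)

__all__ = [
    "ScaffoldParams",
    "ContigPart",
    "GapPart",
    "Scaffold",
    "hybrid_scaffold",
    "estimate_gap",
    "scaffolds_to_fasta",
    "scaffolds_to_agp",
    "iterative_integration",
]

#: AGP sentinel for "adjacent, true gap unknown"
MIN_GAP_BP = 13
#: fixed gap written between contigs joined by proximity-ligation evidence
HIC_GAP_BP = 100


@dataclass
class ScaffoldParams:
    min_gap_bp: int = MIN_GAP_BP
    #: maximum accepted placements per contig (two ends -> two maps)
    max_placements: int = 2


@dataclass
class ContigPart:
    contig_id: str
    orientation: str  # '+' | '-'
    start: int = 0  # 0-based half-open interval of the contig used
    end: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GapPart:
    gap_bp: int
    gap_kind: str = "map_estimated"  # map_estimated | fixed_hic
    flagged: bool = False


@dataclass
class Scaffold:
    scaffold_id: str
    parts: list = field(default_factory=list)  # ContigPart / GapPart alternating
    backbone_map_id: str | None = None

    @property
    def length(self) -> int:
        return sum(p.length if isinstance(p, ContigPart) else p.gap_bp for p in self.parts)

    def contig_ids(self) -> list[str]:
        return [p.contig_id for p in self.parts if isinstance(p, ContigPart)]

    def contig_parts(self) -> list[ContigPart]:
        return [p for p in self.parts if isinstance(p, ContigPart)]


def estimate_gap(
    left_alignment: MapAlignment,
    right_alignment: MapAlignment,
    left_contig_len: int,
    right_contig_len: int,
    min_gap_bp: int = MIN_GAP_BP,
) -> tuple[int, bool]:
    """Gap between two neighbours on one backbone map.

    gap = (map distance between the last matched label of the left contig and
    the first matched label of the right contig) minus the left contig's tail
    beyond its label and the right contig's head before its label.  Negative
    estimates clamp to ``min_gap_bp`` and are flagged.
    """
    if left_alignment.ref_id != right_alignment.ref_id:
        raise ValueError(
            f"gap estimation across different maps: {left_alignment.ref_id} vs {right_alignment.ref_id}"
        )
    r_last_left = left_alignment.ref_span[1]
    r_first_right = right_alignment.ref_span[0]
    # tails are measured from the label START (positions are 1-based starts),
    # so the left tail includes the label base itself
    if left_alignment.orientation == "+":
        tail_left = left_contig_len - left_alignment.query_span[1] + 1
    else:
        tail_left = left_alignment.query_span[0]
    if right_alignment.orientation == "+":
        head_right = right_alignment.query_span[0] - 1
    else:
        head_right = right_contig_len - right_alignment.query_span[1]
    gap = (r_first_right - r_last_left) - tail_left - head_right
    if gap < min_gap_bp:
        return min_gap_bp, True
    return int(gap), False


@dataclass
class _Placement:
    contig_id: str
    map_id: str
    alignment: MapAlignment
    implied_start: int = 0
    implied_end: int = 0


def _implied_span(aln: MapAlignment, contig_len: int) -> tuple[int, int]:
    """Map interval the whole contig would occupy, extending past the labels."""
    if aln.orientation == "+":
        head = aln.query_span[0] - 1
        tail = contig_len - aln.query_span[1]
    else:
        head = contig_len - aln.query_span[1]
        tail = aln.query_span[0] - 1
    return aln.ref_span[0] - head, aln.ref_span[1] + tail


def _flip(o: str) -> str:
    return "-" if o == "+" else "+"


def _reverse_layout(layout: list[tuple[_Placement, str]]) -> list[tuple[_Placement, str]]:
    return [(p, _flip(o)) for p, o in reversed(layout)]


def _try_overlap(a, b):
    """Merge two oriented layouts when one's suffix equals the other's prefix.

    Layout entries are ``(placement, orientation)``; signatures compare
    ``(contig_id, orientation)``.  Returns the merged layout or None.
    """
    a_sig = [(p.contig_id, o) for p, o in a]
    for b_var in (b, _reverse_layout(b)):
        b_sig = [(p.contig_id, o) for p, o in b_var]
        max_k = min(len(a_sig), len(b_sig))
        for k in range(max_k, 0, -1):
            if a_sig[-k:] == b_sig[:k]:
                return a + b_var[k:]
            if b_sig[-k:] == a_sig[:k]:
                return b_var + a[k:]
    return None


def _merge_layouts(layouts: list[list[tuple[_Placement, str]]], placements_by_contig):
    """Overlap-merge per-map layouts on shared contigs.

    A shared contig must form a suffix/prefix overlap (identical ids and
    orientations after possibly reversing one layout); otherwise the
    lower-scoring placement of the offending contig is discarded and merging
    is retried.
    """
    merged = [list(l) for l in layouts if l]
    changed = True
    while changed:
        changed = False
        for i in range(len(merged)):
            for j in range(i + 1, len(merged)):
                a, b = merged[i], merged[j]
                shared = {p.contig_id for p, _ in a} & {p.contig_id for p, _ in b}
                if not shared:
                    continue
                res = _try_overlap(a, b)
                if res is not None:
                    merged[i] = res
                    del merged[j]
                else:
                    cid = sorted(shared)[0]
                    pa = next(p for p, _ in a if p.contig_id == cid)
                    pb = next(p for p, _ in b if p.contig_id == cid)
                    victim, layout = (
                        (pa, a) if pa.alignment.score <= pb.alignment.score else (pb, b)
                    )
                    log.warning(
                        "contig %s: incompatible placements on maps %s/%s; dropping lower score",
                        cid, pa.map_id, pb.map_id,
                    )
                    layout[:] = [(p, o) for p, o in layout if p is not victim]
                    placements_by_contig[cid].remove(victim)
                    merged[:] = [l for l in merged if l]
                changed = True
                break
            if changed:
                break
    return merged


def hybrid_scaffold(
    contig_lengths: dict[str, int],
    contig_maps: dict[str, RestrictionMap],
    consensus_maps: dict[str, RestrictionMap],
    strict_alignments: list[MapAlignment],
    params: ScaffoldParams = ScaffoldParams(),
) -> tuple[list[Scaffold], list[str]]:
    """Order and orient contigs along consensus maps.

    Inputs are assumed post-breaking (conflict-free at strict tier).  Returns
    ``(scaffolds, unplaced)``; contigs aligned to no map become singleton
    scaffolds, contigs fully contained in another's implied span (or with
    irreconcilable duplicate placements) go to ``unplaced``.  Every contig
    appears exactly once across the two.
    """
    strict = [a for a in strict_alignments if a.tier == "strict"]
    # best alignment per (contig, map)
    best: dict[tuple[str, str], MapAlignment] = {}
    for a in strict:
        key = (a.query_id, a.ref_id)
        cur = best.get(key)
        if cur is None or (a.score, a.n_pairs) > (cur.score, cur.n_pairs):
            best[key] = a

    # accept the best few placements per contig (a contig aligning to two
    # maps is what stitches their layouts into one scaffold; consistency is
    # checked at merge time and the lower-scoring placement dropped if not)
    placements_by_contig: dict[str, list[_Placement]] = {}
    by_contig: dict[str, list[MapAlignment]] = {}
    for (cid, _), a in best.items():
        by_contig.setdefault(cid, []).append(a)
    for cid, alns in by_contig.items():
        alns.sort(key=lambda a: (-a.score, -a.n_pairs, a.ref_id))
        placements_by_contig[cid] = [
            _Placement(cid, a.ref_id, a) for a in alns[: params.max_placements]
        ]

    unplaced: list[str] = []
    # per-map layouts
    layouts: dict[str, list[_Placement]] = {m: [] for m in consensus_maps}
    for cid, pls in placements_by_contig.items():
        for p in pls:
            p.implied_start, p.implied_end = _implied_span(p.alignment, contig_lengths[cid])
            layouts.setdefault(p.map_id, []).append(p)

    # containment drop within each map layout
    for map_id, layout in layouts.items():
        kept: list[_Placement] = []
        for p in sorted(layout, key=lambda p: (p.implied_start - p.implied_end, p.implied_start)):
            container = next(
                (
                    q
                    for q in kept
                    if q.implied_start <= p.implied_start and p.implied_end <= q.implied_end
                ),
                None,
            )
            if container is None:
                kept.append(p)
            else:
                placements_by_contig[p.contig_id].remove(p)
                if not placements_by_contig[p.contig_id]:
                    log.info("contig %s contained within %s span on %s; unplaced",
                             p.contig_id, container.contig_id, map_id)
                    unplaced.append(p.contig_id)
        kept.sort(key=lambda p: (p.implied_start, p.implied_end, p.contig_id))
        layouts[map_id] = kept

    oriented = [
        [(p, p.alignment.orientation) for p in layout]
        for layout in layouts.values()
        if layout
    ]
    merged = _merge_layouts(oriented, placements_by_contig)

    scaffolds: list[Scaffold] = []
    counter = 0
    placed: set[str] = set()
    for layout in merged:
        if not layout:
            continue
        counter += 1
        scaf = Scaffold(f"scaffold_{counter}", backbone_map_id=layout[0][0].map_id)
        for idx, (p, orient) in enumerate(layout):
            length = contig_lengths[p.contig_id]
            if idx > 0:
                prev = layout[idx - 1][0]
                gap = _gap_for_pair(prev, p, contig_lengths, placements_by_contig)
                scaf.parts.append(gap)
            scaf.parts.append(ContigPart(p.contig_id, orient, 0, length))
            placed.add(p.contig_id)
        scaffolds.append(scaf)

    for cid in sorted(contig_lengths):
        if cid in placed or cid in unplaced:
            continue
        counter += 1
        scaffolds.append(
            Scaffold(
                f"scaffold_{counter}",
                parts=[ContigPart(cid, "+", 0, contig_lengths[cid])],
            )
        )
    return scaffolds, sorted(set(unplaced))


def _gap_for_pair(left: _Placement, right: _Placement, contig_lengths, placements_by_contig):
    """Estimate the gap between two scaffold neighbours on a common map."""
    maps_left = {p.map_id: p.alignment for p in placements_by_contig[left.contig_id]}
    maps_right = {p.map_id: p.alignment for p in placements_by_contig[right.contig_id]}
    common = set(maps_left) & set(maps_right)
    if not common:
        return GapPart(MIN_GAP_BP, "map_estimated", flagged=True)
    map_id = sorted(common)[0]
    a, b = maps_left[map_id], maps_right[map_id]
    # order on the map axis, not the scaffold axis
    if a.ref_span[0] > b.ref_span[0]:
        a, b = b, a
        la, lb = contig_lengths[right.contig_id], contig_lengths[left.contig_id]
    else:
        la, lb = contig_lengths[left.contig_id], contig_lengths[right.contig_id]
    gap, flagged = estimate_gap(a, b, la, lb)
    return GapPart(gap, "map_estimated", flagged=flagged)


# ---------------------------------------------------------------------------
# sequence / AGP emission
# ---------------------------------------------------------------------------


def scaffolds_to_fasta(
    scaffolds: list[Scaffold], contig_sequences: dict[str, str]
) -> dict[str, str]:
    """Scaffold sequences with N-run gaps; '-' parts are reverse-complemented."""
    out: dict[str, str] = {}
    for scaf in scaffolds:
        chunks: list[str] = []
        for part in scaf.parts:
            if isinstance(part, GapPart):
                chunks.append("N" * part.gap_bp)
            else:
                seq = contig_sequences.get(part.contig_id)
                if seq is None:
                    raise KeyError(f"missing contig sequence {part.contig_id}")
                sub = seq[part.start : part.end]
                chunks.append(reverse_complement(sub) if part.orientation == "-" else sub)
        out[scaf.scaffold_id] = "".join(chunks)
    return out


def scaffolds_to_agp(scaffolds: list[Scaffold]) -> list[tuple]:
    """AGP v2.1 rows (W lines for contigs, N lines for gaps)."""
    rows = []
    for scaf in scaffolds:
        pos = 0
        part_no = 0
        for part in scaf.parts:
            part_no += 1
            if isinstance(part, ContigPart):
                rows.append(
                    (
                        scaf.scaffold_id,
                        pos + 1,
                        pos + part.length,
                        part_no,
                        "W",
                        part.contig_id,
                        part.start + 1,
                        part.end,
                        part.orientation,
                    )
                )
                pos += part.length
            else:
                linkage_evidence = (
                    "proximity_ligation" if part.gap_kind == "fixed_hic" else "map"
                )
                rows.append(
                    (
                        scaf.scaffold_id,
                        pos + 1,
                        pos + part.gap_bp,
                        part_no,
                        "N",
                        part.gap_bp,
                        "scaffold",
                        "yes",
                        linkage_evidence,
                    )
                )
                pos += part.gap_bp
    return rows


# ---------------------------------------------------------------------------
# iterative cross-assembly / proximity-scaffold integration
# ---------------------------------------------------------------------------


@dataclass
class IntegrationResult:
    scaffolds: list[Scaffold]
    sequences: dict[str, str]  # scaffold_id -> sequence
    fragment_sequences: dict[str, str]  # post-breaking units
    lineage: list[tuple[str, str, int, int]]
    conflicts: list
    unplaced: list[str]


def iterative_integration(
    sequences_a: dict[str, str],
    sequences_b: dict[str, str],
    digestion_params: DigestionParams = DigestionParams(),
    alignment_params: AlignmentParams = AlignmentParams(),
    conflict_params: ConflictParams = ConflictParams(),
    scaffold_params: ScaffoldParams = ScaffoldParams(),
    hic_evidence: list | None = None,
    gap_kind: str = "map_estimated",
) -> IntegrationResult:
    """Integrate scaffold set B's contiguity into scaffold set A.

    B's sequences are digested into in-silico consensus maps; A's sequences
    are digested and aligned to them; conflicts are arbitrated and both sides
    broken where demanded; the surviving strict alignments then drive hybrid
    scaffolding of the (possibly broken) A units along the (possibly broken)
    B maps.  An A join is never split unless a conflict verdict demanded it.
    Self-integration is a fixed point and the operation is idempotent.
    """
    b_maps = {
        sid: digest_sequence(seq, digestion_params, sid, source="insilico_scaffold")
        for sid, seq in sequences_b.items()
    }
    a_maps = {
        sid: digest_sequence(seq, digestion_params, sid, source="insilico_scaffold")
        for sid, seq in sequences_a.items()
    }
    alignments = align_all(list(a_maps.values()), list(b_maps.values()), alignment_params)
    strict = filter_dominated_alignments([a for a in alignments if a.tier == "strict"])
    conflicts = detect_conflicts(strict, b_maps, a_maps, conflict_params.min_overhang_sites)
    relaxed_conflicts = detect_conflicts(
        filter_dominated_alignments(alignments), b_maps, a_maps,
        conflict_params.min_overhang_sites,
    )
    seq_bps = []
    map_bps = []
    for c in conflicts:
        arbitrate_conflict(c, conflicts, relaxed_conflicts, None, hic_evidence, conflict_params)
        for bp in place_breakpoints(c, b_maps, a_maps, conflict_params):
            (seq_bps if bp.object_kind == "contig" else map_bps).append(bp)

    new_a, lineage = break_objects(sequences_a, seq_bps, conflict_params)
    new_b_maps, _ = break_objects(b_maps, map_bps, conflict_params)
    new_a_maps = {
        sid: digest_sequence(seq, digestion_params, sid, source="insilico_scaffold")
        for sid, seq in new_a.items()
    }
    strict2 = [
        a
        for a in align_all(
            list(new_a_maps.values()), list(new_b_maps.values()), alignment_params
        )
        if a.tier == "strict"
    ]
    lengths = {sid: len(seq) for sid, seq in new_a.items()}
    scaffolds, unplaced = hybrid_scaffold(
        lengths, new_a_maps, new_b_maps, strict2, scaffold_params
    )
    if gap_kind == "fixed_hic":
        for scaf in scaffolds:
            for part in scaf.parts:
                if isinstance(part, GapPart):
                    part.gap_bp = HIC_GAP_BP
                    part.gap_kind = "fixed_hic"
    seqs = scaffolds_to_fasta(scaffolds, new_a)
    return IntegrationResult(
        scaffolds=scaffolds,
        sequences=seqs,
        fragment_sequences=new_a,
        lineage=lineage,
        conflicts=conflicts,
        unplaced=unplaced,
    )
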