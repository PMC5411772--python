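"""Contig-vs-map conflict detection, arbitration and object breaking.

A *conflict* is an alignment that terminates internally on both objects with
substantial unaligned label overhangs on each side of the terminus: the two
objects agree locally but disagree about what comes next, so one of them is
misassembled.  Arbitration decides which, by looking for corroborating
conflicts in progressively weaker evidence sets (other strict alignments,
relaxed-tier alignments, an assembly built with a different assembler, and
finally proximity-ligation misassembly evidence); when nothing decides, both
objects are cut.  Breakpoints sit at the midpoint between the last aligned
and first unaligned label, shifted onto a nearby unmatched multi-label
indel block when one exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alignment import MapAlignment
from .digestion import RestrictionMap

__all__ = [
    "ConflictParams",
    "ConflictRecord",
    "Breakpoint",
    "filter_dominated_alignments",
    "detect_conflicts",
    "arbitrate_conflict",
    "place_breakpoints",
    "break_objects",
]


def filter_dominated_alignments(
    alignments: list[MapAlignment],
    overlap_frac: float = 0.8,
    dominance_ratio: float = 0.5,
) -> list[MapAlignment]:
    """Drop alignments dominated by a much stronger one of the same contig.

    A chance (or repeat-driven) alignment of a contig region that also
    aligns elsewhere with a far higher score must not seed conflicts:
    overlapping consensus-map windows replicate the same chance hit and
    would corroborate each other.  An alignment is dominated when at least
    ``overlap_frac`` of its contig span is covered by another alignment of
    the same contig scoring more than ``1/dominance_ratio`` times higher.
    Genuine corroborating alignments (several maps of one locus) have
    comparable scores and are never dominated.
    """
    by_query: dict[str, list[MapAlignment]] = {}
    for a in alignments:
        by_query.setdefault(a.query_id, []).append(a)
    kept: list[MapAlignment] = []
    for alns in by_query.values():
        for a in alns:
            span = a.query_span[1] - a.query_span[0]
            dominated = any(
                b is not a
                and a.score < dominance_ratio * b.score
                and min(a.query_span[1], b.query_span[1])
                - max(a.query_span[0], b.query_span[0])
                >= overlap_frac * span
                for b in alns
            )
            if not dominated:
                kept.append(a)
    return kept


@dataclass
class ConflictParams:
    #: unaligned labels required beyond the terminus on BOTH objects
    min_overhang_sites: int = 5
    #: two conflict junctions within this distance count as "the same region"
    same_region_bp: int = 50_000
    #: an unmatched indel block of >= 2 labels within this window of the
    #: midpoint attracts the breakpoint
    adjust_window_bp: int = 50_000
    #: minimum spacing between breakpoints on one object after deduplication
    min_fragment_bp: int = 20_000


@dataclass
class Junction:
    """Cut coordinates implied by one alignment terminus on one object."""

    last_aligned_bp: int
    first_unaligned_bp: int

    @property
    def midpoint(self) -> int:
        return (self.last_aligned_bp + self.first_unaligned_bp) // 2


@dataclass
class ConflictRecord:
    contig_id: str
    map_id: str
    alignment: MapAlignment
    junction_side: str  # ref_left | ref_right (end of the alignment on the map axis)
    contig_junction: Junction = None
    map_junction: Junction = None
    verdict: str = "unresolved"  # contig_error | map_error | both | unresolved
    evidence: str = ""


@dataclass
class Breakpoint:
    object_id: str
    object_kind: str  # contig | map | scaffold
    position_bp: int
    derived_from: ConflictRecord = field(repr=False, default=None)


def _termini(aln: MapAlignment, query: RestrictionMap, ref: RestrictionMap):
    """Overhang label counts and junction coordinates at each alignment end.

    Yields (side, query_overhang, ref_overhang, query_junction, ref_junction)
    for side in ('ref_left', 'ref_right').  The query is the contig by
    pipeline convention but nothing here assumes it.
    """
    q_sites, r_sites = query.sites, ref.sites
    m, n = len(q_sites), len(r_sites)
    pairs = aln.pairs  # ordered by ref index
    first_q, first_r = pairs[0]
    last_q, last_r = pairs[-1]
    plus = aln.orientation == "+"

    # ref_left end: ref overhang below first_r; query overhang on the side of
    # the query that precedes the alignment in ref orientation.
    r_over_left = first_r
    r_junc_left = Junction(
        r_sites[first_r], r_sites[first_r - 1] if first_r > 0 else r_sites[first_r]
    )
    if plus:
        q_over_left = first_q
        q_junc_left = Junction(
            q_sites[first_q], q_sites[first_q - 1] if first_q > 0 else q_sites[first_q]
        )
    else:  # query runs backwards: the part after first_q precedes in ref axis
        q_over_left = m - 1 - first_q
        q_junc_left = Junction(
            q_sites[first_q], q_sites[first_q + 1] if first_q < m - 1 else q_sites[first_q]
        )
    yield "ref_left", q_over_left, r_over_left, q_junc_left, r_junc_left

    r_over_right = n - 1 - last_r
    r_junc_right = Junction(
        r_sites[last_r], r_sites[last_r + 1] if last_r < n - 1 else r_sites[last_r]
    )
    if plus:
        q_over_right = m - 1 - last_q
        q_junc_right = Junction(
            q_sites[last_q], q_sites[last_q + 1] if last_q < m - 1 else q_sites[last_q]
        )
    else:
        q_over_right = last_q
        q_junc_right = Junction(
            q_sites[last_q], q_sites[last_q - 1] if last_q > 0 else q_sites[last_q]
        )
    yield "ref_right", q_over_right, r_over_right, q_junc_right, r_junc_right


def detect_conflicts(
    alignments: list[MapAlignment],
    maps: dict[str, RestrictionMap],
    contig_maps: dict[str, RestrictionMap],
    min_overhang_sites: int = 5,
) -> list[ConflictRecord]:
    """Conflicts among contig(query)-to-map(reference) alignments.

    An alignment terminus with at least ``min_overhang_sites`` unaligned
    labels beyond it on *both* the contig and the map is a conflict.  A pair
    of strict alignments of two different maps to overlapping contig regions
    with incompatible implied extensions also yields a conflict for each
    alignment (these are normally already caught by the per-terminus rule;
    the pair scan only de-duplicates against it).
    """
    out: list[ConflictRecord] = []
    seen: set[tuple[str, str, str]] = set()

    def _emit(aln, side, q_junc, r_junc):
        key = (aln.query_id, aln.ref_id, side)
        if key in seen:
            return
        seen.add(key)
        out.append(
            ConflictRecord(
                contig_id=aln.query_id,
                map_id=aln.ref_id,
                alignment=aln,
                junction_side=side,
                contig_junction=q_junc,
                map_junction=r_junc,
            )
        )

    for aln in alignments:
        if not aln.pairs:
            continue
        query = contig_maps[aln.query_id]
        ref = maps[aln.ref_id]
        for side, q_over, r_over, q_junc, r_junc in _termini(aln, query, ref):
            if q_over >= min_overhang_sites and r_over >= min_overhang_sites:
                _emit(aln, side, q_junc, r_junc)

    # pair scan: different maps claiming overlapping contig regions while both
    # extend past the overlap (incompatible extensions)
    by_contig: dict[str, list[MapAlignment]] = {}
    for aln in alignments:
        if aln.pairs:
            by_contig.setdefault(aln.query_id, []).append(aln)
    for contig_id, alns in by_contig.items():
        query = contig_maps[contig_id]
        for i in range(len(alns)):
            for j in range(i + 1, len(alns)):
                a, b = alns[i], alns[j]
                if a.ref_id == b.ref_id:
                    continue
                lo = max(a.query_span[0], b.query_span[0])
                hi = min(a.query_span[1], b.query_span[1])
                if lo >= hi:
                    continue
                for aln in (a, b):
                    ref = maps[aln.ref_id]
                    for side, q_over, r_over, q_junc, r_junc in _termini(aln, query, ref):
                        # incompatible extension: the contig continues past
                        # this terminus (query overhang) AND the map claims
                        # something else there (ref overhang), inside the
                        # region both maps cover
                        if (
                            q_over >= min_overhang_sites
                            and r_over >= min_overhang_sites
                            and lo <= q_junc.last_aligned_bp <= hi
                        ):
                            _emit(aln, side, q_junc, r_junc)
    return out


def _same_region(a: Junction, b: Junction, window: int) -> bool:
    return abs(a.midpoint - b.midpoint) <= window


def arbitrate_conflict(
    conflict: ConflictRecord,
    strict_conflicts: list[ConflictRecord],
    relaxed_conflicts: list[ConflictRecord],
    alt_assembly_alignments: list[MapAlignment] | None = None,
    hic_evidence: list | None = None,
    params: ConflictParams = ConflictParams(),
) -> str:
    """Decide whether the contig, the map, or both are misassembled.

    Decision tree, evaluated in order; the first step that produces evidence
    sets the verdict (recorded in ``conflict.evidence``):

    1. another strict-tier conflict at the same contig region -> contig_error;
       at the same map region (from a different contig) -> map_error;
    2. the same test on relaxed-tier conflicts;
    3. the focal map aligns cleanly across its junction region to a contig of
       the alternate assembly -> contig_error; the alternate assembly shows
       the same conflict with the map -> map_error;
    4. proximity-ligation misassembly evidence overlapping the contig
       junction -> contig_error;
    5. otherwise both objects are declared misassembled and both are cut.
    """
    w = params.same_region_bp

    def _corroborate(pool: list[ConflictRecord], label: str) -> str | None:
        for other in pool:
            if other is conflict or other.alignment is conflict.alignment:
                continue
            if other.contig_id == conflict.contig_id and _same_region(
                other.contig_junction, conflict.contig_junction, w
            ):
                conflict.evidence = f"{label}: second conflict on contig from {other.map_id}"
                return "contig_error"
        for other in pool:
            if other is conflict or other.alignment is conflict.alignment:
                continue
            if (
                other.map_id == conflict.map_id
                and other.contig_id != conflict.contig_id
                and _same_region(other.map_junction, conflict.map_junction, w)
            ):
                conflict.evidence = f"{label}: second conflict on map from {other.contig_id}"
                return "map_error"
        return None

    verdict = _corroborate(strict_conflicts, "strict")
    if verdict is None:
        verdict = _corroborate(relaxed_conflicts, "relaxed")
    if verdict is None and alt_assembly_alignments:
        junc = conflict.map_junction.midpoint
        for aln in alt_assembly_alignments:
            if aln.ref_id != conflict.map_id or aln.tier != "strict":
                continue
            lo, hi = aln.ref_span
            margin = params.same_region_bp
            if lo + 0 <= junc - margin and junc + margin <= hi:
                conflict.evidence = f"alt-assembly: {aln.query_id} spans map junction"
                verdict = "contig_error"
                break
            if abs(lo - junc) <= margin or abs(hi - junc) <= margin:
                conflict.evidence = f"alt-assembly: {aln.query_id} stops at same map junction"
                verdict = "map_error"
                break
    if verdict is None and hic_evidence:
        junc = conflict.contig_junction.midpoint
        for region in hic_evidence:
            if region.contig_id == conflict.contig_id and (
                region.start - w <= junc <= region.end + w
            ):
                conflict.evidence = "hic: spanning-signal region at contig junction"
                verdict = "contig_error"
                break
    if verdict is None:
        conflict.evidence = "fallback: no corroborating evidence, cutting both"
        verdict = "both"
    conflict.verdict = verdict
    return verdict


def _adjusted_midpoint(junction, aln, sites, axis, window_bp) -> int:
    """Midpoint, moved onto a nearby unmatched block of >= 2 labels if any."""
    mid = junction.midpoint
    idx = sorted(aln.query_indices() if axis == "query" else aln.ref_indices())
    best = None
    for a, b in zip(idx, idx[1:]):
        if b - a - 1 >= 2:
            block_mid = (sites[a + 1] + sites[b - 1]) // 2
            d = abs(block_mid - mid)
            if d <= window_bp and (best is None or d < best[0]):
                best = (d, block_mid)
    return best[1] if best is not None else mid


def place_breakpoints(
    conflict: ConflictRecord,
    maps: dict[str, RestrictionMap],
    contig_maps: dict[str, RestrictionMap],
    params: ConflictParams = ConflictParams(),
) -> list[Breakpoint]:
    """Breakpoint(s) implied by an arbitrated conflict.

    The cut sits at ``floor((last_aligned + first_unaligned)/2)`` on each
    object named by the verdict; if an unmatched insertion/deletion block of
    at least two labels lies within ``adjust_window_bp`` of that midpoint, the
    cut moves to the block midpoint.  A junction flush with the object end
    (no unaligned label) yields no breakpoint.
    """
    if conflict.verdict == "unresolved":
        raise ValueError("arbitrate before placing breakpoints")
    out: list[Breakpoint] = []
    targets = []
    if conflict.verdict in ("contig_error", "both"):
        targets.append(("contig", conflict.contig_id, conflict.contig_junction, "query"))
    if conflict.verdict in ("map_error", "both"):
        targets.append(("map", conflict.map_id, conflict.map_junction, "ref"))
    for kind, obj_id, junction, axis in targets:
        if junction.last_aligned_bp == junction.first_unaligned_bp:
            continue  # terminus at object end: nothing to cut
        sites = (contig_maps if kind == "contig" else maps)[obj_id].sites
        pos = _adjusted_midpoint(junction, conflict.alignment, sites, axis, params.adjust_window_bp)
        length = (contig_maps if kind == "contig" else maps)[obj_id].length_bp
        if 1 < pos < length:
            out.append(Breakpoint(obj_id, kind, pos, conflict))
    return out


def _select_positions(bps: list[Breakpoint], min_gap: int) -> list[int]:
    """One cut per breakpoint cluster, chosen by conflict support.

    Candidate positions closer than ``min_gap`` are clustered (single
    linkage); each cluster is represented by the position backed by the most
    conflicts, then by the highest total alignment score.  This lets a
    junction corroborated from both flanks outvote a stray cut produced by a
    chance chain-extension across the true junction.
    """
    support: dict[int, list[float]] = {}
    for b in bps:
        aln = getattr(b.derived_from, "alignment", None) if b.derived_from else None
        support.setdefault(b.position_bp, []).append(aln.score if aln else 0.0)
    positions = sorted(support)
    clusters: list[list[int]] = [[positions[0]]]
    for p in positions[1:]:
        if p - clusters[-1][-1] < min_gap:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    return sorted(
        max(cl, key=lambda p: (len(support[p]), sum(support[p]), -p)) for cl in clusters
    )


def break_objects(
    objects: dict[str, object],
    breakpoints: list[Breakpoint],
    params: ConflictParams = ConflictParams(),
):
    """Cut sequences and/or maps at their breakpoints.

    ``objects`` maps id -> DNA string or RestrictionMap.  Fragments are named
    ``<id>.1, <id>.2 ...`` left to right; objects without breakpoints pass
    through under their original id.  Returns ``(new_objects, lineage)`` where
    lineage rows are ``(fragment_id, parent_id, start_bp, end_bp)`` with
    0-based half-open parent intervals; sequence and label content are
    partitioned exactly.
    """
    by_obj: dict[str, list[Breakpoint]] = {}
    for bp in breakpoints:
        if bp.object_id not in objects:
            raise KeyError(f"breakpoint on unknown object {bp.object_id}")
        obj = objects[bp.object_id]
        length = len(obj) if isinstance(obj, str) else obj.length_bp
        if not (1 < bp.position_bp < length):
            raise ValueError(
                f"breakpoint {bp.position_bp} outside object {bp.object_id} (len {length})"
            )
        by_obj.setdefault(bp.object_id, []).append(bp)

    new_objects: dict[str, object] = {}
    lineage: list[tuple[str, str, int, int]] = []
    for obj_id, obj in objects.items():
        cuts = (
            _select_positions(by_obj[obj_id], params.min_fragment_bp)
            if obj_id in by_obj
            else []
        )
        length = len(obj) if isinstance(obj, str) else obj.length_bp
        if not cuts:
            new_objects[obj_id] = obj
            lineage.append((obj_id, obj_id, 0, length))
            continue
        bounds = [0] + cuts + [length]
        for k, (lo, hi) in enumerate(zip(bounds, bounds[1:]), start=1):
            frag_id = f"{obj_id}.{k}"
            if isinstance(obj, str):
                new_objects[frag_id] = obj[lo:hi]
            else:
                sites = [s - lo for s in obj.sites if lo < s <= hi]
                new_objects[frag_id] = RestrictionMap(
                    frag_id, hi - lo, sites, source=obj.source
                )
            lineage.append((frag_id, obj_id, lo, hi))
    return new_objects, lineage
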