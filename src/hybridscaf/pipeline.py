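"""End-to-end workflows: correct-then-scaffold and iterative integration.

The core workflow mirrors how optical-map evidence is folded into a long-read
assembly: digest the contigs in silico, align the consensus maps and contig
maps, detect and arbitrate conflicts, cut whichever object the evidence
convicts, then hybrid-scaffold the surviving fragments along the surviving
maps.  Proximity-ligation scaffolds enter through the same machinery by being
digested into in-silico maps first (see
:func:`hybridscaf.scaffolding.iterative_integration`).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

from .alignment import AlignmentParams, align_all
from .conflicts import (
    ConflictParams,
    arbitrate_conflict,
    break_objects,
    detect_conflicts,
    filter_dominated_alignments,
    place_breakpoints,
)
from .digestion import DigestionParams, RestrictionMap, digest_sequence
from .scaffolding import (
    Scaffold,
    ScaffoldParams,
    hybrid_scaffold,
    scaffolds_to_fasta,
)

__all__ = ["derive_seed", "PipelineResult", "correct_and_scaffold"]


def derive_seed(master_seed: int, module_name: str) -> int:
    """Stable child seed per module, independent of other modules.

    Hash-derived so adding a stage never perturbs earlier stages' randomness.
    """
    digest = hashlib.sha256(f"{master_seed}:{module_name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineResult:
    scaffolds: list[Scaffold]
    scaffold_sequences: dict[str, str]
    fragment_sequences: dict[str, str]  # contigs after breaking
    lineage: list[tuple[str, str, int, int]]
    broken_maps: dict[str, RestrictionMap]
    conflicts: list = field(default_factory=list)
    breakpoints: list = field(default_factory=list)
    unplaced: list[str] = field(default_factory=list)

    @property
    def scaffold_lengths(self) -> list[int]:
        return [len(s) for s in self.scaffold_sequences.values()]


def correct_and_scaffold(
    contig_sequences: dict[str, str],
    consensus_maps: list[RestrictionMap],
    digestion_params: DigestionParams = DigestionParams(),
    alignment_params: AlignmentParams = AlignmentParams(),
    conflict_params: ConflictParams = ConflictParams(),
    scaffold_params: ScaffoldParams = ScaffoldParams(),
    alt_contig_sequences: dict[str, str] | None = None,
    hic_evidence: list | None = None,
) -> PipelineResult:
    """Break misassembled contigs/maps, then hybrid-scaffold the fragments.

    ``alt_contig_sequences`` (an assembly of the same genome produced with a
    different assembler) and ``hic_evidence`` (spanning-signal misassembly
    regions) feed the conflict arbitration steps; both are optional.
    """
    maps = {m.map_id: m for m in consensus_maps}
    contig_maps = {
        cid: digest_sequence(seq, digestion_params, cid) for cid, seq in contig_sequences.items()
    }
    alignments = align_all(list(contig_maps.values()), consensus_maps, alignment_params)
    strict = filter_dominated_alignments([a for a in alignments if a.tier == "strict"])
    conflicts = detect_conflicts(strict, maps, contig_maps, conflict_params.min_overhang_sites)
    relaxed_conflicts = detect_conflicts(
        filter_dominated_alignments(alignments), maps, contig_maps,
        conflict_params.min_overhang_sites,
    )
    alt_alignments = None
    if alt_contig_sequences:
        alt_maps = [
            digest_sequence(seq, digestion_params, cid)
            for cid, seq in alt_contig_sequences.items()
        ]
        alt_alignments = [
            a for a in align_all(alt_maps, consensus_maps, alignment_params) if a.tier == "strict"
        ]

    contig_bps, map_bps = [], []
    for c in conflicts:
        arbitrate_conflict(c, conflicts, relaxed_conflicts, alt_alignments, hic_evidence, conflict_params)
        for bp in place_breakpoints(c, maps, contig_maps, conflict_params):
            (contig_bps if bp.object_kind == "contig" else map_bps).append(bp)

    new_contigs, lineage = break_objects(dict(contig_sequences), contig_bps, conflict_params)
    new_maps, _ = break_objects(dict(maps), map_bps, conflict_params)

    new_contig_maps = {
        cid: digest_sequence(seq, digestion_params, cid) for cid, seq in new_contigs.items()
    }
    strict2 = [
        a
        for a in align_all(
            list(new_contig_maps.values()), list(new_maps.values()), alignment_params
        )
        if a.tier == "strict"
    ]
    lengths = {cid: len(seq) for cid, seq in new_contigs.items()}
    scaffolds, unplaced = hybrid_scaffold(
        lengths, new_contig_maps, new_maps, strict2, scaffold_params
    )
    seqs = scaffolds_to_fasta(scaffolds, new_contigs)
    return PipelineResult(
        scaffolds=scaffolds,
        scaffold_sequences=seqs,
        fragment_sequences=new_contigs,
        lineage=lineage,
        broken_maps=new_maps,
        conflicts=conflicts,
        breakpoints=contig_bps + map_bps,
        unplaced=unplaced,
    )
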