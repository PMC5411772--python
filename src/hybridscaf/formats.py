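"""Readers and writers for the tool's tabular interchange formats.

FASTA goes through Biopython; CMAP lives next to the digestion code; here are
AGP v2.1, the XMAP-inspired alignment table, the pairs/markers TSVs and BED
output for misassembly regions, plus the per-run manifest.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alignment import MapAlignment
from .qc import MARKER_COLUMNS, PAIR_COLUMNS, MisassemblyRegion
from .scaffolding import Scaffold, scaffolds_to_agp

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_lengths",
    "write_agp",
    "read_pairs",
    "write_pairs",
    "read_markers",
    "write_markers",
    "write_regions_bed",
    "write_alignments",
    "write_manifest",
]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path, width: int = 80) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_lengths(path) -> list[int]:
    """One positive integer per line (blank lines and # comments skipped)."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(int(line))
    return out


_AGP_HEADER = "##agp-version\t2.1\n"


def write_agp(scaffolds: list[Scaffold], path) -> None:
    with open(path, "w") as fh:
        fh.write(_AGP_HEADER)
        for row in scaffolds_to_agp(scaffolds):
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_pairs(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PAIR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pairs table missing columns: {sorted(missing)}")
    return df


def write_pairs(pairs: pd.DataFrame, path) -> None:
    pairs.to_csv(path, sep="\t", index=False)


def read_markers(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(MARKER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"marker table missing columns: {sorted(missing)}")
    return df


def write_markers(markers: pd.DataFrame, path) -> None:
    markers.to_csv(path, sep="\t", index=False)


def write_regions_bed(regions: list[MisassemblyRegion], path) -> None:
    """Misassembly regions as BED (0-based half-open, evidence in name)."""
    with open(path, "w") as fh:
        for r in sorted(regions, key=lambda r: (r.contig_id, r.start)):
            name = f"{r.evidence};support={r.support_count};groups={','.join(r.groups)}"
            fh.write(f"{r.contig_id}\t{max(r.start - 1, 0)}\t{r.end}\t{name}\n")


_ALN_COLUMNS = [
    "query_id", "ref_id", "orientation", "score", "tier",
    "query_start", "query_end", "ref_start", "ref_end", "n_pairs", "pairs",
]


def write_alignments(alignments: list[MapAlignment], path) -> None:
    """XMAP-inspired tab table; 'pairs' is comma-joined qidx:ridx (0-based)."""
    rows = [
        (
            a.query_id, a.ref_id, a.orientation, round(a.score, 4), a.tier,
            a.query_span[0], a.query_span[1], a.ref_span[0], a.ref_span[1],
            a.n_pairs, ",".join(f"{q}:{r}" for q, r in a.pairs),
        )
        for a in alignments
    ]
    pd.DataFrame(rows, columns=_ALN_COLUMNS).to_csv(path, sep="\t", index=False)


def write_manifest(path, command: str, params: dict, seed: int | None, inputs: list) -> None:
    """Machine-readable run manifest: parameters, seed, input checksums."""
    checksums = {}
    for p in inputs:
        p = Path(p)
        if p.is_file():
            checksums[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {"command": command, "parameters": params, "seed": seed, "input_sha256": checksums}
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
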