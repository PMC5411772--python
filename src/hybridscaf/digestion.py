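"""In-silico restriction-map digestion and CMAP interchange I/O.

A *restriction map* is the ordered list of label (nick) site positions on a
molecule of known length.  Optical platforms observe these maps directly from
single molecules; here the same representation is computed from sequence by
motif search ("in-silico digestion"), so sequence contigs/scaffolds and optical
consensus maps live in one coordinate language and can be aligned to each
other.

Coordinate convention: internal computation is 0-based half-open; every
emitted file (CMAP and friends) is 1-based, the platform convention.  A site
position is the 1-based coordinate of the first base of the recognition-motif
occurrence, always reported on the forward strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "DigestionParams",
    "RestrictionMap",
    "digest_sequence",
    "read_cmap",
    "write_cmap",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: recognition sequence of the nicking endonuclease Nt.BspQI
BSPQI_MOTIF = "GCTCTTC"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DigestionParams:
    """Parameters of an in-silico digestion.

    motif
        Recognition sequence (uppercase ACGT), default Nt.BspQI (GCTCTTC).
    both_strands
        Report occurrences of the reverse-complement motif too (platform
        convention for nicking enzymes labelling either strand).
    merge_resolution_bp
        Collapse runs of sites closer than this to their midpoint; 0 disables.
        Real instruments cannot resolve nearby labels, but merging defaults
        off so digestion is a pure function of the sequence.
    """

    motif: str = BSPQI_MOTIF
    both_strands: bool = True
    merge_resolution_bp: int = 0

    def __post_init__(self) -> None:
        if not self.motif or set(self.motif) - set("ACGT"):
            raise ValueError(f"motif must be non-empty uppercase ACGT: {self.motif!r}")
        if self.merge_resolution_bp < 0:
            raise ValueError("merge_resolution_bp must be >= 0")


@dataclass
class RestrictionMap:
    """Ordered label positions on a molecule of known length.

    ``sites`` are 1-based, strictly increasing, within ``[1, length_bp]``.
    ``source`` records provenance: an optical ``consensus`` map or an
    in-silico digest of a contig or scaffold.
    """

    map_id: str
    length_bp: int
    sites: list[int] = field(default_factory=list)
    source: str = "insilico_contig"

    _SOURCES = ("consensus", "insilico_contig", "insilico_scaffold")

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.length_bp < 0:
            raise ValueError(f"{self.map_id}: negative length")
        if self.source not in self._SOURCES:
            raise ValueError(f"{self.map_id}: unknown source {self.source!r}")
        prev = 0
        for s in self.sites:
            if s <= prev:
                raise ValueError(f"{self.map_id}: sites not strictly increasing at {s}")
            prev = s
        if self.sites and self.sites[-1] > self.length_bp:
            raise ValueError(
                f"{self.map_id}: site {self.sites[-1]} beyond length {self.length_bp}"
            )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def reversed(self) -> "RestrictionMap":
        """Mirror the map (positions counted from the other end)."""
        sites = [self.length_bp - s + 1 for s in reversed(self.sites)]
        return replace(self, sites=sites)


def _find_occurrences(seq: str, motif: str) -> list[int]:
    """0-based start positions of exact motif matches (N never matches)."""
    out = []
    start = seq.find(motif)
    while start != -1:
        out.append(start)
        start = seq.find(motif, start + 1)
    return out


def _merge_close_sites(sites: list[int], resolution_bp: int) -> list[int]:
    if resolution_bp <= 0 or len(sites) < 2:
        return sites
    merged: list[int] = []
    run = [sites[0]]
    for s in sites[1:]:
        if s - run[-1] < resolution_bp:
            run.append(s)
        else:
            merged.append((run[0] + run[-1]) // 2)
            run = [s]
    merged.append((run[0] + run[-1]) // 2)
    return merged


def digest_sequence(
    seq: str,
    params: DigestionParams = DigestionParams(),
    map_id: str = "map",
    source: str = "insilico_contig",
) -> RestrictionMap:
    """In-silico digest of ``seq`` (may contain N) into a RestrictionMap.

    Returns every forward-strand occurrence of the motif and, with
    ``both_strands``, every occurrence of its reverse complement, both
    reported at the forward-strand start of the matched word (1-based).
    N bases contribute to the length but never to a site.
    """
    if len(seq) < 1:
        raise ValueError("empty sequence")
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")
    starts = set(_find_occurrences(seq, params.motif))
    if params.both_strands:
        rc = reverse_complement(params.motif)
        if rc != params.motif:
            starts.update(_find_occurrences(seq, rc))
    sites = [p + 1 for p in sorted(starts)]
    sites = _merge_close_sites(sites, params.merge_resolution_bp)
    return RestrictionMap(map_id=map_id, length_bp=len(seq), sites=sites, source=source)


# ---------------------------------------------------------------------------
# CMAP v0.1 interchange format
# ---------------------------------------------------------------------------

_CMAP_HEADER = """\
# CMAP File Version:\t0.1
# Label Channels:\t1
# Nickase Recognition Site 1:\tunknown
# Number of Consensus Maps:\t{n}
#h CMapId\tContigLength\tNumSites\tSiteID\tLabelChannel\tPosition\tStdDev\tCoverage\tOccurrence
#f int\tfloat\tint\tint\tint\tfloat\tfloat\tfloat\tfloat
"""


def write_cmap(maps: list[RestrictionMap], path) -> None:
    """Write maps in the tabular CMAP v0.1 dialect.

    One row per label plus a terminal channel-0 row carrying the map length.
    Map ids are written verbatim (the dialect nominally uses integer ids; any
    token without whitespace round-trips here).
    """
    for m in maps:
        m.validate()
    with open(path, "w") as fh:
        fh.write(_CMAP_HEADER.format(n=len(maps)))
        for m in maps:
            n = m.n_sites
            for i, pos in enumerate(m.sites, start=1):
                fh.write(
                    f"{m.map_id}\t{m.length_bp:.1f}\t{n}\t{i}\t1\t{pos:.1f}\t1.0\t1.0\t1.0\n"
                )
            fh.write(
                f"{m.map_id}\t{m.length_bp:.1f}\t{n}\t{n + 1}\t0\t{m.length_bp:.1f}\t0.0\t1.0\t0.0\n"
            )


class CmapParseError(ValueError):
    pass


def read_cmap(path, source: str = "consensus") -> list[RestrictionMap]:
    """Read a CMAP v0.1 file; inverse of :func:`write_cmap`.

    Raises :class:`CmapParseError` naming the offending line on malformed
    rows, unsorted positions, or positions beyond the declared length.
    """
    maps: dict[str, RestrictionMap] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise CmapParseError(f"line {lineno}: expected >=6 columns, got {len(fields)}")
            try:
                map_id = fields[0]
                length = int(float(fields[1]))
                channel = int(fields[4])
                pos = int(float(fields[5]))
            except ValueError as e:
                raise CmapParseError(f"line {lineno}: {e}") from None
            m = maps.get(map_id)
            if m is None:
                m = maps[map_id] = RestrictionMap(map_id, length, [], source=source)
            if channel == 0:
                if pos != m.length_bp:
                    raise CmapParseError(
                        f"line {lineno}: terminal row position {pos} != declared length {m.length_bp}"
                    )
                continue
            if pos > m.length_bp:
                raise CmapParseError(
                    f"line {lineno}: site position {pos} exceeds declared length {m.length_bp}"
                )
            if m.sites and pos <= m.sites[-1]:
                raise CmapParseError(f"line {lineno}: unsorted site position {pos}")
            m.sites.append(pos)
    for m in maps.values():
        m.validate()
    return list(maps.values())
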