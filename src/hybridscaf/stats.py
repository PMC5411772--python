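"""Assembly contiguity statistics: N50/L50 and chromosome-normalized CN50/CL50.

N50/L50 conflate assembly quality with chromosome number once an assembly
approaches chromosome-arm contiguity: even a perfect assembly of n
chromosomes has L50 around n/2.  CN50/CL50 normalise for this by dealing the
length-sorted contigs into n sets in serpentine (boustrophedon) order —
set 1..n, then n..1, and so on — computing each set's N50 contig, and
summarising the selected contigs by their median length (CN50) and the
within-set rank of the median contig (CL50).  With one chromosome the
statistic reduces exactly to N50/L50, and CL50 can reach its optimum of 1
regardless of chromosome number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

log = logging.getLogger(__name__)

__all__ = ["ContiguityReport", "n50_l50", "cn50_cl50", "contiguity_report", "serpentine_sets"]


@dataclass
class ContiguityReport:
    n50: int
    l50: int
    cn50: int
    cl50: int
    total_bp: int
    count: int
    n_chromosomes: int


def _check(lengths) -> list[int]:
    lengths = [int(x) for x in lengths]
    if not lengths:
        raise ValueError("empty length list")
    if any(x <= 0 for x in lengths):
        raise ValueError("lengths must be positive")
    return lengths


def n50_l50(lengths) -> tuple[int, int]:
    """Classic N50 and its 1-based rank L50 (cumulative half-total scan)."""
    lengths = sorted(_check(lengths), reverse=True)
    half = sum(lengths) / 2.0
    acc = 0
    for rank, x in enumerate(lengths, start=1):
        acc += x
        if acc >= half:
            return x, rank
    raise AssertionError("unreachable")


def serpentine_sets(lengths, n_chromosomes: int) -> list[list[int]]:
    """Deal descending-sorted lengths into n sets in boustrophedon order.

    The longest contig goes to set 1, the second to set 2, ..., the n-th to
    set n, the (n+1)-th to set n again, the (n+2)-th to set n-1, and so on.
    """
    if n_chromosomes < 1:
        raise ValueError("n_chromosomes must be >= 1")
    ordered = sorted(_check(lengths), reverse=True)
    sets: list[list[int]] = [[] for _ in range(n_chromosomes)]
    for k, x in enumerate(ordered):
        r, p = divmod(k, n_chromosomes)
        idx = p if r % 2 == 0 else n_chromosomes - 1 - p
        sets[idx].append(x)
    return sets


def cn50_cl50(lengths, n_chromosomes: int, median_rule: str = "lower") -> tuple[int, int]:
    """Chromosome-normalized N50/L50.

    Within each serpentine set the N50 contig is selected (first rank at
    which the cumulative set length reaches half the set total); CN50 is the
    median of the selected contigs' lengths and CL50 the within-set rank of
    the CN50 contig.  With an even number of sets the lower median is used by
    default so CN50 is always a real contig length and CL50 well defined;
    ``median_rule='midpoint'`` averages the two central lengths for CN50
    while CL50 still follows the lower-median contig.  Ties between equal
    selected lengths resolve to the smallest rank.  Empty sets (more
    chromosomes than contigs) are excluded from the median with a warning.
    """
    sets = serpentine_sets(lengths, n_chromosomes)
    selected: list[tuple[int, int]] = []  # (length, within-set rank)
    n_empty = 0
    for s in sets:
        if not s:
            n_empty += 1
            continue
        half = sum(s) / 2.0
        acc = 0
        for rank, x in enumerate(s, start=1):
            acc += x
            if acc >= half:
                selected.append((x, rank))
                break
    if n_empty:
        log.warning("%d of %d chromosome sets empty; excluded from CN50 median", n_empty, n_chromosomes)
    by_len = sorted(selected, key=lambda t: t[0])
    k = len(by_len)
    lower = by_len[(k - 1) // 2][0]
    if median_rule == "lower" or k % 2 == 1:
        cn50 = lower
    elif median_rule == "midpoint":
        cn50 = (lower + by_len[k // 2][0]) / 2
    else:
        raise ValueError(f"unknown median_rule {median_rule!r}")
    cl50 = min(rank for length, rank in selected if length == lower)
    return cn50, cl50


def contiguity_report(lengths, n_chromosomes: int) -> ContiguityReport:
    lengths = _check(lengths)
    n50, l50 = n50_l50(lengths)
    cn50, cl50 = cn50_cl50(lengths, n_chromosomes)
    return ContiguityReport(
        n50=n50,
        l50=l50,
        cn50=cn50,
        cl50=cl50,
        total_bp=sum(lengths),
        count=len(lengths),
        n_chromosomes=n_chromosomes,
    )
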