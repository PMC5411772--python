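"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by the most literal method available
(full enumeration, direct scans, explicit set construction) and stay
independent of the library code paths they check.
"""

from __future__ import annotations

import math


def scan_motif_positions(seq: str, motif: str, both_strands: bool = True) -> list[int]:
    """1-based motif occurrence positions by scanning every offset."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    rc = "".join(comp[b] for b in reversed(motif))
    words = {motif, rc} if both_strands else {motif}
    hits = set()
    for i in range(len(seq) - len(motif) + 1):
        if seq[i : i + len(motif)] in words:
            hits.add(i + 1)
    return sorted(hits)


def n50_l50_scan(lengths) -> tuple[int, int]:
    """Cumulative re-scan N50/L50."""
    ordered = sorted(lengths, reverse=True)
    total = sum(ordered)
    acc = 0
    for rank, x in enumerate(ordered, 1):
        acc += x
        if 2 * acc >= total:
            return x, rank


def cn50_cl50_brute(lengths, n: int):
    """Literal set construction: serpentine deal, per-set cumulative scan,
    median of selected contigs (lower median), rank of the median contig."""
    ordered = sorted(lengths, reverse=True)
    # serpentine deal: 1..n then n..1 (edge sets repeated at each turn)
    sets = [[] for _ in range(n)]
    for pos, x in enumerate(ordered):
        r, p = divmod(pos, n)
        sets[p if r % 2 == 0 else n - 1 - p].append(x)
    chosen = []  # (length, rank)
    for s in sets:
        if not s:
            continue
        total = sum(s)
        acc = 0
        for rank, x in enumerate(s, 1):
            acc += x
            if 2 * acc >= total:
                chosen.append((x, rank))
                break
    by_len = sorted(c[0] for c in chosen)
    cn50 = by_len[(len(by_len) - 1) // 2]
    cl50 = min(rank for length, rank in chosen if length == cn50)
    return cn50, cl50


def enumerate_best_alignment(q_sites, r_sites, params, max_skips: int = None):
    """Exhaustive enumeration over all monotone pairings, both orientations.

    Returns (score, n_pairs, orientation) of the optimum with ties broken by
    more pairs, then orientation '+'.  Scoring follows the published chunk
    formula literally.
    """
    K = (max_skips if max_skips is not None else params.max_consecutive_skips) + 1
    best = [float("-inf"), 0, "+"]

    def chunk(qlen, rlen, qskip, rskip):
        sd = params.sizing_sd_coeff * math.sqrt(max(rlen, params.min_interval_bp))
        return (
            params.match_reward
            - 0.5 * ((qlen - rlen) / sd) ** 2
            - params.false_penalty * qskip
            - params.miss_penalty * rskip
        )

    def consider(score, npairs, orient):
        if (score, npairs, orient == "+") > (best[0], best[1], best[2] == "+"):
            best[0], best[1], best[2] = score, npairs, orient

    for orient in ("+", "-"):
        q = q_sites if orient == "+" else [q_sites[-1] + q_sites[0] - s for s in reversed(q_sites)]
        m, n = len(q), len(r_sites)

        def extend(i, j, score, npairs):
            consider(score, npairs, orient)
            for di in range(1, K + 1):
                for dj in range(1, K + 1):
                    ni, nj = i + di, j + dj
                    if ni < m and nj < n:
                        extend(
                            ni,
                            nj,
                            score
                            + chunk(q[ni] - q[i], r_sites[nj] - r_sites[j], di - 1, dj - 1),
                            npairs + 1,
                        )

        for i in range(m):
            for j in range(n):
                extend(i, j, params.match_reward, 1)
    return best[0], best[1], best[2]
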