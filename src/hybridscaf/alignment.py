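"""Dynamic-programming alignment of restriction maps.

Two maps are aligned through their *interval patterns*: consecutive matched
label pairs define chunks whose query/reference lengths must agree up to the
platform sizing error, which grows with the square root of the interval
length.  The score of an alignment is a sum of Gaussian log-likelihood-style
chunk rewards minus fixed penalties for labels skipped inside the aligned
span (missing labels on the reference, false labels on the query).  Alignments
are local: unaligned overhangs at either end are free, and are exactly what
downstream conflict detection inspects.

Significance is expressed as two stringency *tiers* (strict/relaxed) given by
score thresholds.  The shipped defaults come from a seeded Monte-Carlo null
calibration (:func:`calibrate_tiers`) at empirical false-discovery targets of
1e-3 (strict) and 1e-2 (relaxed); rerun the calibration if your maps have a
very different label density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .digestion import RestrictionMap

__all__ = [
    "AlignmentParams",
    "MapAlignment",
    "align_maps",
    "align_all",
    "calibrate_tiers",
    "chunk_score",
]

NEG_INF = float("-inf")


@dataclass
class AlignmentParams:
    """Scoring and significance parameters for map-to-map alignment.

    sizing_sd_coeff
        Standard deviation of the interval-length error is
        ``coeff * sqrt(interval_bp)``; the default 0.79 corresponds to a
        250 bp sd on a 100 kb interval, a typical nick-map error scale.
    match_reward
        Constant reward per matched label pair (before the sizing term).
    miss_penalty / false_penalty
        Cost per unmatched reference / query label inside the aligned span.
    max_consecutive_skips
        At most this many labels may be skipped on either side between two
        consecutive matched pairs.
    min_interval_bp
        Floor on the interval length used in the sizing sd, so that near-zero
        intervals do not produce infinite penalties.
    tier_thresholds
        Minimum score per significance tier; ``strict >= relaxed`` required.
    """

    sizing_sd_coeff: float = 0.79
    match_reward: float = 3.0
    miss_penalty: float = 1.0
    false_penalty: float = 1.0
    max_consecutive_skips: int = 3
    min_interval_bp: float = 500.0
    tier_thresholds: dict = field(
        default_factory=lambda: {"strict": 17.4, "relaxed": 14.4}
    )

    def __post_init__(self) -> None:
        if self.miss_penalty <= 0 or self.false_penalty <= 0:
            raise ValueError("penalties must be > 0")
        if self.max_consecutive_skips < 0:
            raise ValueError("max_consecutive_skips must be >= 0")
        t = self.tier_thresholds
        if set(t) != {"strict", "relaxed"} or t["strict"] < t["relaxed"]:
            raise ValueError("tier_thresholds needs strict >= relaxed")


@dataclass
class MapAlignment:
    """A monotone pairing of query labels to reference labels.

    ``pairs`` holds ``(query_site_index, ref_site_index)`` in original (0-based)
    site indices, ordered by increasing reference index; for orientation '-'
    the query indices decrease along the list.  Spans are 1-based inclusive
    bp intervals on each object.
    """

    query_id: str
    ref_id: str
    orientation: str  # '+' or '-'
    pairs: list[tuple[int, int]]
    score: float
    tier: str = "none"  # strict | relaxed | none
    query_span: tuple[int, int] = (0, 0)
    ref_span: tuple[int, int] = (0, 0)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def query_indices(self) -> list[int]:
        return [q for q, _ in self.pairs]

    def ref_indices(self) -> list[int]:
        return [r for _, r in self.pairs]


def chunk_score(
    q_len: float, r_len: float, n_query_skipped: int, n_ref_skipped: int, params: AlignmentParams
) -> float:
    """Score of one matched chunk: Gaussian sizing term minus skip penalties."""
    sd = params.sizing_sd_coeff * math.sqrt(max(r_len, params.min_interval_bp))
    return (
        params.match_reward
        - 0.5 * ((q_len - r_len) / sd) ** 2
        - params.false_penalty * n_query_skipped
        - params.miss_penalty * n_ref_skipped
    )


def score_pairing(
    q_pos: np.ndarray, r_pos: np.ndarray, pairs: list[tuple[int, int]], params: AlignmentParams
) -> float:
    """Score a given monotone pairing (indices into q_pos/r_pos)."""
    if not pairs:
        return NEG_INF
    score = params.match_reward
    for (qi0, ri0), (qi1, ri1) in zip(pairs, pairs[1:]):
        score += chunk_score(
            q_pos[qi1] - q_pos[qi0],
            r_pos[ri1] - r_pos[ri0],
            qi1 - qi0 - 1,
            ri1 - ri0 - 1,
            params,
        )
    return score


def _dp_align(
    q_pos: np.ndarray,
    r_pos: np.ndarray,
    params: AlignmentParams,
    q_mask: np.ndarray | None = None,
):
    """Best local chain; returns (score, n_pairs, pairs) or None.

    Vectorised over the reference axis.  ``q_mask`` marks query sites that
    may not be matched (already consumed by a previously reported alignment);
    masked sites still count as skipped sites in the penalties.
    """
    m, n = len(q_pos), len(r_pos)
    if m < 2 or n < 2:
        return None
    K = params.max_consecutive_skips + 1
    S = np.full((m, n), params.match_reward)
    P = np.ones((m, n), dtype=np.int32)  # matched pairs in best chain ending here
    BI = np.full((m, n), -1, dtype=np.int32)
    BJ = np.full((m, n), -1, dtype=np.int32)
    if q_mask is not None:
        S[q_mask, :] = NEG_INF

    coeff = params.sizing_sd_coeff
    min_iv = params.min_interval_bp
    # precompute ref interval terms per dj
    r_terms = {}
    for dj in range(1, K + 1):
        if dj >= n:
            break
        rlen = r_pos[dj:] - r_pos[:-dj]
        sd = coeff * np.sqrt(np.maximum(rlen, min_iv))
        r_terms[dj] = (rlen, sd)

    base = params.match_reward
    for i in range(1, m):
        if q_mask is not None and q_mask[i]:
            continue
        row_s = S[i]
        row_p = P[i]
        row_bi = BI[i]
        row_bj = BJ[i]
        for di in range(1, min(K, i) + 1):
            prev_s = S[i - di]
            prev_p = P[i - di]
            qlen = q_pos[i] - q_pos[i - di]
            fp = params.false_penalty * (di - 1)
            for dj, (rlen, sd) in r_terms.items():
                cs = base - 0.5 * ((qlen - rlen) / sd) ** 2 - fp - params.miss_penalty * (dj - 1)
                cand = prev_s[:-dj] + cs
                cand_p = prev_p[:-dj] + 1
                cur_s = row_s[dj:]
                cur_p = row_p[dj:]
                upd = (cand > cur_s) | ((cand == cur_s) & (cand_p > cur_p))
                if upd.any():
                    idx = np.nonzero(upd)[0] + dj
                    row_s[idx] = cand[upd]
                    row_p[idx] = cand_p[upd]
                    row_bi[idx] = i - di
                    row_bj[idx] = idx - dj
    # pick best cell: score, then more pairs, then smaller ref index
    flat = S.ravel()
    best = flat.max()
    if not np.isfinite(best):
        return None
    cand = np.nonzero(flat >= best - 1e-12)[0]
    if len(cand) > 1:
        pairs_at = P.ravel()[cand]
        cand = cand[pairs_at == pairs_at.max()]
        # smaller ref start: traceback each? use smaller ref index of end as proxy,
        # then smaller query index — deterministic.
        cand = cand[np.argsort(cand % n, kind="stable")]
    ci = int(cand[0])
    i, j = divmod(ci, n)
    pairs = []
    while i >= 0:
        pairs.append((i, j))
        i, j = int(BI[pairs[-1][0], pairs[-1][1]]), int(BJ[pairs[-1][0], pairs[-1][1]])
        if i < 0:
            break
    pairs.reverse()
    return float(best), len(pairs), pairs


def _assign_tier(score: float, params: AlignmentParams) -> str:
    if score >= params.tier_thresholds["strict"]:
        return "strict"
    if score >= params.tier_thresholds["relaxed"]:
        return "relaxed"
    return "none"


def align_maps(
    query: RestrictionMap,
    ref: RestrictionMap,
    params: AlignmentParams = AlignmentParams(),
    max_alignments: int = 4,
    min_tier: str = "relaxed",
) -> list[MapAlignment]:
    """All local alignments of ``query`` to ``ref`` reaching a tier.

    Both orientations are tried; non-overlapping (in query labels) alignments
    are reported independently, best first.  Ties prefer more matched pairs,
    then the smaller reference start, then orientation '+'.  Maps with fewer
    than two labels yield no alignments.
    """
    q = np.asarray(query.sites, dtype=float)
    r = np.asarray(ref.sites, dtype=float)
    if len(q) < 2 or len(r) < 2:
        return []
    floor = params.tier_thresholds["relaxed" if min_tier == "relaxed" else "strict"]
    m = len(q)
    q_rev = np.asarray(query.reversed().sites, dtype=float)

    out: list[MapAlignment] = []
    q_mask = np.zeros(m, dtype=bool)
    while len(out) < max_alignments:
        cands = []
        for orient in ("+", "-"):
            qq = q if orient == "+" else q_rev
            mask = q_mask if orient == "+" else q_mask[::-1]
            res = _dp_align(qq, r, params, q_mask=mask if q_mask.any() else None)
            if res is None:
                continue
            score, npairs, pairs = res
            cands.append((score, npairs, orient, pairs))
        if not cands:
            break
        # best score, then more pairs, then '+'
        cands.sort(key=lambda c: (-c[0], -c[1], c[2] != "+"))
        score, npairs, orient, pairs = cands[0]
        if score < floor:
            break
        if orient == "-":
            # map oriented indices back to original query indices
            pairs = [(m - 1 - qi, ri) for qi, ri in pairs]
        q_idx = [qi for qi, _ in pairs]
        r_idx = [ri for _, ri in pairs]
        aln = MapAlignment(
            query_id=query.map_id,
            ref_id=ref.map_id,
            orientation=orient,
            pairs=pairs,
            score=score,
            tier=_assign_tier(score, params),
            query_span=(query.sites[min(q_idx)], query.sites[max(q_idx)]),
            ref_span=(ref.sites[min(r_idx)], ref.sites[max(r_idx)]),
        )
        out.append(aln)
        for qi in q_idx:
            q_mask[qi] = True
        if q_mask.sum() > m - 2:
            break
    return out


def align_all(
    queries: list[RestrictionMap],
    refs: list[RestrictionMap],
    params: AlignmentParams = AlignmentParams(),
    min_tier: str = "relaxed",
) -> list[MapAlignment]:
    """Align every query against every reference; pooled result list."""
    out: list[MapAlignment] = []
    for q in queries:
        for r in refs:
            if q.map_id == r.map_id:
                continue
            out.extend(align_maps(q, r, params, min_tier=min_tier))
    return out


def calibrate_tiers(
    params: AlignmentParams,
    n_null: int = 2000,
    seed: int = 0,
    reference_panel: list[RestrictionMap] | None = None,
    site_density_per_bp: float = 1.0 / 2000.0,
    query_length_bp: int = 60_000,
    fdr_targets: tuple[float, float] = (1e-3, 1e-2),
) -> dict:
    """Empirical tier thresholds from a Monte-Carlo null.

    Simulates ``n_null`` random Poisson label patterns of the given density,
    records each one's best alignment score against a fixed reference panel
    (simulated from the same density when not supplied), and returns
    ``{'strict': q(1 - fdr_strict), 'relaxed': q(1 - fdr_relaxed)}`` of the
    null score distribution.  Deterministic given ``seed``.
    """
    if n_null < 1000:
        raise ValueError("n_null must be >= 1000")
    strict_fdr, relaxed_fdr = fdr_targets
    if n_null * strict_fdr < 1:
        raise ValueError(
            f"n_null={n_null} too small for strict target {strict_fdr} (need >= {int(1 / strict_fdr)})"
        )
    rng = np.random.default_rng(seed)

    def _poisson_map(map_id: str, length: int) -> RestrictionMap:
        k = rng.poisson(length * site_density_per_bp)
        sites = np.unique(rng.integers(1, length + 1, size=max(k, 2)))
        return RestrictionMap(map_id, length, [int(s) for s in sites], source="consensus")

    if reference_panel is None:
        reference_panel = [_poisson_map(f"null_ref_{i}", 300_000) for i in range(5)]
    scores = np.empty(n_null)
    relaxed = min(params.tier_thresholds.values())
    loose = replace(params, tier_thresholds={"strict": relaxed, "relaxed": -1e18})
    for i in range(n_null):
        q = _poisson_map(f"null_q_{i}", query_length_bp)
        best = NEG_INF
        for ref in reference_panel:
            alns = align_maps(q, ref, loose, max_alignments=1)
            if alns:
                best = max(best, alns[0].score)
        scores[i] = best if np.isfinite(best) else 0.0
    return {
        "strict": float(np.quantile(scores, 1 - strict_fdr)),
        "relaxed": float(np.quantile(scores, 1 - relaxed_fdr)),
    }
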