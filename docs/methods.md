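# Methods

This note documents the models, parameter choices and numerical conventions
behind `hybridscaf`, and what the simulator-based tests do and do not show
about real data.

## Coordinates and formats

Internal computation uses 0-based half-open intervals; every emitted file
(CMAP v0.1, AGP v2.1, the XMAP-inspired alignment table, BED for regions)
uses the 1-based conventions of its format. A restriction-map label position
is the 1-based coordinate of the first base of the motif occurrence,
reported on the forward strand regardless of which strand matched. Motif
occurrences overlapping N bases cannot match and are therefore never
reported; N runs contribute to map length only.

## In-silico digestion

The default motif is the Nt.BspQI recognition sequence `GCTCTTC`, searched
on both strands (`both_strands=True`, the platform convention for nicking
enzymes; configurable because single-strand digests are conceivable).
Deduplication of palindromic double counts is applied even though this motif
is not palindromic. `merge_resolution_bp` (default 0 = off) collapses label
runs closer than the given resolution to their midpoint; real instruments
cannot resolve nearby labels, but merging defaults off so digestion is a
pure function of sequence.

## Map alignment

Two maps are aligned through inter-label interval patterns by local dynamic
programming. A chunk joining matched pair *(i′, j′)* to *(i, j)* scores

    match_reward − (δq − δr)²/(2 σ(δr)²)
                 − false_penalty·(i − i′ − 1) − miss_penalty·(j − j′ − 1)

with sizing sd σ(δr) = `sizing_sd_coeff`·√max(δr, `min_interval_bp`). The
√-length scaling is the standard optical sizing-error model; the default
coefficient 0.79 corresponds to a 250 bp sd on a 100 kb interval. The
interval floor (500 bp) prevents near-zero intervals from dominating the
penalty. Defaults: match_reward 3, miss = false = 1, at most 3 consecutive
skips per side. Alignments are local (free end gaps); the unaligned
overhangs are the object of conflict detection, not an error to penalise.
Ties between equal scores prefer more matched pairs, then the smaller
reference start, then '+' orientation. Multiple non-overlapping alignments
per map pair are reported by masking the query labels of each accepted
alignment and re-running (up to 4).

**Significance tiers.** The original workflow used an aligner with two
P-value cutoffs (an initial strict set and a relaxed set for arbitration);
that P-value model is proprietary, so tiers are expressed as score
thresholds calibrated as empirical quantiles of a seeded Monte-Carlo null
(`calibrate_tiers`): random Poisson label patterns aligned against a fixed
reference panel, thresholds at the 1−10⁻³ (strict) and 1−10⁻² (relaxed)
quantiles of the best-score distribution. Because the null maximum grows
with the number of comparisons, calibration should use a panel comparable
to the intended workload. The shipped defaults (strict 17.4, relaxed 14.4)
come from one seeded run (`n_null=1000, seed=0`) with 40 kb queries against
eighteen 350 kb references at the package's default label density (one per
2 kb); recalibrate for substantially different densities or panel sizes.

## Conflict detection and arbitration

A conflict is an alignment terminus with at least `min_overhang_sites`
(default 5 — a customary evidence floor; the source workflow does not
quantify it) unaligned labels beyond it on *both* objects. Two alignments of
different maps claiming overlapping contig regions with incompatible
extensions reduce to the same per-terminus test and are de-duplicated.

Before conflicts are sought, *dominated* alignments are removed: an
alignment whose contig span is ≥ 80% covered by another alignment of the
same contig scoring more than twice as high is a chance or repeat hit.
This matters because consensus-map windows overlap — a chance hit
replicates across the windows of one locus and would otherwise corroborate
itself into a contig conviction. Genuinely corroborating maps of one locus
score comparably and are never dominated.

Arbitration is a fixed-order decision tree: (1) a second strict-tier
conflict at the same contig region (junctions within `same_region_bp`,
default 50 kb) convicts the contig; at the same map region, the map;
(2) the same test on relaxed-tier conflicts; (3) if a contig of an
alternate assembly aligns cleanly across the focal map's junction the
contig is convicted, and if it reproduces the conflict the map is;
(4) proximity-ligation spanning-signal evidence overlapping the contig
junction convicts the contig; (5) otherwise both objects are cut. Verdict
"both" splits map *and* contig deliberately — the conservative alternative
(dropping the alignment) leaves the putative misassembly in place.

**Breakpoints** sit at ⌊(last aligned + first unaligned)/2⌋ on each
convicted object, moved to the midpoint of an unmatched ≥ 2-label indel
block when one lies within `adjust_window_bp` (50 kb; "close" is otherwise
undefined). A terminus flush with the object end yields no cut. Candidate
cuts on one object are clustered at `min_fragment_bp` (20 kb, preventing
unalignable slivers); each cluster is represented by the position supported
by the most conflicts, then the highest total alignment score. This
support-weighted choice matters: a chain that chance-extends one or two
labels across a true junction shifts its implied cut by several kb, and the
junction corroborated from both flanks must outvote it.

## Hybrid scaffolding

Per consensus map, aligned contigs are ordered by the map interval their
whole length would occupy (alignment span widened by the unaligned tails)
and oriented by alignment orientation. Contigs whose implied span is
contained in another's go to the unplaced set. A contig with strict
alignments to two maps (best few placements per contig, default 2) stitches
those maps: layouts are merged when one's suffix equals the other's prefix
(ids + orientations, after possibly mirroring one layout), otherwise the
lower-scoring placement of the offending contig is discarded — score, then
longer alignment, then lexicographic id, for determinism.

Gap between neighbours = (map distance between the flanking matched labels)
− (left contig's tail from its label through its end) − (right contig's
head before its label). Estimates below `min_gap_bp` clamp to 13 — the AGP
sentinel for "adjacent, size unknown" — and are flagged (AGP gap_type
`scaffold`, linkage `yes`). Scaffold FASTA writes gaps as N runs;
proximity-ligation joins always write 100 N because insert sizes make those
gaps unestimable.

**Iterative integration** digests scaffold set B into in-silico maps,
aligns set A's digests to them, resolves conflicts (breaking A sequences
and/or B maps), and re-scaffolds the surviving A fragments along the
surviving maps. A's joins are never split without a conflict verdict;
self-integration is a fixed point and the operation is idempotent. The
optical-map → proximity → optical-map triple workflow is two chained calls.

## Misassembly QC

*Insert-size models*: inserts of same-contig pairs, trimmed symmetrically
(1% total tail mass) before taking mean and sd; the sd is divided by the
truncated-normal consistency factor √(1 − 2cφ(c)/(2Φ(c)−1)), c = Φ⁻¹(1−α/2),
so it is unbiased under Gaussian inserts while staying robust to outliers.

*Mate-pair clusters*: records must have mapping quality strictly above 30 on
both reads and zero edit distance. Cross-contig pairs grouped by unordered
contig pair are single-linkage clustered with radius 3 insert-sd per side;
clusters need strictly more than five pairs, and at least one side's read
cluster must lie in the contig's *inner part* — farther than insert mean +
3 sd from both ends, the zone a legitimate boundary-spanning pair cannot
reach. Regions from the three libraries are union-merged (≥ 1 bp overlap).

*Genetic map*: a contig with ≥ 2 markers from each of ≥ 2 linkage groups is
flagged at each transition between marker blocks.

*Spanning signal*: windows (default 20 kb, half-window steps) count
same-scaffold pairs straddling the window midpoint with separation at least
one window; midpoints within one window of a scaffold end are excluded, and
runs of windows below `min_span` (default 3) merge into regions.

*Error rate*: homozygous SNVs + indel events inside intervals with mapping
quality > 25 and depth > 5, divided by the total length of those intervals.

## CN50 / CL50

Descending-sorted lengths are dealt into n sets serpentine-fashion (1…n,
then n…1, repeating, so edge sets receive consecutive picks at each turn).
Each set's N50 contig is the first whose cumulative length reaches half the
set total. CN50 is the median of the selected lengths — the *lower* median
when |M| is even, so CN50 is always an actual contig length and CL50 (the
within-set rank of the CN50 contig) is well defined; `median_rule='midpoint'`
averages the central pair for CN50 while CL50 follows the lower-median
contig. Ties between equal selected lengths take the smallest rank. Sets
left empty when n exceeds the contig count are excluded from the median
with a warning. Note that CL50 can exceed L50 on degenerate inputs (one
huge contig plus many tiny ones); the statistic's value is for assemblies
approaching per-chromosome contiguity.

## The simulator, and what passing tests show

Genomes are i.i.d. background sequence (GC 0.36, a plant-like value) with
near-identical interspersed repeat copies and optional tandem arrays. The
nicking motif is additionally planted as a Poisson process (exponential
spacings, mean 2 kb, 600 bp resolvability floor) so that desk-scale contigs
(tens of kb) carry enough labels to satisfy the 5-label overhang rule; this
is an intentionally elevated label density (real BspQI density is closer to
one per 8–10 kb), chosen so that study conditions — 30 chimeric contigs
inside a 2 × 1 Mb genome — are meaningful at desk scale. The exponential
spacing matters: regular spacing would make unrelated loci's interval
patterns look alike and let skip-tolerant chains extend across junctions by
sizing coincidence. Set `site_spacing_bp=0` for raw-sequence density.

Contigs partition the genome minus short "unassembled" stretches (mean
3 kb, capped at 6 kb so jumping libraries can span them); misjoins splice
fragments of unlinked loci whose junction-adjacent loci both continue
elsewhere (otherwise no mate-pair signal exists by construction). Consensus
maps tile each chromosome at 3× window coverage — real consensus maps
overlap heavily, and lower tiling leaves junctions near window edges
without the labels the conflict rule requires. Map noise: interval
perturbation with sd c·√interval, label dropout, Poisson false labels,
optional chimeric splices, random mirroring. Mate pairs and proximity
pairs are drawn on the *true* genome and reported in contig coordinates;
`depth` is per-library physical coverage. Proximity separations are a
mixture of a short-insert bulk (Normal(500, 150)) and a 2.5% long-range
fraction with a 1/s decay on [1 kb, 1 Mb], putting ≈ 1.3% of pairs beyond
25 kb separation, matching the long-range usable fraction of real
reconstituted-chromatin libraries.

A known limitation of the method itself shows up clearly in these runs: a
misjoin whose junction falls inside a label desert (a long inter-label
interval) is invisible to map conflicts — the overhang rule cannot be met
and the breakpoint, defined between labels, cannot be closer than that
interval. Such junctions are exactly what the orthogonal mate-pair and
proximity-ligation channels are for.

What the simulator does **not** model: sequencing errors at the base level,
fine-scale repeat structure (contigs end at prescribed cuts, not at repeat
boundaries), optical molecule stretch, fragile-site breaks, chromatin
contact-frequency structure beyond a distance decay, or mapping ambiguity
(the lift from genome to contigs is exact; mapq/edit noise is injected
synthetically). Passing the test battery therefore shows the algorithms are
correct and well-calibrated under the declared error models at desk scale —
it does not by itself demonstrate performance on a real multi-hundred-Mb
assembly.

## Benchmark problem sizes

The acceptance battery runs on a 2 × 1 Mb genome: ~70 contigs with 30
planted misjoins for repair/QC runs, 200 query maps for placement, 40
misjoin-free contigs for gap accuracy, and a two-assembly end-to-end
integration. These sizes make every property measurable in seconds to a
couple of minutes on one CPU while leaving dozens of independent events per
measured rate.
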