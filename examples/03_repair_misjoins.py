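"""Conflict arbitration: find and cut chimeric contigs with optical maps.

Plants 5 misjoins (contigs splicing unlinked loci) in a 2 x 1 Mb genome,
runs the correct-then-scaffold workflow, and scores the cuts against the
simulator's truth table.
"""

from hybridscaf import simulate as sim
from hybridscaf.pipeline import correct_and_scaffold
from hybridscaf.stats import n50_l50

genome, gtruth = sim.simulate_genome(seed=5)
contigs, ct = sim.simulate_contigs(genome, gtruth, n_breaks=40, n_misjoins=5, seed=6)
maps, _ = sim.simulate_consensus_maps(genome, seed=7)

result = correct_and_scaffold(contigs, maps)
verdicts = {}
for c in result.conflicts:
    verdicts[c.verdict] = verdicts.get(c.verdict, 0) + 1
print("conflict verdicts:", verdicts)

tol = sim.junction_interval_tolerances(contigs, ct)
rep = sim.evaluate_misjoin_repair(result.lineage, ct, tol_bp=tol)
print(f"misjoins repaired: {rep['n_repaired']}/{rep['n_misjoins']}, "
      f"clean contigs broken: {len(rep['clean_contigs_broken'])}")
print("contig N50 ", n50_l50([len(s) for s in contigs.values()])[0])
print("scaffold N50", n50_l50([len(s) for s in result.scaffold_sequences.values()])[0])
# Every chimeric contig should be convicted (contig_error) because several
# independent maps conflict with it at the same region, and the breakpoint
# lands within one label interval of the planted junction.
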