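"""Iterative integration: borrow joins from a second scaffold set.

A = {c1+c2}, {c3}; B contains a scaffold spanning c2+c3.  Digesting B into
in-silico maps and re-scaffolding A along them transfers B's extra join, so
the output is a single c1+c2+c3 scaffold.  Running the integration again
changes nothing (idempotence).
"""

from hybridscaf import simulate as sim
from hybridscaf.scaffolding import iterative_integration

genome, _ = sim.simulate_genome(n_chrom=1, chrom_length_bp=300_000, seed=20)
chrom = genome["chr1"]
c1, c2, c3 = chrom[0:100_000], chrom[103_000:200_000], chrom[204_000:300_000]

a = {"a1": c1 + "N" * 50 + c2, "a2": c3}
b = {"b1": c2 + "N" * 50 + c3}

result = iterative_integration(a, b)
print("scaffolds:", [(s.scaffold_id, s.contig_ids()) for s in result.scaffolds])
print("conflicts:", len(result.conflicts))

again = iterative_integration(result.sequences, b)
print("idempotent:", sorted(again.sequences.values()) == sorted(result.sequences.values()))
# Expected: one scaffold ordering a1 then a2 (c1+c2+c3), no conflicts, and
# a second integration that is a no-op.
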