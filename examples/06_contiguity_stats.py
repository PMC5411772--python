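"""N50/L50 vs the chromosome-normalized CN50/CL50.

For an assembly approaching chromosome-arm contiguity, L50 is bounded below
by about half the chromosome number even when every chromosome is nearly
one piece; CN50/CL50 normalises for that.
"""

from hybridscaf.stats import contiguity_report

# eight chromosomes, each assembled into one big and two small pieces
lengths = [30_000_000] * 8 + [2_000_000] * 8 + [500_000] * 8
rep = contiguity_report(lengths, n_chromosomes=8)
print(f"count={rep.count} total={rep.total_bp/1e6:.0f} Mb")
print(f"N50 = {rep.n50/1e6:.1f} Mb, L50 = {rep.l50}")
print(f"CN50 = {rep.cn50/1e6:.1f} Mb, CL50 = {rep.cl50}")
# L50 is 5 purely because there are 8 chromosomes; CL50 = 1 says half of a
# typical chromosome sits in its single largest contig — the fact L50 hides.
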