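"""In-silico digestion: sequence -> restriction map -> CMAP file.

Builds a small sequence with known Nt.BspQI sites on both strands, digests
it, and writes/reads the CMAP interchange format.
"""

from hybridscaf import DigestionParams, digest_sequence, read_cmap, write_cmap

seq = "A" * 1000 + "GCTCTTC" + "C" * 2000 + "GAAGAGC" + "T" * 1000
rmap = digest_sequence(seq, DigestionParams(), map_id="demo")
print(f"length {rmap.length_bp} bp, sites at {rmap.sites}")
# -> sites at 1001 (forward motif) and 3008 (reverse-complement occurrence,
#    reported on forward-strand coordinates)

write_cmap([rmap], "demo.cmap")
back = read_cmap("demo.cmap")[0]
print("round trip identical:", back.sites == rmap.sites and back.length_bp == rmap.length_bp)
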