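"""Digest a synthetic locus in silico and decompose it into segment tokens.

Builds the default 3q29-like locus (three SD blocks over a 7-segment
inventory with a 1.48-Mbp unique spacer), digests it at the DLE-1 motif
CTTAAG, and recovers the ordered segment string from the raw sequence.
"""

from sdhap import decompose_sequence, digest_sequence
from sdhap.simulate import SimulationConfig, simulate_locus

locus = simulate_locus(SimulationConfig(seed=1))
lmap = digest_sequence(locus.sequence)
print(f"locus length: {len(locus.sequence):,} bp, "
      f"{lmap.n_labels} CTTAAG labels "
      f"({1000 * lmap.n_labels / len(locus.sequence):.2f} per kbp)")

structure = decompose_sequence(locus.sequence, locus.model.segments)
print("token string:", structure.token_string())
print("copy counts: ", structure.counts())
# The token string is the haplotype's identity: each entry is one segment
# copy with orientation; the '*' marks the 15-kbp partial copy of the
# 26-kbp segment.  Copy counts 3/4/3/2/1/1/1 match the locus inventory.
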