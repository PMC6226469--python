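"""Resolving a terminal tandem expansion from a long read.

Builds a q terminus carrying four tandem copies of its terminal 11 kb unit
(the structure resolved at 15q), simulates a terminus-spanning read with 1%
error, and estimates unit length and copy number from the read's self-dotplot:
off-main-diagonal chain offsets are multiples of the unit, and their
approximate GCD recovers it.
"""

from teloforge.nanopore import chain_matches, estimate_tandem, kmer_dotplot
from teloforge.simulate import (
    EndEvent, SimConfig, apply_end_event, simulate_reference, simulate_terminal_read,
)

genome, _ = simulate_reference(
    SimConfig(n_chromosomes=1, chrom_length=500_000, placements=[], seed=4)
)
event = EndEvent("tandem_expansion", ("chr1", "q"), 11_000, copies=4)
allele = {"chr1": apply_end_event(genome["chr1"], event, genome)}

read = simulate_terminal_read(allele, "chr1", "q", 100_000, error_rate=0.01, seed=1)
window = read.sequence[-50_000:]
segs = chain_matches(kmer_dotplot(window, window, k=16), k=16)
offsets = sorted({round(abs(s.diagonal)) for s in segs if abs(s.diagonal) > 100})
est = estimate_tandem(read.sequence, window=50_000)

print(f"read length          : {len(read.sequence):,} bp (1% error)")
print(f"off-diagonal offsets : {offsets} bp")
print(f"estimated unit       : {est.unit_len:.0f} bp")
print(f"estimated copies     : {est.copies}")
# Offsets at ~11/22/33 kb are the pairwise separations of the four copies;
# their common divisor is the unit and 1 + max/unit the copy number.
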