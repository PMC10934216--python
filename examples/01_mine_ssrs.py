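"""Mine perfect and compound SSRs from a single sequence.

Builds the classic ambiguous repetitive region — three GTAT units running
straight into twelve GT units — and shows that the miner reports it as two
plain adjacent runs merged into one compound SSR, not as an overlap-style
description.
"""

from ssrscape import find_perfect_ssrs, merge_compound

seq = "GTAT" * 3 + "GT" * 12
print(f"sequence ({len(seq)} nt): {seq}")

ssrs = find_perfect_ssrs(seq)
for s in ssrs:
    print(f"  perfect SSR {s.label}  degapped {s.start}..{s.end}  ({s.length_bp} bp)")

compounds, simples = merge_compound(ssrs)
for c in compounds:
    print(f"  compound    {c.label}  spanning {c.start}..{c.end}  ({c.total_length_bp} bp)")

# The two runs are strictly adjacent (zero interspersed nucleotides), so they
# form one compound SSR; the dinucleotide component keeps its full 12 repeats.
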