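"""Tn5 insertion-site transforms on one constructed read pair.

The plus-strand mate aligns to [100, 150) and the minus-strand mate to
[200, 250).  The +4/-5 shift moves each read end onto the transposition
centre; PE-asSE then extends 75 bp either side of each centre (two
150-bp pseudo single-end reads per pair), while PE-noShift keeps one
fragment spanning the two centres.
"""
from atacqc import AlignedPair, ChromSizes, pe_as_se, pe_noshift, tn5_insertions

sizes = ChromSizes({"chr1": 1_000_000})
pair = AlignedPair("chr1", start_plus=100, end_plus=150,
                   start_minus=200, end_minus=250, mapq=60)

plus, minus = tn5_insertions(pair)
print(f"plus-strand insertion site : {plus.pos}  (= 100 + 4)")
print(f"minus-strand insertion site: {minus.pos}  (= 250 - 5)")

f1, f2 = pe_as_se(pair, sizes)
print(f"pseudo-SE fragment 1: [{f1.start}, {f1.end})  length {f1.length}")
print(f"pseudo-SE fragment 2: [{f2.start}, {f2.end})  length {f2.length}")

frag = pe_noshift(pair)
print(f"noShift fragment    : [{frag.start}, {frag.end})  length {frag.length}")
print("One pair therefore yields 2 events in PE-asSE mode and 1 in PE-noShift.")
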