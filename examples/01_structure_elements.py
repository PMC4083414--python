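"""Parse a hairpin's dot-bracket structure and classify its elements.

Builds a small stem-loop, derives the pairing table, partitions every
position into duplex / bulge / internal-loop / hairpin-loop / flank, and
counts single- vs double-stranded nucleotides (the N_ss/N_ds that the
observed-vs-expected editing statistic uses).
"""

from miredit import classify_elements, count_ss_ds, parse_dotbracket

dotbracket = "((.((...)).))"
pt = parse_dotbracket(dotbracket)
print(f"structure  {dotbracket}")
print(f"base pairs {pt.pairs()}")

elements = classify_elements(pt)
for e in elements:
    extra = f" (opposite run: {e.opposite_bulge_len} nt)" if e.opposite_bulge_len else ""
    print(f"  {e.kind.value:13s} positions {e.start}-{e.end}{extra}")

c = count_ss_ds(elements)
print(f"N_ss={c.n_ss}  N_ds={c.n_ds}   (terminal loop and flanks excluded by default)")
# N_ss counts only stem interruptions: the two 1-nt internal-loop runs here.
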