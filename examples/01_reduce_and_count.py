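"""Reduce a sequence onto the 5-letter alphabet and count gapped dipeptides.

The conserved immunoglobulin-domain motif ISNVTREDAGTYTC maps onto the
reduced alphabet as VGGVGGGGGGGFGC; counting ordered residue pairs with
one intervening position (gap 1) shows it carries exactly one F-gap-C
pair (the Y...C of the motif, with Y reduced to F) and no G-gap-C pair —
the mechanism that makes F*C a positive-class marker.
"""

from raacdip import default_scheme, gapped_dipeptide_counts, reduce_sequence

motif = "ISNVTREDAGTYTC"
scheme = default_scheme()
reduced = reduce_sequence(motif, scheme)
print(f"motif          : {motif}")
print(f"reduced (5-letter): {reduced}")

counts = gapped_dipeptide_counts(reduced, gap=1, alphabet=scheme.representatives)
nonzero = {k: v for k, v in counts.items() if v}
print(f"gap-1 dipeptide counts (nonzero): {nonzero}")
print(f"F*C count = {counts['F*C']}, G*C count = {counts['G*C']}")
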