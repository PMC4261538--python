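"""Construct the 147-bp nucleosomal bending-site template and print it.

Each row is one 4-bp bending site: its superhelical location (helical turns
from the dyad), whether the DNA bends into the minor or the major groove
there, and its 1-based start/end positions along the 147-bp fragment.
Minor-groove sites (half-integer SHL) favour WW dinucleotides, major-groove
sites (integer SHL) favour SS.
"""

from wsnuc import build_template, serialize_template

template = build_template(147)
print(serialize_template(template), end="")
print(f"\n{len(template.minor_sites)} minor-groove and "
      f"{len(template.major_sites)} major-groove sites; the SHL -5.5 site "
      f"spans positions {template.site_at(-5.5).start}-{template.site_at(-5.5).end}.")
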