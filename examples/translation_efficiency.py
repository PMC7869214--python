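"""The UME6 translation-efficiency comparison from published inputs.

Translation efficiency (TE) is relative protein level / relative mRNA
level.  Inputs: under no stress the eIF5A-overexpressing strain makes 67%
more Ume6 protein at unchanged mRNA (TE ratio 1.67).  Acetic acid induces
mRNA 1.6x and protein 2.4x in the control strain, 2.7x and 4.1x in the
overexpressor (each vs its own unstressed state).  The chain below yields
the overexpressor's TE advantage under acid stress.
"""

from acidtol.quant import RelativeLevel, percent_difference, translation_efficiency

CAL = "control_unstressed"
mrna = {
    "control_acid": RelativeLevel("control_acid", "UME6", 1.6, "mRNA", CAL),
    "overexp_acid": RelativeLevel("overexp_acid", "UME6", 2.7, "mRNA", CAL),
}
protein = {
    "control_acid": RelativeLevel("control_acid", "UME6", 2.4, "protein", CAL),
    # the overexpressor's protein scale starts 1.67x higher (its unstressed TE)
    "overexp_acid": RelativeLevel("overexp_acid", "UME6", 1.67 * 4.1, "protein", CAL),
}

te = {s: translation_efficiency(protein[s], mrna[s]) for s in mrna}
for s, t in te.items():
    print(f"TE {s}: {t.te:.3f}")

gain = percent_difference(te["overexp_acid"].te, te["control_acid"].te)
print(f"\nTE advantage of the eIF5A overexpressor under acetic acid: {gain:.1f}%")
print("(~69%: enhanced eIF5A boosts Ume6p synthesis mainly translationally)")
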