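"""Date LTR retrotransposon insertions and find shared elements.

Builds two tiny element sets, dates each element with the Prunus clock
T = (1 - identity) / (2µ), and matches shared elements collinearly.
"""

from allohe.ltr import (LTRElement, age_sweep_mya, date_elements,
                        insertion_generations, match_shared_ltrs)

# left-right LTR identities as an annotation tool would report them
subgenome_a = [
    LTRElement("subgenome_a", "chr1", 200_000, 208_000, "Gypsy_G1", 0.9984),
    LTRElement("subgenome_a", "chr1", 900_000, 908_000, "Copia_C1", 0.9960),
]
ancestor = [
    LTRElement("ancestor", "chr1", 150_000, 158_000, "Gypsy_G1", 0.9984),
    LTRElement("ancestor", "chr1", 700_000, 708_000, "Copia_C1", 0.9960),
]

print(date_elements(subgenome_a).to_string(index=False))
# t_generations is the insertion age in generations; the age_*_mya columns
# sweep 10-60 years per generation.

matches = match_shared_ltrs(subgenome_a, ancestor,
                            chromosome_pairs=[("chr1", "chr1")])
print(f"\nshared elements (same family, same age, same order): {len(matches)}")

T = insertion_generations(0.9984)
lo, hi = age_sweep_mya(T)
print(f"youngest shared element: {T:,.1f} generations "
      f"-> {lo:.2f}-{hi:.2f} Mya over 10-60 yr/generation")
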