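"""The five-sample two-source titration and its mixing fractions.

Three mixtures dilute a reference RNA (source A) into bone-marrow RNA
(source B) so expected expression is linear in the source-B fraction.
"""

from titrabench import canonical_design, mixing_fraction

design = canonical_design({"array": 2, "rnaseq": 1})
print("sample      %B RNA")
for sample in design.samples:
    print(f"{sample:<10}  {mixing_fraction(sample) * 100:g}")

# The percentages 0 / 75 / 93.75 / 98.4375 / 100 are what make the series a
# titration: any platform faithful to input RNA must track them linearly.
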