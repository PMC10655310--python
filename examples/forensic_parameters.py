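"""Forensic parameters of a 282-man cohort at six nested Y-STR panels.

Builds a synthetic haplotype table whose 9-locus class spectrum is 242
singletons, 14 pairs and 4 trios, then evaluates random matching
probability, haplotype diversity and discrimination capacity at each
panel from the minimal 9-locus haplotype up to the 26-locus set.
"""

from ystrkit import BUILTIN_PANELS, PANEL_ORDER, forensic_summary, format_summary
from ystrkit.forensic import ClassSpectrum
from ystrkit.simulate import table_from_spectrum

# invert the observed 9-locus spectrum into a concrete table
table = table_from_spectrum(
    ClassSpectrum(282, {1: 242, 2: 14, 3: 4}), panel="MH9", seed=1
)
summary = forensic_summary(table, [BUILTIN_PANELS["MH9"]])
print(format_summary(summary))
print()
print(
    "RMP is the chance two random men share a haplotype; HD its "
    "bias-corrected complement;\nDC the fraction of distinct haplotypes. "
    "With 260 haplotypes among 282 men the 9-locus\npanel already resolves "
    "92% of individuals."
)
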