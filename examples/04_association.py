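"""Genotype-phenotype association in a hybrid cohort.

Simulates 116 crossbred animals genotyped at four markers (two tagging the
swept locus in complete LD, carrying planted additive effects of −3.3 cm on
tail length and +3.5 cm on tail width) and fits linear models under the
additive, dominant and recessive encodings, with and without age/sex
adjustment.
"""

import pandas as pd

from tailsweep import association_report, simulate_association_cohort

table, truth = simulate_association_cohort(seed=3)
report = association_report(
    table,
    markers=["IBH_SNP1", "BMP2_SNP", "PDGFD_SNP"],
    phenotypes=["tail_length_cm", "tail_width_cm"],
)

pd.set_option("display.float_format", lambda v: f"{v:.4g}")
adj = report[report.adjusted]
print(adj.to_string(index=False))
print(
    "\nThe swept-locus marker (IBH_SNP1) shows the planted additive effects"
    "\n(≈ −3.3 cm per allele on length, ≈ +3.5 cm on width) at very small"
    "\np-values, while the null markers do not; the dominant/recessive"
    "\nencodings fit the same data less sharply, as expected for a truly"
    "\nadditive effect."
)
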