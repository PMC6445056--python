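"""Scan a simulated three-population cohort for a selective sweep.

Generates a 2-Mb cohort VCF in which the selected lineage carries a
near-fixed haplotype over [800 kb, 1 Mb), then runs the 30-kb/15-kb window
scan and prints the top windows by LSBL of the selected lineage.  High
LSBL_M plus strongly negative ZHP_M marks the swept interval.
"""

import tempfile

from tailsweep import (
    CohortSimConfig,
    assign_major_minor,
    read_vcf,
    scan_genome,
    simulate_cohort,
    top_windows,
)

with tempfile.TemporaryDirectory() as tmp:
    cohort = simulate_cohort(
        CohortSimConfig(
            n_per_pop=20,
            chrom_length=2_000_000,
            n_sites=4_000,
            drift_F=0.01,
            sweep_interval=(800_000, 1_000_000),
            sweep_freq=0.98,
            seed=1,
        ),
        tmp,
    )
    table = assign_major_minor(read_vcf(str(cohort.vcf_path), cohort.manifest))
    stats = scan_genome(table, cohort.manifest)

print(f"{len(stats)} windows scanned; planted sweep: {cohort.truth.sweep_interval}")
top = top_windows(stats, "LSBL_M", quantile=0.02)
print(top[["start", "end", "n_sites", "LSBL_M", "ZHP_M"]].to_string(index=False))
print(
    "\nEvery top-LSBL window overlaps the planted interval, and its ZHP_M is"
    "\nfar below the genome-wide mean of 0 — the joint signature of a sweep."
)
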