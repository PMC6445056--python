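"""Repeat-class coverage and focal-vs-random enrichment.

Simulates a RepeatMasker annotation of a 5-Mb genome whose 100-kb focal
region carries BovB LINE coverage at roughly twice the background density,
then reports per-class coverage of the focal region, its 50-kb windowed
density profile and the comparison against 10 random same-length loci.
"""

import tempfile
from pathlib import Path

from tailsweep import (
    class_coverage,
    parse_repeatmasker_out,
    random_region_comparison,
    simulate_genome_annotation,
    windowed_density,
)

FOCAL = (2_000_000, 2_100_000)
text = simulate_genome_annotation(
    5_000_000,
    {"LINE/RTE-BovB": 0.1007, "LINE/L1": 0.14, "SINE/MIR": 0.05},
    FOCAL,
    {"LINE/RTE-BovB": 0.2132, "LINE/L1": 0.14, "SINE/MIR": 0.05},
    seed=9,
)
with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "genome.out"
    path.write_text(text)
    anns = parse_repeatmasker_out(str(path))

print("focal-region class coverage:")
print(class_coverage(anns, ("chrGenome", *FOCAL)).to_string(index=False))

dens = windowed_density(
    anns, ("chrGenome", *FOCAL), window=50_000,
    element_filter=lambda a: a.class_family == "LINE/RTE-BovB",
)
print("\nBovB density per 50-kb window over the focal region:")
print(dens.to_string(index=False))

comp = random_region_comparison(anns, ("chrGenome", 0, 5_000_000), FOCAL, n=10, seed=10)
print("\nfocal vs 10 random loci:")
print(comp.to_string(index=False))
print(
    "\nBovB focal coverage exceeds the random mean by well over two standard"
    "\ndeviations — the enrichment signature of a retro-transposition hotspot —"
    "\nwhile the other classes match their background levels."
)
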