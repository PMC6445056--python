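import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from tailsweep import CohortSimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A small cohort with a planted sweep, shared across tests."""
    out = tmp_path_factory.mktemp("cohort")
    config = CohortSimConfig(
        n_per_pop=12,
        chrom_length=1_500_000,
        n_sites=3_000,
        drift_F=0.01,
        sweep_interval=(600_000, 800_000),
        sweep_freq=1.0,
        seed=7,
    )
    return simulate_cohort(config, out)


# a hand-checkable 5-sample VCF: 3 usable SNVs plus one tri-allelic and one
# indel record that the reader must drop
HAND_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=100000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA1\tA2\tA3\tB1\tB2
chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/0\t0/0\t1/1\t1/1
chr1\t200\t.\tC\tT\t.\tPASS\t.\tGT\t0/1\t0/0\t1/1\t./.\t0/1
chr1\t250\t.\tG\tA,C\t.\tPASS\t.\tGT\t0/1\t0/0\t0/2\t0/0\t0/1
chr1\t300\t.\tT\tTA\t.\tPASS\t.\tGT\t0/0\t0/1\t0/0\t0/0\t0/0
chr1\t400\t.\tG\tC\t.\tPASS\t.\tGT\t1/1\t0/1\t0/1\t0/0\t0/0
"""

HAND_MANIFEST = "A1\tpopA\nA2\tpopA\nA3\tpopA\nB1\tpopB\nB2\tpopB\n"


@pytest.fixture()
def hand_vcf(tmp_path):
    vcf = tmp_path / "hand.vcf"
    vcf.write_text(HAND_VCF)
    manifest = tmp_path / "manifest.tsv"
    manifest.write_text(HAND_MANIFEST)
    return vcf, manifest
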