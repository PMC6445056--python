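"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here, with the planted
signal recorded in a truth object, so recovery can be tested end to end:

* a three-population cohort VCF (selected / sister / outgroup lineages)
  whose allele frequencies drift around a shared ancestral frequency under
  the Balding–Nichols model, with a localized sweep planted by overriding
  the selected lineage's derived-allele frequency inside an interval;
* phenotype tables built from an additive linear model with age and sex
  covariate effects plus Gaussian noise;
* genomic regions with planted retro-copies (intron-less mRNA insertions)
  or intron-retaining duplications of randomly generated parent genes;
* RepeatMasker-format annotation files with controlled per-class coverage.

All generators are pure functions of (configuration, seed).

Under Balding–Nichols drift each population's allele frequency is drawn
from Beta(p(1−F)/F, (1−p)(1−F)/F) around the ancestral frequency p, so the
per-population frequency variance is p(1−p)F.  Two populations drifting
independently with the same F then show an expected Wright fixation index
of F/(2−F) on true frequencies (≈ 0.005 at F = 0.01); frequencies estimated
from finite samples sit above that because of binomial sampling noise.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .retrocopy import GeneModel
from .variants import ROLES, PopulationManifest

__all__ = [
    "CohortSimConfig",
    "CohortTruth",
    "SimulatedCohort",
    "simulate_cohort",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_association_cohort",
    "random_gene",
    "plant_retrocopy",
    "simulate_retrocopy_fixture",
    "simulate_repeat_annotation",
    "simulate_genome_annotation",
]

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# cohort VCF


@dataclass(frozen=True)
class CohortSimConfig:
    """Study design for a simulated three-population cohort.

    ``drift_F`` is the Balding–Nichols differentiation parameter applied to
    every population (or a per-role mapping).  ``sweep_interval`` is a
    half-open [start, end) interval in 0-based bp; inside it the selected
    population's derived (ALT) allele frequency is overridden to
    ``sweep_freq`` while the other populations keep their drifted
    frequencies.  REF is the ancestral allele throughout.
    """

    n_per_pop: int = 30
    chrom_length: int = 10_000_000
    n_sites: int = 20_000
    drift_F: float = 0.01
    sweep_interval: tuple[int, int] | None = None
    sweep_freq: float = 0.98
    seed: int = 0
    chrom: str = "chr1"
    pop_labels: tuple[str, str, str] = ROLES  # (selected, sister, outgroup)

    def __post_init__(self) -> None:
        if not (0.0 < self.drift_F < 1.0):
            raise ValueError("drift_F must be in (0, 1)")
        if self.n_sites < 1:
            raise ValueError("n_sites must be ≥ 1")
        if self.n_sites > self.chrom_length:
            raise ValueError("n_sites exceeds chrom_length (inter-site spacing < 1 bp)")
        if self.sweep_interval is not None:
            s, e = self.sweep_interval
            if not (0 <= s < e <= self.chrom_length):
                raise ValueError("sweep_interval outside [0, chrom_length)")
        if not (0.0 <= self.sweep_freq <= 1.0):
            raise ValueError("sweep_freq must be in [0, 1]")
        if self.n_per_pop < 2:
            raise ValueError("need ≥2 samples per population")


@dataclass
class CohortTruth:
    """Planted ground truth for one simulated cohort: site positions
    (1-based), true ALT frequency per population, and the sweep interval."""

    chrom: str
    positions: list[int]
    alt_freq: dict[str, list[float]]
    sweep_interval: tuple[int, int] | None
    sweep_freq: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self)))


@dataclass
class SimulatedCohort:
    vcf_path: Path
    manifest_path: Path
    truth_path: Path
    manifest: PopulationManifest
    truth: CohortTruth


def _unique_sorted_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """1-based site positions, uniform without replacement, sorted."""
    return np.sort(rng.choice(length, size=n, replace=False)) + 1


def simulate_cohort(config: CohortSimConfig, out_dir: str | Path) -> SimulatedCohort:
    """Generate a bi-allelic SNV VCF, a sample→population manifest and a
    truth JSON under ``out_dir``.  Byte-identical output for identical
    (config, seed)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    pos = _unique_sorted_positions(rng, config.n_sites, config.chrom_length)
    p_anc = rng.uniform(0.05, 0.95, size=config.n_sites)
    alpha = (1.0 - config.drift_F) / config.drift_F

    pops = list(config.pop_labels)
    freqs = {
        pop: rng.beta(p_anc * alpha, (1.0 - p_anc) * alpha) for pop in pops
    }
    if config.sweep_interval is not None:
        s, e = config.sweep_interval
        in_sweep = (pos - 1 >= s) & (pos - 1 < e)
        freqs[pops[0]] = np.where(in_sweep, config.sweep_freq, freqs[pops[0]])

    # distinct REF/ALT nucleotides per site
    ref_idx = rng.integers(0, 4, size=config.n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=config.n_sites)) % 4
    refs = _BASES[ref_idx]
    alts = _BASES[alt_idx]

    # genotypes: ALT dose ~ Binomial(2, f) per sample
    doses = {
        pop: rng.binomial(2, freqs[pop][:, None], size=(config.n_sites, config.n_per_pop))
        for pop in pops
    }

    samples = [f"{pop}_{i:03d}" for pop in pops for i in range(1, config.n_per_pop + 1)]
    gt_str = np.array(["0/0", "0/1", "1/1"])

    vcf_path = out / "cohort.vcf"
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={config.chrom},length={config.chrom_length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        all_doses = np.hstack([doses[pop] for pop in pops])
        for k in range(config.n_sites):
            gts = "\t".join(gt_str[all_doses[k]])
            fh.write(
                f"{config.chrom}\t{pos[k]}\t.\t{refs[k]}\t{alts[k]}\t.\tPASS\t.\tGT\t{gts}\n"
            )

    manifest_path = out / "manifest.tsv"
    with open(manifest_path, "w") as fh:
        for pop in pops:
            for i in range(1, config.n_per_pop + 1):
                fh.write(f"{pop}_{i:03d}\t{pop}\n")

    manifest = PopulationManifest(
        samples={s: s.rsplit("_", 1)[0] for s in samples},
        roles=dict(zip(ROLES, pops)),
    )
    truth = CohortTruth(
        chrom=config.chrom,
        positions=pos.tolist(),
        alt_freq={pop: freqs[pop].tolist() for pop in pops},
        sweep_interval=config.sweep_interval,
        sweep_freq=config.sweep_freq,
    )
    truth_path = out / "truth.json"
    truth.to_json(truth_path)
    return SimulatedCohort(vcf_path, manifest_path, truth_path, manifest, truth)


# ---------------------------------------------------------------------------
# phenotypes


def simulate_genotypes(
    n: int, markers: dict[str, float], seed: int, ld_copies: dict[str, str] | None = None
) -> pd.DataFrame:
    """Hardy–Weinberg genotypes (ALT-allele counts 0/1/2) for ``n`` samples
    at the given marker frequencies.  ``ld_copies`` maps a new marker name
    to an existing one to create markers in complete LD."""
    rng = np.random.default_rng(seed)
    data = {"sample": [f"S{i:03d}" for i in range(1, n + 1)]}
    for name, freq in markers.items():
        data[name] = rng.binomial(2, freq, size=n)
    df = pd.DataFrame(data)
    for copy, source in (ld_copies or {}).items():
        df[copy] = df[source]
    return df


@dataclass
class PhenotypeTruth:
    betas: dict[str, float]
    beta_age: float
    beta_sex: float
    noise_sd: float
    intercept: float


def simulate_phenotypes(
    genotypes: pd.DataFrame,
    betas: dict[str, float],
    beta_age: float,
    beta_sex: float,
    noise_sd: float,
    seed: int,
    *,
    intercept: float = 30.0,
    phenotype: str = "tail_length_cm",
    ages: np.ndarray | None = None,
    sex: np.ndarray | None = None,
    male_fraction: float = 88 / 116,
) -> tuple[pd.DataFrame, PhenotypeTruth]:
    """Phenotypes from a linear model:
    y = intercept + Σ beta_m·g_m + beta_age·age + beta_sex·sex + N(0, noise_sd²).

    ``genotypes`` must carry a ``sample`` column plus marker columns coded
    as ALT-allele counts in {0, 1, 2} (anything else raises).  Sex is coded
    0 = female, 1 = male; ages are in years.  When not supplied, ages are
    uniform on {1..6} and sex is Bernoulli(``male_fraction``).
    """
    rng = np.random.default_rng(seed)
    n = len(genotypes)
    marker_cols = [c for c in genotypes.columns if c != "sample"]
    for col in marker_cols:
        vals = genotypes[col].to_numpy()
        valid = np.isin(vals[~pd.isna(vals)], [0, 1, 2])
        if not valid.all():
            raise ValueError(f"marker {col!r} has genotype codes outside {{0,1,2}}")
    unknown = set(betas) - set(marker_cols)
    if unknown:
        raise ValueError(f"effects declared for absent markers: {sorted(unknown)}")

    if ages is None:
        ages = rng.integers(1, 7, size=n).astype(float)
    ages = np.asarray(ages, dtype=float)
    if np.any(ages <= 0):
        raise ValueError("ages must be positive")
    if sex is None:
        sex = (rng.random(n) < male_fraction).astype(int)
    sex = np.asarray(sex, dtype=int)
    if not np.isin(sex, [0, 1]).all():
        raise ValueError("sex must be binary 0/1")

    y = np.full(n, float(intercept))
    for marker, beta in betas.items():
        y = y + beta * genotypes[marker].to_numpy(dtype=float)
    y = y + beta_age * ages + beta_sex * sex
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n)

    out = pd.DataFrame({"sample": genotypes["sample"], "age": ages, "sex": sex})
    out[phenotype] = y
    for col in marker_cols:
        out[col] = genotypes[col].to_numpy()
    truth = PhenotypeTruth(dict(betas), beta_age, beta_sex, noise_sd, intercept)
    return out, truth


def simulate_association_cohort(
    seed: int,
    n: int = 116,
    *,
    beta_length: float = -3.3,
    beta_width: float = 3.5,
    noise_sd_length: float = 3.0,
    noise_sd_width: float = 2.1,
) -> tuple[pd.DataFrame, dict[str, PhenotypeTruth]]:
    """A hybrid-cohort genotype/phenotype table in one call.

    Four markers are genotyped: two in complete LD tagging the swept locus
    (frequency 0.5, carrying the planted effects: ``beta_length`` cm per
    allele on tail length, ``beta_width`` on tail width) and two null
    markers at frequency 0.3.  Age (years) and sex (0 = female, 1 = male;
    ~76% male) carry their own effects so covariate adjustment matters.
    """
    geno = simulate_genotypes(
        n,
        {"IBH_SNP1": 0.5, "BMP2_SNP": 0.3, "PDGFD_SNP": 0.3},
        seed,
        ld_copies={"IBH_SNP2": "IBH_SNP1"},
    )
    length_tbl, t_len = simulate_phenotypes(
        geno,
        {"IBH_SNP1": beta_length},
        beta_age=0.6,
        beta_sex=1.5,
        noise_sd=noise_sd_length,
        seed=seed + 1,
        intercept=35.0,
        phenotype="tail_length_cm",
    )
    width_tbl, t_wid = simulate_phenotypes(
        geno,
        {"IBH_SNP1": beta_width},
        beta_age=0.4,
        beta_sex=1.0,
        noise_sd=noise_sd_width,
        seed=seed + 1,  # same draw of age/sex: identical covariates
        intercept=14.0,
        phenotype="tail_width_cm",
        ages=length_tbl["age"].to_numpy(),
        sex=length_tbl["sex"].to_numpy(),
    )
    table = length_tbl.copy()
    table.insert(4, "tail_width_cm", width_tbl["tail_width_cm"])
    cols = ["sample", "age", "sex", "tail_length_cm", "tail_width_cm"]
    table = table[cols + ["IBH_SNP1", "IBH_SNP2", "BMP2_SNP", "PDGFD_SNP"]]
    return table, {"tail_length_cm": t_len, "tail_width_cm": t_wid}


# ---------------------------------------------------------------------------
# retro-copy fixtures


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def random_gene(
    gene_id: str,
    rng: np.random.Generator,
    *,
    n_exons: int = 5,
    exon_len: tuple[int, int] = (150, 400),
    intron_len: tuple[int, int] = (300, 900),
) -> GeneModel:
    """A random multi-exon gene model (uniform exon/intron lengths)."""
    pieces = []
    exons = []
    cursor = 0
    for i in range(n_exons):
        if i > 0:
            ilen = int(rng.integers(*intron_len))
            pieces.append(_random_seq(rng, ilen))
            cursor += ilen
        elen = int(rng.integers(*exon_len))
        exons.append((cursor, cursor + elen))
        pieces.append(_random_seq(rng, elen))
        cursor += elen
    return GeneModel(gene_id, "".join(pieces), tuple(exons))


@dataclass
class PlantedCopy:
    gene_id: str
    start: int
    end: int
    identity: float
    intron_retained: bool
    strand: str


def plant_retrocopy(
    parent: GeneModel,
    host: str,
    insert_at: int,
    identity: float,
    retain_introns: bool,
    seed: int,
    *,
    strand: str = "+",
) -> tuple[str, PlantedCopy]:
    """Insert a copy of ``parent`` into ``host`` at ``insert_at``.

    With ``retain_introns=False`` the concatenated-exon (mRNA-like)
    sequence is inserted; otherwise the full genomic sequence.  Point
    substitutions at rate (1 − identity) are placed uniformly at random
    (exact count, distinct positions, always to a different base).
    """
    if not (0 <= insert_at <= len(host)):
        raise ValueError("insert_at outside host sequence")
    if not (0.5 <= identity <= 1.0):
        raise ValueError("identity must be in [0.5, 1]")
    rng = np.random.default_rng(seed)
    insert = parent.sequence if retain_introns else parent.mrna()
    if strand == "-":
        from .retrocopy import reverse_complement

        insert = reverse_complement(insert)
    n_sub = round((1.0 - identity) * len(insert))
    if n_sub:
        seq = np.array(list(insert))
        positions = rng.choice(len(insert), size=n_sub, replace=False)
        shifts = rng.integers(1, 4, size=n_sub)
        base_idx = np.searchsorted(_BASES, seq[positions])
        seq[positions] = _BASES[(base_idx + shifts) % 4]
        insert = "".join(seq)
    new_host = host[:insert_at] + insert + host[insert_at:]
    truth = PlantedCopy(
        gene_id=parent.gene_id,
        start=insert_at,
        end=insert_at + len(insert),
        identity=identity,
        intron_retained=retain_introns,
        strand=strand,
    )
    return new_host, truth


def simulate_retrocopy_fixture(
    seed: int,
    *,
    n_retro: int = 10,
    n_intron_retaining: int = 2,
    region_length: int = 150_000,
    identity_range: tuple[float, float] = (0.85, 0.95),
    n_exons_range: tuple[int, int] = (3, 7),
    minus_strand_fraction: float = 0.3,
) -> tuple[str, list[GeneModel], list[PlantedCopy]]:
    """A target region with planted mRNA retro-copies and intron-retaining
    duplications of distinct random parent genes, with per-copy truth."""
    rng = np.random.default_rng(seed)
    n_total = n_retro + n_intron_retaining
    genes = [
        random_gene(
            f"gene{i + 1:02d}", rng, n_exons=int(rng.integers(*n_exons_range))
        )
        for i in range(n_total)
    ]
    background = _random_seq(rng, region_length)
    # one insertion slot per copy keeps planted copies well separated
    slot = region_length // n_total
    specs = []
    for i, gene in enumerate(genes):
        offset = int(rng.integers(slot // 4, 3 * slot // 4))
        specs.append(
            {
                "gene": gene,
                "bg_pos": i * slot + offset,
                "identity": float(rng.uniform(*identity_range)),
                "retain": i >= n_retro,
                "strand": "-" if rng.random() < minus_strand_fraction else "+",
                "seed": int(rng.integers(0, 2**31 - 1)),
            }
        )
    pieces = []
    truths = []
    cursor = 0
    shift = 0
    for s in specs:
        pieces.append(background[cursor : s["bg_pos"]])
        # planting into an empty host yields the mutated insert directly
        mutated, truth = plant_retrocopy(
            s["gene"],
            "",
            0,
            s["identity"],
            s["retain"],
            s["seed"],
            strand=s["strand"],
        )
        pieces.append(mutated)
        truth.start = s["bg_pos"] + shift
        truth.end = truth.start + len(mutated)
        truths.append(truth)
        shift += len(mutated)
        cursor = s["bg_pos"]
    pieces.append(background[cursor:])
    return "".join(pieces), genes, truths


# ---------------------------------------------------------------------------
# repeat annotations

#: representative repeat names per class/family, echoing common mammalian
#: RepeatMasker vocabulary (ruminant-specific BovB and Bov-tA included)
CLASS_NAMES = {
    "SINE/MIR": ["MIR", "MIR3"],
    "SINE/tRNA-Core-RTE": ["Bov-tA2", "Bov-A2"],
    "LINE/L1": ["L1_BT", "L1-2_BT"],
    "LINE/L2": ["L2"],
    "LINE/RTE-BovB": ["BovB"],
    "LTR/ERVL": ["ERVL-E", "LTR16"],
    "LTR/ERVL-MaLR": ["MLT1D"],
    "LTR/ERV1": ["ERV1"],
    "DNA/TcMar-Tigger": ["Tigger1"],
    "DNA/hAT-Charlie": ["Charlie1"],
}

_RM_HEADER = (
    "   SW   perc perc perc  query      position in query           matching"
    "       repeat              position in repeat\n"
    "score   div. del. ins.  sequence    begin     end    (left)    repeat"
    "          class/family         begin  end (left)   ID\n"
    "\n"
)


def _default_length_sampler(rng: np.random.Generator) -> int:
    return int(np.clip(rng.lognormal(mean=6.0, sigma=0.7), 60, 6000))


def _generate_elements(
    start: int,
    end: int,
    class_targets: dict[str, float],
    rng: np.random.Generator,
    length_sampler=None,
) -> list[tuple[int, int, str, str]]:
    """Non-overlapping (start, end, name, class) elements inside
    [start, end) whose per-class coverage hits the target fractions."""
    region_len = end - start
    sampler = length_sampler or _default_length_sampler
    if sum(class_targets.values()) > 1.0 + 1e-9:
        raise ValueError("class coverage targets sum to more than 1")
    pieces: list[tuple[int, str, str]] = []  # (length, name, class)
    for cls in sorted(class_targets):
        target_bp = int(round(class_targets[cls] * region_len))
        names = CLASS_NAMES.get(cls, [cls.split("/")[-1]])
        acc = 0
        while acc < target_bp:
            length = min(sampler(rng), target_bp - acc)
            length = max(length, min(30, target_bp - acc))
            name = names[int(rng.integers(0, len(names)))]
            pieces.append((length, name, cls))
            acc += length
    total = sum(p[0] for p in pieces)
    if total > region_len:
        raise ValueError("infeasible packing: targets exceed region length")
    order = rng.permutation(len(pieces))
    pieces = [pieces[i] for i in order]
    free = region_len - total
    # integer gaps before each element plus trailing space
    weights = rng.random(len(pieces) + 1)
    gaps = np.floor(np.cumsum(weights) / weights.sum() * free).astype(int)
    gaps = np.diff(np.concatenate([[0], gaps]))
    out = []
    cursor = start
    for (length, name, cls), gap in zip(pieces, gaps[:-1]):
        cursor += int(gap)
        out.append((cursor, cursor + length, name, cls))
        cursor += length
    return out


def _format_out(elements: list[tuple[int, int, str, str]], chrom: str, chrom_len: int,
                rng: np.random.Generator) -> str:
    lines = [_RM_HEADER]
    for i, (s, e, name, cls) in enumerate(sorted(elements), 1):
        div = rng.uniform(1.0, 30.0)
        strand = "+" if rng.random() < 0.5 else "C"
        rep_len = e - s
        lines.append(
            f"{int(rng.integers(200, 5000)):>5} {div:5.1f}  0.0  0.0  {chrom:<10}"
            f"{s + 1:>8}{e:>8} ({chrom_len - e:>d}) {strand} {name:<15}"
            f" {cls:<20}{1:>6}{rep_len:>5} (0) {i:>4}\n"
        )
    return "".join(lines)


def simulate_repeat_annotation(
    region_length: int,
    class_targets: dict[str, float],
    seed: int,
    *,
    chrom: str = "region",
    length_sampler=None,
) -> str:
    """RepeatMasker ``.out`` text for one sequence with per-class coverage
    matching ``class_targets`` (realised coverage is exact up to integer
    rounding; elements never overlap)."""
    rng = np.random.default_rng(seed)
    elements = _generate_elements(0, region_length, class_targets, rng, length_sampler)
    return _format_out(elements, chrom, region_length, rng)


def simulate_genome_annotation(
    genome_length: int,
    background_targets: dict[str, float],
    focal_region: tuple[int, int],
    focal_targets: dict[str, float],
    seed: int,
    *,
    chrom: str = "chrGenome",
    length_sampler=None,
) -> str:
    """Genome-wide ``.out`` text with one focal interval at different
    per-class coverages than the background (e.g. an enrichment fixture
    where a repeat class runs at twice its background density)."""
    fs, fe = focal_region
    if not (0 <= fs < fe <= genome_length):
        raise ValueError("focal region outside genome")
    rng = np.random.default_rng(seed)
    elements = []
    for a, b, targets in (
        (0, fs, background_targets),
        (fs, fe, focal_targets),
        (fe, genome_length, background_targets),
    ):
        if b > a:
            elements.extend(_generate_elements(a, b, targets, rng, length_sampler))
    return _format_out(elements, chrom, genome_length, rng)
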