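"""Read multi-sample VCFs into per-population allele-frequency tables.

The sweep statistics downstream are all functions of per-population allele
frequencies at bi-allelic SNVs, together with the number of successfully
called alleles per site.  This module turns a VCF plus a sample→population
manifest into that representation, and fixes the major/minor allele
convention: by default the *major* allele at a site is the one whose pooled
(all-samples) frequency is ≥ 0.5, and the same physical allele is labelled
major in every population.  Only a shared allele identity makes the
cross-population products in d_xy refer to the same nucleotide on both
sides, keeps d_xy symmetric, and lets d_xy(x, x) reduce to within-population
heterozygosity.  A per-population convention is available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

__all__ = [
    "PopulationManifest",
    "AlleleFrequencyTable",
    "read_manifest",
    "read_vcf",
    "assign_major_minor",
]

#: canonical lineage roles used by the LSBL computation
ROLES = ("selected", "sister", "outgroup")


@dataclass
class PopulationManifest:
    """Sample→population assignment plus lineage roles.

    ``roles`` maps each of the three roles ``selected`` (the focal lineage,
    M), ``sister`` (T) and ``outgroup`` (E) to a population label.  Roles
    are only required when a three-lineage statistic (LSBL) is requested.
    """

    samples: dict[str, str]
    roles: dict[str, str] = field(default_factory=dict)

    @property
    def populations(self) -> list[str]:
        seen: list[str] = []
        for pop in self.samples.values():
            if pop not in seen:
                seen.append(pop)
        return seen

    def members(self, pop: str) -> list[str]:
        return [s for s, p in self.samples.items() if p == pop]

    def require_roles(self) -> None:
        missing = [r for r in ROLES if r not in self.roles]
        if missing:
            raise ValueError(f"manifest lacks role assignment for: {missing}")
        for role, pop in self.roles.items():
            if len(self.members(pop)) < 2:
                raise ValueError(
                    f"population {pop!r} (role {role}) has <2 samples; "
                    "allele frequencies would be degenerate"
                )

    def validate(self) -> None:
        # populations with <2 samples are only an error once a lineage
        # statistic requests them (require_roles); plain reading tolerates them
        if not self.samples:
            raise ValueError("empty manifest")


def read_manifest(path: str, roles: dict[str, str] | None = None) -> PopulationManifest:
    """Read a two-column TSV (sample, population) into a manifest.

    Duplicate sample ids are rejected (including a sample listed under two
    populations).  If ``roles`` is not given and the population labels are
    exactly the canonical role names, roles are assigned by name.
    """
    samples: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected ≥2 tab-separated columns")
            sample, pop = parts[0], parts[1]
            if sample in samples:
                raise ValueError(f"{path}:{lineno}: duplicate sample id {sample!r}")
            samples[sample] = pop
    manifest = PopulationManifest(samples)
    pops = set(manifest.populations)
    if roles is not None:
        manifest.roles = dict(roles)
    elif pops == set(ROLES):
        manifest.roles = {r: r for r in ROLES}
    manifest.validate()
    return manifest


@dataclass
class AlleleFrequencyTable:
    """Per-site, per-population allele frequencies for bi-allelic SNVs.

    ``sites`` has columns chrom, pos (1-based, as in the VCF), ref, alt and —
    after :func:`assign_major_minor` — allele_major / allele_minor.
    ``f_alt[pop]`` and ``f_major[pop]`` are frequency arrays aligned with
    ``sites``; ``n_alleles[pop]`` counts called alleles (missing genotypes
    shrink the denominator, they are never imputed).
    """

    sites: pd.DataFrame
    pops: list[str]
    f_alt: dict[str, np.ndarray]
    n_alleles: dict[str, np.ndarray]
    f_major: dict[str, np.ndarray] = field(default_factory=dict)
    major_scope: str | None = None
    n_dropped: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sites)

    def positions(self, chrom: str) -> np.ndarray:
        """0-based positions on ``chrom`` (pos − 1), for windowing."""
        mask = self.sites["chrom"].to_numpy() == chrom
        return self.sites.loc[mask, "pos"].to_numpy() - 1

    def chrom_mask(self, chrom: str) -> np.ndarray:
        return self.sites["chrom"].to_numpy() == chrom

    @property
    def chroms(self) -> list[str]:
        return list(pd.unique(self.sites["chrom"]))

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: one row per site × population."""
        if not self.f_major:
            raise ValueError("call assign_major_minor first")
        rows = []
        for pop in self.pops:
            df = self.sites[["chrom", "pos", "allele_major", "allele_minor"]].copy()
            df["pop"] = pop
            df["f_major"] = self.f_major[pop]
            df["f_minor"] = 1.0 - self.f_major[pop]
            df["n_alleles"] = self.n_alleles[pop]
            rows.append(df)
        out = pd.concat(rows, ignore_index=True)
        return out.sort_values(["chrom", "pos", "pop"], kind="mergesort").reset_index(drop=True)

    def write_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_vcf(
    path: str,
    manifest: PopulationManifest,
    *,
    min_call_rate: float = 0.0,
    on_unknown_sample: str = "error",
) -> AlleleFrequencyTable:
    """Extract per-population ALT allele frequencies from a VCF.

    Multi-allelic and non-SNV records are dropped (counted in
    ``n_dropped``), as are sites whose overall call rate falls below
    ``min_call_rate``.  Frequencies are computed from called alleles only.
    """
    vcf = VCF(path)
    vcf_samples = list(vcf.samples)
    unknown = [s for s in vcf_samples if s not in manifest.samples]
    if unknown:
        msg = f"VCF samples absent from manifest: {unknown[:5]}"
        if on_unknown_sample == "error":
            raise ValueError(msg)
        import warnings

        warnings.warn(msg, stacklevel=2)

    pops = manifest.populations
    pop_idx = {
        pop: np.array(
            [i for i, s in enumerate(vcf_samples) if manifest.samples.get(s) == pop],
            dtype=int,
        )
        for pop in pops
    }
    for pop, idx in pop_idx.items():
        if len(idx) == 0:
            raise ValueError(f"population {pop!r} has no samples in the VCF")

    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    falt: dict[str, list[float]] = {p: [] for p in pops}
    nall: dict[str, list[int]] = {p: [] for p in pops}
    dropped = {"multiallelic": 0, "non_snv": 0, "low_call_rate": 0}
    n_total = len(vcf_samples)

    for variant in vcf:
        if len(variant.ALT) != 1:
            dropped["multiallelic"] += 1
            continue
        if len(variant.REF) != 1 or len(variant.ALT[0]) != 1:
            dropped["non_snv"] += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gts = np.asarray(variant.gt_types)
        known = gts != 2
        if known.sum() < min_call_rate * n_total:
            dropped["low_call_rate"] += 1
            continue
        alt_dose = np.where(gts == 1, 1, np.where(gts == 3, 2, 0))
        chroms.append(variant.CHROM)
        poss.append(variant.POS)
        refs.append(variant.REF)
        alts.append(variant.ALT[0])
        for pop in pops:
            idx = pop_idx[pop]
            n = int(2 * known[idx].sum())
            a = int(alt_dose[idx][known[idx]].sum())
            nall[pop].append(n)
            falt[pop].append(a / n if n > 0 else np.nan)

    if not chroms:
        raise ValueError(f"no usable bi-allelic SNVs in {path} (dropped: {dropped})")

    sites = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    order = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].to_numpy()))
    sites = sites.iloc[order].reset_index(drop=True)
    table = AlleleFrequencyTable(
        sites=sites,
        pops=pops,
        f_alt={p: np.asarray(falt[p])[order] for p in pops},
        n_alleles={p: np.asarray(nall[p], dtype=int)[order] for p in pops},
        n_dropped=dropped,
    )
    return table


def assign_major_minor(table: AlleleFrequencyTable, scope: str = "global") -> AlleleFrequencyTable:
    """Label major/minor alleles and fill per-population major frequencies.

    scope="global" (default): the major allele is the one with pooled
    all-sample frequency ≥ 0.5 (tie → REF), identical across populations.
    scope="per-pop": each population majorises independently; cross-
    population statistics then compare folded frequencies, not alleles.
    """
    pops = table.pops
    n_tot = sum(table.n_alleles[p] for p in pops)
    alt_tot = sum(table.f_alt[p] * table.n_alleles[p] for p in pops)
    with np.errstate(invalid="ignore"):
        pooled_alt = np.where(n_tot > 0, alt_tot / np.maximum(n_tot, 1), np.nan)

    sites = table.sites.copy()
    if scope == "global":
        alt_major = pooled_alt > 0.5  # tie → REF
        sites["allele_major"] = np.where(alt_major, sites["alt"], sites["ref"])
        sites["allele_minor"] = np.where(alt_major, sites["ref"], sites["alt"])
        f_major = {
            p: np.where(alt_major, table.f_alt[p], 1.0 - table.f_alt[p]) for p in pops
        }
    elif scope == "per-pop":
        sites["allele_major"] = "."  # not a single allele per site
        sites["allele_minor"] = "."
        f_major = {p: np.maximum(table.f_alt[p], 1.0 - table.f_alt[p]) for p in pops}
    else:
        raise ValueError(f"unknown major/minor scope {scope!r}")

    return AlleleFrequencyTable(
        sites=sites,
        pops=pops,
        f_alt=table.f_alt,
        n_alleles=table.n_alleles,
        f_major=f_major,
        major_scope=scope,
        n_dropped=table.n_dropped,
    )
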