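"""Sliding-window selective-sweep statistics.

The scan computes, for every window of a genome:

* three pairwise fixation indices FI (F_ST) between the selected (M),
  sister (T) and outgroup (E) lineages;
* the lineage-specific branch length
  ``LSBL_M = (FI_MT + FI_ME − FI_TE) / 2`` (and the two permutations),
  which isolates differentiation private to one branch of the
  three-lineage star;
* the between-population distance d_xy built from major/minor allele
  frequencies;
* the pooled within-population heterozygosity
  ``H_P = 2·Σf_major·Σf_minor / (Σf_major + Σf_minor)²`` (sums over the
  window's variants) and its genome-wide standardisation
  ``ZH_P = (H_P − μ)/σ``.

A selective sweep in the selected lineage shows up as a run of windows with
high LSBL_M and strongly negative ZH_P.  The default window design is 30 kb
with a 15-kb step.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variants import AlleleFrequencyTable, PopulationManifest, assign_major_minor

__all__ = [
    "WindowSpec",
    "window_fst",
    "lsbl",
    "window_dxy",
    "window_hp",
    "standardize_zhp",
    "scan_genome",
    "top_windows",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window design: size, step, and the minimum number of variant
    sites for a window's statistics to be reported (NaN otherwise)."""

    window_size: int = 30_000
    step: int = 15_000
    min_sites: int = 10

    def __post_init__(self) -> None:
        if self.step > self.window_size:
            raise ValueError("step must not exceed window_size")
        if self.min_sites < 1:
            raise ValueError("min_sites must be ≥ 1")

    def tile(self, chrom_length: int) -> list[tuple[int, int]]:
        """Half-open [start, end) windows from 0; the last partial window is
        kept so terminal regions are never silently dropped."""
        out = []
        start = 0
        while start < chrom_length:
            out.append((start, min(start + self.window_size, chrom_length)))
            start += self.step
        return out


def window_fst(
    f_a: np.ndarray,
    f_b: np.ndarray,
    n_a: np.ndarray | None = None,
    n_b: np.ndarray | None = None,
    estimator: str = "wright",
) -> float:
    """Window fixation index between two populations.

    ``f_a``/``f_b`` are per-site frequencies of the same allele in the two
    populations.  "wright" (default) is the frequency-based ratio of sums
    Σ(H_T − H_S)/ΣH_T with H_T computed from the unweighted mean frequency
    and H_S the mean of the two per-population 2pq terms; it needs no sample
    sizes and lies in [0, 1].  "hudson" is the ratio of averages of the
    sample-size-corrected per-site numerator/denominator and may be
    negative; it requires per-site called-allele counts ``n_a``/``n_b``.
    Sites monomorphic in both populations contribute zero to both sums.
    """
    f_a = np.asarray(f_a, dtype=float)
    f_b = np.asarray(f_b, dtype=float)
    ok = ~(np.isnan(f_a) | np.isnan(f_b))
    f_a, f_b = f_a[ok], f_b[ok]
    if f_a.size == 0:
        return float("nan")
    if estimator == "wright":
        p_bar = (f_a + f_b) / 2.0
        h_t = 2.0 * p_bar * (1.0 - p_bar)
        h_s = (2.0 * f_a * (1.0 - f_a) + 2.0 * f_b * (1.0 - f_b)) / 2.0
        denom = h_t.sum()
        if denom == 0.0:
            return float("nan")
        return float((h_t - h_s).sum() / denom)
    if estimator == "hudson":
        if n_a is None or n_b is None:
            raise ValueError("hudson estimator requires per-site allele counts")
        n_a = np.asarray(n_a, dtype=float)[ok]
        n_b = np.asarray(n_b, dtype=float)[ok]
        if np.any(n_a < 2) or np.any(n_b < 2):
            raise ValueError("hudson estimator needs ≥2 called alleles per site")
        q_a, q_b = 1.0 - f_a, 1.0 - f_b
        num = (f_a - f_b) ** 2 - f_a * q_a / (n_a - 1.0) - f_b * q_b / (n_b - 1.0)
        den = f_a * q_b + f_b * q_a
        if den.sum() == 0.0:
            return float("nan")
        return float(num.mean() / den.mean())
    raise ValueError(f"unknown estimator {estimator!r}")


def lsbl(fi_mt: float, fi_me: float, fi_te: float) -> tuple[float, float, float]:
    """Lineage-specific branch lengths from the three pairwise fixation
    indices: lsbl_m = (fi_mt + fi_me − fi_te)/2 and the two permutations.
    NaN inputs propagate to all three outputs."""
    if any(np.isnan(v) for v in (fi_mt, fi_me, fi_te)):
        nan = float("nan")
        return nan, nan, nan
    lsbl_m = (fi_mt + fi_me - fi_te) / 2.0
    lsbl_t = (fi_mt + fi_te - fi_me) / 2.0
    lsbl_e = (fi_me + fi_te - fi_mt) / 2.0
    return lsbl_m, lsbl_t, lsbl_e


def window_dxy(
    fmaj_x: np.ndarray,
    fmaj_y: np.ndarray,
    mode: str = "per_site",
) -> float:
    """Between-population distance from shared major/minor frequencies.

    "per_site": (1/n)·Σ_k [f_{k,x,maj}·f_{k,y,min} + f_{k,y,maj}·f_{k,x,min}],
    the mean per-site probability that one allele drawn from each population
    differs in the major/minor sense; bounded by [0, 1].
    "literal": the unnormalised window-sum product form
    Σf_{x,maj}·Σf_{y,min} + Σf_{y,maj}·Σf_{x,min}, which scales with n² and
    is only comparable between windows of equal site count.
    Symmetric in (x, y) in both modes.
    """
    fx = np.asarray(fmaj_x, dtype=float)
    fy = np.asarray(fmaj_y, dtype=float)
    ok = ~(np.isnan(fx) | np.isnan(fy))
    fx, fy = fx[ok], fy[ok]
    if fx.size == 0:
        return float("nan")
    if mode == "per_site":
        return float(np.mean(fx * (1.0 - fy) + fy * (1.0 - fx)))
    if mode == "literal":
        return float(fx.sum() * (1.0 - fy).sum() + fy.sum() * (1.0 - fx).sum())
    raise ValueError(f"unknown d_xy mode {mode!r}")


def window_hp(fmaj: np.ndarray) -> float:
    """Pooled window heterozygosity 2·Σmaj·Σmin/(Σmaj + Σmin)².

    Sums run over the window's sites; the statistic lies in [0, 0.5] and is
    the quantity later standardised into ZH_P.
    """
    f = np.asarray(fmaj, dtype=float)
    f = f[~np.isnan(f)]
    if f.size == 0:
        return float("nan")
    s_maj = f.sum()
    s_min = (1.0 - f).sum()
    return float(2.0 * s_maj * s_min / (s_maj + s_min) ** 2)


def standardize_zhp(hp_values: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Z-standardise window H_P values: (H_P − μ)/σ over non-NaN windows.

    σ is the sample (n−1) standard deviation by default (``ddof=0`` for the
    population form).  NaNs propagate; a zero σ yields all-NaN with a
    warning.
    """
    hp = np.asarray(hp_values, dtype=float)
    ok = ~np.isnan(hp)
    if ok.sum() < 2:
        raise ValueError("need ≥2 non-NaN H_P values to standardise")
    mu = hp[ok].mean()
    sigma = hp[ok].std(ddof=ddof)
    if sigma == 0.0:
        warnings.warn("H_P is constant across windows; ZH_P undefined", stacklevel=2)
        return np.full_like(hp, np.nan)
    return (hp - mu) / sigma


# role → short letter used in output column names
_ROLE_LETTER = {"selected": "M", "sister": "T", "outgroup": "E"}


def scan_genome(
    table: AlleleFrequencyTable,
    manifest: PopulationManifest,
    spec: WindowSpec = WindowSpec(),
    *,
    estimator: str = "wright",
    dxy_mode: str = "per_site",
    chrom_lengths: dict[str, int] | None = None,
    zhp_ddof: int = 1,
) -> pd.DataFrame:
    """Compute all window statistics over every chromosome in the table.

    Windows tile each chromosome from 0 in steps of ``spec.step``; the last
    partial window is retained and flagged.  ZH_P is standardised per
    population across all windows after the sweep.  If ``chrom_lengths`` is
    not given, each chromosome extends to its last variant position.
    """
    manifest.require_roles()
    if not table.f_major:
        table = assign_major_minor(table)
    pop_of = {letter: manifest.roles[role] for role, letter in _ROLE_LETTER.items()}

    rows = []
    chroms = table.chroms
    if chrom_lengths:
        absent = [c for c in chrom_lengths if c not in chroms]
        for c in absent:
            logger.info("chromosome %s absent from table; skipped", c)
    for chrom in chroms:
        mask = table.chrom_mask(chrom)
        pos0 = table.sites.loc[mask, "pos"].to_numpy() - 1  # 0-based
        length = (
            chrom_lengths.get(chrom, int(pos0.max()) + 1)
            if chrom_lengths
            else int(pos0.max()) + 1
        )
        fmaj = {L: table.f_major[pop_of[L]][mask] for L in "MTE"}
        nall = {L: table.n_alleles[pop_of[L]][mask] for L in "MTE"}
        # sites are sorted, so windows are contiguous slices
        for start, end in spec.tile(length):
            lo, hi = np.searchsorted(pos0, [start, end])
            n_sites = hi - lo
            row: dict = {
                "chrom": chrom,
                "start": start,
                "end": end,
                "n_sites": int(n_sites),
                "partial": end - start < spec.window_size,
            }
            if n_sites < spec.min_sites:
                for col in _STAT_COLUMNS:
                    row[col] = np.nan
            else:
                sl = slice(lo, hi)
                fi = {}
                for a, b in (("M", "T"), ("M", "E"), ("T", "E")):
                    fi[a + b] = window_fst(
                        fmaj[a][sl], fmaj[b][sl], nall[a][sl], nall[b][sl], estimator
                    )
                lm, lt, le = lsbl(fi["MT"], fi["ME"], fi["TE"])
                row.update(
                    FI_MT=fi["MT"],
                    FI_ME=fi["ME"],
                    FI_TE=fi["TE"],
                    LSBL_M=lm,
                    LSBL_T=lt,
                    LSBL_E=le,
                )
                for a, b in (("M", "T"), ("M", "E"), ("T", "E")):
                    row[f"d_{a}{b}"] = window_dxy(fmaj[a][sl], fmaj[b][sl], dxy_mode)
                for L in "MTE":
                    # H_P is intra-population: fold to the population's own
                    # major allele regardless of the global labelling
                    row[f"HP_{L}"] = window_hp(np.maximum(fmaj[L][sl], 1.0 - fmaj[L][sl]))
            rows.append(row)

    stats = pd.DataFrame(rows).sort_values(["chrom", "start"], kind="mergesort")
    stats = stats.reset_index(drop=True)
    for L in "MTE":
        hp = stats[f"HP_{L}"].to_numpy()
        if (~np.isnan(hp)).sum() >= 2:
            stats[f"ZHP_{L}"] = standardize_zhp(hp, ddof=zhp_ddof)
        else:
            stats[f"ZHP_{L}"] = np.nan
    return stats


_STAT_COLUMNS = [
    "FI_MT",
    "FI_ME",
    "FI_TE",
    "LSBL_M",
    "LSBL_T",
    "LSBL_E",
    "d_MT",
    "d_ME",
    "d_TE",
    "HP_M",
    "HP_T",
    "HP_E",
]


def top_windows(
    stats: pd.DataFrame, column: str = "LSBL_M", quantile: float = 0.005
) -> pd.DataFrame:
    """Windows whose ``column`` value reaches the top ``quantile`` of the
    empirical distribution (ties at the threshold all included), sorted
    descending."""
    if stats.empty:
        raise ValueError("empty window table")
    values = stats[column].to_numpy(dtype=float)
    ok = ~np.isnan(values)
    if not ok.any():
        raise ValueError(f"no non-NaN values in column {column!r}")
    threshold = np.quantile(values[ok], 1.0 - quantile)
    keep = ok & (values >= threshold)
    return stats.loc[keep].sort_values(column, ascending=False, kind="mergesort")
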