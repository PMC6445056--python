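"""Repeat-annotation parsing, coverage, windowed density and enrichment.

Works from standard RepeatMasker ``.out`` files (15-column whitespace
body under a 3-line header; 1-based inclusive coordinates, converted to
0-based half-open on input).  Coverage is always computed as the length of
the *union* of member intervals divided by the region length, so nested or
overlapping annotations never push a class above 100%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RepeatAnnotation",
    "parse_repeatmasker_out",
    "write_repeatmasker_out",
    "class_coverage",
    "windowed_density",
    "random_region_comparison",
    "union_length",
]


@dataclass(frozen=True)
class RepeatAnnotation:
    """One repeat element interval (0-based half-open) with its repeat name
    and class/family string; divergence and score are carried but unused."""

    chrom: str
    start: int
    end: int
    name: str
    class_family: str
    strand: str = "+"
    divergence: float = 0.0
    score: int = 0

    @property
    def repeat_class(self) -> str:
        """Top-level class, e.g. "LINE" from "LINE/RTE-BovB"."""
        return self.class_family.split("/")[0]


def parse_repeatmasker_out(path: str) -> list[RepeatAnnotation]:
    """Parse a RepeatMasker ``.out`` file.

    The 3-line header is skipped when present (its absence only warns);
    strand "C" (complement) is accepted; a malformed body row raises with
    its line number.
    """
    annotations: list[RepeatAnnotation] = []
    with open(path) as fh:
        lines = fh.readlines()
    start_line = 0
    if lines and lines[0].lstrip().startswith("SW"):
        start_line = 3
    else:
        warnings.warn(f"{path}: no RepeatMasker header found", stacklevel=2)
    for lineno, line in enumerate(lines[start_line:], start_line + 1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) < 14:
            raise ValueError(f"{path}:{lineno}: expected ≥14 columns, got {len(fields)}")
        try:
            score = int(fields[0])
            divergence = float(fields[1])
            chrom = fields[4]
            begin = int(fields[5])
            end = int(fields[6])
            strand = fields[8]
            name = fields[9]
            class_family = fields[10]
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}:{lineno}: unparseable row: {line.rstrip()}") from exc
        if strand not in ("+", "C"):
            raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
        if begin > end:
            raise ValueError(f"{path}:{lineno}: begin > end ({begin} > {end})")
        annotations.append(
            RepeatAnnotation(
                chrom=chrom,
                start=begin - 1,  # 1-based inclusive → 0-based half-open
                end=end,
                name=name,
                class_family=class_family,
                strand="-" if strand == "C" else "+",
                divergence=divergence,
                score=score,
            )
        )
    return annotations


def write_repeatmasker_out(annotations: list[RepeatAnnotation], path: str) -> None:
    """Write annotations back to ``.out`` format (inverse of the parser for
    the fields the package uses)."""
    header = (
        "   SW   perc perc perc  query      position in query           matching"
        "       repeat              position in repeat\n"
        "score   div. del. ins.  sequence    begin     end    (left)    repeat"
        "          class/family         begin  end (left)   ID\n\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for i, a in enumerate(annotations, 1):
            strand = "C" if a.strand == "-" else "+"
            fh.write(
                f"{a.score:>5} {a.divergence:5.1f}  0.0  0.0  {a.chrom:<10}"
                f"{a.start + 1:>8}{a.end:>8} (0) {strand} {a.name:<15}"
                f" {a.class_family:<20}{1:>6}{a.end - a.start:>5} (0) {i:>4}\n"
            )


def union_length(
    intervals: list[tuple[int, int]], clip: tuple[int, int] | None = None
) -> int:
    """Total length of the union of half-open intervals, optionally clipped
    to a [start, end) window."""
    if clip is not None:
        lo, hi = clip
        intervals = [(max(s, lo), min(e, hi)) for s, e in intervals]
    intervals = sorted((s, e) for s, e in intervals if e > s)
    total = 0
    cur_s = cur_e = None
    for s, e in intervals:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def _grouper(grouping: str):
    if grouping == "class_family":
        return lambda a: a.class_family
    if grouping == "class":
        return lambda a: a.repeat_class
    if grouping == "name":
        return lambda a: a.name
    if callable(grouping):
        return grouping
    raise ValueError(f"unknown grouping {grouping!r}")


def class_coverage(
    annotations: list[RepeatAnnotation],
    region: tuple[str, int, int],
    grouping: str = "class_family",
) -> pd.DataFrame:
    """Per-group element count, union-covered bp and coverage fraction of a
    region (elements are clipped to the region; overlaps within a group are
    counted once)."""
    chrom, start, end = region
    if end <= start:
        raise ValueError("region length must be > 0")
    key = _grouper(grouping)
    groups: dict[str, list[RepeatAnnotation]] = {}
    for a in annotations:
        if a.chrom != chrom or a.end <= start or a.start >= end:
            continue
        groups.setdefault(key(a), []).append(a)
    rows = []
    length = end - start
    for group in sorted(groups):
        members = groups[group]
        covered = union_length([(a.start, a.end) for a in members], clip=(start, end))
        rows.append(
            {
                "group": group,
                "element_count": len(members),
                "covered_bp": covered,
                "fraction": covered / length,
            }
        )
    return pd.DataFrame(rows, columns=["group", "element_count", "covered_bp", "fraction"])


def windowed_density(
    annotations: list[RepeatAnnotation],
    region: tuple[str, int, int],
    *,
    window: int = 50_000,
    step: int | None = None,
    element_filter=None,
) -> pd.DataFrame:
    """Union-coverage fraction of (filtered) elements in sliding windows
    over ``region``; the default step is half the window, and the last
    partial window is kept."""
    chrom, start, end = region
    if window > end - start:
        raise ValueError("window exceeds region length")
    step = step or window // 2
    kept = [
        (a.start, a.end)
        for a in annotations
        if a.chrom == chrom and (element_filter is None or element_filter(a))
    ]
    rows = []
    w_start = start
    while w_start < end:
        w_end = min(w_start + window, end)
        covered = union_length(kept, clip=(w_start, w_end))
        rows.append(
            {
                "chrom": chrom,
                "start": w_start,
                "end": w_end,
                "fraction": covered / (w_end - w_start),
            }
        )
        w_start += step
    return pd.DataFrame(rows)


def random_region_comparison(
    genome_annotations: list[RepeatAnnotation],
    genome_extent: tuple[str, int, int],
    focal_region: tuple[int, int],
    n: int = 10,
    seed: int = 0,
    *,
    grouping: str = "class_family",
    max_tries: int = 10_000,
) -> pd.DataFrame:
    """Per-class coverage of the focal region versus ``n`` random regions of
    the same length drawn uniformly from the genome (seeded; random regions
    overlap neither the focal region nor each other).

    Returns one row per group with focal_fraction, random_mean and
    random_sd (sample sd over the ``n`` random regions).
    """
    if n < 1:
        raise ValueError("need n ≥ 1 random regions")
    chrom, g_start, g_end = genome_extent
    f_start, f_end = focal_region
    length = f_end - f_start
    if length <= 0:
        raise ValueError("focal region length must be > 0")
    if (g_end - g_start) < (n + 1) * length:
        raise ValueError("genome extent too small to place the random regions")
    rng = np.random.default_rng(seed)
    taken = [(f_start, f_end)]
    placed: list[tuple[int, int]] = []
    tries = 0
    while len(placed) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError(f"could not place {n} non-overlapping random regions")
        s = int(rng.integers(g_start, g_end - length + 1))
        e = s + length
        if any(s < te and ts < e for ts, te in taken):
            continue
        taken.append((s, e))
        placed.append((s, e))

    focal = class_coverage(genome_annotations, (chrom, f_start, f_end), grouping)
    focal = focal.set_index("group")["fraction"]
    randoms = [
        class_coverage(genome_annotations, (chrom, s, e), grouping)
        .set_index("group")["fraction"]
        for s, e in placed
    ]
    random_df = pd.DataFrame(randoms).reindex(
        columns=sorted(set(focal.index) | set().union(*[set(r.index) for r in randoms]))
    )
    random_df = random_df.fillna(0.0)
    rows = []
    for group in random_df.columns:
        rows.append(
            {
                "group": group,
                "focal_fraction": float(focal.get(group, 0.0)),
                "random_mean": float(random_df[group].mean()),
                "random_sd": float(random_df[group].std(ddof=1)) if n > 1 else float("nan"),
            }
        )
    return pd.DataFrame(rows)
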