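"""Retro-copy (processed-gene) detection by alignment and intron-loss calling.

A retro-copy arises when a processed mRNA is reverse-transcribed and
re-inserted into the genome: the derived copy resembles its parent gene but
lacks introns.  Given intron-containing parent gene models and a target
genomic region, this module

1. finds local alignments between each gene and the region with an
   exact-k-mer seed → collinear chain → extension strategy (both strands);
2. applies the candidate thresholds — strictly more than ``min_aligned``
   bases aligned at strictly more than ``min_identity`` length-weighted
   identity;
3. classifies every exon–exon junction: *collapsed* when the target-side
   gap between the flanking exon alignments is at most ``max_junction_gap``
   while the parent intron is longer than that, *retained* when the target
   gap matches the intron length within 20%, *ambiguous* otherwise,
   *uncalled* when a flanking exon is unaligned;
4. issues a verdict per gene × locus: ``retrocopy`` when at least half of
   the junctions are collapsed, ``duplication_with_introns`` when at least
   half are retained, ``no_candidate`` when the thresholds fail, and
   ``no_intron_evidence`` when the gene has no junctions (single exon) or
   the junction calls are inconclusive.

Alignment identity is computed from an edit-distance alignment (edlib) of
each chained block, so small indels are tolerated even though seeding is
exact.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

__all__ = [
    "GeneModel",
    "AlignmentBlock",
    "RetrocopyCall",
    "chain_alignments",
    "candidate_filter",
    "detect_intron_loss",
    "call_retrocopies",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """A parent gene: its genomic sequence and exon intervals (0-based,
    half-open, on the gene sequence).  Introns are the gaps between
    consecutive exons."""

    gene_id: str
    sequence: str
    exons: tuple[tuple[int, int], ...]
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene needs ≥1 exon")
        prev_end = -1
        for start, end in self.exons:
            if not (0 <= start < end <= len(self.sequence)):
                raise ValueError(f"{self.gene_id}: exon ({start},{end}) outside gene")
            if start < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = end

    @property
    def n_junctions(self) -> int:
        return len(self.exons) - 1

    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(self.n_junctions)
        ]

    def mrna(self) -> str:
        """Concatenated exon sequence (the processed transcript)."""
        return "".join(self.sequence[s:e] for s, e in self.exons)


@dataclass
class AlignmentBlock:
    """One gapless-ish local alignment between query (gene) and target
    (region).  Coordinates are 0-based half-open on the forward strand of
    each sequence; for ``strand == '-'`` increasing query positions map to
    decreasing target positions."""

    q_start: int
    q_end: int
    t_start: int
    t_end: int
    strand: str
    identity: float
    matches: int

    @property
    def q_len(self) -> int:
        return self.q_end - self.q_start

    def target_at(self, q: int) -> int:
        """Target coordinate corresponding to query position ``q`` under the
        block's (approximately linear) mapping; extrapolates past the block
        ends, which is only meaningful for small overhangs."""
        if self.strand == "+":
            return self.t_start + (q - self.q_start)
        return self.t_end - (q - self.q_start)


class TargetIndex:
    """Exact k-mer index of a target sequence, reusable across queries."""

    def __init__(self, sequence: str, k: int = 12, max_hits: int = 64):
        if k < 8:
            raise ValueError("seed length k must be ≥ 8")
        if not sequence:
            raise ValueError("empty target sequence")
        self.sequence = sequence.upper()
        self.k = k
        self.max_hits = max_hits
        index: dict[str, list[int]] = defaultdict(list)
        seq = self.sequence
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" not in kmer:
                index[kmer].append(i)
        # drop hyper-repetitive seeds
        self.index = {km: pos for km, pos in index.items() if len(pos) <= max_hits}

    def seeds(self, query: str) -> list[tuple[int, int]]:
        k = self.k
        out = []
        q = query.upper()
        for i in range(len(q) - k + 1):
            kmer = q[i : i + k]
            if "N" in kmer:
                continue
            for j in self.index.get(kmer, ()):
                out.append((i, j))
        return out


def _cigar_stats(cigar: str) -> tuple[int, int]:
    """(matches, alignment columns) from an extended CIGAR (=/X/I/D)."""
    matches = cols = 0
    for count, op in re.findall(r"(\d+)([=XID])", cigar):
        n = int(count)
        cols += n
        if op == "=":
            matches += n
    return matches, cols


def _extend_ungapped(
    query: str, target: str, q: int, t: int, direction: int, xdrop: int = 12
) -> int:
    """Greedy ungapped X-drop extension; returns the number of columns
    advanced in ``direction`` (+1 forward from q/t, −1 backward from
    q−1/t−1)."""
    score = best = 0
    best_steps = 0
    steps = 0
    lq, lt = len(query), len(target)
    while True:
        if direction > 0:
            qi, ti = q + steps, t + steps
            if qi >= lq or ti >= lt:
                break
        else:
            qi, ti = q - 1 - steps, t - 1 - steps
            if qi < 0 or ti < 0:
                break
        score += 1 if query[qi] == target[ti] else -2
        steps += 1
        if score > best:
            best, best_steps = score, steps
        elif best - score > xdrop:
            break
    return best_steps


def chain_alignments(
    query: str,
    target: "str | TargetIndex",
    k: int = 12,
    min_chain_score: int = 20,
    *,
    max_seed_gap: int = 250,
    diag_band: int = 15,
    min_block_identity: float = 0.5,
) -> list[AlignmentBlock]:
    """Seed-chain-extend local alignment of ``query`` against ``target``.

    Exact k-mer seed matches are grouped into collinear chains (seeds on
    nearby diagonals with query gaps ≤ ``max_seed_gap``); chains whose
    summed seed coverage reaches ``min_chain_score`` bases are extended
    outward by greedy X-drop and scored with an edit-distance alignment.
    Both strands are searched; blocks come back sorted by target position.
    """
    if not query:
        raise ValueError("empty query sequence")
    index = target if isinstance(target, TargetIndex) else TargetIndex(target, k=k)
    blocks: list[AlignmentBlock] = []
    for strand, q_seq in (("+", query.upper()), ("-", reverse_complement(query).upper())):
        blocks.extend(
            _chain_one_strand(
                q_seq,
                index,
                strand,
                min_chain_score=min_chain_score,
                max_seed_gap=max_seed_gap,
                diag_band=diag_band,
                min_block_identity=min_block_identity,
            )
        )
    # minus-strand blocks carry rc-frame query coords; flip to forward frame
    lq = len(query)
    for b in blocks:
        if b.strand == "-":
            b.q_start, b.q_end = lq - b.q_end, lq - b.q_start
    blocks.sort(key=lambda b: (b.t_start, b.q_start))
    return blocks


def _chain_one_strand(
    q_seq: str,
    index: TargetIndex,
    strand: str,
    *,
    min_chain_score: int,
    max_seed_gap: int,
    diag_band: int,
    min_block_identity: float,
) -> list[AlignmentBlock]:
    k = index.k
    seeds = index.seeds(q_seq)
    if not seeds:
        return []
    # cluster on (diagonal, query-position) adjacency
    seeds.sort(key=lambda s: (s[1] - s[0], s[0]))
    clusters: list[list[tuple[int, int]]] = []
    for q, t in seeds:
        d = t - q
        if clusters:
            lq, lt = clusters[-1][-1]
            if abs(d - (lt - lq)) <= diag_band and 0 <= q - lq <= max_seed_gap:
                clusters[-1].append((q, t))
                continue
        clusters.append([(q, t)])
    # merge clusters that are collinear continuations of each other
    clusters.sort(key=lambda c: (c[0][1] - c[0][0], c[0][0]))
    merged: list[list[tuple[int, int]]] = []
    for c in clusters:
        if merged:
            prev = merged[-1]
            pd_, pq = prev[-1][1] - prev[-1][0], prev[-1][0]
            cd, cq = c[0][1] - c[0][0], c[0][0]
            if abs(cd - pd_) <= diag_band and 0 <= cq - pq <= max_seed_gap:
                prev.extend(c)
                continue
        merged.append(c)

    target = index.sequence
    out = []
    for cluster in merged:
        qs = min(q for q, _ in cluster)
        qe = max(q for q, _ in cluster) + k
        ts = min(t for _, t in cluster)
        te = max(t for _, t in cluster) + k
        coverage = min(qe - qs, len(set(q for q, _ in cluster)) * k)
        if coverage < min_chain_score:
            continue
        back = _extend_ungapped(q_seq, target, qs, ts, -1)
        fwd = _extend_ungapped(q_seq, target, qe, te, +1)
        qs, ts = qs - back, ts - back
        qe, te = qe + fwd, te + fwd
        res = edlib.align(q_seq[qs:qe], target[ts:te], mode="NW", task="path")
        matches, cols = _cigar_stats(res["cigar"])
        identity = matches / cols if cols else 0.0
        if identity < min_block_identity:
            continue
        out.append(
            AlignmentBlock(
                q_start=qs,
                q_end=qe,
                t_start=ts,
                t_end=te,
                strand=strand,
                identity=identity,
                matches=matches,
            )
        )
    return out


def candidate_filter(
    blocks: list[AlignmentBlock],
    min_aligned: int = 500,
    min_identity: float = 0.80,
) -> tuple[bool, dict]:
    """Candidate duplication thresholds: strictly more than ``min_aligned``
    query bases aligned in total AND length-weighted identity strictly above
    ``min_identity``."""
    total = sum(b.q_len for b in blocks)
    identity = (
        sum(b.identity * b.q_len for b in blocks) / total if total else 0.0
    )
    passed = total > min_aligned and identity > min_identity
    return passed, {"aligned_bp": total, "identity": identity}


def detect_intron_loss(
    gene: GeneModel,
    blocks: list[AlignmentBlock],
    *,
    max_junction_gap: int = 30,
    retained_tol: float = 0.20,
    flank: int = 20,
) -> list[str]:
    """Classify each exon–exon junction of ``gene`` given alignment blocks.

    For junction *j* the query positions of interest are the end of exon *j*
    and the start of exon *j+1*; the blocks covering those flanks determine
    the target-side gap.  Returns one label per junction from
    {"collapsed", "retained", "ambiguous", "uncalled"}.
    """
    labels = []
    strands = {b.strand for b in blocks}
    for (ex_end, nx_start) in gene.introns():
        intron_len = nx_start - ex_end
        left = _covering_block(blocks, ex_end - 1, flank)
        right = _covering_block(blocks, nx_start, flank)
        if left is None or right is None or left.strand != right.strand:
            labels.append("uncalled")
            continue
        t_left = left.target_at(ex_end)
        t_right = right.target_at(nx_start)
        gap = (t_right - t_left) if left.strand == "+" else (t_left - t_right)
        if gap <= max_junction_gap and intron_len > max_junction_gap:
            labels.append("collapsed")
        elif abs(gap - intron_len) <= retained_tol * intron_len:
            labels.append("retained")
        else:
            labels.append("ambiguous")
    if len(strands) > 1 and all(lab == "uncalled" for lab in labels):
        # mixed-strand chimeric hit with no consistent junction
        pass
    return labels


def _covering_block(
    blocks: list[AlignmentBlock], q: int, flank: int
) -> AlignmentBlock | None:
    """Block whose query span covers position ``q`` (with ``flank`` bp of
    slack at the block edge); prefers the block covering most of the
    neighbourhood."""
    best = None
    best_cov = 0
    for b in blocks:
        if b.q_start - flank <= q < b.q_end + flank:
            cov = min(b.q_end, q + flank + 1) - max(b.q_start, q - flank)
            if cov > best_cov:
                best, best_cov = b, cov
    return best


@dataclass
class RetrocopyCall:
    """Verdict for one parent-gene × target-locus comparison."""

    gene_id: str
    t_start: int | None
    t_end: int | None
    aligned_bp: int
    identity: float
    junctions_collapsed: int
    junctions_retained: int
    junctions_total: int
    verdict: str
    blocks: list[AlignmentBlock] = field(default_factory=list)

    def as_row(self) -> dict:
        return {
            "gene": self.gene_id,
            "target_start": self.t_start,
            "target_end": self.t_end,
            "aligned_bp": self.aligned_bp,
            "identity": round(self.identity, 4),
            "junctions_collapsed": self.junctions_collapsed,
            "junctions_retained": self.junctions_retained,
            "junctions_total": self.junctions_total,
            "verdict": self.verdict,
        }


def _split_loci(blocks: list[AlignmentBlock], locus_gap: int) -> list[list[AlignmentBlock]]:
    loci: list[list[AlignmentBlock]] = []
    for b in sorted(blocks, key=lambda b: b.t_start):
        if loci and b.t_start - max(x.t_end for x in loci[-1]) <= locus_gap:
            loci[-1].append(b)
        else:
            loci.append([b])
    return loci


def call_retrocopies(
    genes: list[GeneModel],
    region: str,
    *,
    k: int = 12,
    min_aligned: int = 500,
    min_identity: float = 0.80,
    max_junction_gap: int = 30,
    retained_tol: float = 0.20,
    locus_gap: int = 10_000,
    min_chain_score: int = 20,
) -> list[RetrocopyCall]:
    """Full pipeline: align every gene to ``region``, filter candidates and
    classify intron loss.  One call per gene × locus; a gene with no
    passing locus yields a single ``no_candidate`` call summarising its
    best (possibly empty) alignment."""
    if not region:
        raise ValueError("empty region sequence")
    index = TargetIndex(region, k=k)
    calls: list[RetrocopyCall] = []
    for gene in genes:
        blocks = chain_alignments(
            gene.sequence, index, k=k, min_chain_score=min_chain_score
        )
        any_pass = False
        for locus in _split_loci(blocks, locus_gap):
            passed, summary = candidate_filter(locus, min_aligned, min_identity)
            if not passed:
                continue
            any_pass = True
            labels = detect_intron_loss(
                gene,
                locus,
                max_junction_gap=max_junction_gap,
                retained_tol=retained_tol,
            )
            collapsed = labels.count("collapsed")
            retained = labels.count("retained")
            total = gene.n_junctions
            need = -(-total // 2)  # ceil(total/2)
            if total == 0:
                verdict = "no_intron_evidence"
            elif collapsed >= need:
                verdict = "retrocopy"
            elif retained >= need:
                verdict = "duplication_with_introns"
            else:
                verdict = "no_intron_evidence"
            calls.append(
                RetrocopyCall(
                    gene_id=gene.gene_id,
                    t_start=min(b.t_start for b in locus),
                    t_end=max(b.t_end for b in locus),
                    aligned_bp=summary["aligned_bp"],
                    identity=summary["identity"],
                    junctions_collapsed=collapsed,
                    junctions_retained=retained,
                    junctions_total=total,
                    verdict=verdict,
                    blocks=locus,
                )
            )
        if not any_pass:
            passed, summary = candidate_filter(blocks, min_aligned, min_identity)
            calls.append(
                RetrocopyCall(
                    gene_id=gene.gene_id,
                    t_start=min((b.t_start for b in blocks), default=None),
                    t_end=max((b.t_end for b in blocks), default=None),
                    aligned_bp=summary["aligned_bp"],
                    identity=summary["identity"],
                    junctions_collapsed=0,
                    junctions_retained=0,
                    junctions_total=gene.n_junctions,
                    verdict="no_candidate",
                    blocks=blocks,
                )
            )
    return calls


def calls_to_frame(calls: list[RetrocopyCall]) -> pd.DataFrame:
    return pd.DataFrame([c.as_row() for c in calls])


def blocks_to_frame(call: RetrocopyCall) -> pd.DataFrame:
    """PAF-like dot-plot table for one call (query/target block intervals)."""
    rows = [
        {
            "gene": call.gene_id,
            "q_start": b.q_start,
            "q_end": b.q_end,
            "t_start": b.t_start,
            "t_end": b.t_end,
            "strand": b.strand,
            "identity": round(b.identity, 4),
            "matches": b.matches,
        }
        for b in call.blocks
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "q_start",
            "q_end",
            "t_start",
            "t_end",
            "strand",
            "identity",
            "matches",
        ],
    )
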