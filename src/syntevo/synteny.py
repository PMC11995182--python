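"""Collinear-block detection in gene-rank space.

Homolog pairs become dot-plot anchors (rank coordinates); anchors are
chained per chromosome pair and orientation by dynamic programming under
an additive score (anchor scores minus a per-rank gap penalty, both rank
gaps capped); chains are extracted greedily by descending score so each
anchor joins at most one block. Depth ratios — the polyploidy signal — are
the modal number of blocks covering a gene on each side, and blocks are
classified (syntenic / inversion / translocation / duplication) against an
exact maximum-weight one-to-one chromosome correspondence.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .types import Anchor, CollinearBlock, Genome, HomologPair

__all__ = [
    "DepthRatio",
    "build_anchors",
    "chain_anchors",
    "estimate_depth_ratio",
    "classify_blocks",
    "dominant_chromosome_pairs",
]


def build_anchors(
    pairs: list[HomologPair], genome_a: Genome, genome_b: Genome
) -> tuple[list[Anchor], list[HomologPair]]:
    """One anchor per resolvable pair; unresolvable pairs are returned as
    rejects, never fatal. The anchor set is independent of pair order."""
    anchors: list[Anchor] = []
    rejects: list[HomologPair] = []
    for p in pairs:
        if p.gene_a not in genome_a or p.gene_b not in genome_b:
            rejects.append(p)
            continue
        ga, gb = genome_a[p.gene_a], genome_b[p.gene_b]
        anchors.append(
            Anchor(
                gene_a=p.gene_a, gene_b=p.gene_b,
                chr_a=ga.chromosome, rank_a=ga.rank,
                chr_b=gb.chromosome, rank_b=gb.rank,
                strand_match="same" if ga.strand == gb.strand else "opposite",
                score=1.0 if p.score is None else p.score,
            )
        )
    anchors.sort(key=lambda a: (a.chr_a, a.rank_a, a.chr_b, a.rank_b, a.gene_a, a.gene_b))
    return anchors, rejects


def _best_chain(
    anchors: list[Anchor], orientation: str, max_gap: int, gap_penalty: float
) -> tuple[float, list[int]]:
    """Best single chain by DP. Anchors must share (chr_a, chr_b) and be
    sorted by (rank_a, rank_b). Returns (score, indices into anchors)."""
    n = len(anchors)
    sign = 1 if orientation == "+" else -1
    best_score = [a.score for a in anchors]
    best_len = [1] * n
    prev = [-1] * n
    for i in range(n):
        ai = anchors[i]
        for j in range(i):
            aj = anchors[j]
            gap_a = ai.rank_a - aj.rank_a - 1
            if gap_a < 0:
                continue
            gap_b = sign * (ai.rank_b - aj.rank_b) - 1
            if gap_b < 0 or gap_a > max_gap or gap_b > max_gap:
                continue
            cand = best_score[j] + ai.score - gap_penalty * (gap_a + gap_b)
            if cand > best_score[i] or (
                cand == best_score[i] and best_len[j] + 1 > best_len[i]
            ):
                best_score[i] = cand
                best_len[i] = best_len[j] + 1
                prev[i] = j
    # deterministic argmax: score, then chain length, then smallest sort index
    top = max(range(n), key=lambda i: (best_score[i], best_len[i], -i))
    chain = []
    i = top
    while i != -1:
        chain.append(i)
        i = prev[i]
    chain.reverse()
    return best_score[top], chain


def chain_anchors(
    anchors: list[Anchor],
    max_gap: int = 25,
    min_block_size: int = 5,
    gap_penalty: float = 1.0,
) -> list[CollinearBlock]:
    """Partition anchors into maximal-scoring collinear chains.

    Chaining runs per (chr_a, chr_b) group and per orientation; blocks are
    extracted greedily by descending (score, size, chromosome names) and
    extraction in a group stops once the best remaining chain is shorter
    than ``min_block_size``.
    """
    groups: dict[tuple[str, str], list[Anchor]] = {}
    for a in anchors:
        groups.setdefault((a.chr_a, a.chr_b), []).append(a)
    blocks: list[CollinearBlock] = []
    for (ca, cb) in sorted(groups):
        remaining = sorted(groups[(ca, cb)], key=lambda a: (a.rank_a, a.rank_b))
        while remaining:
            candidates = []
            for orient in ("+", "-"):
                score, idx = _best_chain(remaining, orient, max_gap, gap_penalty)
                candidates.append((score, len(idx), orient == "+", orient, idx))
            candidates.sort(key=lambda t: (t[0], t[1], t[2]), reverse=True)
            score, n, _, orient, idx = candidates[0]
            if n < min_block_size:
                break
            chosen = [remaining[i] for i in idx]
            if orient == "-":
                chosen.sort(key=lambda a: a.rank_a)  # block order: rank_a ascending
            blocks.append(
                CollinearBlock(
                    block_id=len(blocks), anchors=chosen, chr_a=ca, chr_b=cb,
                    orientation=orient, chain_score=score,
                )
            )
            taken = set(idx)
            remaining = [a for i, a in enumerate(remaining) if i not in taken]
    # stable global ordering and ids: by score desc then chromosomes
    blocks.sort(key=lambda b: (-b.chain_score, -len(b.anchors), b.chr_a, b.chr_b,
                               b.anchors[0].rank_a))
    for i, b in enumerate(blocks):
        b.block_id = i
    return blocks


@dataclass
class DepthRatio:
    """Block-coverage histograms per genome and the modal ratio.

    ``ratio`` is "x:y" with x the modal nonzero coverage of genome_b genes
    and y that of genome_a genes, so (reference, post-triplication genome)
    reads "1:3".
    """

    histogram_a: dict[int, float] = field(default_factory=dict)
    histogram_b: dict[int, float] = field(default_factory=dict)
    modal_a: int = 0
    modal_b: int = 0
    ratio: str = "0:0"


def _coverage(blocks: list[CollinearBlock], genome: Genome, side: str) -> np.ndarray:
    cover: dict[str, np.ndarray] = {
        c: np.zeros(genome.n_genes(c), dtype=int) for c in genome.chromosomes
    }
    for b in blocks:
        chrom = b.chr_a if side == "a" else b.chr_b
        lo, hi = b.span_a if side == "a" else b.span_b
        if chrom in cover:
            cover[chrom][lo:hi + 1] += 1
    return np.concatenate([cover[c] for c in genome.chromosomes]) if cover else np.zeros(0, int)


def estimate_depth_ratio(
    blocks: list[CollinearBlock], genome_a: Genome, genome_b: Genome
) -> DepthRatio:
    """Count, for every gene, how many blocks of the other genome span its
    rank; report histograms and the modal nonzero coverages as "a:b"."""
    if not blocks:
        warnings.warn("no blocks: depth ratio undefined (0:0)")
        return DepthRatio()
    cov_a = _coverage(blocks, genome_a, "a")
    cov_b = _coverage(blocks, genome_b, "b")

    def hist(cov: np.ndarray) -> tuple[dict[int, float], int]:
        counts = Counter(int(v) for v in cov)
        total = sum(counts.values())
        h = {k: v / total for k, v in sorted(counts.items())}
        nonzero = {k: v for k, v in counts.items() if k > 0}
        modal = max(sorted(nonzero), key=lambda k: nonzero[k]) if nonzero else 0
        return h, modal

    ha, ma = hist(cov_a)
    hb, mb = hist(cov_b)
    return DepthRatio(histogram_a=ha, histogram_b=hb, modal_a=ma, modal_b=mb,
                      ratio=f"{mb}:{ma}")


def dominant_chromosome_pairs(blocks: list[CollinearBlock]) -> set[tuple[str, str]]:
    """Maximum-weight one-to-one chromosome correspondence, weighted by
    summed block anchors, solved exactly."""
    weights: dict[tuple[str, str], int] = {}
    for b in blocks:
        weights[(b.chr_a, b.chr_b)] = weights.get((b.chr_a, b.chr_b), 0) + len(b.anchors)
    chroms_a = sorted({k[0] for k in weights})
    chroms_b = sorted({k[1] for k in weights})
    W = np.zeros((len(chroms_a), len(chroms_b)))
    for (ca, cb), w in weights.items():
        W[chroms_a.index(ca), chroms_b.index(cb)] = w
    rows, cols = linear_sum_assignment(W, maximize=True)
    return {
        (chroms_a[i], chroms_b[j]) for i, j in zip(rows, cols) if W[i, j] > 0
    }


def classify_blocks(
    blocks: list[CollinearBlock],
    genome_a: Genome,
    genome_b: Genome,
    duplication_overlap: float = 0.5,
) -> list[CollinearBlock]:
    """Label blocks at gene-order resolution.

    duplication: the block's rank interval overlaps a higher-scoring
    block's interval by more than ``duplication_overlap`` of its own length
    on either side; syntenic / inversion: "+" / "-" orientation on a
    dominant chromosome pair; translocation: any orientation elsewhere.
    """
    dominant = dominant_chromosome_pairs(blocks)
    order = sorted(
        blocks, key=lambda b: (-b.chain_score, -len(b.anchors), b.chr_a, b.chr_b,
                               b.anchors[0].rank_a)
    )

    def overlap(lo1, hi1, lo2, hi2) -> int:
        return max(0, min(hi1, hi2) - max(lo1, lo2) + 1)

    for i, b in enumerate(order):
        dup = False
        for better in order[:i]:
            if better.chr_a == b.chr_a:
                lo, hi = b.span_a
                blo, bhi = better.span_a
                if overlap(lo, hi, blo, bhi) > duplication_overlap * (hi - lo + 1):
                    dup = True
                    break
            if better.chr_b == b.chr_b:
                lo, hi = b.span_b
                blo, bhi = better.span_b
                if overlap(lo, hi, blo, bhi) > duplication_overlap * (hi - lo + 1):
                    dup = True
                    break
        if dup:
            b.classification = "duplication"
        elif (b.chr_a, b.chr_b) in dominant:
            b.classification = "syntenic" if b.orientation == "+" else "inversion"
        else:
            b.classification = "translocation"
    return blocks


def classification_counts(blocks: list[CollinearBlock]) -> dict[str, dict[str, int]]:
    """Per-class block and anchor counts."""
    out: dict[str, dict[str, int]] = {}
    for b in blocks:
        d = out.setdefault(b.classification, {"blocks": 0, "anchors": 0})
        d["blocks"] += 1
        d["anchors"] += len(b.anchors)
    return out
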