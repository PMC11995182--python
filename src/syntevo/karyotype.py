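"""Ancestral karyotype reconstruction from cross-species collinearity.

The genomes are segmented into ancestral blocks by cutting every genome at
the union of all pairwise collinear-block boundaries, propagated through
the homology families until no genome splits an adjacency another genome
keeps (a common refinement of all pairwise segmentations). Oriented block
adjacencies observed along extant chromosomes are then voted on across
species — optionally with a Dollo criterion on a species tree, keeping
only adjacencies seen on both sides of the root — and greedily linearised
into contiguous ancestral regions (CARs) under linearity constraints
(each block extremity used once, no cycles). Per-branch rearrangements are
classified by comparing a descendant's block order against the CARs:
orientation-flipped runs are inversions, and the distribution of CAR
fragments across descendant chromosomes yields fusion, fission and
(reciprocal) translocation counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from io import StringIO

from Bio import Phylo

from .types import CollinearBlock, Genome

__all__ = [
    "AncestralBlockSet",
    "AdjacencyGraph",
    "AncestralKaryotype",
    "RearrangementSummary",
    "partition_ancestral_blocks",
    "score_adjacencies",
    "linearize_cars",
    "classify_rearrangements",
]


# ---------------------------------------------------------------------------
# ancestral block partition


class _UnionFind:
    def __init__(self):
        self.parent: dict = {}

    def find(self, x):
        p = self.parent.setdefault(x, x)
        if p != x:
            p = self.parent[x] = self.find(p)
        return p

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller representative wins
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


@dataclass
class AncestralBlockSet:
    """Ancestral blocks and their ordered, oriented projection onto every
    genome. Projections are (block_id, orientation, start_rank, end_rank)
    with inclusive rank bounds; a block id appears in >= min_support
    species."""

    block_ids: list[int]
    projections: dict[str, dict[str, list[tuple[int, str, int, int]]]]
    support: dict[int, int]
    block_n_genes: dict[int, int]
    dropped: list[tuple[str, str, int, int, int, str]] = field(default_factory=list)


def partition_ancestral_blocks(
    pairwise_blocks: dict[tuple[str, str], list[CollinearBlock]],
    genomes: dict[str, Genome],
    min_support: int = 2,
    min_genes: int = 1,
) -> AncestralBlockSet:
    """Cut every genome at the union of projected pairwise block
    boundaries and group the resulting minimal segments across species.

    Segments supported in fewer than ``min_support`` species, or shorter
    than ``min_genes``, are dropped with a report entry. Adding a species
    can only refine the segmentation (the cut set only grows).
    """
    species = sorted(genomes)
    # homology families over (species, gene_id) from block anchors
    uf = _UnionFind()
    anchored: set[tuple[str, str]] = set()
    for (sa, sb), blocks in sorted(pairwise_blocks.items()):
        for b in blocks:
            for a in b.anchors:
                uf.union((sa, a.gene_a), (sb, a.gene_b))
                anchored.add((sa, a.gene_a))
                anchored.add((sb, a.gene_b))
    family_of: dict[tuple[str, str], tuple[str, str]] = {
        key: uf.find(key) for key in anchored
    }
    # family sequences per chromosome: (gene rank, family, strand)
    fam_seq: dict[str, dict[str, list[tuple[int, tuple, str]]]] = {}
    pos_of: dict[tuple[str, str], dict[tuple, list[int]]] = {}
    for sp in species:
        fam_seq[sp] = {}
        for chrom in genomes[sp].chromosomes:
            seq = []
            for g in genomes[sp].genes_on(chrom):
                fam = family_of.get((sp, g.gene_id))
                if fam is not None:
                    seq.append((g.rank, fam, g.strand))
            fam_seq[sp][chrom] = seq

    # initial cuts from pairwise block boundaries, expressed as broken
    # family adjacencies
    gene_pos: dict[tuple[str, str], tuple[str, int]] = {}
    for sp in species:
        for chrom, seq in fam_seq[sp].items():
            for i, (rank, fam, strand) in enumerate(seq):
                gene = genomes[sp].gene_at(chrom, rank)
                gene_pos[(sp, gene.gene_id)] = (chrom, i)

    cuts: dict[str, dict[str, set[int]]] = {
        sp: {c: set() for c in genomes[sp].chromosomes} for sp in species
    }

    def add_cut(sp: str, chrom: str, k: int) -> bool:
        seq = fam_seq[sp][chrom]
        if 0 < k < len(seq) and k not in cuts[sp][chrom]:
            cuts[sp][chrom].add(k)
            return True
        return False

    broken: set[frozenset] = set()
    for (sa, sb), blocks in sorted(pairwise_blocks.items()):
        for b in blocks:
            for side, sp in (("a", sa), ("b", sb)):
                genes = [a.gene_a if side == "a" else a.gene_b for a in b.anchors]
                positions = sorted(gene_pos[(sp, g)][1] for g in genes if (sp, g) in gene_pos)
                if not positions:
                    continue
                chrom = gene_pos[(sp, genes[0])][0]
                add_cut(sp, chrom, positions[0])
                add_cut(sp, chrom, positions[-1] + 1)

    def record_broken() -> None:
        for sp in species:
            for chrom, ks in cuts[sp].items():
                seq = fam_seq[sp][chrom]
                for k in ks:
                    broken.add(frozenset((seq[k - 1][1], seq[k][1])))

    record_broken()
    # propagate until no genome keeps an adjacency another genome cuts
    changed = True
    while changed:
        changed = False
        for sp in species:
            for chrom, seq in fam_seq[sp].items():
                for k in range(1, len(seq)):
                    if k in cuts[sp][chrom]:
                        continue
                    if frozenset((seq[k - 1][1], seq[k][1])) in broken:
                        add_cut(sp, chrom, k)
                        changed = True
        if changed:
            record_broken()

    # segments between cuts
    canonical_strand: dict[tuple, str] = {}
    segments: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for sp in species:
        segments[sp] = {}
        for chrom, seq in fam_seq[sp].items():
            bounds = sorted(cuts[sp][chrom]) + [len(seq)]
            segs = []
            start = 0
            for end in bounds:
                if end > start:
                    segs.append((start, end))
                start = end
            segments[sp][chrom] = segs
            for _, fam, strand in seq:
                canonical_strand.setdefault(fam, strand)

    # group segments by canonical family signature
    by_sig: dict[tuple, list[tuple[str, str, int, int, str]]] = {}
    for sp in species:
        for chrom, segs in segments[sp].items():
            seq = fam_seq[sp][chrom]
            for (start, end) in segs:
                fams = tuple(f for _, f, _ in seq[start:end])
                rev = tuple(reversed(fams))
                if rev < fams:
                    sig, orient = rev, "-"
                elif fams < rev:
                    sig, orient = fams, "+"
                else:  # palindromic or single family: orient by strand
                    sig = fams
                    orient = "+" if seq[start][2] == canonical_strand[fams[0]] else "-"
                by_sig.setdefault(sig, []).append((sp, chrom, start, end, orient))

    kept = []
    dropped: list[tuple[str, str, int, int, int, str]] = []
    for sig in sorted(by_sig):
        occ = by_sig[sig]
        n_species = len({sp for sp, *_ in occ})
        if len(sig) < min_genes:
            reason = "short"
        elif n_species < min_support:
            reason = "support"
        else:
            kept.append(sig)
            continue
        for sp, chrom, start, end, _ in occ:
            seq = fam_seq[sp][chrom]
            dropped.append((sp, chrom, seq[start][0], seq[end - 1][0], len(sig), reason))

    block_id_of = {sig: i for i, sig in enumerate(kept)}
    projections: dict[str, dict[str, list[tuple[int, str, int, int]]]] = {
        sp: {c: [] for c in genomes[sp].chromosomes} for sp in species
    }
    support: dict[int, int] = {}
    for sig in kept:
        bid = block_id_of[sig]
        support[bid] = len({sp for sp, *_ in by_sig[sig]})
        for sp, chrom, start, end, orient in by_sig[sig]:
            seq = fam_seq[sp][chrom]
            projections[sp][chrom].append((bid, orient, seq[start][0], seq[end - 1][0]))
    for sp in species:
        for chrom in projections[sp]:
            projections[sp][chrom].sort(key=lambda t: t[2])
    return AncestralBlockSet(
        block_ids=sorted(block_id_of.values()),
        projections=projections,
        support=support,
        block_n_genes={block_id_of[s]: len(s) for s in kept},
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# adjacency consensus


@dataclass
class AdjacencyGraph:
    """Oriented block extremities and the species-weighted adjacencies
    between them. An extremity is (block_id, 'h'|'t')."""

    blocks: set[int]
    weights: dict[frozenset, float]

    def edges(self) -> list[tuple[float, tuple, tuple]]:
        out = []
        for pair, w in self.weights.items():
            e1, e2 = sorted(pair)
            out.append((w, e1, e2))
        out.sort(key=lambda t: (-t[0], t[1], t[2]))
        return out


def _chromosome_adjacencies(blocks_on_chrom: list[tuple[int, str, int, int]]):
    """Extremity pairs between consecutive oriented blocks. A '+' block
    exposes its head on the left and tail on the right."""
    for (b1, o1, *_), (b2, o2, *_) in zip(blocks_on_chrom, blocks_on_chrom[1:]):
        if b1 == b2:
            continue
        right = (b1, "t" if o1 == "+" else "h")
        left = (b2, "h" if o2 == "+" else "t")
        yield frozenset((right, left))


def score_adjacencies(
    block_set: AncestralBlockSet,
    species_tree: str | None = None,
) -> AdjacencyGraph:
    """Weight each observed adjacency by the number of species exhibiting
    it. With a Newick tree, a Dollo criterion applies: an adjacency is an
    ancestral candidate only if observed in species on at least two sides
    of the root; others get weight 0 (and are excluded)."""
    seen_by: dict[frozenset, set[str]] = {}
    for sp, chroms in block_set.projections.items():
        for chrom, blocks in chroms.items():
            for adj in _chromosome_adjacencies(blocks):
                seen_by.setdefault(adj, set()).add(sp)
    clade_of: dict[str, int] = {}
    if species_tree is not None:
        handle = StringIO(species_tree) if species_tree.strip().startswith("(") else species_tree
        tree = Phylo.read(handle, "newick")
        for i, clade in enumerate(tree.root.clades):
            for leaf in clade.get_terminals():
                clade_of[leaf.name] = i
    weights: dict[frozenset, float] = {}
    for adj, sps in seen_by.items():
        if species_tree is not None:
            sides = {clade_of[sp] for sp in sps if sp in clade_of}
            if len(sides) < 2:
                continue
        weights[adj] = float(len(sps))
    all_blocks = set(block_set.block_ids)
    return AdjacencyGraph(blocks=all_blocks, weights=weights)


@dataclass
class AncestralKaryotype:
    """Contiguous ancestral regions: ordered, oriented block lists."""

    cars: list[list[tuple[int, str]]]

    @property
    def n_chromosomes(self) -> int:
        return len(self.cars)


def linearize_cars(graph: AdjacencyGraph) -> AncestralKaryotype:
    """Greedy maximum-weight matching on extremities under linearity:
    each extremity joins at most one adjacency and cycle-closing edges are
    rejected. Connected paths become CARs; isolated blocks are singleton
    CARs. Deterministic tie-break by (weight, extremities)."""
    uf = _UnionFind()
    used: set[tuple] = set()
    partner: dict[tuple, tuple] = {}
    for w, e1, e2 in graph.edges():
        if e1 in partner or e2 in partner:
            continue
        b1, b2 = e1[0], e2[0]
        if uf.find(b1) == uf.find(b2):
            continue  # would close a cycle
        partner[e1] = e2
        partner[e2] = e1
        uf.union(b1, b2)
    cars: list[list[tuple[int, str]]] = []
    visited: set[int] = set()
    for start in sorted(graph.blocks):
        if start in visited:
            continue
        # walk to the end of the path containing `start`
        ext = (start, "h")
        if ext in partner:
            block, side = start, "h"
            seen = {start}
            while (block, side) in partner:
                nb, nside = partner[(block, side)]
                if nb in seen:
                    break
                seen.add(nb)
                block, side = nb, "t" if nside == "h" else "h"
            head_block, head_side = block, side
        else:
            head_block, head_side = start, "h"
        # traverse from the free end
        car: list[tuple[int, str]] = []
        block = head_block
        enter = "h" if head_side == "h" else "t"
        while True:
            orient = "+" if enter == "h" else "-"
            car.append((block, orient))
            visited.add(block)
            out = (block, "t" if enter == "h" else "h")
            nxt = partner.get(out)
            if nxt is None:
                break
            block = nxt[0]
            enter = nxt[1]
            if block in visited:
                break
        rev = [(b, "+" if o == "-" else "-") for b, o in reversed(car)]
        cars.append(min(car, rev))
    cars.sort(key=lambda c: (-len(c), c[0][0]))
    return AncestralKaryotype(cars=cars)


# ---------------------------------------------------------------------------
# rearrangement classification


@dataclass
class RearrangementSummary:
    fusion: int = 0
    fission: int = 0
    translocation: int = 0
    inversion: int = 0
    unclassifiable: list[int] = field(default_factory=list)


def _runs(values: list[int], target: int) -> int:
    n = 0
    prev = None
    for v in values:
        if v == target and prev != target:
            n += 1
        prev = v
    return n


def classify_rearrangements(
    ancestor: AncestralKaryotype,
    descendant: dict[str, list[tuple[int, str]]],
) -> RearrangementSummary:
    """Compare a descendant's ordered oriented block lists against the
    ancestral CARs.

    Inversions: per CAR fragment, maximal runs of blocks whose orientation
    is flipped relative to the CAR, counted up to whole-fragment reversal
    (a chromosome read backwards costs nothing). Fusions, fissions and
    translocations come from how CAR fragments distribute over descendant
    chromosomes: per connected component of the CAR-chromosome graph,
    fissions = max(0, chromosomes - CARs), fusions = max(0, CARs -
    chromosomes); remaining inter-chromosomal moves pair up into reciprocal
    translocations, an unpaired moved segment counting singly.
    """
    car_pos: dict[int, tuple[int, int, str]] = {}
    for ci, car in enumerate(ancestor.cars):
        for pos, (bid, orient) in enumerate(car):
            car_pos[bid] = (ci, pos, orient)
    summary = RearrangementSummary()
    # fragments: maximal same-CAR runs per descendant chromosome
    fragments: list[tuple[int, str, list[tuple[int, str]]]] = []  # (car, chrom, blocks)
    for chrom in sorted(descendant):
        blocks = []
        for bid, orient, *_ in descendant[chrom]:
            if bid not in car_pos:
                summary.unclassifiable.append(bid)
                continue
            blocks.append((bid, orient))
        run: list[tuple[int, str]] = []
        run_car = None
        for bid, orient in blocks:
            ci = car_pos[bid][0]
            if run and ci != run_car:
                fragments.append((run_car, chrom, run))
                run = []
            run_car = ci
            run.append((bid, orient))
        if run:
            fragments.append((run_car, chrom, run))

    # inversions
    for _car, _chrom, run in fragments:
        rel = [1 if orient == car_pos[bid][2] else -1 for bid, orient in run]
        summary.inversion += min(_runs(rel, -1), _runs(rel, 1))

    # fusion / fission / translocation bookkeeping
    uf = _UnionFind()
    car_chroms: dict[int, set[str]] = {}
    for car, chrom, _ in fragments:
        uf.union(("car", car), ("chrom", chrom))
        car_chroms.setdefault(car, set()).add(chrom)
    comps: dict[tuple, tuple[set[int], set[str]]] = {}
    for car, chrom, _ in fragments:
        root = uf.find(("car", car))
        cars, chroms = comps.setdefault(root, (set(), set()))
        cars.add(car)
        chroms.add(chrom)
    for cars, chroms in comps.values():
        fission = max(0, len(chroms) - len(cars))
        fusion = max(0, len(cars) - len(chroms))
        moves = sum(len(car_chroms[c]) - 1 for c in cars)
        summary.fission += fission
        summary.fusion += fusion
        summary.translocation += math.ceil(max(0, moves - fission) / 2)
    return summary
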