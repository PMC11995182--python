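"""Ancestral-block partitioning, adjacency consensus (with the Dollo
criterion), CAR linearisation, and rearrangement classification against
simulator event logs."""

import itertools

import pytest

from syntevo.karyotype import (
    AdjacencyGraph,
    AncestralKaryotype,
    classify_rearrangements,
    linearize_cars,
    partition_ancestral_blocks,
    score_adjacencies,
)
from syntevo.simulate import (
    Fusion,
    Inversion,
    SimulationConfig,
    Translocation,
    simulate_clade,
)
from syntevo.synteny import build_anchors, chain_anchors

TIPS6 = ("t1", "t2", "t3", "t4", "t5", "t6")
TREE6 = "((t1,t2,t3),(t4,t5,t6));"


def _pairwise_blocks(bundle, max_gap=0, min_block=3):
    genomes = bundle.tips
    out = {}
    for a, b in itertools.combinations(sorted(genomes), 2):
        anchors, _ = build_anchors(bundle.all_pairs(a, b), genomes[a], genomes[b])
        out[(a, b)] = chain_anchors(anchors, max_gap=max_gap, min_block_size=min_block)
    return out


def _reconstruct(bundle, tree=None, min_genes=1):
    blocks = _pairwise_blocks(bundle)
    block_set = partition_ancestral_blocks(blocks, bundle.tips, min_genes=min_genes)
    graph = score_adjacencies(block_set, species_tree=tree)
    return block_set, graph, linearize_cars(graph)


def test_identical_genomes_one_block_per_chromosome():
    cfg = SimulationConfig(seed=1, n_chromosomes=4, genes_per_chromosome=20,
                           wgt=False, tips=("x", "y"), with_cds=False)
    bundle = simulate_clade(cfg)
    block_set, _, karyo = _reconstruct(bundle)
    assert len(block_set.block_ids) == 4
    assert karyo.n_chromosomes == 4
    assert all(len(car) == 1 for car in karyo.cars)


def test_translocation_only_tips_recover_true_breakpoints():
    """Three tips derived by one reciprocal translocation each: the block
    partition's cut positions equal the union of true event breakpoints."""
    cfg = SimulationConfig(
        seed=2, n_chromosomes=4, genes_per_chromosome=25, wgt=False,
        tips=("x", "y", "z"), with_cds=False,
        event_schedule=[
            ("y", Translocation("chr1", "chr2", 10, 15)),
            ("z", Translocation("chr3", "chr4", 5, 20)),
        ],
    )
    bundle = simulate_clade(cfg)
    block_set, _, karyo = _reconstruct(bundle)
    # untouched tip x: segment boundaries sit exactly at the breakpoints
    cuts = {
        (chrom, seg[2])
        for chrom, lst in block_set.projections["x"].items()
        for seg in lst
        if seg[2] > 0
    }
    assert cuts == {("chr1", 10), ("chr2", 15), ("chr3", 5), ("chr4", 20)}
    assert karyo.n_chromosomes == 4


def test_dropping_a_species_never_refines_the_partition():
    cfg = SimulationConfig(
        seed=3, n_chromosomes=4, genes_per_chromosome=25, wgt=False,
        tips=("x", "y", "z"), with_cds=False,
        random_events={"y": (1, 1), "z": (1, 1)},
    )
    bundle = simulate_clade(cfg)
    full = partition_ancestral_blocks(_pairwise_blocks(bundle), bundle.tips)

    two = {k: v for k, v in bundle.tips.items() if k != "z"}
    blocks_two = {
        (a, b): v for (a, b), v in _pairwise_blocks(bundle).items()
        if a in two and b in two
    }
    reduced = partition_ancestral_blocks(blocks_two, two)

    def cutset(bs, sp):
        return {
            (chrom, seg[2])
            for chrom, lst in bs.projections[sp].items()
            for seg in lst
        }

    for sp in two:
        assert cutset(reduced, sp) <= cutset(full, sp)


class TestAdjacencies:
    def test_weights_equal_per_species_counts(self):
        cfg = SimulationConfig(seed=4, n_chromosomes=3, genes_per_chromosome=20,
                               wgt=False, tips=("x", "y", "z"), with_cds=False,
                               event_schedule=[("z", Translocation("chr1", "chr2", 8, 8))])
        bundle = simulate_clade(cfg)
        block_set = partition_ancestral_blocks(_pairwise_blocks(bundle), bundle.tips)
        graph = score_adjacencies(block_set)
        # brute-force recount
        for adj, w in graph.weights.items():
            count = 0
            for sp, chroms in block_set.projections.items():
                found = False
                for lst in chroms.values():
                    for (b1, o1, *_), (b2, o2, *_) in zip(lst, lst[1:]):
                        r = (b1, "t" if o1 == "+" else "h")
                        l = (b2, "h" if o2 == "+" else "t")
                        if frozenset((r, l)) == adj:
                            found = True
                count += found
            assert w == count

    def test_private_adjacency_zero_under_dollo(self):
        cfg = SimulationConfig(
            seed=5, n_chromosomes=4, genes_per_chromosome=25, wgt=False,
            tips=TIPS6, with_cds=False,
            event_schedule=[("t1", Translocation("chr1", "chr2", 10, 10))],
        )
        bundle = simulate_clade(cfg)
        block_set = partition_ancestral_blocks(_pairwise_blocks(bundle), bundle.tips)
        no_tree = score_adjacencies(block_set)
        dollo = score_adjacencies(block_set, species_tree=TREE6)
        private = [adj for adj, w in no_tree.weights.items() if w == 1]
        assert private, "translocation should create t1-private adjacencies"
        for adj in private:
            assert adj not in dollo.weights
        # ancestral adjacencies broken only in t1 keep the other 5 votes
        assert any(w == 5 for w in dollo.weights.values())


class TestLinearize:
    def test_disjoint_chains_become_cars(self):
        blocks = set(range(16))
        weights = {}
        for c in range(8):
            b1, b2 = 2 * c, 2 * c + 1
            weights[frozenset(((b1, "t"), (b2, "h")))] = 1.0
        karyo = linearize_cars(AdjacencyGraph(blocks=blocks, weights=weights))
        assert karyo.n_chromosomes == 8
        assert sorted(len(c) for c in karyo.cars) == [2] * 8

    def test_greedy_keeps_heavier_conflicting_edge(self):
        weights = {
            frozenset(((0, "t"), (1, "h"))): 3.0,
            frozenset(((0, "t"), (2, "h"))): 1.0,
        }
        karyo = linearize_cars(AdjacencyGraph(blocks={0, 1, 2}, weights=weights))
        joined = {frozenset(b for b, _ in car) for car in karyo.cars if len(car) > 1}
        assert joined == {frozenset({0, 1})}

    def test_isolated_blocks_become_singletons(self):
        karyo = linearize_cars(AdjacencyGraph(blocks={5, 7}, weights={}))
        assert karyo.n_chromosomes == 2

    def test_every_block_in_exactly_one_car(self):
        cfg = SimulationConfig(seed=6, n_chromosomes=8, genes_per_chromosome=30,
                               wgt=False, tips=TIPS6, with_cds=False,
                               random_events={t: (1, 1) for t in TIPS6})
        bundle = simulate_clade(cfg)
        block_set, _, karyo = _reconstruct(bundle, tree=TREE6)
        placed = [b for car in karyo.cars for b, _ in car]
        assert sorted(placed) == sorted(block_set.block_ids)


class TestClassify:
    def test_identity_all_zero(self):
        cfg = SimulationConfig(seed=7, n_chromosomes=4, genes_per_chromosome=20,
                               wgt=False, tips=("x", "y"), with_cds=False)
        bundle = simulate_clade(cfg)
        _, _, karyo = _reconstruct(bundle)
        block_set, _, _ = _reconstruct(bundle)
        s = classify_rearrangements(karyo, block_set.projections["x"])
        assert (s.fusion, s.fission, s.translocation, s.inversion) == (0, 0, 0, 0)

    def test_two_translocations_one_inversion_recovered(self):
        cfg = SimulationConfig(
            seed=8, n_chromosomes=6, genes_per_chromosome=30, wgt=False,
            tips=("x", "y", "z", "w"), with_cds=False,
            event_schedule=[
                ("w", Translocation("chr1", "chr2", 12, 9)),
                ("w", Translocation("chr3", "chr4", 15, 18)),
                ("w", Inversion("chr5", 8, 20)),
            ],
        )
        bundle = simulate_clade(cfg)
        block_set, _, karyo = _reconstruct(bundle, tree="((x,y),(z,w));")
        s = classify_rearrangements(karyo, block_set.projections["w"])
        assert (s.fusion, s.fission, s.translocation, s.inversion) == (0, 0, 2, 1)
        for other in ("x", "y", "z"):
            s0 = classify_rearrangements(karyo, block_set.projections[other])
            assert (s0.fusion, s0.fission, s0.translocation, s0.inversion) == (0, 0, 0, 0)

    def test_fusion_detected(self):
        cfg = SimulationConfig(
            seed=9, n_chromosomes=5, genes_per_chromosome=25, wgt=False,
            tips=("x", "y", "z", "w"), with_cds=False,
            event_schedule=[("w", Fusion("chr1", "chr2"))],
        )
        bundle = simulate_clade(cfg)
        block_set, _, karyo = _reconstruct(bundle, tree="((x,y),(z,w));")
        assert karyo.n_chromosomes == 5
        assert len(bundle.tips["w"].chromosomes) == 4
        s = classify_rearrangements(karyo, block_set.projections["w"])
        assert s.fusion == 1
        assert (s.fission, s.translocation) == (0, 0)

    def test_unknown_blocks_reported(self):
        karyo = AncestralKaryotype(cars=[[(0, "+"), (1, "+")]])
        s = classify_rearrangements(karyo, {"c1": [(0, "+"), (9, "+"), (1, "+")]})
        assert s.unclassifiable == [9]
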