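"""Simulator truth: determinism, conservation laws, replay closure, and
calibration of the synonymous-divergence process against the NG86
estimator."""

import numpy as np
import pytest
from scipy import stats

from syntevo import io_core
from syntevo.ksrates import CodonAlignment, ks_ng86
from syntevo.simulate import (
    Fission,
    Fusion,
    Inversion,
    SimulationConfig,
    Translocation,
    apply_rearrangements,
    apply_wgt,
    draw_random_events,
    emit_fixtures,
    evolve_cds_pair,
    replay,
    simulate_ancestor,
    simulate_clade,
    source_id,
)


def _codons(seq):
    return [seq[i:i + 3] for i in range(0, len(seq), 3)]


class TestAncestor:
    def test_counts(self):
        g = simulate_ancestor(8, 100, seed=1)
        assert len(g.chromosomes) == 8
        assert len(g) == 800

    def test_determinism_and_seed_sensitivity(self):
        a = simulate_ancestor(4, 50, seed=1)
        b = simulate_ancestor(4, 50, seed=1)
        c = simulate_ancestor(4, 50, seed=2)
        assert a == b
        assert [g.strand for g in a] != [g.strand for g in c]

    def test_config_validation(self):
        with pytest.raises(ValueError):
            simulate_ancestor(0, 10)


class TestWGT:
    def test_full_retention_triples_everything(self):
        g = simulate_ancestor(8, 100, seed=1)
        tripled, _ = apply_wgt(g, retention=1.0, seed=0)
        assert len(tripled) == 2400
        assert len(tripled.chromosomes) == 24

    def test_partial_retention_within_binomial_interval(self):
        g = simulate_ancestor(8, 100, seed=1)
        kept, event = apply_wgt(g, retention=0.3, seed=7)
        n_dup = len(event.kept_w1) + len(event.kept_w2)
        lo, hi = stats.binom.interval(0.99, 1600, 0.3)
        assert lo <= n_dup <= hi
        assert len(kept) == 800 + n_dup

    def test_duplicates_map_to_source(self):
        g = simulate_ancestor(2, 20, seed=1)
        tripled, event = apply_wgt(g, retention=0.5, seed=3)
        originals = {x.gene_id for x in g}
        for copy in tripled:
            assert source_id(copy.gene_id).removesuffix("_w1").removesuffix("_w2") in originals


class TestRearrangements:
    def test_inversion_reverses_and_flips(self):
        g = simulate_ancestor(1, 30, seed=5)
        before = [(x.gene_id, x.strand) for x in g.genes_on("chr1")]
        out, _ = apply_rearrangements(g, [Inversion("chr1", 10, 21)])
        after = [(x.gene_id, x.strand) for x in out.genes_on("chr1")]
        assert after[:10] == before[:10]
        assert after[21:] == before[21:]
        flipped = [(gid, "-" if s == "+" else "+") for gid, s in before[10:21]]
        assert after[10:21] == list(reversed(flipped))

    def test_translocation_conserves_content(self):
        g = simulate_ancestor(2, 30, seed=5)
        out, _ = apply_rearrangements(g, [Translocation("chr1", "chr2", 10, 20)])
        assert len(out.chromosomes) == 2
        assert out.n_genes("chr1") == 10 + 10
        assert out.n_genes("chr2") == 20 + 20
        assert {x.gene_id for x in out} == {x.gene_id for x in g}

    def test_fusion_fission_change_chromosome_count(self):
        g = simulate_ancestor(2, 30, seed=5)
        fused, _ = apply_rearrangements(g, [Fusion("chr1", "chr2")])
        assert len(fused.chromosomes) == 1
        split, _ = apply_rearrangements(g, [Fission("chr1", 15, "chr1b")])
        assert len(split.chromosomes) == 3

    def test_replay_closure_on_random_events(self, rng):
        g = simulate_ancestor(8, 40, seed=9)
        events = draw_random_events(g, n_inversions=3, n_translocations=2, rng=rng)
        out, log = apply_rearrangements(g, events)
        assert replay(g, log) == out

    def test_out_of_range_event_rejected(self):
        g = simulate_ancestor(1, 10, seed=0)
        with pytest.raises(ValueError):
            apply_rearrangements(g, [Inversion("chr1", 5, 20)])


class TestCdsEvolution:
    def test_zero_target_identical(self):
        a, b, realized = evolve_cds_pair(100, 0.0, seed=4)
        assert a == b
        assert realized == 0.0
        est = ks_ng86(CodonAlignment(_codons(a), _codons(b)))
        assert est.ks == 0.0

    def test_determinism(self):
        assert evolve_cds_pair(100, 0.8, seed=5) == evolve_cds_pair(100, 0.8, seed=5)

    def test_target_recovery_monte_carlo(self):
        """Mean NG86 Ks over 200 replicates at 500 codons lands within 5%
        of the 1.22 target (the deep-triplication depth)."""
        vals = []
        for i in range(200):
            a, b, _ = evolve_cds_pair(500, 1.22, kappa=2.0, seed=10_000 + i)
            est = ks_ng86(CodonAlignment(_codons(a), _codons(b)))
            if est.ks is not None:
                vals.append(est.ks)
        assert 1.16 <= np.mean(vals) <= 1.28

    def test_kappa_changes_transition_fraction_not_mean(self):
        def stats_for(kappa):
            ks_vals, ts, tv = [], 0, 0
            transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
            for i in range(60):
                a, b, _ = evolve_cds_pair(300, 0.6, kappa=kappa, seed=777 + i)
                est = ks_ng86(CodonAlignment(_codons(a), _codons(b)))
                ks_vals.append(est.ks)
                for x, y in zip(a, b):
                    if x != y:
                        if (x, y) in transitions:
                            ts += 1
                        else:
                            tv += 1
            return np.mean(ks_vals), ts / (ts + tv)

        mean1, frac1 = stats_for(1.0)
        mean4, frac4 = stats_for(4.0)
        assert abs(mean1 - mean4) / mean4 < 0.06
        assert frac4 > frac1 + 0.15

    def test_unreachable_target_raises(self):
        with pytest.raises(ValueError):
            evolve_cds_pair(100, 3.5, seed=0)
        with pytest.raises(ValueError):
            evolve_cds_pair(10, 0.5, seed=0)


class TestCladeAndFixtures:
    def test_fixture_file_count_and_roundtrip(self, tmp_path):
        cfg = SimulationConfig(
            seed=2, n_chromosomes=2, genes_per_chromosome=20, wgt=True,
            wgt_retention=0.5, tips=("x", "y", "z"), n_codons=60,
        )
        bundle = simulate_clade(cfg)
        files = emit_fixtures(bundle, tmp_path)
        assert len(files) == 3 * 3 + 1
        for tip in cfg.tips:
            back = io_core.read_gene_positions(tmp_path / f"{tip}.bed", species_label=tip)
            cds = io_core.read_cds_fasta(tmp_path / f"{tip}.cds.fa")
            assert back == Genome_strip_cds(bundle.tips[tip])
            assert cds == bundle.tips[tip].cds
            pairs, rejects = io_core.read_homolog_pairs(
                tmp_path / f"{tip}.pairs.tsv", bundle.tips[tip], bundle.tips[tip]
            )
            assert rejects == []
            assert set((p.gene_a, p.gene_b) for p in pairs) == set(
                (p.gene_a, p.gene_b) for p in bundle.paralog_pairs[tip]
            )

    def test_byte_identical_fixtures_under_same_config(self, tmp_path):
        cfg = SimulationConfig(seed=3, n_chromosomes=2, genes_per_chromosome=15,
                               tips=("x", "y"), n_codons=60)
        f1 = emit_fixtures(simulate_clade(cfg), tmp_path / "a")
        f2 = emit_fixtures(simulate_clade(cfg), tmp_path / "b")
        for p1, p2 in zip(f1, f2):
            assert p1.read_bytes() == p2.read_bytes()

    def test_no_events_means_tips_equal_root_structure(self):
        cfg = SimulationConfig(seed=4, n_chromosomes=3, genes_per_chromosome=10,
                               wgt=False, tips=("x", "y"), with_cds=False)
        bundle = simulate_clade(cfg)
        for tip in cfg.tips:
            stripped = [
                (source_id(g.gene_id), g.chromosome, g.rank, g.strand)
                for g in bundle.tips[tip]
            ]
            root = [
                (g.gene_id, g.chromosome, g.rank, g.strand) for g in bundle.root
            ]
            assert stripped == root

    def test_every_emitted_pair_is_in_truth(self):
        cfg = SimulationConfig(seed=5, n_chromosomes=2, genes_per_chromosome=15,
                               wgt=True, wgt_retention=0.5, tips=("x", "y"),
                               with_cds=False)
        bundle = simulate_clade(cfg)
        for (a, b), pairs in bundle.ortholog_pairs.items():
            for p in pairs:
                assert (p.gene_a, p.gene_b) in bundle.true_ks
        for tip, pairs in bundle.paralog_pairs.items():
            for p in pairs:
                assert (p.gene_a, p.gene_b) in bundle.true_ks


def Genome_strip_cds(g):
    from syntevo.types import Genome

    return Genome(
        g.species_label,
        [(x.gene_id, x.chromosome, x.start, x.end, x.strand, 0) for x in g],
        chromosomes=list(g.chromosomes),
    )
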