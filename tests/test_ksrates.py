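"""NG86 counting against an independent enumeration oracle, alignment DP
against a hand-rolled Needleman-Wunsch, mixture recovery, correction and
dating."""

import itertools
import math
import statistics

import numpy as np
import pytest
from Bio.Data.CodonTable import standard_dna_table

from syntevo.ksrates import (
    CodonAlignment,
    DatingConfig,
    GammaAmbiguityError,
    PeakModel,
    align_codons,
    block_median_ks,
    correct_rates,
    date_event,
    designate_gamma,
    fit_peaks,
    ks_ng86,
)
from syntevo.types import Anchor, CollinearBlock

from _oracles import SENSE, oracle_counts


def test_ng86_matches_enumeration_oracle_on_random_pairs(rng):
    """S, N, Sd, Nd agree exactly with the oracle on 500 random ungapped
    codon pairs."""
    for _ in range(500):
        n = int(rng.integers(1, 30))
        ca = [SENSE[i] for i in rng.integers(0, len(SENSE), n)]
        cb = [SENSE[i] for i in rng.integers(0, len(SENSE), n)]
        est = ks_ng86(CodonAlignment(list(ca), list(cb)))
        S, N, Sd, Nd = oracle_counts(ca, cb)
        assert est.S == pytest.approx(S)
        assert est.N == pytest.approx(N)
        assert est.Sd == pytest.approx(Sd)
        assert est.Nd == pytest.approx(Nd)


def test_worked_example_alanine_third_position():
    est = ks_ng86(CodonAlignment(["ATG", "GCT", "GCT"], ["ATG", "GCC", "GCT"]))
    assert est.S == pytest.approx(2.0)
    assert est.N == pytest.approx(7.0)
    assert est.Sd == pytest.approx(1.0)
    assert est.pS == pytest.approx(0.5)
    assert est.ks == pytest.approx(-0.75 * math.log(1 / 3))
    assert not est.saturated


def test_saturation_guard_phenylalanine():
    est = ks_ng86(CodonAlignment(["ATG", "TTT"], ["ATG", "TTC"]))
    assert est.saturated
    assert est.ks is None
    assert est.pS == pytest.approx(3.0)


def test_identical_sequences_zero_distance():
    est = ks_ng86(CodonAlignment(["ATG", "GGG"], ["ATG", "GGG"]))
    assert (est.Sd, est.Nd) == (0.0, 0.0)
    assert est.ks == 0.0 and est.ka == 0.0


def test_ks_monotone_in_ps():
    last = -1.0
    for ps in np.linspace(0, 0.74, 50):
        ks = -0.75 * math.log(1 - 4 * ps / 3)
        assert ks > last
        last = ks


class TestAlignment:
    def test_identical_gapless(self):
        aln = align_codons("ATGGCTAAA", "ATGGCTAAA")
        assert aln.n_codons_ungapped == 3
        assert None not in aln.codons_a and None not in aln.codons_b

    def test_single_codon_deletion_one_gap_column(self):
        a = "ATGGCTCATAAAGGG"
        b = "ATGGCTAAAGGG"  # CAT removed
        aln = align_codons(a, b)
        gaps = [(x, y) for x, y in zip(aln.codons_a, aln.codons_b) if y is None]
        assert gaps == [("CAT", None)]

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            align_codons("ATGTAAGCT", "ATGGCTGCT")

    def test_score_matches_needleman_wunsch_oracle(self, rng):
        """Protein alignment score equals a hand-rolled NW with linear
        gaps on short random sequences."""
        def nw(p, q, match, mismatch, gap):
            m, n = len(p), len(q)
            D = [[0.0] * (n + 1) for _ in range(m + 1)]
            for i in range(1, m + 1):
                D[i][0] = i * gap
            for j in range(1, n + 1):
                D[0][j] = j * gap
            for i in range(1, m + 1):
                for j in range(1, n + 1):
                    sub = match if p[i - 1] == q[j - 1] else mismatch
                    D[i][j] = max(D[i - 1][j - 1] + sub, D[i - 1][j] + gap,
                                  D[i][j - 1] + gap)
            return D[m][n]

        from Bio.Align import PairwiseAligner

        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(10):
            p = "".join(rng.choice(aas, size=int(rng.integers(4, 11))))
            q = "".join(rng.choice(aas, size=int(rng.integers(4, 11))))
            aligner = PairwiseAligner()
            aligner.mode = "global"
            aligner.match_score, aligner.mismatch_score = 2.0, -1.0
            aligner.open_gap_score = aligner.extend_gap_score = -2.0
            assert aligner.score(p, q) == pytest.approx(nw(p, q, 2.0, -1.0, -2.0))


class TestBlockMedian:
    def _block(self, n):
        anchors = [Anchor(f"a{i}", f"b{i}", "A", i, "B", i, "same") for i in range(n)]
        return CollinearBlock(0, anchors, "A", "B", "+", float(n))

    def test_examples(self):
        blk = self._block(3)
        assert block_median_ks(blk, {("a0", "b0"): 0.1, ("a1", "b1"): 0.2,
                                     ("a2", "b2"): 0.3}) == pytest.approx(0.2)
        assert block_median_ks(blk, {("a0", "b0"): None}) is None

    def test_median_matches_sort_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 12))
            blk = self._block(n)
            vals = rng.random(n) * 3
            table = {(f"a{i}", f"b{i}"): float(v) for i, v in enumerate(vals)}
            assert block_median_ks(blk, table) == pytest.approx(
                statistics.median(sorted(vals))
            )


class TestMixture:
    def test_single_lognormal_component_recovered(self):
        rng = np.random.default_rng(42)
        draws = np.exp(rng.normal(np.log(1.22), 0.2, 2000))
        model = fit_peaks(draws, max_components=4, seed=0)
        assert model.n_components == 1
        assert 1.16 <= model.gamma_peak_ks <= 1.28

    def test_two_component_mixture_recovered(self):
        rng = np.random.default_rng(43)
        draws = np.concatenate([
            np.exp(rng.normal(np.log(0.25), 0.2, 1000)),
            np.exp(rng.normal(np.log(1.22), 0.2, 1000)),
        ])
        model = fit_peaks(draws, max_components=4, seed=0)
        assert model.n_components == 2
        lo, hi = model.modes_ks
        assert abs(lo - 0.25) / 0.25 < 0.05
        assert abs(hi - 1.22) / 1.22 < 0.05

    def test_guards(self):
        with pytest.raises(ValueError, match="identical"):
            fit_peaks(np.full(200, 0.7))
        with pytest.raises(ValueError, match=">= 50"):
            fit_peaks(np.linspace(0.1, 1.0, 30))

    def test_em_fit_is_seed_reproducible(self):
        rng = np.random.default_rng(44)
        draws = np.exp(rng.normal(0.0, 0.3, 500))
        m1 = fit_peaks(draws, seed=5)
        m2 = fit_peaks(draws, seed=5)
        assert m1.components == m2.components

    def test_gamma_designation_ambiguity(self):
        model = PeakModel(
            components=[(0.5, math.log(1.1), 0.2), (0.5, math.log(1.2), 0.2)],
            n_components=2, bic=0.0,
        )
        with pytest.raises(GammaAmbiguityError):
            designate_gamma(model, prior=1.15)
        far = PeakModel(
            components=[(0.5, math.log(0.25), 0.2), (0.5, math.log(1.22), 0.2)],
            n_components=2, bic=0.0,
        )
        assert designate_gamma(far, prior=1.2) == pytest.approx(1.22)


class TestCorrectionAndDating:
    def test_identity_when_peaks_equal(self):
        vals = np.array([0.5, 1.0, 2.0])
        corrected, factor = correct_rates(vals, 1.22, 1.22)
        assert factor.factor == 1.0
        assert np.allclose(corrected, vals)

    def test_rejects_nonpositive_peak(self):
        with pytest.raises(ValueError):
            correct_rates([1.0], 0.0, 1.22)

    def test_dating_arithmetic(self):
        assert date_event(0.0, DatingConfig(5e-9)) == 0.0
        assert date_event(1.22, 5.0e-9) == pytest.approx(122.0)
        # doubling r halves T
        assert date_event(0.9, 2e-9) == pytest.approx(2 * date_event(0.9, 4e-9))

    def test_rate_must_be_positive(self):
        with pytest.raises(ValueError):
            DatingConfig(-1e-9)
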