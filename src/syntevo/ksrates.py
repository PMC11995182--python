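"""Codon-aware alignment, NG86 Ka/Ks estimation, Ks-distribution mixture
fitting, shared-event rate correction, and molecular dating.

The Ks estimator is Nei–Gojobori (1986) counting with Jukes–Cantor
multiple-hit correction: per-codon synonymous site fractions are computed
from all single-nucleotide neighbours (mutations creating stop codons count
as nonsynonymous, the original convention), site totals are averaged over
the two sequences, and codons differing at several positions are scored by
averaging over all minimal substitution pathways with equal weights
(pathways passing through a stop codon are excluded unless every pathway is
blocked). Saturation (pS >= 3/4) is flagged, never silently clipped.

Mixture fitting works on log-Ks with Gaussian components, seeded EM
restarts and BIC model selection; the gamma-event component is designated
as the component nearest a prior location (default 1.2), and a single
multiplicative factor per species aligns each lineage's gamma peak to a
reference — the rate correction that makes cross-lineage Ks comparable.
Dating converts a synonymous distance to time via T = Ks / (2 r).
"""

from __future__ import annotations

import itertools
import math
import statistics
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from sklearn.mixture import GaussianMixture

from .types import CollinearBlock

__all__ = [
    "CodonAlignment",
    "KsEstimate",
    "PeakModel",
    "CorrectionFactor",
    "DatingConfig",
    "GammaAmbiguityError",
    "align_codons",
    "ks_ng86",
    "block_median_ks",
    "fit_peaks",
    "designate_gamma",
    "correct_rates",
    "date_event",
]

_BASES = "ACGT"
_CODON_TABLE = standard_dna_table.forward_table
_STOP_CODONS = set(standard_dna_table.stop_codons)


def _aa(codon: str) -> str | None:
    """Amino acid for a codon, None for stops."""
    if codon in _STOP_CODONS:
        return None
    return _CODON_TABLE[codon]


def _syn_site_fractions() -> dict[str, float]:
    """Synonymous sites per codon: at each position the fraction of the
    three single-base changes that preserve the amino acid. Changes to stop
    codons are nonsynonymous."""
    out: dict[str, float] = {}
    for codon in map("".join, itertools.product(_BASES, repeat=3)):
        if codon in _STOP_CODONS:
            continue
        s = 0.0
        for pos in range(3):
            syn = 0
            for base in _BASES:
                if base == codon[pos]:
                    continue
                alt = codon[:pos] + base + codon[pos + 1:]
                if alt not in _STOP_CODONS and _aa(alt) == _aa(codon):
                    syn += 1
            s += syn / 3.0
        out[codon] = s
    return out


_SYN_SITES = _syn_site_fractions()


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons, averaged
    over all minimal substitution pathways with equal weights."""
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in itertools.permutations(diffs):
        cur = c1
        sd = nd = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in _STOP_CODONS:
                through_stop = True
            if (
                cur not in _STOP_CODONS
                and nxt not in _STOP_CODONS
                and _aa(cur) == _aa(nxt)
            ):
                sd += 1
            else:
                nd += 1
            cur = nxt
        (blocked if through_stop else valid).append((sd, nd))
    paths = valid if valid else blocked
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


_PAIR_COUNTS: dict[tuple[str, str], tuple[float, float]] = {}


def _pair_counts(c1: str, c2: str) -> tuple[float, float]:
    key = (c1, c2)
    hit = _PAIR_COUNTS.get(key)
    if hit is None:
        hit = _pathway_counts(c1, c2)
        _PAIR_COUNTS[key] = hit
        _PAIR_COUNTS[(c2, c1)] = hit
    return hit


# ---------------------------------------------------------------------------
# codon alignment


@dataclass
class CodonAlignment:
    """Two CDS aligned at codon resolution; None marks a codon gap."""

    codons_a: list[str | None]
    codons_b: list[str | None]

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("aligned codon columns differ in length")

    @property
    def n_codons_ungapped(self) -> int:
        return sum(
            1 for a, b in zip(self.codons_a, self.codons_b) if a is not None and b is not None
        )


def _check_cds(seq: str, label: str) -> str:
    seq = seq.upper()
    if len(seq) % 3 != 0 or not seq:
        raise ValueError(f"{label}: length {len(seq)} is not a positive multiple of 3")
    for i in range(0, len(seq) - 3, 3):
        if seq[i:i + 3] in _STOP_CODONS:
            raise ValueError(f"{label}: internal stop codon at codon {i // 3}")
    return seq


def align_codons(
    cds_a: str,
    cds_b: str,
    matrix: str | None = "BLOSUM62",
    match: float = 2.0,
    mismatch: float = -1.0,
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> CodonAlignment:
    """Protein-guided global codon alignment.

    The translated proteins are globally aligned (substitution matrix or
    simple match/mismatch when ``matrix`` is None, affine gaps) and the
    alignment is back-translated to codon columns. A trailing stop codon is
    tolerated and trimmed; internal stops are an error.
    """
    cds_a, cds_b = _check_cds(cds_a, "cds_a"), _check_cds(cds_b, "cds_b")
    if cds_a[-3:] in _STOP_CODONS:
        cds_a = cds_a[:-3]
    if cds_b[-3:] in _STOP_CODONS:
        cds_b = cds_b[:-3]
    prot_a = str(Seq(cds_a).translate())
    prot_b = str(Seq(cds_b).translate())
    aligner = PairwiseAligner()
    aligner.mode = "global"
    if matrix is not None:
        aligner.substitution_matrix = substitution_matrices.load(matrix)
    else:
        aligner.match_score = match
        aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(prot_a, prot_b)[0]
    codons_a: list[str | None] = []
    codons_b: list[str | None] = []
    for (sa, sb) in zip(*aln.indices):
        codons_a.append(None if sa < 0 else cds_a[3 * sa:3 * sa + 3])
        codons_b.append(None if sb < 0 else cds_b[3 * sb:3 * sb + 3])
    return CodonAlignment(codons_a, codons_b)


# ---------------------------------------------------------------------------
# NG86


@dataclass
class KsEstimate:
    """NG86 site and difference counts with Jukes–Cantor-corrected
    distances. ``ks``/``ka`` are None when undefined or saturated."""

    S: float
    N: float
    Sd: float
    Nd: float
    pS: float | None
    pN: float | None
    ks: float | None
    ka: float | None
    saturated: bool
    n_codons: int


def _jc(p: float) -> float | None:
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0.0:
        return None
    return -0.75 * math.log(arg)


def ks_ng86(alignment: CodonAlignment) -> KsEstimate:
    """Nei–Gojobori (1986) Ka/Ks on the counted codon columns.

    Columns with a gap, an N, or a stop codon in either sequence are
    excluded from counting; S + N = 3 x n_codons counted.
    """
    S1 = S2 = 0.0
    Sd = Nd = 0.0
    n_codons = 0
    for ca, cb in zip(alignment.codons_a, alignment.codons_b):
        if ca is None or cb is None or "N" in ca or "N" in cb:
            continue
        if ca in _STOP_CODONS or cb in _STOP_CODONS:
            continue
        n_codons += 1
        S1 += _SYN_SITES[ca]
        S2 += _SYN_SITES[cb]
        sd, nd = _pair_counts(ca, cb)
        Sd += sd
        Nd += nd
    if n_codons == 0:
        raise ValueError("no countable codon columns in alignment")
    S = 0.5 * (S1 + S2)
    N = 3.0 * n_codons - S
    pS = Sd / S if S > 0 else None
    pN = Nd / N if N > 0 else None
    ks = _jc(pS) if pS is not None else None
    ka = _jc(pN) if pN is not None else None
    saturated = (pS is not None and pS >= 0.75) or pS is None
    return KsEstimate(S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN, ks=ks, ka=ka,
                      saturated=saturated, n_codons=n_codons)


def block_median_ks(block: CollinearBlock, ks_by_pair: dict) -> float | None:
    """Median anchor Ks of a block; saturated/undefined estimates are
    ignored. Values may be floats or KsEstimate objects."""
    values = []
    for a in block.anchors:
        est = ks_by_pair.get((a.gene_a, a.gene_b))
        if est is None:
            est = ks_by_pair.get((a.gene_b, a.gene_a))
        if est is None:
            continue
        ks = est.ks if isinstance(est, KsEstimate) else est
        if ks is not None and math.isfinite(ks):
            values.append(ks)
    if not values:
        return None
    return float(statistics.median(values))


# ---------------------------------------------------------------------------
# mixture fitting


class GammaAmbiguityError(ValueError):
    """Two mixture components are too close to the gamma prior to choose."""


@dataclass
class PeakModel:
    """Gaussian mixture over log-Ks; components sorted by mean."""

    components: list[tuple[float, float, float]]  # (weight, mu, sigma)
    n_components: int
    bic: float
    gamma_peak_ks: float | None = None
    bic_by_k: dict[int, float] = field(default_factory=dict)

    @property
    def modes_ks(self) -> list[float]:
        return [math.exp(mu) for _, mu, _ in self.components]


def fit_peaks(
    ks_values,
    max_components: int = 4,
    ks_min: float = 0.005,
    ks_max: float = 5.0,
    seed: int = 0,
    n_init: int = 10,
    gamma_prior: float | None = 1.2,
) -> PeakModel:
    """Fit 1..max_components Gaussian mixtures to log-Ks by seeded EM
    (k-means initialisation) and pick the component count by BIC.

    Values outside (ks_min, ks_max) are dropped first. Fewer than 50
    usable values, or a degenerate (zero-variance) sample, is refused.
    When ``gamma_prior`` is given the gamma component is designated as the
    component nearest that Ks.
    """
    arr = np.asarray([v for v in np.ravel(np.asarray(ks_values, dtype=float))
                      if np.isfinite(v) and ks_min < v < ks_max], dtype=float)
    if arr.size < 50:
        raise ValueError(
            f"only {arr.size} Ks values inside ({ks_min}, {ks_max}); "
            "need >= 50 for a stable mixture fit"
        )
    logks = np.log(arr).reshape(-1, 1)
    if np.ptp(logks) == 0.0:
        raise ValueError("degenerate Ks sample: all values identical")
    best: GaussianMixture | None = None
    best_bic = math.inf
    bic_by_k: dict[int, float] = {}
    for k in range(1, max_components + 1):
        gm = GaussianMixture(
            n_components=k, covariance_type="full", n_init=n_init,
            init_params="k-means++", random_state=seed, reg_covar=1e-6,
        ).fit(logks)
        bic = float(gm.bic(logks))
        bic_by_k[k] = bic
        if bic < best_bic:
            best, best_bic = gm, bic
    assert best is not None
    comps = sorted(
        (float(w), float(m[0]), float(math.sqrt(c[0][0])))
        for w, m, c in zip(best.weights_, best.means_, best.covariances_)
    )
    comps.sort(key=lambda t: t[1])
    model = PeakModel(components=comps, n_components=len(comps), bic=best_bic,
                      bic_by_k=bic_by_k)
    if gamma_prior is not None:
        model.gamma_peak_ks = designate_gamma(model, gamma_prior)
    return model


def designate_gamma(model: PeakModel, prior: float = 1.2) -> float:
    """Pick the gamma-event component: the one nearest ``prior`` on the log
    scale. If the two nearest candidates sit within 15% of each other the
    choice is ambiguous and must be made explicitly."""
    if prior <= 0:
        raise ValueError("gamma prior must be positive")
    dists = sorted(
        (abs(mu - math.log(prior)), mu) for _, mu, _ in model.components
    )
    if len(dists) > 1 and abs(dists[0][1] - dists[1][1]) < math.log(1.15):
        raise GammaAmbiguityError(
            "two mixture components within 15% of each other near the gamma "
            f"prior {prior}; designate the gamma peak explicitly"
        )
    return math.exp(dists[0][1])


# ---------------------------------------------------------------------------
# rate correction and dating


@dataclass(frozen=True)
class CorrectionFactor:
    """Multiplicative Ks rescaling aligning a species' gamma peak to the
    reference's: f = peak_reference / peak_species."""

    species: str
    factor: float
    reference: str


def correct_rates(
    ks_values,
    peak_species: float,
    peak_reference: float,
    species: str = "species",
    reference: str = "reference",
) -> tuple[np.ndarray, CorrectionFactor]:
    """Rescale a species' Ks values so its gamma peak lands on the
    reference gamma peak. Linear in Ks: one factor per species."""
    if peak_species <= 0:
        raise ValueError(f"species gamma peak must be positive, got {peak_species}")
    if peak_reference <= 0:
        raise ValueError(f"reference gamma peak must be positive, got {peak_reference}")
    f = peak_reference / peak_species
    corrected = np.asarray(ks_values, dtype=float) * f
    return corrected, CorrectionFactor(species=species, factor=f, reference=reference)


@dataclass(frozen=True)
class DatingConfig:
    """Synonymous substitution rate r, per site per year."""

    r: float

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError(f"substitution rate must be positive, got {self.r}")


def date_event(gamma_peak_ks: float, config: DatingConfig | float) -> float:
    """Date a Ks peak: T = Ks / (2 r), returned in Mya."""
    if not isinstance(config, DatingConfig):
        config = DatingConfig(float(config))
    if gamma_peak_ks < 0:
        raise ValueError("Ks must be nonnegative")
    return gamma_peak_ks / (2.0 * config.r) / 1e6
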