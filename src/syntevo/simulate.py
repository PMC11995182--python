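"""Forward simulation of genome evolution with known truth.

The generator emulates the history behind the analyses this package
implements: an ancestral karyotype of ordered genes (default 8
chromosomes), an ancient whole-genome triplication (WGT) followed by heavy
independent gene loss in the two duplicated subgenomes, a star of
descendant lineages whose whole-path synonymous rates differ by per-lineage
multipliers, and post-speciation structural events (inversions, reciprocal
terminal translocations, fusions, fissions) at gene-order resolution.
Speciation is treated as recent relative to the triplication, so both
within-genome paralog pairs and cross-genome ortholog pairs carry the
triplication-depth synonymous divergence — a single deep Ks peak per
lineage, scaled by that lineage's rate multiplier.

Coding sequences evolve under a K80-style nucleotide process restricted to
synonymous changes with stop-codon avoidance: substitution counts are
Poisson with mean target_ks x (synonymous sites), events pick uniformly
among the current synonymous single-base options with transition weight
kappa. Per-gene rate heterogeneity is lognormal on the log-Ks scale
(sigma = ks_sigma). NG86 on the resulting pairs recovers the target
distance; the estimator itself defines truth.

Every stochastic choice is resolved when an event is drawn and stored in
the event log with concrete breakpoints and gene lists, so replaying the
log from the ancestor reproduces each tip genome exactly.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_core import write_cds_fasta, write_gene_positions, write_homolog_pairs
from .types import Genome, HomologPair

__all__ = [
    "SimulationConfig",
    "Inversion",
    "Translocation",
    "Fusion",
    "Fission",
    "Loss",
    "WGT",
    "TruthBundle",
    "simulate_ancestor",
    "apply_wgt",
    "apply_rearrangements",
    "apply_event",
    "replay",
    "draw_random_events",
    "evolve_cds_pair",
    "simulate_clade",
    "emit_fixtures",
    "source_id",
]

_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

# ---------------------------------------------------------------------------
# events — all parameters concrete so replay is pure


@dataclass(frozen=True)
class Inversion:
    """Reverse the rank interval [start, end) and flip strands."""

    chromosome: str
    start: int
    end: int


@dataclass(frozen=True)
class Translocation:
    """Reciprocal exchange of the terminal segments after break_a/break_b."""

    chrom_a: str
    chrom_b: str
    break_a: int
    break_b: int


@dataclass(frozen=True)
class Fusion:
    chrom_a: str
    chrom_b: str


@dataclass(frozen=True)
class Fission:
    chromosome: str
    at: int
    new_name: str


@dataclass(frozen=True)
class Loss:
    gene_ids: tuple[str, ...]


@dataclass(frozen=True)
class WGT:
    """Triplication: subgenome 0 keeps every gene; the kept gene ids of the
    two duplicated subgenomes are recorded explicitly."""

    kept_w1: tuple[str, ...]
    kept_w2: tuple[str, ...]


_EVENT_TYPES = {c.__name__: c for c in (Inversion, Translocation, Fusion, Fission, Loss, WGT)}


# ---------------------------------------------------------------------------
# struct representation: ordered (gene_id, strand) lists per chromosome

Struct = dict[str, list[tuple[str, str]]]


def _to_struct(genome: Genome) -> tuple[list[str], Struct]:
    names = list(genome.chromosomes)
    chroms = {c: [(g.gene_id, g.strand) for g in genome.genes_on(c)] for c in names}
    return names, chroms


def _materialize(
    names: list[str],
    chroms: Struct,
    species_label: str,
    spacing: int = 1000,
    gene_length: int = 900,
    cds: dict[str, str] | None = None,
) -> Genome:
    records = []
    for c in names:
        for i, (gid, strand) in enumerate(chroms[c]):
            start = i * spacing
            records.append((gid, c, start, start + gene_length, strand, 0))
    return Genome(species_label, records, cds=cds, chromosomes=list(names))


def apply_event(names: list[str], chroms: Struct, event) -> tuple[list[str], Struct]:
    """Apply one event to a struct; pure, deterministic."""
    names = list(names)
    chroms = {c: list(v) for c, v in chroms.items()}
    if isinstance(event, Inversion):
        seq = chroms[event.chromosome]
        if not (0 <= event.start < event.end <= len(seq)):
            raise ValueError(f"inversion [{event.start},{event.end}) out of range on {event.chromosome}")
        seg = [(g, "-" if s == "+" else "+") for g, s in reversed(seq[event.start:event.end])]
        chroms[event.chromosome] = seq[:event.start] + seg + seq[event.end:]
    elif isinstance(event, Translocation):
        a, b = chroms[event.chrom_a], chroms[event.chrom_b]
        if not (0 < event.break_a < len(a)) or not (0 < event.break_b < len(b)):
            raise ValueError("translocation breakpoint out of range")
        chroms[event.chrom_a] = a[:event.break_a] + b[event.break_b:]
        chroms[event.chrom_b] = b[:event.break_b] + a[event.break_a:]
    elif isinstance(event, Fusion):
        chroms[event.chrom_a] = chroms[event.chrom_a] + chroms[event.chrom_b]
        del chroms[event.chrom_b]
        names.remove(event.chrom_b)
    elif isinstance(event, Fission):
        seq = chroms[event.chromosome]
        if not (0 < event.at < len(seq)):
            raise ValueError("fission point out of range")
        chroms[event.chromosome] = seq[:event.at]
        chroms[event.new_name] = seq[event.at:]
        names.insert(names.index(event.chromosome) + 1, event.new_name)
    elif isinstance(event, Loss):
        drop = set(event.gene_ids)
        for c in names:
            chroms[c] = [(g, s) for g, s in chroms[c] if g not in drop]
    elif isinstance(event, WGT):
        kept1, kept2 = set(event.kept_w1), set(event.kept_w2)
        new_names = list(names)
        for suffix, kept in (("_w1", kept1), ("_w2", kept2)):
            for c in names:
                copy = [(g + suffix, s) for g, s in chroms[c] if g in kept]
                chroms[c + suffix] = copy
                new_names.append(c + suffix)
        names = new_names
    else:
        raise TypeError(f"unknown event {event!r}")
    return names, chroms


# ---------------------------------------------------------------------------
# public operations on Genome


def simulate_ancestor(
    n_chromosomes: int = 8,
    genes_per_chromosome: int = 100,
    seed: int = 0,
    species_label: str = "ancestor",
    spacing: int = 1000,
    gene_length: int = 900,
) -> Genome:
    """Uniformly spaced genes on dense ranks, strands drawn at random."""
    if n_chromosomes < 1 or genes_per_chromosome < 2:
        raise ValueError("need >= 1 chromosome and >= 2 genes per chromosome")
    rng = np.random.default_rng(seed)
    names = [f"chr{i + 1}" for i in range(n_chromosomes)]
    chroms: Struct = {}
    for ci, c in enumerate(names):
        strands = rng.choice(["+", "-"], size=genes_per_chromosome)
        chroms[c] = [
            (f"g{ci + 1}_{i:04d}", strands[i]) for i in range(genes_per_chromosome)
        ]
    return _materialize(names, chroms, species_label, spacing, gene_length)


def apply_wgt(genome: Genome, retention: float, seed: int = 0) -> tuple[Genome, WGT]:
    """Triplicate every chromosome; in each duplicated copy each gene is
    independently kept with probability ``retention``."""
    if not (0 < retention <= 1):
        raise ValueError(f"retention must be in (0, 1], got {retention}")
    rng = np.random.default_rng(seed)
    ids = [g.gene_id for g in genome]
    kept_w1 = tuple(g for g in ids if rng.random() < retention)
    kept_w2 = tuple(g for g in ids if rng.random() < retention)
    event = WGT(kept_w1=kept_w1, kept_w2=kept_w2)
    names, chroms = _to_struct(genome)
    names, chroms = apply_event(names, chroms, event)
    return _materialize(names, chroms, genome.species_label + "_wgt"), event


def apply_rearrangements(genome: Genome, events: list, species_label: str | None = None) -> tuple[Genome, list]:
    """Apply a list of concrete rearrangement events; gene content is
    conserved (use Loss/WGT separately for content changes)."""
    names, chroms = _to_struct(genome)
    for ev in events:
        names, chroms = apply_event(names, chroms, ev)
    return _materialize(names, chroms, species_label or genome.species_label), list(events)


def replay(genome: Genome, events: list, species_label: str | None = None) -> Genome:
    """Fold an event log over a genome — the closure property the truth
    bundle guarantees."""
    names, chroms = _to_struct(genome)
    for ev in events:
        names, chroms = apply_event(names, chroms, ev)
    return _materialize(names, chroms, species_label or genome.species_label)


def draw_random_events(
    genome: Genome,
    n_inversions: int,
    n_translocations: int,
    rng: np.random.Generator,
    margin: int = 3,
    min_segment: int = 3,
) -> list:
    """Draw concrete inversion/translocation events with interior
    breakpoints. Translocations use distinct chromosome pairs so reciprocal
    exchanges remain individually countable."""
    names, chroms = _to_struct(genome)
    eligible = [c for c in names if len(chroms[c]) >= 2 * margin + min_segment]
    blocked: set[str] = set()  # genes already involved in an event

    def gene(c: str, i: int) -> str:
        return chroms[c][i][0]

    events: list = []
    # inversions first (lengths unchanged), then translocations against the
    # evolving struct; events never share genes, so each drawn event maps
    # to exactly one recoverable rearrangement
    for _ in range(n_inversions):
        for _attempt in range(200):
            c = eligible[int(rng.integers(len(eligible)))]
            n = len(chroms[c])
            start = int(rng.integers(margin, n - margin - min_segment))
            seg = int(rng.integers(min_segment, max(min_segment + 1, (n - margin) - start)))
            end = min(start + seg, n - margin)
            touched = {gene(c, i) for i in range(start - 1, end + 1)}
            if not (touched & blocked):
                break
        else:
            raise ValueError("cannot place a non-interfering inversion")
        blocked |= touched
        ev = Inversion(c, start, end)
        events.append(ev)
        names, chroms = apply_event(names, chroms, ev)
    used_pairs: set[frozenset[str]] = set()
    for _ in range(n_translocations):
        for _attempt in range(200):
            ca, cb = rng.choice(len(eligible), size=2, replace=False)
            ca, cb = eligible[ca], eligible[cb]
            if frozenset((ca, cb)) in used_pairs:
                continue
            na, nb = len(chroms[ca]), len(chroms[cb])
            if na < 2 * margin or nb < 2 * margin:
                continue
            ba = int(rng.integers(margin, na - margin))
            bb = int(rng.integers(margin, nb - margin))
            touched = {gene(ca, ba - 1), gene(ca, ba), gene(cb, bb - 1), gene(cb, bb)}
            if not (touched & blocked):
                break
        else:
            raise ValueError("cannot place a non-interfering translocation on a fresh chromosome pair")
        used_pairs.add(frozenset((ca, cb)))
        blocked |= touched
        ev = Translocation(ca, cb, ba, bb)
        events.append(ev)
        names, chroms = apply_event(names, chroms, ev)
    return events


def draw_random_loss(genome: Genome, fraction: float, rng: np.random.Generator) -> Loss:
    """A Loss event removing a uniform random ``fraction`` of all genes
    (each gene dropped independently with probability ``fraction``)."""
    if not (0 <= fraction < 1):
        raise ValueError("loss fraction must be in [0, 1)")
    ids = tuple(g.gene_id for g in genome if rng.random() < fraction)
    return Loss(gene_ids=ids)


# ---------------------------------------------------------------------------
# coding-sequence evolution


def _syn_options(codon: str) -> list[tuple[str, bool]]:
    from .ksrates import _STOP_CODONS, _aa  # shared codon table

    opts = []
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if alt not in _STOP_CODONS and _aa(alt) == _aa(codon):
                opts.append((alt, _TRANSITION[codon[pos]] == base))
    return opts


_SYN_OPTIONS = {
    c: _syn_options(c)
    for c in map("".join, itertools.product(_BASES, repeat=3))
    if c not in ("TAA", "TAG", "TGA")
}


def _syn_sites_of(codons: list[str]) -> float:
    from .ksrates import _SYN_SITES

    return sum(_SYN_SITES[c] for c in codons)


def random_cds(n_codons: int, rng: np.random.Generator) -> list[str]:
    """Random coding sequence with no internal stops, ATG start."""
    sense = sorted(_SYN_OPTIONS)
    codons = ["ATG"] + [sense[i] for i in rng.integers(0, len(sense), size=n_codons - 1)]
    return codons


# Synonymous evolution is an exact continuous-time Markov chain per codon:
# each synonymous single-base option fires at rate kappa (transition) or 1
# (transversion), so a codon walks its amino acid's synonymous-codon graph
# and can never create a stop. Because the NG86 estimator is slightly
# non-linear in the substitution load (twofold-degenerate sites saturate
# faster than their 1/3-site weight implies), the chain is run for a time
# chosen by inverting the analytically expected NG86 estimate — computed
# from the per-amino-acid chain matrices — so that E[ks_ng86] equals the
# requested target.


def _class_chains(kappa: float):
    """Per amino-acid-class (codon list, syn-site vector, rate matrix,
    pairwise Sd matrix)."""
    from .ksrates import _SYN_SITES, _pair_counts

    classes: dict[str, list[str]] = {}
    from .ksrates import _aa

    for c in _SYN_OPTIONS:
        classes.setdefault(_aa(c), []).append(c)
    out = []
    for _, codons in sorted(classes.items()):
        codons = sorted(codons)
        idx = {c: i for i, c in enumerate(codons)}
        n = len(codons)
        Q = np.zeros((n, n))
        for c in codons:
            for alt, ts in _SYN_OPTIONS[c]:
                Q[idx[c], idx[alt]] = kappa if ts else 1.0
        np.fill_diagonal(Q, -Q.sum(axis=1))
        S = np.array([_SYN_SITES[c] for c in codons])
        SD = np.array([[_pair_counts(a, b)[0] for b in codons] for a in codons])
        out.append((codons, S, Q, SD))
    return out


_CALIBRATION_CACHE: dict[float, tuple[np.ndarray, np.ndarray]] = {}


def _calibration_curve(kappa: float) -> tuple[np.ndarray, np.ndarray]:
    """Monotone map from total chain time (both branches summed) to the
    expected NG86 Ks for a uniform-random sense-codon root."""
    key = round(float(kappa), 6)
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]
    from scipy.linalg import expm

    chains = _class_chains(kappa)
    n_codons_total = sum(len(c[0]) for c in chains)
    times = np.concatenate([[0.0], np.geomspace(1e-3, 60.0, 120)])
    exp_ks = np.zeros_like(times)
    for ti, total_t in enumerate(times[1:], start=1):
        e_sd = 0.0
        e_s = 0.0
        for codons, S, Q, SD in chains:
            P = expm(Q * (total_t / 2.0))
            # root uniform within the sense-codon alphabet
            e_sd += float(np.einsum("ri,ij,rj->", P, SD, P))
            e_s += float((P @ S).sum())
        p_s = (e_sd / e_s) if e_s > 0 else 0.0
        arg = 1.0 - 4.0 * p_s / 3.0
        exp_ks[ti] = math.inf if arg <= 0 else -0.75 * math.log(arg)
        _ = n_codons_total  # normalisation cancels in the ratio
    exp_ks = np.maximum.accumulate(exp_ks)
    _CALIBRATION_CACHE[key] = (times, exp_ks)
    return times, exp_ks


def _total_time_for_ks(target_ks: float, kappa: float) -> float:
    times, exp_ks = _calibration_curve(kappa)
    finite = np.isfinite(exp_ks)
    if target_ks > exp_ks[finite].max():
        raise ValueError(
            f"target_ks {target_ks} is beyond NG86 saturation for this process; "
            "use a smaller target or longer sequences"
        )
    return float(np.interp(target_ks, exp_ks[finite], times[finite]))


def _evolve_codons(
    codons: list[str], branch_time: float, kappa: float, rng: np.random.Generator
) -> tuple[list[str], int]:
    """Run each codon's synonymous chain for ``branch_time`` (Gillespie)."""
    codons = list(codons)
    n_events = 0
    for i, c in enumerate(codons):
        t = 0.0
        while True:
            opts = _SYN_OPTIONS[c]
            if not opts:
                break
            weights = [kappa if ts else 1.0 for _, ts in opts]
            rate = sum(weights)
            t += rng.exponential(1.0 / rate)
            if t >= branch_time:
                break
            u = rng.random() * rate
            acc = 0.0
            for (alt, _ts), w in zip(opts, weights):
                acc += w
                if u < acc:
                    c = alt
                    break
            n_events += 1
        codons[i] = c
    return codons, n_events


def evolve_cds_pair(
    n_codons: int,
    target_ks: float,
    kappa: float = 2.0,
    seed: int = 0,
) -> tuple[str, str, float]:
    """Generate a CDS pair whose NG86 Ks matches ``target_ks`` on average.

    A random ancestral CDS is evolved independently down two branches of
    equal depth. Returns (cds_a, cds_b, realized) where ``realized`` is the
    actual substitution load per ancestral synonymous site.
    """
    if n_codons < 50:
        raise ValueError("need n_codons >= 50 for a stable target")
    if not (0 <= target_ks < 3):
        raise ValueError(f"target_ks must be in [0, 3) (below saturation), got {target_ks}")
    rng = np.random.default_rng(seed)
    root = random_cds(n_codons, rng)
    s0 = _syn_sites_of(root)
    branch_time = _total_time_for_ks(target_ks, kappa) / 2.0
    a, ev_a = _evolve_codons(root, branch_time, kappa, rng)
    b, ev_b = _evolve_codons(root, branch_time, kappa, rng)
    return "".join(a), "".join(b), (ev_a + ev_b) / s0


# ---------------------------------------------------------------------------
# clade simulation


def source_id(gene_id: str) -> str:
    """Ancestral source of a (possibly tip-labelled, possibly WGT-copy)
    gene id: strips the 'tip|' prefix but keeps the subgenome suffix."""
    return gene_id.split("|", 1)[-1]


def ancestral_gene(gene_id: str) -> str:
    """Pre-WGT ancestral gene id (also strips _w1/_w2)."""
    sid = source_id(gene_id)
    for suf in ("_w1", "_w2"):
        if sid.endswith(suf):
            return sid[: -len(suf)]
    return sid


@dataclass
class SimulationConfig:
    """Study conditions for a simulated clade. Defaults are the conditions
    the pipeline's recovery tests run under: an 8-chromosome ancestor, an
    ancient triplication at Ks 1.22 with heavy (70%) loss of duplicated
    copies, and three lineages with unit rate multipliers."""

    seed: int = 0
    n_chromosomes: int = 8
    genes_per_chromosome: int = 100
    wgt: bool = True
    wgt_retention: float = 0.3
    tips: tuple[str, ...] = ("t1", "t2", "t3")
    rate_multipliers: dict[str, float] = field(default_factory=dict)
    ks_targets: dict[str, float] = field(default_factory=lambda: {"wgt": 1.22, "speciation": 0.3})
    event_schedule: list[tuple[str, object]] = field(default_factory=list)
    random_events: dict[str, tuple[int, int]] = field(default_factory=dict)  # tip -> (n_inv, n_transloc)
    kappa: float = 2.0
    ks_sigma: float = 0.2
    n_codons: int = 300
    with_cds: bool = True
    false_pair_rate: float = 0.0
    spacing: int = 1000
    gene_length: int = 900

    def __post_init__(self) -> None:
        if not (0 < self.wgt_retention <= 1):
            raise ValueError("wgt_retention must be in (0, 1]")
        if not (0 <= self.false_pair_rate < 1):
            raise ValueError("false_pair_rate must be in [0, 1)")
        if self.ks_sigma < 0:
            raise ValueError("ks_sigma must be nonnegative")
        for tip, m in self.rate_multipliers.items():
            if m <= 0:
                raise ValueError(f"rate multiplier for {tip} must be positive")

    def multiplier(self, tip: str) -> float:
        return self.rate_multipliers.get(tip, 1.0)


@dataclass
class TruthBundle:
    """Everything a recovery test needs: genomes, the event log, true
    homology and true synonymous distances."""

    config: SimulationConfig
    ancestor: Genome
    root: Genome  # post-WGT, pre-divergence
    tips: dict[str, Genome]
    event_log: list[tuple[str, object]]
    ortholog_pairs: dict[tuple[str, str], list[HomologPair]]
    paralog_pairs: dict[str, list[HomologPair]]
    true_ks: dict[tuple[str, str], float]

    def all_pairs(self, a: str, b: str) -> list[HomologPair]:
        if a == b:
            return self.paralog_pairs[a]
        key = (a, b) if (a, b) in self.ortholog_pairs else (b, a)
        pairs = self.ortholog_pairs[key]
        if key != (a, b):
            pairs = [HomologPair(p.gene_b, p.gene_a, p.score) for p in pairs]
        return pairs

    def ancestor_pairs(self, tip: str) -> list[HomologPair]:
        """Homolog pairs between the pre-WGT ancestor and one tip: each
        tip gene against its ancestral source gene."""
        return [
            HomologPair(ancestral_gene(g.gene_id), g.gene_id)
            for g in self.tips[tip]
        ]


def simulate_clade(config: SimulationConfig) -> TruthBundle:
    """Simulate ancestor -> (WGT) -> star of tips with rearrangements,
    gene-order truth and (optionally) coding sequences."""
    rng = np.random.default_rng(config.seed)
    ancestor = simulate_ancestor(
        config.n_chromosomes, config.genes_per_chromosome,
        seed=int(rng.integers(2**31)), spacing=config.spacing,
        gene_length=config.gene_length,
    )
    log: list[tuple[str, object]] = []
    if config.wgt:
        root, wgt_event = apply_wgt(ancestor, config.wgt_retention, seed=int(rng.integers(2**31)))
        log.append(("root", wgt_event))
    else:
        root = ancestor

    # structural evolution per tip
    tips: dict[str, Genome] = {}
    tip_events: dict[str, list] = {t: [] for t in config.tips}
    for tip, ev in config.event_schedule:
        tip_events[tip].append(ev)
    for tip in config.tips:
        if tip in config.random_events:
            n_inv, n_tr = config.random_events[tip]
            tip_events[tip].extend(
                draw_random_events(root, n_inv, n_tr, rng)
            )
        g, _ = apply_rearrangements(root, tip_events[tip], species_label=tip)
        for ev in tip_events[tip]:
            log.append((tip, ev))
        # relabel with tip prefix
        records = [
            (f"{tip}|{g2.gene_id}", g2.chromosome, g2.start, g2.end, g2.strand, 0)
            for g2 in g
        ]
        tips[tip] = Genome(tip, records, chromosomes=list(g.chromosomes))

    # per-gene lognormal rate factor shared across copies and tips
    anc_ids = [g.gene_id for g in ancestor]
    gene_factor = {
        gid: float(np.exp(rng.normal(0.0, config.ks_sigma))) for gid in anc_ids
    }

    # event depth per tip branch (synonymous substitutions per site from
    # the duplication/speciation node to the tip)
    depth_key = "wgt" if config.wgt else "speciation"
    event_ks = config.ks_targets.get(depth_key, 1.22 if config.wgt else 0.3)
    branch_depth = {t: 0.5 * event_ks * config.multiplier(t) for t in config.tips}

    # sequences: root CDS per post-WGT gene copy, evolved independently to
    # each tip
    cds: dict[str, dict[str, str]] = {t: {} for t in config.tips}
    if config.with_cds:
        root_seq: dict[str, list[str]] = {}
        for gid in anc_ids:
            root_seq[gid] = random_cds(config.n_codons, rng)
        for tip in config.tips:
            genome = tips[tip]
            for g in genome:
                anc = ancestral_gene(g.gene_id)
                depth = branch_depth[tip] * gene_factor[anc]
                branch_time = _total_time_for_ks(2.0 * depth, config.kappa) / 2.0
                evolved, _ = _evolve_codons(
                    root_seq[anc], branch_time, config.kappa, rng
                )
                cds[tip][g.gene_id] = "".join(evolved)
        tips = {
            t: Genome(t, [(g.gene_id, g.chromosome, g.start, g.end, g.strand, 0) for g in gm],
                      cds=cds[t], chromosomes=list(gm.chromosomes))
            for t, gm in tips.items()
        }

    # truth pairs: intended synonymous depth on the NG86 scale
    def _true_ks(tip_a: str, ga: str, tip_b: str, gb: str) -> float:
        anc = ancestral_gene(ga)
        return (branch_depth[tip_a] + branch_depth[tip_b]) * gene_factor[anc]

    by_source: dict[str, dict[str, list[str]]] = {t: {} for t in config.tips}
    by_anc: dict[str, dict[str, list[str]]] = {t: {} for t in config.tips}
    for tip, genome in tips.items():
        for g in genome:
            by_source[tip].setdefault(source_id(g.gene_id), []).append(g.gene_id)
            by_anc[tip].setdefault(ancestral_gene(g.gene_id), []).append(g.gene_id)

    true_ks: dict[tuple[str, str], float] = {}
    paralog_pairs: dict[str, list[HomologPair]] = {}
    for tip in config.tips:
        pairs = []
        for anc, members in sorted(by_anc[tip].items()):
            for ga, gb in itertools.combinations(sorted(members), 2):
                pairs.append(HomologPair(ga, gb))
                true_ks[(ga, gb)] = _true_ks(tip, ga, tip, gb)
        paralog_pairs[tip] = pairs

    ortholog_pairs: dict[tuple[str, str], list[HomologPair]] = {}
    for ta, tb in itertools.combinations(config.tips, 2):
        pairs = []
        for src in sorted(set(by_source[ta]) & set(by_source[tb])):
            for ga in sorted(by_source[ta][src]):
                for gb in sorted(by_source[tb][src]):
                    pairs.append(HomologPair(ga, gb))
                    true_ks[(ga, gb)] = _true_ks(ta, ga, tb, gb)
        ortholog_pairs[(ta, tb)] = pairs

    if config.false_pair_rate > 0:
        for tip_pair, pairs in ortholog_pairs.items():
            n_false = int(config.false_pair_rate * len(pairs))
            ga_pool = [g.gene_id for g in tips[tip_pair[0]]]
            gb_pool = [g.gene_id for g in tips[tip_pair[1]]]
            for _ in range(n_false):
                pairs.append(
                    HomologPair(
                        ga_pool[int(rng.integers(len(ga_pool)))],
                        gb_pool[int(rng.integers(len(gb_pool)))],
                    )
                )

    return TruthBundle(
        config=config, ancestor=ancestor, root=root, tips=tips,
        event_log=log, ortholog_pairs=ortholog_pairs,
        paralog_pairs=paralog_pairs, true_ks=true_ks,
    )


# ---------------------------------------------------------------------------
# fixture emission

TRUTH_SCHEMA_VERSION = 1


def _event_to_json(ev) -> dict:
    d = {"type": type(ev).__name__}
    d.update({k: (list(v) if isinstance(v, tuple) else v) for k, v in ev.__dict__.items()})
    return d


def event_from_json(d: dict):
    cls = _EVENT_TYPES[d["type"]]
    kwargs = {k: v for k, v in d.items() if k != "type"}
    for k, v in kwargs.items():
        if isinstance(v, list):
            kwargs[k] = tuple(v)
    return cls(**kwargs)


def emit_fixtures(bundle: TruthBundle, out_dir, cross_pairs: bool = False) -> list[Path]:
    """Write BED + CDS FASTA + within-genome homolog TSV per tip, plus one
    truth JSON (3k + 1 files for k tips; cross-tip pair files optional)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for tip, genome in bundle.tips.items():
        bed = out / f"{tip}.bed"
        write_gene_positions(genome, bed)
        fa = out / f"{tip}.cds.fa"
        write_cds_fasta(genome.cds or {}, fa)
        tsv = out / f"{tip}.pairs.tsv"
        write_homolog_pairs(bundle.paralog_pairs[tip], tsv)
        written += [bed, fa, tsv]
    if cross_pairs:
        for (ta, tb), pairs in sorted(bundle.ortholog_pairs.items()):
            p = out / f"{ta}--{tb}.pairs.tsv"
            write_homolog_pairs(pairs, p)
            written.append(p)
    truth = {
        "schema_version": TRUTH_SCHEMA_VERSION,
        "seed": bundle.config.seed,
        "tips": list(bundle.config.tips),
        "event_log": [
            {"branch": branch, "event": _event_to_json(ev)}
            for branch, ev in bundle.event_log
        ],
        "ortholog_pairs": {
            f"{a}--{b}": [[p.gene_a, p.gene_b] for p in pairs]
            for (a, b), pairs in sorted(bundle.ortholog_pairs.items())
        },
        "true_ks": {f"{a}\t{b}": ks for (a, b), ks in sorted(bundle.true_ks.items())},
    }
    tj = out / "truth.json"
    tj.write_text(json.dumps(truth, indent=1, sort_keys=True))
    written.append(tj)
    return written
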