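"""Independent oracles shared by the unit and acceptance suites.

These deliberately re-derive quantities by enumeration rather than calling
the library code paths they check.
"""

import itertools

from Bio.Data.CodonTable import standard_dna_table

from syntevo.types import Anchor

STOPS = set(standard_dna_table.stop_codons)
TABLE = standard_dna_table.forward_table
SENSE = sorted(set(map("".join, itertools.product("ACGT", repeat=3))) - STOPS)


def translate(codon):
    return None if codon in STOPS else TABLE[codon]


def grid_anchors(rng, n=30, size=50):
    """Random anchors on a size x size rank grid, unique rank_a."""
    ras = rng.choice(size, size=n, replace=False)
    rbs = rng.integers(0, size, size=n)
    return [
        Anchor(f"a{i}", f"b{i}", "A", int(ra), "B", int(rb), "same", 1.0)
        for i, (ra, rb) in enumerate(zip(ras, rbs))
    ]


def brute_force_best_score(anchors, max_gap, gap_penalty):
    """Exhaustive DFS over every gap-feasible monotonic chain, both
    orientations."""
    pts = sorted((a.rank_a, a.rank_b, a.score) for a in anchors)
    best = 0.0

    def extend(i, score, sign):
        nonlocal best
        best = max(best, score)
        ra, rb, _ = pts[i]
        for j in range(i + 1, len(pts)):
            ra2, rb2, s2 = pts[j]
            gap_a = ra2 - ra - 1
            gap_b = sign * (rb2 - rb) - 1
            if gap_a < 0 or gap_b < 0 or gap_a > max_gap or gap_b > max_gap:
                continue
            extend(j, score + s2 - gap_penalty * (gap_a + gap_b), sign)

    for i in range(len(pts)):
        for sign in (1, -1):
            extend(i, pts[i][2], sign)
    return best


def oracle_sites(codon):
    s = 0.0
    for pos, base in enumerate(codon):
        syn = sum(
            1
            for alt in "ACGT"
            if alt != base
            and codon[:pos] + alt + codon[pos + 1:] not in STOPS
            and translate(codon[:pos] + alt + codon[pos + 1:]) == translate(codon)
        )
        s += syn / 3
    return s


def oracle_diffs(c1, c2):
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    blocked, stop_free = [], []
    for order in itertools.permutations(positions):
        cur, sd, nd, hit_stop = c1, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOPS:
                hit_stop = True
            if translate(cur) is not None and translate(nxt) == translate(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        (stop_free if not hit_stop else blocked).append((sd, nd))
    use = stop_free or blocked
    return (
        sum(p[0] for p in use) / len(use),
        sum(p[1] for p in use) / len(use),
    )


def oracle_counts(codons_a, codons_b):
    S = Sd = Nd = n = 0.0
    for ca, cb in zip(codons_a, codons_b):
        if ca in STOPS or cb in STOPS:
            continue
        n += 1
        S += (oracle_sites(ca) + oracle_sites(cb)) / 2
        sd, nd = oracle_diffs(ca, cb)
        Sd += sd
        Nd += nd
    return S, 3 * n - S, Sd, Nd
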