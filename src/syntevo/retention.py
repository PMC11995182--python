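"""Gene retention of a target genome within collinear regions of a
reference genome.

A reference gene counts as retained iff it appears as an anchor in at
least one collinear block (blocks computed with the reference as
genome_a). Retention is profiled in sliding rank windows along each
reference chromosome and summarised genome-wide; after a polyploidy event
with per-copy retention q and three subgenomes the expected reference-side
retention is 1 - (1 - q)^3 when the target keeps all subgenomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .types import CollinearBlock, Genome

__all__ = ["RetentionProfile", "retention_profile", "overall_retention", "retained_gene_ids"]


@dataclass
class RetentionProfile:
    """Per-window retained fractions along one reference chromosome.

    windows: (start_rank, end_rank, n_reference_genes, n_retained, rho)
    with end exclusive; windows start every ``step`` ranks and the final
    windows are clipped at the chromosome end.
    """

    chromosome: str
    window_size: int
    step: int
    windows: list[tuple[int, int, int, int, float]] = field(default_factory=list)
    overall_fraction: float = 0.0


def retained_gene_ids(reference: Genome, blocks: list[CollinearBlock]) -> set[str]:
    """Reference gene ids that anchor at least one block."""
    return {a.gene_a for b in blocks for a in b.anchors if a.gene_a in reference}


def retention_profile(
    reference: Genome,
    blocks: list[CollinearBlock],
    window_size: int = 100,
    step: int = 50,
) -> list[RetentionProfile]:
    """Windowed retention along every reference chromosome."""
    if window_size < 5:
        raise ValueError("window_size < 5 gives unstable fractions; refuse")
    if step < 1:
        raise ValueError("step must be >= 1")
    retained = retained_gene_ids(reference, blocks)
    profiles = []
    for chrom in reference.chromosomes:
        genes = reference.genes_on(chrom)
        n = len(genes)
        flags = [g.gene_id in retained for g in genes]
        windows = []
        chrom_ret = sum(flags)
        for start in range(0, n, step):
            end = min(start + window_size, n)
            n_ref = end - start
            n_ret = sum(flags[start:end])
            windows.append((start, end, n_ref, n_ret, n_ret / n_ref if n_ref else 0.0))
        profiles.append(
            RetentionProfile(
                chromosome=chrom, window_size=window_size, step=step,
                windows=windows, overall_fraction=chrom_ret / n if n else 0.0,
            )
        )
    return profiles


def overall_retention(
    reference: Genome,
    blocks: list[CollinearBlock],
    in_block_only: bool = False,
) -> float:
    """Retained reference genes over all reference genes.

    With ``in_block_only`` the denominator is restricted to genes whose
    rank falls inside at least one block span on the reference side.
    """
    retained = retained_gene_ids(reference, blocks)
    if not in_block_only:
        total = len(reference)
        return len(retained) / total if total else 0.0
    in_span = set()
    for b in blocks:
        lo, hi = b.span_a
        try:
            genes = reference.genes_on(b.chr_a)
        except KeyError:
            continue
        for g in genes[lo:hi + 1]:
            in_span.add(g.gene_id)
    return (len(retained & in_span) / len(in_span)) if in_span else 0.0
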