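"""Core datatypes shared across the pipeline.

All genome coordinates are 0-based half-open. Gene order is expressed in
*rank* space: the rank of a gene is its 0-based position along its
chromosome when genes are sorted by (start, end, gene_id).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping


@dataclass(frozen=True, order=True)
class GeneModel:
    """A single gene placed on a chromosome.

    ``rank`` is dense (0..n-1 per chromosome) and ordered by start
    coordinate with (start, end, gene_id) as the deterministic tie-break.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str  # "+" or "-"
    rank: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} must be < end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")


class Genome:
    """Ordered gene models per chromosome plus optional coding sequences.

    The constructor assigns ranks; input record order never matters.
    """

    def __init__(
        self,
        species_label: str,
        genes: Iterable[GeneModel] | Iterable[tuple],
        cds: Mapping[str, str] | None = None,
        chromosomes: list[str] | None = None,
    ) -> None:
        raw: list[GeneModel] = []
        for g in genes:
            if not isinstance(g, GeneModel):
                g = GeneModel(*g)
            raw.append(g)
        seen: set[str] = set()
        for g in raw:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in raw:
            by_chrom.setdefault(g.chromosome, []).append(g)
        if chromosomes is None:
            chromosomes = sorted(by_chrom)
        else:
            missing = set(by_chrom) - set(chromosomes)
            if missing:
                raise ValueError(f"genes on undeclared chromosomes: {sorted(missing)}")
        self.species_label = species_label
        self.chromosomes: list[str] = list(chromosomes)
        self._by_chrom: dict[str, list[GeneModel]] = {}
        self._by_id: dict[str, GeneModel] = {}
        for chrom in self.chromosomes:
            ordered = sorted(
                by_chrom.get(chrom, ()), key=lambda g: (g.start, g.end, g.gene_id)
            )
            ranked = [replace(g, rank=i) for i, g in enumerate(ordered)]
            self._by_chrom[chrom] = ranked
            for g in ranked:
                self._by_id[g.gene_id] = g
        self.cds: dict[str, str] | None = None
        if cds is not None:
            for gid, seq in cds.items():
                if len(seq) % 3 != 0 or len(seq) == 0:
                    raise ValueError(
                        f"CDS for {gid} has length {len(seq)}, not a positive multiple of 3"
                    )
            self.cds = dict(cds)

    # -- access ---------------------------------------------------------
    def genes_on(self, chromosome: str) -> list[GeneModel]:
        return self._by_chrom[chromosome]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self):
        for chrom in self.chromosomes:
            yield from self._by_chrom[chrom]

    def n_genes(self, chromosome: str | None = None) -> int:
        if chromosome is None:
            return len(self._by_id)
        return len(self._by_chrom[chromosome])

    def gene_at(self, chromosome: str, rank: int) -> GeneModel:
        return self._by_chrom[chromosome][rank]

    def __eq__(self, other) -> bool:
        if not isinstance(other, Genome):
            return NotImplemented
        return (
            self.species_label == other.species_label
            and self.chromosomes == other.chromosomes
            and self._by_chrom == other._by_chrom
            and self.cds == other.cds
        )


@dataclass(frozen=True)
class HomologPair:
    """A homologous gene pair, typically reciprocal-best-hit output."""

    gene_a: str
    gene_b: str
    score: float | None = None


@dataclass(frozen=True)
class Anchor:
    """A homolog pair in rank coordinates — one dot-plot point."""

    gene_a: str
    gene_b: str
    chr_a: str
    rank_a: int
    chr_b: str
    rank_b: int
    strand_match: str  # "same" or "opposite"
    score: float = 1.0


@dataclass
class CollinearBlock:
    """A maximal chained run of anchors with consistent orientation."""

    block_id: int
    anchors: list[Anchor]
    chr_a: str
    chr_b: str
    orientation: str  # "+" (rank_b ascending) or "-" (descending)
    chain_score: float
    classification: str = "unassigned"
    median_ks: float | None = None

    def __post_init__(self) -> None:
        ra = [a.rank_a for a in self.anchors]
        rb = [a.rank_b for a in self.anchors]
        if ra != sorted(ra) or len(set(ra)) != len(ra):
            raise ValueError(f"block {self.block_id}: rank_a not strictly increasing")
        if self.orientation == "+":
            ok = all(x < y for x, y in zip(rb, rb[1:]))
        else:
            ok = all(x > y for x, y in zip(rb, rb[1:]))
        if not ok:
            raise ValueError(
                f"block {self.block_id}: rank_b not monotone for orientation {self.orientation}"
            )

    @property
    def span_a(self) -> tuple[int, int]:
        return self.anchors[0].rank_a, self.anchors[-1].rank_a

    @property
    def span_b(self) -> tuple[int, int]:
        rb = [a.rank_b for a in self.anchors]
        return min(rb), max(rb)

    def __len__(self) -> int:
        return len(self.anchors)
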