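"""Readers and writers for gene positions (BED/GFF3), CDS FASTA, homolog
pair tables and the collinearity block format.

Internal coordinates are 0-based half-open everywhere; GFF3's 1-based
inclusive coordinates are converted at this boundary and converted back on
write. Re-reading anything written here reproduces it exactly.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import Anchor, CollinearBlock, Genome, HomologPair

__all__ = [
    "ParseError",
    "read_gene_positions",
    "write_gene_positions",
    "read_cds_fasta",
    "write_cds_fasta",
    "read_homolog_pairs",
    "write_homolog_pairs",
    "read_collinearity",
    "write_collinearity",
]


class ParseError(ValueError):
    """Raised for malformed input lines; carries the 1-based line number."""

    def __init__(self, path, lineno: int, message: str) -> None:
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


# ---------------------------------------------------------------------------
# gene positions


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".bed",):
        return "bed"
    if suffix in (".gff", ".gff3"):
        return "gff3"
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def read_gene_positions(
    path,
    format: str | None = None,
    species_label: str | None = None,
    feature_types: tuple[str, ...] = ("gene", "mRNA"),
) -> Genome:
    """Read a BED (0-based half-open) or GFF3 (1-based inclusive) gene table.

    Ranks are assigned per chromosome by start coordinate regardless of the
    record order in the file. For GFF3, only records whose type is in
    ``feature_types`` are used and the ``ID=`` attribute is the gene id.
    """
    path = Path(path)
    fmt = (format or _infer_format(path)).lower()
    if species_label is None:
        species_label = path.stem
    records: list[tuple] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fmt == "bed":
                if len(fields) < 4:
                    raise ParseError(path, lineno, f"BED needs >= 4 columns, got {len(fields)}")
                chrom, start_s, end_s, name = fields[:4]
                strand = fields[5] if len(fields) >= 6 else "+"
                try:
                    start, end = int(start_s), int(end_s)
                except ValueError:
                    raise ParseError(path, lineno, f"non-integer coordinates {start_s!r}/{end_s!r}")
            elif fmt == "gff3":
                if len(fields) != 9:
                    raise ParseError(path, lineno, f"GFF3 needs 9 columns, got {len(fields)}")
                chrom, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
                if ftype not in feature_types:
                    continue
                m = re.search(r"(?:^|;)ID=([^;]+)", attrs)
                if not m:
                    raise ParseError(path, lineno, "missing ID= attribute")
                name = m.group(1)
                try:
                    start, end = int(start_s) - 1, int(end_s)  # to 0-based half-open
                except ValueError:
                    raise ParseError(path, lineno, f"non-integer coordinates {start_s!r}/{end_s!r}")
            else:
                raise ValueError(f"unknown format {fmt!r}")
            if strand not in ("+", "-"):
                raise ParseError(path, lineno, f"bad strand {strand!r}")
            if name in seen:
                raise ParseError(path, lineno, f"duplicate gene_id {name!r}")
            seen.add(name)
            records.append((name, chrom, start, end, strand, 0))
    chrom_order = list(dict.fromkeys(r[1] for r in records))  # first appearance
    return Genome(species_label, records, chromosomes=chrom_order)


def write_gene_positions(genome: Genome, path, format: str | None = None) -> None:
    path = Path(path)
    fmt = (format or _infer_format(path)).lower()
    with open(path, "w") as fh:
        if fmt == "gff3":
            fh.write("##gff-version 3\n")
        for gene in genome:
            if fmt == "bed":
                fh.write(
                    f"{gene.chromosome}\t{gene.start}\t{gene.end}\t{gene.gene_id}\t0\t{gene.strand}\n"
                )
            elif fmt == "gff3":
                fh.write(
                    f"{gene.chromosome}\tsyntevo\tgene\t{gene.start + 1}\t{gene.end}\t.\t"
                    f"{gene.strand}\t.\tID={gene.gene_id}\n"
                )
            else:
                raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# CDS FASTA

_VALID_CDS = re.compile(r"^[ACGTN]*$")


def read_cds_fasta(path, strict: bool = True) -> dict[str, str]:
    """Read coding sequences; header first token is the gene id.

    Sequences are uppercased. A length not divisible by 3 is an error in
    strict mode, otherwise the record is skipped. Characters outside ACGTN
    are always an error.
    """
    out: dict[str, str] = {}
    bad_chars: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        gid = rec.id
        seq = str(rec.seq).upper()
        if not _VALID_CDS.match(seq):
            bad_chars.append(gid)
            continue
        if len(seq) % 3 != 0 or len(seq) == 0:
            if strict:
                raise ValueError(f"CDS {gid!r} has length {len(seq)}, not a positive multiple of 3")
            continue
        out[gid] = seq
    if bad_chars:
        raise ValueError(f"non-ACGTN characters in CDS records: {bad_chars}")
    return out


def write_cds_fasta(cds: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=gid, description="") for gid, seq in cds.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# homolog pairs


def read_homolog_pairs(
    path,
    genome_a: Genome | None = None,
    genome_b: Genome | None = None,
    collapse_unordered: bool = True,
) -> tuple[list[HomologPair], list[HomologPair]]:
    """Read a tab-delimited homolog table (gene_a, gene_b[, score]).

    Returns ``(pairs, rejects)``: pairs are deduplicated (unordered
    duplicates collapsed when ``collapse_unordered``); pairs whose ids do
    not resolve in the supplied genomes land in ``rejects`` instead of
    raising.
    """
    path = Path(path)
    pairs: list[HomologPair] = []
    rejects: list[HomologPair] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(path, lineno, "need >= 2 tab-separated columns")
            ga, gb = fields[0], fields[1]
            score = None
            if len(fields) >= 3 and fields[2] != "":
                try:
                    score = float(fields[2])
                except ValueError:
                    raise ParseError(path, lineno, f"bad score {fields[2]!r}")
            key = (ga, gb)
            if collapse_unordered:
                key = (min(ga, gb), max(ga, gb))
            if key in seen:
                continue
            seen.add(key)
            pair = HomologPair(ga, gb, score)
            resolvable = True
            if genome_a is not None and ga not in genome_a:
                resolvable = False
            if genome_b is not None and gb not in genome_b:
                resolvable = False
            (pairs if resolvable else rejects).append(pair)
    return pairs, rejects


def write_homolog_pairs(pairs: Iterable[HomologPair], path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            score = "" if p.score is None else f"{p.score:g}"
            fh.write(f"{p.gene_a}\t{p.gene_b}\t{score}\n")


# ---------------------------------------------------------------------------
# collinearity blocks (MCScanX-like text layout)

_HEADER = "## syntevo collinearity v1"


def write_collinearity(blocks: Iterable[CollinearBlock], path) -> None:
    """Serialise blocks: a ``#`` header line per block, one anchor per line.

    Anchors of a "-" block are written in block order, i.e. descending
    rank_b.
    """
    with open(path, "w") as fh:
        fh.write(_HEADER + "\n")
        for b in blocks:
            ks = "NA" if b.median_ks is None else repr(b.median_ks)
            fh.write(
                f"# block {b.block_id}: chr_a={b.chr_a} chr_b={b.chr_b} "
                f"orientation={b.orientation} score={b.chain_score!r} "
                f"n={len(b.anchors)} class={b.classification} median_ks={ks}\n"
            )
            for a in b.anchors:
                fh.write(
                    f"{a.gene_a}\t{a.gene_b}\t{a.chr_a}\t{a.rank_a}\t{a.chr_b}\t"
                    f"{a.rank_b}\t{a.strand_match}\t{a.score!r}\n"
                )


_BLOCK_RE = re.compile(
    r"# block (\d+): chr_a=(\S+) chr_b=(\S+) orientation=([+-]) "
    r"score=(\S+) n=(\d+) class=(\S+) median_ks=(\S+)"
)


def read_collinearity(path) -> list[CollinearBlock]:
    blocks: list[CollinearBlock] = []
    current: CollinearBlock | None = None
    anchors: list[Anchor] = []
    meta = None
    path = Path(path)

    def flush():
        nonlocal meta, anchors
        if meta is None:
            return
        bid, ca, cb, orient, score, n, cls, ks = meta
        if len(anchors) != n:
            raise ValueError(f"block {bid}: expected {n} anchors, found {len(anchors)}")
        blocks.append(
            CollinearBlock(
                block_id=bid, anchors=anchors, chr_a=ca, chr_b=cb, orientation=orient,
                chain_score=score, classification=cls, median_ks=ks,
            )
        )
        meta, anchors = None, []

    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != _HEADER:
            raise ParseError(path, 1, f"bad header {first!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                m = _BLOCK_RE.match(line)
                if not m:
                    raise ParseError(path, lineno, "malformed block header")
                flush()
                bid, ca, cb, orient, score, n, cls, ks = m.groups()
                meta = (
                    int(bid), ca, cb, orient, float(score), int(n), cls,
                    None if ks == "NA" else float(ks),
                )
            else:
                fields = line.split("\t")
                if len(fields) != 8:
                    raise ParseError(path, lineno, f"anchor line needs 8 columns, got {len(fields)}")
                ga, gb, ca, ra, cb, rb, sm, score = fields
                anchors.append(
                    Anchor(ga, gb, ca, int(ra), cb, int(rb), sm, float(score))
                )
    flush()
    return blocks
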