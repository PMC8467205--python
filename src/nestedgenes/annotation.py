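"""Gene-model construction from GTF annotations.

A gene model is the union of the exons of *all* annotated transcripts of a
gene, with introns defined as the maximal gaps in that union.  A region is
therefore intronic only if it is intronic in every transcript — the
conservative reading required when asking whether another gene lies "in an
intron" of its host.

Coordinates are 0-based half-open internally; GTF I/O converts at the
boundary (GTF is 1-based inclusive).
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "AnnotationSet",
    "GtfParseError",
    "merge_intervals",
    "derive_introns",
    "read_gtf",
    "write_gtf",
    "gene_model_table",
]

_STRANDS = ("+", "-")


class GtfParseError(ValueError):
    """Raised for a malformed GTF record; message names the offending line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded interval on a chromosome, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"interval start must precede end: [{self.start}, {self.end})"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {_STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        """True if ``other`` lies entirely within this interval (same chrom)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Strand-agnostic overlap; abutting intervals do not overlap."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals on one chromosome: sorted, pairwise-disjoint blocks.

    Abutting intervals ([0,10) and [10,20)) are merged into one block, so the
    gaps that remain are genuine gaps.
    """
    if not intervals:
        return []
    chroms = {iv.chrom for iv in intervals}
    if len(chroms) > 1:
        raise ValueError(f"cannot merge intervals on mixed chromosomes: {sorted(chroms)}")
    ivs = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    strand = ivs[0].strand
    merged: list[list[int]] = [[ivs[0].start, ivs[0].end]]
    for iv in ivs[1:]:
        if iv.start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], iv.end)
        else:
            merged.append([iv.start, iv.end])
    chrom = ivs[0].chrom
    return [GenomicInterval(chrom, s, e, strand) for s, e in merged]


def derive_introns(exons: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Maximal gaps between the merged union of exons.

    A single-exon gene (or one whose exons merge to a single block) has no
    introns.  Exons must share a chromosome.
    """
    if not exons:
        raise ValueError("derive_introns requires at least one exon")
    merged = merge_intervals(exons)
    strand = merged[0].strand
    chrom = merged[0].chrom
    return [
        GenomicInterval(chrom, a.end, b.start, strand)
        for a, b in zip(merged, merged[1:])
    ]


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene as a merged-exon model with derived introns."""

    gene_id: str
    biotype: str
    span: GenomicInterval
    merged_exons: tuple[GenomicInterval, ...]
    introns: tuple[GenomicInterval, ...]

    @classmethod
    def from_exons(
        cls, gene_id: str, biotype: str, exons: Sequence[GenomicInterval]
    ) -> "GeneModel":
        merged = tuple(merge_intervals(exons))
        introns = tuple(derive_introns(exons))
        span = GenomicInterval(
            merged[0].chrom, merged[0].start, merged[-1].end, merged[0].strand
        )
        return cls(gene_id, biotype, span, merged, introns)

    @property
    def chrom(self) -> str:
        return self.span.chrom

    @property
    def strand(self) -> str:
        return self.span.strand


@dataclass
class AnnotationSet:
    """All retained gene models of one species, indexed by id and chromosome."""

    species: str
    genes: dict[str, GeneModel] = field(default_factory=dict)

    def add(self, gene: GeneModel) -> None:
        if gene.gene_id in self.genes:
            raise ValueError(f"duplicate gene_id {gene.gene_id!r} in {self.species}")
        self.genes[gene.gene_id] = gene

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def by_chrom(self) -> dict[str, list[GeneModel]]:
        out: dict[str, list[GeneModel]] = {}
        for g in self.genes.values():
            out.setdefault(g.chrom, []).append(g)
        for lst in out.values():
            lst.sort(key=lambda g: (g.span.start, g.span.end, g.gene_id))
        return out


def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _validate_gtf_lines(path: Path) -> int:
    """Stream the file once, rejecting structurally broken lines.

    Returns the number of records with an unrecognized strand symbol (these
    are later dropped with a warning rather than aborting the parse).
    """
    bad_strand = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise GtfParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            start_s, end_s = fields[3], fields[4]
            if not (start_s.isdigit() and end_s.isdigit()):
                raise GtfParseError(
                    f"{path}: line {lineno}: non-integer coordinates "
                    f"{start_s!r}/{end_s!r}"
                )
            if int(start_s) > int(end_s):
                raise GtfParseError(
                    f"{path}: line {lineno}: start {start_s} exceeds end {end_s}"
                )
            if fields[6] not in _STRANDS:
                bad_strand += 1
    return bad_strand


def read_gtf(
    path: str | Path,
    biotype_filter: str | None = "protein_coding",
    species: str | None = None,
) -> AnnotationSet:
    """Read an Ensembl-dialect GTF into per-gene merged-exon models.

    Exons from all transcripts of a gene are pooled and merged before intron
    derivation; duplicate gene records collapse into one model.  Records with
    a strand other than ``+``/``-`` are dropped with a warning.  Gzipped
    input is accepted.

    Parameters
    ----------
    path:
        GTF file (1-based inclusive coordinates; attribute column must carry
        ``gene_id`` and ``gene_biotype``).
    biotype_filter:
        Retain only genes of this biotype (``None`` keeps everything).
    species:
        Species tag for the returned :class:`AnnotationSet` (defaults to the
        file stem).
    """
    import pyranges as pr

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation file not found: {path}")
    tag = species if species is not None else path.stem.removesuffix(".gtf")

    bad_strand = _validate_gtf_lines(path)
    if bad_strand:
        warnings.warn(
            f"{path}: dropped {bad_strand} record(s) with unrecognized strand",
            stacklevel=2,
        )

    annotation = AnnotationSet(species=tag)
    with _open_text(path) as fh:
        if not any(line.strip() and not line.startswith("#") for line in fh):
            return annotation

    df = pr.read_gtf(str(path)).df
    df = df[df.Strand.isin(_STRANDS)]
    exons = df[df.Feature == "exon"].copy()
    if "gene_biotype" in exons.columns and biotype_filter is not None:
        exons = exons[exons.gene_biotype == biotype_filter]
    biotypes = (
        exons.groupby("gene_id").gene_biotype.first()
        if "gene_biotype" in exons.columns
        else pd.Series(dtype=object)
    )
    for gene_id, sub in exons.groupby("gene_id", sort=True):
        if sub.Chromosome.nunique() > 1:
            warnings.warn(
                f"{path}: gene {gene_id} has exons on multiple chromosomes; skipped",
                stacklevel=2,
            )
            continue
        ivs = [
            GenomicInterval(str(r.Chromosome), int(r.Start), int(r.End), str(r.Strand))
            for r in sub.itertuples()
        ]
        biotype = str(biotypes.get(gene_id, "unknown"))
        annotation.add(GeneModel.from_exons(str(gene_id), biotype, ivs))
    return annotation


def write_gtf(annotation: AnnotationSet, path: str | Path) -> None:
    """Serialize merged-exon models back to Ensembl-dialect GTF.

    Each gene is written as one gene record, one synthetic transcript, and
    its merged exons (internal 0-based half-open converted to GTF 1-based
    inclusive).  ``read_gtf(write_gtf(x)) == x`` for merged models.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for gene in sorted(
            annotation, key=lambda g: (g.chrom, g.span.start, g.gene_id)
        ):
            attrs = f'gene_id "{gene.gene_id}"; gene_biotype "{gene.biotype}";'
            tx_attrs = (
                f'gene_id "{gene.gene_id}"; transcript_id "{gene.gene_id}.t1"; '
                f'gene_biotype "{gene.biotype}";'
            )
            s, e = gene.span.start + 1, gene.span.end
            fh.write(
                f"{gene.chrom}\tnestedgenes\tgene\t{s}\t{e}\t.\t{gene.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{gene.chrom}\tnestedgenes\ttranscript\t{s}\t{e}\t.\t{gene.strand}\t.\t{tx_attrs}\n"
            )
            for ex in gene.merged_exons:
                fh.write(
                    f"{gene.chrom}\tnestedgenes\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{gene.strand}\t.\t{tx_attrs}\n"
                )


def gene_model_table(annotation: AnnotationSet) -> pd.DataFrame:
    """Per-gene summary table (one row per gene model)."""
    rows = [
        {
            "gene_id": g.gene_id,
            "chrom": g.chrom,
            "start": g.span.start,
            "end": g.span.end,
            "strand": g.strand,
            "n_exons": len(g.merged_exons),
            "n_introns": len(g.introns),
            "span_length": len(g.span),
        }
        for g in sorted(annotation, key=lambda g: (g.chrom, g.span.start, g.gene_id))
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "chrom",
            "start",
            "end",
            "strand",
            "n_exons",
            "n_introns",
            "span_length",
        ],
    )
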