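"""Nested gene-pair detection and the unnested/non-overlapping gene universe.

A pair (external, internal) is nested when the internal gene's span lies
entirely within a single intron of the external gene's merged-exon model.
Genes that overlap another gene in any other way (exon overlap, partial
span overlap, same-strand or not) belong to neither the nested pairs nor
the unnested universe.  For nesting chains (A hosts B, B hosts C) each
internal gene is assigned to its innermost host, so only direct host
relationships are emitted.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
from intervaltree import IntervalTree

from .annotation import AnnotationSet, GeneModel, GenomicInterval

__all__ = [
    "NestedPair",
    "NestingCatalog",
    "StrandBiasSummary",
    "detect_nested",
    "count_pair_universes",
    "strand_bias_summary",
    "write_catalog",
    "read_catalog",
]


@dataclass(frozen=True)
class NestedPair:
    """An (external, internal) gene pair with its host intron.

    ``orientation`` is ``"same"`` when both genes are transcribed from the
    same strand and ``"opposite"`` otherwise; ``simple`` marks pairs whose
    external gene hosts exactly one internal gene.
    """

    external_id: str
    internal_id: str
    host_intron: Optional[GenomicInterval]
    orientation: str
    simple: bool


@dataclass
class NestingCatalog:
    """All nested pairs of one species plus the unnested gene universe."""

    species: str
    pairs: list[NestedPair] = field(default_factory=list)
    unnested_ids: set[str] = field(default_factory=set)
    unnested_chrom: dict[str, str] = field(default_factory=dict)

    @property
    def per_chrom_unnested_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for chrom in self.unnested_chrom.values():
            counts[chrom] = counts.get(chrom, 0) + 1
        return counts

    def pair_set(self) -> set[tuple[str, str]]:
        return {(p.external_id, p.internal_id) for p in self.pairs}

    def internal_ids(self) -> set[str]:
        return {p.internal_id for p in self.pairs}

    def external_ids(self) -> set[str]:
        return {p.external_id for p in self.pairs}


def _containing_intron(
    gene: GeneModel, span: GenomicInterval
) -> Optional[GenomicInterval]:
    """The single intron of ``gene`` containing ``span``, or None.

    Introns are sorted and disjoint, so at most one can contain the span;
    located by bisection on intron starts.
    """
    introns = gene.introns
    if not introns or not gene.span.contains(span):
        return None
    starts = [iv.start for iv in introns]
    i = bisect_right(starts, span.start) - 1
    if i >= 0 and introns[i].contains(span):
        return introns[i]
    return None


def detect_nested(annotation: AnnotationSet) -> NestingCatalog:
    """Detect nested pairs and the unnested/non-overlapping universe.

    The unnested universe holds genes whose span overlaps no other gene's
    span.  Nested genes and partially overlapping genes are both excluded
    from it; only intron-contained genes yield pairs.
    """
    catalog = NestingCatalog(species=annotation.species)
    by_chrom = annotation.by_chrom()

    overlapping: set[str] = set()
    host_of: dict[str, tuple[str, GenomicInterval]] = {}

    for chrom, genes in by_chrom.items():
        if len(genes) == 1:
            continue
        tree = IntervalTree()
        for idx, g in enumerate(genes):
            tree.addi(g.span.start, g.span.end, idx)
        for g in genes:
            hits = [
                genes[iv.data]
                for iv in tree.overlap(g.span.start, g.span.end)
                if genes[iv.data].gene_id != g.gene_id
            ]
            if hits:
                overlapping.add(g.gene_id)
            # candidate hosts: genes whose one intron fully contains g's span
            hosts = []
            for other in hits:
                intron = _containing_intron(other, g.span)
                if intron is not None:
                    hosts.append((other, intron))
            if hosts:
                # innermost host = smallest span; gene_id breaks exact ties
                host, intron = min(
                    hosts, key=lambda h: (len(h[0].span), h[0].gene_id)
                )
                host_of[g.gene_id] = (host.gene_id, intron)

    n_internal_per_external: dict[str, int] = {}
    for _, (ext, _) in host_of.items():
        n_internal_per_external[ext] = n_internal_per_external.get(ext, 0) + 1

    for internal_id in sorted(host_of):
        external_id, intron = host_of[internal_id]
        ext = annotation.genes[external_id]
        inner = annotation.genes[internal_id]
        catalog.pairs.append(
            NestedPair(
                external_id=external_id,
                internal_id=internal_id,
                host_intron=intron,
                orientation="same" if ext.strand == inner.strand else "opposite",
                simple=n_internal_per_external[external_id] == 1,
            )
        )

    for g in annotation:
        if g.gene_id not in overlapping:
            catalog.unnested_ids.add(g.gene_id)
            catalog.unnested_chrom[g.gene_id] = g.chrom
    return catalog


def count_pair_universes(
    per_chrom_counts: Mapping[str, int]
) -> tuple[int, int]:
    """Exact intra- and inter-chromosomal pair counts from per-chromosome
    gene counts: intra = sum of C(n_c, 2); inter = C(total, 2) - intra."""
    for chrom, n in per_chrom_counts.items():
        if n < 0:
            raise ValueError(f"negative count for chromosome {chrom!r}")
    intra = sum(math.comb(n, 2) for n in per_chrom_counts.values())
    total = sum(per_chrom_counts.values())
    return intra, math.comb(total, 2) - intra


@dataclass(frozen=True)
class StrandBiasSummary:
    same: int
    opposite: int
    fraction_opposite: Optional[float]


def strand_bias_summary(
    catalog: NestingCatalog, simple_only: bool = True
) -> StrandBiasSummary:
    """Same- vs opposite-strand counts over nested pairs.

    With ``simple_only`` (the default) only pairs whose external gene hosts a
    single internal gene are counted, giving 1:1 external/internal
    comparisons.  The opposite fraction is None when there are no pairs.
    """
    pairs = [p for p in catalog.pairs if p.simple or not simple_only]
    same = sum(1 for p in pairs if p.orientation == "same")
    opposite = len(pairs) - same
    frac = opposite / len(pairs) if pairs else None
    return StrandBiasSummary(same=same, opposite=opposite, fraction_opposite=frac)


def write_catalog(catalog: NestingCatalog, pairs_path: str | Path, unnested_path: str | Path, header_lines: list[str] | None = None) -> None:
    """Write nested-pair and unnested-gene TSVs."""
    rows = [
        {
            "species": catalog.species,
            "external_id": p.external_id,
            "internal_id": p.internal_id,
            "chrom": p.host_intron.chrom if p.host_intron else ".",
            "orientation": p.orientation,
            "simple": int(p.simple),
            "host_intron_start": p.host_intron.start if p.host_intron else -1,
            "host_intron_end": p.host_intron.end if p.host_intron else -1,
        }
        for p in catalog.pairs
    ]
    cols = [
        "species", "external_id", "internal_id", "chrom", "orientation",
        "simple", "host_intron_start", "host_intron_end",
    ]
    _write_tsv(pd.DataFrame(rows, columns=cols), pairs_path, header_lines)
    un = pd.DataFrame(
        sorted(
            ({"species": catalog.species, "gene_id": g, "chrom": catalog.unnested_chrom.get(g, ".")}
             for g in catalog.unnested_ids),
            key=lambda r: r["gene_id"],
        ),
        columns=["species", "gene_id", "chrom"],
    )
    _write_tsv(un, unnested_path, header_lines)


def read_catalog(pairs_path: str | Path, unnested_path: str | Path) -> NestingCatalog:
    """Read a catalog written by :func:`write_catalog`."""
    pairs_df = pd.read_csv(pairs_path, sep="\t", comment="#")
    un_df = pd.read_csv(unnested_path, sep="\t", comment="#")
    species = ""
    if len(pairs_df):
        species = str(pairs_df.species.iloc[0])
    elif len(un_df):
        species = str(un_df.species.iloc[0])
    catalog = NestingCatalog(species=species)
    for r in pairs_df.itertuples():
        intron = None
        if r.host_intron_start >= 0:
            intron = GenomicInterval(str(r.chrom), int(r.host_intron_start), int(r.host_intron_end), "+")
        catalog.pairs.append(
            NestedPair(
                external_id=str(r.external_id),
                internal_id=str(r.internal_id),
                host_intron=intron,
                orientation=str(r.orientation),
                simple=bool(r.simple),
            )
        )
    for r in un_df.itertuples():
        catalog.unnested_ids.add(str(r.gene_id))
        catalog.unnested_chrom[str(r.gene_id)] = str(r.chrom)
    return catalog


def _write_tsv(df: pd.DataFrame, path: str | Path, header_lines: list[str] | None) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
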