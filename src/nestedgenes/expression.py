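"""Expression breadth and divergence over a fixed seven-tissue panel.

Genes are profiled over brain, lung, liver, spleen, kidney, colon and testis
TPM values.  Expression breadth is the tissue-specificity index

    tau = sum_i (1 - x_i / x_max) / (N - 1),   N = 7,

which is 0 for uniform expression and 1 for single-tissue expression; genes
with tau > 0.9 are called tissue specific.  Expression divergence between two
genes (within or across species) is the Euclidean distance between their
relative TPM profiles (TPM vector divided by its tissue sum), bounded by
sqrt(2).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .nesting import NestingCatalog
from .phylo_events import NestingEventCall, SpeciesTopology

__all__ = [
    "TISSUES",
    "ExpressionTable",
    "TissueProfile",
    "PairDivergence",
    "filter_expressed",
    "compute_tau",
    "tau_table",
    "tissue_profile",
    "profile_table",
    "expression_divergence",
    "divergence_distributions",
    "derived_vs_ancestral_divergence",
]

logger = logging.getLogger(__name__)

TISSUES = ("brain", "lung", "liver", "spleen", "kidney", "colon", "testis")

TAU_SPECIFIC_CUTOFF = 0.9


@dataclass
class ExpressionTable:
    """A gene x tissue TPM matrix for one species over the 7-tissue panel."""

    species: str
    values: pd.DataFrame
    tissues: tuple[str, ...] = TISSUES

    def __post_init__(self) -> None:
        if len(self.tissues) != len(self.values.columns):
            raise ValueError("tissue list must match matrix columns")
        if not self.values.index.is_unique:
            raise ValueError("gene ids must be unique")
        if (self.values.values < 0).any():
            raise ValueError("TPM values must be non-negative")
        self.values.columns = list(self.tissues)

    @classmethod
    def from_tsv(cls, path: str | Path, species: str) -> "ExpressionTable":
        """Read a TPM TSV: first column gene_id, then the seven tissue
        columns (any order; tissue names matched case-insensitively)."""
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
        lower = {c.lower().strip(): c for c in df.columns}
        missing = [t for t in TISSUES if t not in lower]
        if missing:
            raise ValueError(f"{path}: missing tissue column(s) {missing}")
        df = df[[lower[t] for t in TISSUES]].astype(float)
        return cls(species=species, values=df)

    def to_tsv(self, path: str | Path, header_lines: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            out = self.values.copy()
            out.index.name = "gene_id"
            out.to_csv(fh, sep="\t", float_format="%.6g")

    def relative(self) -> pd.DataFrame:
        """Per-gene relative profiles (rows sum to 1; all-zero rows dropped)."""
        sums = self.values.sum(axis=1)
        keep = sums > 0
        return self.values.loc[keep].div(sums[keep], axis=0)

    def __len__(self) -> int:
        return len(self.values)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.values.index


@dataclass(frozen=True)
class TissueProfile:
    gene_id: str
    tissues: tuple[str, ...]
    tpm: tuple[float, ...]
    relative: tuple[float, ...]
    tau: float
    primary_tissue: str
    is_specific: bool


@dataclass(frozen=True)
class PairDivergence:
    gene_a: str
    gene_b: str
    distance: float


def filter_expressed(table: ExpressionTable, threshold: float = 1.0) -> ExpressionTable:
    """Retain genes with TPM >= threshold in at least one tissue.

    Pair-level analyses additionally require both members of a pair to
    survive this filter; that rule is applied by the pair operations.
    """
    keep = table.values.max(axis=1) >= threshold
    return ExpressionTable(species=table.species, values=table.values.loc[keep].copy(),
                           tissues=table.tissues)


def compute_tau(tpm: Sequence[float]) -> float:
    """Tissue-specificity index of one expression vector.

    Scale invariant; undefined (ValueError) for an all-zero vector.
    """
    x = np.asarray(tpm, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("tau needs a 1-D vector of at least two tissues")
    if (x < 0).any():
        raise ValueError("TPM values must be non-negative")
    xmax = x.max()
    if xmax == 0:
        raise ValueError("tau is undefined for an all-zero expression vector")
    return float((1.0 - x / xmax).sum() / (len(x) - 1))


def tau_table(table: ExpressionTable) -> pd.Series:
    """Vectorized tau for every gene with nonzero expression."""
    vals = table.values
    keep = vals.max(axis=1) > 0
    x = vals.loc[keep]
    return (1.0 - x.div(x.max(axis=1), axis=0)).sum(axis=1) / (x.shape[1] - 1)


def tissue_profile(table: ExpressionTable, gene_id: str) -> TissueProfile:
    """Full profile of one gene: relative vector, tau, primary tissue.

    Ties for the maximal TPM are broken by the canonical tissue order and
    logged.
    """
    if gene_id not in table:
        raise KeyError(f"gene {gene_id!r} not in expression table")
    tpm = table.values.loc[gene_id].to_numpy(dtype=float)
    total = tpm.sum()
    if total == 0:
        raise ValueError(f"gene {gene_id!r} has zero expression in every tissue")
    rel = tpm / total
    tau = compute_tau(tpm)
    top = int(np.argmax(tpm))
    if (tpm == tpm[top]).sum() > 1:
        logger.info("gene %s: tied maximal TPM; primary tissue set to %s by canonical order",
                    gene_id, table.tissues[top])
    return TissueProfile(
        gene_id=gene_id,
        tissues=tuple(table.tissues),
        tpm=tuple(tpm),
        relative=tuple(rel),
        tau=tau,
        primary_tissue=table.tissues[top],
        is_specific=tau > TAU_SPECIFIC_CUTOFF,
    )


def profile_table(table: ExpressionTable) -> pd.DataFrame:
    """Per-gene summary: tau, primary tissue, specificity flag."""
    vals = table.values
    keep = vals.max(axis=1) > 0
    x = vals.loc[keep]
    tau = (1.0 - x.div(x.max(axis=1), axis=0)).sum(axis=1) / (x.shape[1] - 1)
    primary = x.idxmax(axis=1)  # first column wins ties = canonical order
    return pd.DataFrame(
        {
            "gene_id": x.index,
            "tau": tau.to_numpy(),
            "primary_tissue": primary.to_numpy(),
            "is_specific": (tau > TAU_SPECIFIC_CUTOFF).to_numpy(),
        }
    ).reset_index(drop=True)


def expression_divergence(a: TissueProfile, b: TissueProfile) -> PairDivergence:
    """Euclidean distance between two relative profiles.

    Cross-species comparison is allowed whenever the ordered tissue lists
    match.
    """
    if a.tissues != b.tissues:
        raise ValueError(
            f"tissue lists differ: {a.tissues} vs {b.tissues}"
        )
    d = float(np.linalg.norm(np.subtract(a.relative, b.relative)))
    return PairDivergence(gene_a=a.gene_id, gene_b=b.gene_id, distance=d)


def _pair_distances(rel: pd.DataFrame, pairs: Iterable[tuple[str, str]]) -> list[PairDivergence]:
    out = []
    idx = rel.index
    mat = rel.to_numpy()
    pos = {g: i for i, g in enumerate(idx)}
    for a, b in pairs:
        d = float(np.linalg.norm(mat[pos[a]] - mat[pos[b]]))
        out.append(PairDivergence(a, b, d))
    return out


def divergence_distributions(
    catalog: NestingCatalog,
    table: ExpressionTable,
    subsample: int = 10_000,
    seed: int = 0,
) -> dict[str, list[PairDivergence]]:
    """Divergence distributions for the nested, intra- and inter-chromosomal
    pair universes.

    The nested universe uses every pair with both members expressed.  The
    intra/inter universes are seeded uniform subsamples (without
    replacement) of all pairs of unnested, non-overlapping, expressed genes
    on the same / on different chromosomes; when the requested subsample
    meets or exceeds a universe it is enumerated in full with a warning.
    ``table`` should already be expression-filtered.
    """
    rng = np.random.default_rng(seed)
    rel = table.relative()
    expressed = set(rel.index)

    nested_pairs = [
        (p.external_id, p.internal_id)
        for p in catalog.pairs
        if p.external_id in expressed and p.internal_id in expressed
    ]

    by_chrom: dict[str, list[str]] = {}
    for g in sorted(catalog.unnested_ids & expressed):
        by_chrom.setdefault(catalog.unnested_chrom.get(g, "."), []).append(g)
    chroms = sorted(by_chrom)
    n_per = np.array([len(by_chrom[c]) for c in chroms], dtype=np.int64)
    intra_total = int(sum(math.comb(int(n), 2) for n in n_per))
    total_genes = int(n_per.sum())
    inter_total = math.comb(total_genes, 2) - intra_total

    def sample_intra(k: int) -> list[tuple[str, str]]:
        if k >= intra_total:
            if k > intra_total:
                warnings.warn("intra-chromosomal subsample exceeds universe; using all pairs")
            return [
                (genes[i], genes[j])
                for genes in by_chrom.values()
                for i in range(len(genes))
                for j in range(i + 1, len(genes))
            ]
        weights = np.array([math.comb(int(n), 2) for n in n_per], dtype=float)
        weights /= weights.sum()
        chosen: set[tuple[str, str]] = set()
        while len(chosen) < k:
            c = chroms[rng.choice(len(chroms), p=weights)]
            genes = by_chrom[c]
            i, j = rng.choice(len(genes), size=2, replace=False)
            chosen.add((genes[min(i, j)], genes[max(i, j)]))
        return sorted(chosen)

    def sample_inter(k: int) -> list[tuple[str, str]]:
        all_genes = [g for c in chroms for g in by_chrom[c]]
        chrom_of = {g: c for c in chroms for g in by_chrom[c]}
        if k >= inter_total:
            if k > inter_total:
                warnings.warn("inter-chromosomal subsample exceeds universe; using all pairs")
            return [
                (all_genes[i], all_genes[j])
                for i in range(len(all_genes))
                for j in range(i + 1, len(all_genes))
                if chrom_of[all_genes[i]] != chrom_of[all_genes[j]]
            ]
        chosen: set[tuple[str, str]] = set()
        while len(chosen) < k:
            i, j = rng.choice(len(all_genes), size=2, replace=False)
            a, b = all_genes[min(i, j)], all_genes[max(i, j)]
            if chrom_of[a] != chrom_of[b]:
                chosen.add((a, b))
        return sorted(chosen)

    return {
        "nested": _pair_distances(rel, nested_pairs),
        "intra": _pair_distances(rel, sample_intra(subsample)) if intra_total else [],
        "inter": _pair_distances(rel, sample_inter(subsample)) if inter_total else [],
    }


def derived_vs_ancestral_divergence(
    calls: Iterable[NestingEventCall],
    tables: Mapping[str, ExpressionTable],
    topology: SpeciesTopology = SpeciesTopology(),
) -> list[PairDivergence]:
    """Cross-species divergence for lineage-specific nesting events.

    For each ``<species>_nesting`` call, the derived (nested) copy of each
    member gene is compared against its unnested ortholog in the other
    ingroup species — the proxy for the ancestral expression state.  Pairs
    with missing expression data are skipped with a log entry.
    """
    i1, i2 = topology.ingroup
    out: list[PairDivergence] = []
    for call in calls:
        if not call.call.endswith("_nesting") or call.call == "unresolved":
            continue
        nested_sp = call.call.removesuffix("_nesting")
        other_sp = i2 if nested_sp == i1 else i1
        if nested_sp not in tables or other_sp not in tables:
            raise ValueError(f"expression tables needed for {nested_sp} and {other_sp}")
        t_nested, t_other = tables[nested_sp], tables[other_sp]
        if tuple(t_nested.tissues) != tuple(t_other.tissues):
            raise ValueError("expression tables must share the same ordered tissue list")
        for group in (call.external_orthogroup, call.internal_orthogroup):
            g_nested = group.get(nested_sp)
            g_other = group.get(other_sp)
            if g_nested is None or g_other is None:
                logger.info("orthogroup lacks an ortholog id; skipped")
                continue
            if g_nested not in t_nested or g_other not in t_other:
                logger.info(
                    "missing expression for %s (%s) or %s (%s); pair skipped",
                    g_nested, nested_sp, g_other, other_sp,
                )
                continue
            out.append(
                expression_divergence(
                    tissue_profile(t_nested, g_nested),
                    tissue_profile(t_other, g_other),
                )
            )
    return out


def write_divergence(
    dists: Mapping[str, Iterable[PairDivergence]],
    path: str | Path,
    header_lines: list[str] | None = None,
) -> None:
    rows = [
        {"universe": universe, "gene_a": d.gene_a, "gene_b": d.gene_b, "distance": d.distance}
        for universe, lst in dists.items()
        for d in lst
    ]
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        pd.DataFrame(rows, columns=["universe", "gene_a", "gene_b", "distance"]).to_csv(
            fh, sep="\t", index=False, float_format="%.6g"
        )
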