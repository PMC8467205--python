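"""Synthetic inputs with planted ground truth.

Three generators emulate the statistical structure of the pipeline's real
inputs:

* :func:`simulate_annotation` — multi-exon external genes with heavy-tailed
  (log-normal) intron lengths, internal genes planted wholly inside host
  introns with a configurable opposite-strand probability, and unnested
  genes placed collision-free in intergenic space.
* :func:`simulate_orthologs` — orthogroups for the 7-species vertebrate
  panel with nesting/unnesting events planted on chosen branches, plus
  independent per-gene/per-species loss of ortholog links (BioMart-style
  dropout).
* :func:`simulate_expression` — TPM profiles over the seven-tissue panel:
  a configurable fraction of tissue-specific genes (one dominant tissue
  holding >= 95% of relative expression) against broadly expressed genes
  with symmetric-Dirichlet relative profiles, scaled by log-normal per-gene
  totals.

All generators are deterministic under the config seed, and every emitted
file round-trips through the corresponding reader.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotationSet, GeneModel, GenomicInterval
from .expression import TISSUES, ExpressionTable
from .nesting import NestedPair, NestingCatalog
from .phylo_events import DEFAULT_SPECIES, OrthologMap

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_annotation",
    "simulate_orthologs",
    "simulate_expression",
    "write_ground_truth",
    "read_ground_truth",
]

EVENT_PLAN_CLASSES = (
    "pre_divergence",
    "human_nesting",
    "mouse_nesting",
    "human_unnesting",
    "mouse_unnesting",
)


@dataclass
class SimulationConfig:
    """Knobs for all three generators; defaults are the study conditions the
    pipeline is meant to analyze (see docs/methods.md for rationale)."""

    seed: int = 0
    n_external: int = 60
    n_internal: int = 60
    n_unnested: int = 150
    n_chromosomes: int = 5
    intron_length_law: tuple = ("lognormal", {"mean": 8.7, "sigma": 0.8})
    nesting_rate: float = 1.0
    opposite_strand_fraction: float = 0.75
    event_plan: Optional[dict] = None
    ortholog_dropout: float = 0.0
    n_background_orthogroups: int = 25
    specificity_fraction: float = 0.3
    dirichlet_concentration: float = 3.0
    tpm_scale: tuple = ("lognormal", {"mean": 3.0, "sigma": 1.2})

    def __post_init__(self) -> None:
        for name in ("nesting_rate", "opposite_strand_fraction", "ortholog_dropout",
                     "specificity_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("n_external", "n_internal", "n_unnested", "n_chromosomes",
                     "n_background_orthogroups"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.event_plan:
            bad = set(self.event_plan) - set(EVENT_PLAN_CLASSES)
            if bad:
                raise ValueError(f"unknown event classes in plan: {sorted(bad)}")


@dataclass
class GroundTruth:
    """The planted configuration the detectors are expected to recover."""

    planted_pairs: list[tuple[str, str, str]] = field(default_factory=list)
    planted_events: list[tuple[str, str, str]] = field(default_factory=list)
    planted_profiles: dict[str, str] = field(default_factory=dict)

    def planted_pair_set(self) -> set[tuple[str, str]]:
        return {(e, i) for e, i, _ in self.planted_pairs}


def _draw_lengths(rng: np.random.Generator, law: tuple, size: int,
                  minimum: int) -> np.ndarray:
    family, params = law
    if family == "lognormal":
        x = rng.lognormal(params["mean"], params["sigma"], size)
    elif family == "uniform":
        x = rng.uniform(params["low"], params["high"], size)
    elif family == "constant":
        x = np.full(size, float(params["value"]))
    else:
        raise ValueError(f"unknown distribution family {family!r}")
    return np.maximum(x.astype(np.int64), minimum)


def simulate_annotation(config: SimulationConfig) -> tuple[AnnotationSet, GroundTruth]:
    """Generate a collision-free annotation with planted nested pairs.

    External genes carry 3-7 exons with introns drawn from
    ``intron_length_law``; a ``nesting_rate`` fraction of internal genes is
    planted as single-exon genes inside randomly chosen free host introns
    (one internal per intron, so the planted pairs are the complete nested
    set); remaining internal genes and all unnested genes go to intergenic
    space with generous gaps, so no unplanned overlaps exist.
    """
    rng = np.random.default_rng([0, config.seed])
    truth = GroundTruth()
    annotation = AnnotationSet(species="sim")

    chrom_names = [f"chr{i + 1}" for i in range(max(1, config.n_chromosomes))]
    cursors = {c: 10_000 for c in chrom_names}

    def place_gene(gene_id: str, exon_lens: Sequence[int], intron_lens: Sequence[int],
                   strand: str) -> GeneModel:
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        start = cursors[chrom]
        exons = []
        pos = start
        for k, el in enumerate(exon_lens):
            exons.append(GenomicInterval(chrom, pos, pos + int(el), strand))
            pos += int(el)
            if k < len(intron_lens):
                pos += int(intron_lens[k])
        cursors[chrom] = pos + int(rng.integers(5_000, 20_000))
        model = GeneModel.from_exons(gene_id, "protein_coding", exons)
        annotation.add(model)
        return model

    # external (host) genes
    externals: list[GeneModel] = []
    for i in range(config.n_external):
        n_ex = int(rng.integers(3, 8))
        exon_lens = _draw_lengths(rng, ("lognormal", {"mean": 5.2, "sigma": 0.5}),
                                  n_ex, 50)
        intron_lens = _draw_lengths(rng, config.intron_length_law, n_ex - 1, 2_000)
        strand = "+" if rng.random() < 0.5 else "-"
        externals.append(place_gene(f"EXT{i:04d}", exon_lens, intron_lens, strand))

    # internal genes: a nesting_rate fraction goes into free host introns
    n_nested = int(round(config.nesting_rate * config.n_internal))
    free_slots = [
        (g, k) for g in externals for k in range(len(g.introns))
    ]
    if n_nested > len(free_slots):
        raise ValueError(
            f"cannot place {n_nested} internal genes in {len(free_slots)} host "
            "introns without overlap; increase n_external or intron lengths"
        )
    slot_idx = rng.choice(len(free_slots), size=n_nested, replace=False)
    for i in range(config.n_internal):
        gene_id = f"INT{i:04d}"
        if i < n_nested:
            host, k = free_slots[int(slot_idx[i])]
            intron = host.introns[k]
            max_len = len(intron) - 2
            length = int(min(_draw_lengths(
                rng, ("lognormal", {"mean": 6.5, "sigma": 0.5}), 1, 200)[0], max_len))
            offset = int(rng.integers(intron.start + 1, intron.end - length))
            opposite = rng.random() < config.opposite_strand_fraction
            strand = ("-" if host.strand == "+" else "+") if opposite else host.strand
            annotation.add(
                GeneModel.from_exons(
                    gene_id, "protein_coding",
                    [GenomicInterval(intron.chrom, offset, offset + length, strand)],
                )
            )
            truth.planted_pairs.append(
                (host.gene_id, gene_id, "opposite" if opposite else "same")
            )
        else:
            strand = "+" if rng.random() < 0.5 else "-"
            place_gene(gene_id, _draw_lengths(
                rng, ("lognormal", {"mean": 6.5, "sigma": 0.5}), 1, 200), [], strand)

    # unnested background genes
    for i in range(config.n_unnested):
        n_ex = int(rng.integers(1, 4))
        exon_lens = _draw_lengths(rng, ("lognormal", {"mean": 5.2, "sigma": 0.5}),
                                  n_ex, 50)
        intron_lens = _draw_lengths(rng, ("lognormal", {"mean": 6.5, "sigma": 0.5}),
                                    n_ex - 1, 200)
        strand = "+" if rng.random() < 0.5 else "-"
        place_gene(f"UNN{i:04d}", exon_lens, intron_lens, strand)

    return annotation, truth


def _nested_in(event_class: str, rng: np.random.Generator,
               outgroups: Sequence[str]) -> set[str]:
    if event_class == "pre_divergence":
        return {"human", "mouse"} | {og for og in outgroups if rng.random() < 0.5}
    if event_class == "human_nesting":
        return {"human"}
    if event_class == "mouse_nesting":
        return {"mouse"}
    if event_class == "human_unnesting":
        return {"mouse"} | set(outgroups)
    if event_class == "mouse_unnesting":
        return {"human"} | set(outgroups)
    raise ValueError(f"unknown event class {event_class!r}")


def simulate_orthologs(
    config: SimulationConfig, truth: Optional[GroundTruth] = None
) -> tuple[list[OrthologMap], dict[str, NestingCatalog]]:
    """Plant nesting/unnesting events on the 7-species topology.

    Each planted event is one orthogroup of an (external, internal) gene
    pair; per-species gene ids are species-prefixed copies of a shared root
    id.  Every gene exists in every species' catalog; ``ortholog_dropout``
    removes individual human-anchored ortholog *links*, which is how real
    1:1 tables lose genes.  Returns the human-anchored ortholog maps and a
    nesting catalog per species.
    """
    rng = np.random.default_rng([1, config.seed])
    if truth is None:
        truth = GroundTruth()
    outgroups = [sp for sp in DEFAULT_SPECIES if sp not in ("human", "mouse")]
    plan = config.event_plan or {}

    groups: list[tuple[str, str, set[str], str]] = []  # ext_root, int_root, nested_in, class
    counter = 0
    for cls in EVENT_PLAN_CLASSES:
        for _ in range(int(plan.get(cls, 0))):
            ext_root, int_root = f"EVX{counter:04d}", f"EVI{counter:04d}"
            groups.append((ext_root, int_root, _nested_in(cls, rng, outgroups), cls))
            truth.planted_events.append((ext_root, int_root, cls))
            counter += 1
    for b in range(config.n_background_orthogroups):
        groups.append((f"BGX{b:04d}", f"BGI{b:04d}", set(), "background"))

    catalogs: dict[str, NestingCatalog] = {}
    for sp in DEFAULT_SPECIES:
        cat = NestingCatalog(species=sp)
        for idx, (ext_root, int_root, nested_in, _) in enumerate(groups):
            ext_id, int_id = f"{sp}_{ext_root}", f"{sp}_{int_root}"
            chrom = f"chr{1 + idx % max(1, config.n_chromosomes)}"
            if sp in nested_in:
                cat.pairs.append(
                    NestedPair(
                        external_id=ext_id,
                        internal_id=int_id,
                        host_intron=None,
                        orientation="opposite"
                        if rng.random() < config.opposite_strand_fraction
                        else "same",
                        simple=True,
                    )
                )
            else:
                for gid in (ext_id, int_id):
                    cat.unnested_ids.add(gid)
                    cat.unnested_chrom[gid] = chrom
        catalogs[sp] = cat

    maps: list[OrthologMap] = []
    for sp in DEFAULT_SPECIES:
        if sp == "human":
            continue
        pairs = []
        for ext_root, int_root, _, _ in groups:
            for root in (ext_root, int_root):
                if rng.random() >= config.ortholog_dropout:
                    pairs.append((f"human_{root}", f"{sp}_{root}"))
        maps.append(OrthologMap("human", sp, pairs))
    return maps, catalogs


def simulate_expression(
    config: SimulationConfig,
    gene_ids: Sequence[str],
    truth: Optional[GroundTruth] = None,
    disjoint_pairs: Optional[Iterable[tuple[str, str]]] = None,
) -> ExpressionTable:
    """TPM profiles with a planted mixture of specific and broad genes.

    A ``specificity_fraction`` of genes receives a dominant-tissue profile
    (>= 95% of relative expression in one random tissue, guaranteeing
    tau > 0.9); the rest receive symmetric-Dirichlet relative profiles with
    concentration ``dirichlet_concentration`` (infinity gives the exactly
    uniform profile, tau = 0).  ``disjoint_pairs`` forces both members of
    each listed pair to be tissue specific with *different* primary tissues
    — the transcriptional-interference scenario; by default all profiles
    are independent, the no-interference null.
    """
    rng = np.random.default_rng([2, config.seed])
    gene_ids = list(gene_ids)
    n = len(gene_ids)
    n_t = len(TISSUES)

    specific = rng.random(n) < config.specificity_fraction
    forced_primary: dict[str, int] = {}
    if disjoint_pairs:
        index = {g: i for i, g in enumerate(gene_ids)}
        for a, b in disjoint_pairs:
            ta = int(rng.integers(n_t))
            tb = int((ta + 1 + rng.integers(n_t - 1)) % n_t)
            for g, t in ((a, ta), (b, tb)):
                if g not in index:
                    raise KeyError(f"disjoint pair gene {g!r} not in gene_ids")
                specific[index[g]] = True
                forced_primary[g] = t

    rel = np.empty((n, n_t))
    for i, g in enumerate(gene_ids):
        if specific[i]:
            t = forced_primary.get(g, int(rng.integers(n_t)))
            dom = rng.uniform(0.95, 0.99)
            rest = rng.dirichlet(np.ones(n_t - 1)) * (1.0 - dom)
            rel[i] = np.insert(rest, t, dom)
            label = "specific"
        else:
            if np.isinf(config.dirichlet_concentration):
                rel[i] = np.full(n_t, 1.0 / n_t)
            else:
                rel[i] = rng.dirichlet(
                    np.full(n_t, config.dirichlet_concentration)
                )
            label = "broad"
        if truth is not None:
            truth.planted_profiles[g] = label

    totals = _draw_lengths(rng, config.tpm_scale, n, 1).astype(float)
    values = pd.DataFrame(rel * totals[:, None], index=gene_ids, columns=list(TISSUES))
    values.index.name = "gene_id"
    return ExpressionTable(species="sim", values=values)


def write_ground_truth(truth: GroundTruth, path: str | Path,
                       header_lines: Optional[list[str]] = None) -> None:
    """Single-TSV dump: one row per planted fact, tagged by kind."""
    rows = []
    for ext, internal, orientation in truth.planted_pairs:
        rows.append({"kind": "pair", "field1": ext, "field2": internal, "field3": orientation})
    for ext, internal, cls in truth.planted_events:
        rows.append({"kind": "event", "field1": ext, "field2": internal, "field3": cls})
    for gene, label in sorted(truth.planted_profiles.items()):
        rows.append({"kind": "profile", "field1": gene, "field2": label, "field3": "."})
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        pd.DataFrame(rows, columns=["kind", "field1", "field2", "field3"]).to_csv(
            fh, sep="\t", index=False
        )


def read_ground_truth(path: str | Path) -> GroundTruth:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    truth = GroundTruth()
    for r in df.itertuples():
        if r.kind == "pair":
            truth.planted_pairs.append((r.field1, r.field2, r.field3))
        elif r.kind == "event":
            truth.planted_events.append((r.field1, r.field2, r.field3))
        elif r.kind == "profile":
            truth.planted_profiles[r.field1] = r.field2
    return truth
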