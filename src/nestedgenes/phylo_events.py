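"""Inference of nesting and unnesting events on a fixed vertebrate topology.

The ingroup is {human, mouse}; cow, opossum, platypus, chicken and zebrafish
serve as outgroups.  Given per-species nested-pair catalogs and pairwise 1:1
ortholog maps anchored to a single reference species, each candidate
orthogroup of an (external, internal) pair is classified by strict parsimony:

* ``pre_divergence`` — nested in both ingroup species.
* ``<ingroup>_nesting`` — nested in exactly one ingroup species, not nested
  in the other (both orthologs present there), not nested in any outgroup
  where both orthologs exist, and at least one such outgroup exists.  The
  outgroup requirement guards against calling an event when the genes are
  simply absent ancestrally.
* ``<ingroup>_unnesting`` — not nested in one ingroup species (both
  orthologs present), but nested in the other ingroup species and in at
  least one outgroup: the nested state is ancestral and was lost.
* ``unresolved`` — anything else, including conflicting outgroup signals
  and missing orthologs.

Repeated nesting/unnesting cycles are not modeled.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from .nesting import NestingCatalog

__all__ = [
    "DEFAULT_SPECIES",
    "OrthologMap",
    "SpeciesTopology",
    "NestingEventCall",
    "call_events",
    "summarize_events",
    "write_events",
]

DEFAULT_SPECIES = (
    "human",
    "mouse",
    "cow",
    "opossum",
    "platypus",
    "chicken",
    "zebrafish",
)

EVENT_CLASSES = (
    "pre_divergence",
    "human_nesting",
    "mouse_nesting",
    "human_unnesting",
    "mouse_unnesting",
    "unresolved",
)


@dataclass(frozen=True)
class SpeciesTopology:
    """The fixed species tree: an ingroup pair and ordered outgroups."""

    ingroup: tuple[str, str] = ("human", "mouse")
    outgroups: tuple[str, ...] = ("cow", "opossum", "platypus", "chicken", "zebrafish")

    def __post_init__(self) -> None:
        if set(self.ingroup) & set(self.outgroups):
            raise ValueError("ingroup and outgroups must be disjoint")

    @property
    def species(self) -> tuple[str, ...]:
        return self.ingroup + self.outgroups


class OrthologMap:
    """A 1:1 ortholog table between two species.

    Each gene id may appear at most once on either side; a violation raises
    ``ValueError`` naming the offending gene.
    """

    def __init__(self, species_a: str, species_b: str, pairs: Iterable[tuple[str, str]]):
        self.species_pair = (species_a, species_b)
        self.a_to_b: dict[str, str] = {}
        self.b_to_a: dict[str, str] = {}
        for a, b in pairs:
            if a in self.a_to_b:
                raise ValueError(
                    f"ortholog map {species_a}-{species_b} is not 1:1: "
                    f"gene {a!r} appears twice on the {species_a} side"
                )
            if b in self.b_to_a:
                raise ValueError(
                    f"ortholog map {species_a}-{species_b} is not 1:1: "
                    f"gene {b!r} appears twice on the {species_b} side"
                )
            self.a_to_b[a] = b
            self.b_to_a[b] = a

    def __len__(self) -> int:
        return len(self.a_to_b)

    def mapping_from(self, species: str) -> dict[str, str]:
        if species == self.species_pair[0]:
            return self.a_to_b
        if species == self.species_pair[1]:
            return self.b_to_a
        raise KeyError(f"{species!r} not in ortholog map {self.species_pair}")

    @classmethod
    def from_tsv(cls, path: str | Path, species_a: str, species_b: str) -> "OrthologMap":
        """Two-column TSV with a header row naming the species columns."""
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        if df.shape[1] < 2:
            raise ValueError(f"{path}: ortholog TSV needs two columns")
        return cls(species_a, species_b, zip(df.iloc[:, 0], df.iloc[:, 1]))

    def to_tsv(self, path: str | Path, header_lines: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            fh.write(f"{self.species_pair[0]}\t{self.species_pair[1]}\n")
            for a, b in sorted(self.a_to_b.items()):
                fh.write(f"{a}\t{b}\n")


@dataclass(frozen=True)
class NestingEventCall:
    """One orthogroup-level call with its per-species evidence pattern."""

    external_orthogroup: Mapping[str, str]
    internal_orthogroup: Mapping[str, str]
    call: str
    evidence: str


def _infer_reference(orthologs: Iterable[OrthologMap]) -> str:
    """The pivot species: the one species present in every supplied map."""
    maps = list(orthologs)
    if not maps:
        raise ValueError("no ortholog maps supplied")
    common = set(maps[0].species_pair)
    for m in maps[1:]:
        common &= set(m.species_pair)
    if len(common) != 1:
        raise ValueError(
            "ortholog maps must share exactly one pivot species; "
            f"found common species {sorted(common)}"
        )
    return common.pop()


def call_events(
    catalogs: Mapping[str, NestingCatalog],
    orthologs: Iterable[OrthologMap],
    topology: SpeciesTopology = SpeciesTopology(),
) -> list[NestingEventCall]:
    """Classify every candidate nested-pair orthogroup.

    Candidates are pairs nested in at least one ingroup species.  Orthogroups
    are assembled by pivoting through the reference species shared by all
    ortholog maps (which must be one of the two ingroup species); a
    non-reference ingroup pair whose genes lack reference orthologs is
    emitted as ``unresolved``.
    """
    maps = list(orthologs)
    ref = _infer_reference(maps)
    if ref not in topology.ingroup:
        raise ValueError(f"pivot species {ref!r} must be an ingroup species")
    other = topology.ingroup[0] if topology.ingroup[1] == ref else topology.ingroup[1]
    to_sp = {
        (m.species_pair[0] if m.species_pair[1] == ref else m.species_pair[1]):
            m.mapping_from(ref)
        for m in maps
    }
    needed = set(topology.species) - {ref}
    missing = needed - set(to_sp)
    if missing:
        raise ValueError(f"no ortholog map anchors species {sorted(missing)} to {ref!r}")

    pair_sets = {sp: cat.pair_set() for sp, cat in catalogs.items()}
    for sp in topology.ingroup:
        if sp not in pair_sets:
            raise ValueError(f"missing nesting catalog for ingroup species {sp!r}")

    calls: list[NestingEventCall] = []
    seen: set[tuple[str, str]] = set()

    # candidates anchored at the reference species
    candidates = sorted(pair_sets[ref])
    other_from_ref = to_sp[other]
    ref_from_other = {v: k for k, v in other_from_ref.items()}
    for ext_o, int_o in sorted(pair_sets[other]):
        ext_r = ref_from_other.get(ext_o)
        int_r = ref_from_other.get(int_o)
        if ext_r is None or int_r is None:
            # nested pair in the non-pivot ingroup with no reference anchor
            ev = ",".join(
                f"{sp}:{'nested' if sp == other else 'absent'}"
                for sp in topology.species
            )
            calls.append(
                NestingEventCall(
                    external_orthogroup={other: ext_o},
                    internal_orthogroup={other: int_o},
                    call="unresolved",
                    evidence=ev,
                )
            )
        elif (ext_r, int_r) not in pair_sets[ref]:
            candidates.append((ext_r, int_r))

    for ext_r, int_r in sorted(set(candidates)):
        if (ext_r, int_r) in seen:
            continue
        seen.add((ext_r, int_r))
        ext_group: dict[str, str] = {ref: ext_r}
        int_group: dict[str, str] = {ref: int_r}
        status: dict[str, str] = {}
        for sp in topology.species:
            if sp == ref:
                ext_sp, int_sp = ext_r, int_r
            else:
                ext_sp = to_sp[sp].get(ext_r)
                int_sp = to_sp[sp].get(int_r)
            if ext_sp is None or int_sp is None:
                status[sp] = "absent"
                continue
            ext_group[sp] = ext_sp
            int_group[sp] = int_sp
            if (ext_sp, int_sp) in pair_sets.get(sp, set()):
                status[sp] = "nested"
            else:
                status[sp] = "unnested"
        calls.append(
            NestingEventCall(
                external_orthogroup=ext_group,
                internal_orthogroup=int_group,
                call=_classify(status, topology),
                evidence=",".join(f"{sp}:{status[sp]}" for sp in topology.species),
            )
        )
    return calls


def _classify(status: Mapping[str, str], topology: SpeciesTopology) -> str:
    i1, i2 = topology.ingroup
    out_present = [sp for sp in topology.outgroups if status[sp] != "absent"]
    out_nested = [sp for sp in out_present if status[sp] == "nested"]

    if status[i1] == "nested" and status[i2] == "nested":
        return "pre_divergence"
    for nested_sp, other_sp in ((i1, i2), (i2, i1)):
        if (
            status[nested_sp] == "nested"
            and status[other_sp] == "unnested"
            and out_present
            and not out_nested
        ):
            return f"{nested_sp}_nesting"
    for lost_sp, kept_sp in ((i1, i2), (i2, i1)):
        if (
            status[lost_sp] == "unnested"
            and status[kept_sp] == "nested"
            and out_nested
        ):
            return f"{lost_sp}_unnesting"
    return "unresolved"


def summarize_events(calls: Iterable[NestingEventCall]) -> dict[str, int]:
    """Integer counts per call class; classes with no calls report zero."""
    counts = Counter(c.call for c in calls)
    return {cls: counts.get(cls, 0) for cls in EVENT_CLASSES}


def write_events(
    calls: Iterable[NestingEventCall],
    path: str | Path,
    topology: SpeciesTopology = SpeciesTopology(),
    header_lines: list[str] | None = None,
) -> None:
    """Event-call TSV with ingroup gene ids and the evidence pattern."""
    i1, i2 = topology.ingroup
    rows = [
        {
            "call": c.call,
            f"{i1}_external": c.external_orthogroup.get(i1, "."),
            f"{i1}_internal": c.internal_orthogroup.get(i1, "."),
            f"{i2}_external": c.external_orthogroup.get(i2, "."),
            f"{i2}_internal": c.internal_orthogroup.get(i2, "."),
            "evidence": c.evidence,
        }
        for c in calls
    ]
    cols = ["call", f"{i1}_external", f"{i1}_internal", f"{i2}_external", f"{i2}_internal", "evidence"]
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        pd.DataFrame(rows, columns=cols).to_csv(fh, sep="\t", index=False)
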