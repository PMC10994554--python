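"""Domain model for step-centric pathway representation.

A pathway is a series of steps (molecular activities), each enabled by a
molecular entity: a single protein, a complex (AND logic over subunits), or a
set of interchangeable proteins/complexes (OR logic over members).  For
enrichment purposes every enabler is recursively simplified into
*step-enabling entities*: either a solo gene or a set of genes, any one of
which suffices for the step.  The resulting entity list has length equal to
the minimum number of genes required to enable every step of the pathway,
which is the ``n`` of the step-centric hypergeometric test.

Simplification rules
--------------------
* protein                       -> one solo entity
* complex                       -> concatenation of its flattened subunits
* set of proteins (no complex
  anywhere below)               -> one set entity over the union of leaf
                                   genes; nested sets dissolve by union; a
                                   singleton collapses to a solo entity
* set containing >=1 complex    -> the intersection of the children's leaf
                                   genes becomes solo entities (the shared
                                   subunits), the remaining leaf genes become
                                   one set entity; an empty intersection
                                   leaves only the remainder set

The set-of-complexes rule mirrors how a group of near-identical complexes is
usually annotated: e.g. prolyl 4-hydroxylase variants sharing the beta
subunit P4HB1 but differing in the alpha subunit reduce to
``P4HB1 AND (P4HA1 OR P4HA2 OR P4HA3)``.  The rule is knowingly lossy for
heterogeneous groups of complexes (multiple distinct specific subunits).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "PathwayStructureError",
    "normalize_gene_id",
    "EntityNode",
    "StepEntity",
    "step_entity",
    "Pathway",
    "Background",
    "PathwayDB",
    "flatten_entity",
    "entity_weight",
    "build_pathway",
    "build_background",
    "size_reduction_stats",
    "SizeReduction",
    "PROTEIN",
    "COMPLEX",
    "SET",
    "SOLO",
]

PROTEIN = "protein"
COMPLEX = "complex"
SET = "set"
SOLO = "solo"


class PathwayStructureError(ValueError):
    """Raised for malformed pathway structures (empty sets, unknown kinds...)."""


def normalize_gene_id(value: str) -> str:
    """Normalize a gene/protein identifier: strip whitespace, uppercase.

    Normalization is idempotent; an empty identifier is an error.
    """
    if not isinstance(value, str):
        raise PathwayStructureError(f"gene identifier must be a string, got {type(value).__name__}")
    norm = value.strip().upper()
    if not norm:
        raise PathwayStructureError("empty gene identifier")
    return norm


@dataclass(frozen=True)
class EntityNode:
    """Raw (possibly nested) pathway participant as found in the database.

    ``protein`` nodes carry a gene and no children; ``complex`` and ``set``
    nodes carry >=1 children and no gene.
    """

    kind: str
    gene: str | None = None
    children: tuple["EntityNode", ...] = ()

    @staticmethod
    def protein(gene: str) -> "EntityNode":
        return EntityNode(PROTEIN, normalize_gene_id(gene))

    @staticmethod
    def complex(children: Iterable["EntityNode"]) -> "EntityNode":
        return EntityNode(COMPLEX, None, tuple(children))

    @staticmethod
    def set_of(children: Iterable["EntityNode"]) -> "EntityNode":
        return EntityNode(SET, None, tuple(children))

    def validate(self) -> None:
        if self.kind == PROTEIN:
            if self.children:
                raise PathwayStructureError(f"protein node {self.gene!r} must not have children")
            if not self.gene:
                raise PathwayStructureError("protein node without a gene identifier")
        elif self.kind in (COMPLEX, SET):
            if self.gene is not None:
                raise PathwayStructureError(f"{self.kind} node must not carry a gene ({self.gene!r})")
            if not self.children:
                raise PathwayStructureError(f"{self.kind} node with no children")
            for child in self.children:
                child.validate()
        else:
            raise PathwayStructureError(f"unknown node kind {self.kind!r}")

    def leaf_genes(self) -> frozenset[str]:
        if self.kind == PROTEIN:
            return frozenset((self.gene,))
        out: set[str] = set()
        for child in self.children:
            out |= child.leaf_genes()
        return frozenset(out)


@dataclass(frozen=True)
class StepEntity:
    """A flattened step-enabling unit: a solo gene or a set of genes.

    ``canonical_id`` is a deterministic, order-insensitive signature used for
    deduplication within a pathway and across the background.
    """

    kind: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise PathwayStructureError("step entity with no members")
        if (self.kind == SOLO) != (len(self.members) == 1):
            raise PathwayStructureError(
                f"kind {self.kind!r} inconsistent with {len(self.members)} members"
            )
        if self.kind not in (SOLO, SET):
            raise PathwayStructureError(f"unknown entity kind {self.kind!r}")

    @property
    def canonical_id(self) -> str:
        return f"{self.kind}:" + "|".join(sorted(self.members))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"StepEntity({self.canonical_id})"


def step_entity(members: Iterable[str]) -> StepEntity:
    """Build a solo or set entity from member genes (solo iff one member)."""
    ms = frozenset(normalize_gene_id(g) for g in members)
    return StepEntity(SOLO if len(ms) == 1 else SET, ms)


def entity_weight(entity: StepEntity) -> int:
    """Weight of an entity = number of genes it stands for.

    A set of five genes has weight 5 (five chances for a uniform draw of a
    gene to hit the entity); a solo gene has weight 1.
    """
    return len(entity.members)


def _contains_complex(node: EntityNode) -> bool:
    if node.kind == COMPLEX:
        return True
    return any(_contains_complex(c) for c in node.children)


def flatten_entity(node: EntityNode) -> list[StepEntity]:
    """Recursively simplify a raw participant into step-enabling entities.

    Returns entities sorted by ``canonical_id`` (duplicates possible for a
    complex listing the same subunit twice; deduplication happens in
    :func:`build_pathway`).
    """
    node.validate()
    return sorted(_flatten(node), key=lambda e: e.canonical_id)


def _flatten(node: EntityNode) -> list[StepEntity]:
    if node.kind == PROTEIN:
        return [step_entity((node.gene,))]
    if node.kind == COMPLEX:
        out: list[StepEntity] = []
        for child in node.children:
            out.extend(_flatten(child))
        return out
    # set
    if not any(_contains_complex(c) for c in node.children):
        # pure protein set (possibly nested sets): OR over the union of leaves
        return [step_entity(node.leaf_genes())]
    # set containing at least one complex: shared subunits become solos,
    # everything else one remainder set
    child_leaves = [c.leaf_genes() for c in node.children]
    for c in node.children:
        _flatten(c)  # recurse first: validates + applies nested reductions
    common = frozenset.intersection(*child_leaves)
    union = frozenset.union(*child_leaves)
    remainder = union - common
    out = [step_entity((g,)) for g in sorted(common)]
    if remainder:
        out.append(step_entity(remainder))
    return out


@dataclass(frozen=True)
class Pathway:
    """A named pathway as a deduplicated list of step-enabling entities."""

    id: str
    title: str
    entities: tuple[StepEntity, ...]
    raw_enablers: tuple[EntityNode, ...] | None = None

    @property
    def n(self) -> int:
        """Entity-list size: minimum genes required to enable every step."""
        return len(self.entities)

    @property
    def gene_list(self) -> frozenset[str]:
        """Expanded gene list (the traditional enrichment list)."""
        out: set[str] = set()
        for e in self.entities:
            out |= e.members
        return frozenset(out)

    @property
    def entity_ids(self) -> frozenset[str]:
        return frozenset(e.canonical_id for e in self.entities)


def build_pathway(
    pathway_id: str,
    title: str,
    raw_enablers: Sequence[EntityNode],
    keep_raw: bool = True,
) -> Pathway:
    """Flatten every enabler and deduplicate entities by canonical id."""
    if not raw_enablers:
        raise PathwayStructureError(f"pathway {pathway_id!r} has no enablers")
    seen: dict[str, StepEntity] = {}
    for node in raw_enablers:
        for ent in flatten_entity(node):
            seen.setdefault(ent.canonical_id, ent)
    entities = tuple(seen[cid] for cid in sorted(seen))
    return Pathway(
        id=pathway_id,
        title=title,
        entities=entities,
        raw_enablers=tuple(raw_enablers) if keep_raw else None,
    )


@dataclass(frozen=True)
class Background:
    """Sampling universe: deduplicated entities and annotated genes.

    A set entity and a solo entity sharing a gene remain distinct background
    entities (entities are identified by kind + members).
    """

    entities: frozenset[StepEntity]
    genes: frozenset[str]

    @property
    def M_entities(self) -> int:
        return len(self.entities)

    @property
    def M_genes(self) -> int:
        return len(self.genes)

    def entity_index(self) -> dict[str, StepEntity]:
        return {e.canonical_id: e for e in self.entities}


def build_background(pathways: Sequence[Pathway]) -> Background:
    if not pathways:
        raise PathwayStructureError("cannot build a background from zero pathways")
    entities: set[StepEntity] = set()
    genes: set[str] = set()
    for pw in pathways:
        entities.update(pw.entities)
        genes.update(pw.gene_list)
    return Background(frozenset(entities), frozenset(genes))


@dataclass
class PathwayDB:
    """A pathway collection plus its derived background."""

    pathways: list[Pathway]
    background: Background

    @staticmethod
    def from_pathways(pathways: Sequence[Pathway]) -> "PathwayDB":
        return PathwayDB(list(pathways), build_background(pathways))

    def get(self, pathway_id: str) -> Pathway:
        for pw in self.pathways:
            if pw.id == pathway_id:
                return pw
        raise KeyError(pathway_id)

    def __len__(self) -> int:
        return len(self.pathways)


@dataclass
class SizeReduction:
    """Per-pathway gene-list-vs-entity-list size reductions with summary."""

    table: pd.DataFrame
    summary: pd.DataFrame


def size_reduction_stats(db: PathwayDB) -> SizeReduction:
    """Absolute (n_gene - n_entity) and relative reductions per pathway.

    The summary reports the 50th/75th/95th percentiles and the maximum of
    both columns (relative reductions as fractions, not percent).
    """
    if not db.pathways:
        raise PathwayStructureError("empty pathway database")
    rows = []
    for pw in db.pathways:
        n_gene = len(pw.gene_list)
        n_entity = pw.n
        absolute = n_gene - n_entity
        rows.append(
            {
                "pathway_id": pw.id,
                "n_gene": n_gene,
                "n_entity": n_entity,
                "absolute_reduction": absolute,
                "relative_reduction": absolute / n_gene if n_gene else 0.0,
            }
        )
    table = pd.DataFrame(rows)
    cols = ["absolute_reduction", "relative_reduction"]
    summary = table[cols].quantile([0.50, 0.75, 0.95])
    summary.index = ["50%", "75%", "95%"]
    summary.loc["max"] = table[cols].max()
    return SizeReduction(table=table, summary=summary)
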