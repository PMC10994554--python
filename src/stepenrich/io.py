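"""File formats: native pathway JSON, GMT export, gene lists, result TSVs.

The native pathway-definition format mirrors the raw participant tree so it
round-trips losslessly::

    {
      "format": "stepenrich-pathways",
      "version": 1,
      "pathways": [
        {"id": "...", "title": "...",
         "enablers": [
            {"kind": "protein", "gene": "P4HB1"},
            {"kind": "set", "children": [{"kind": "protein", "gene": "P4HA1"}, ...]},
            {"kind": "complex", "children": [...]}
         ]}
      ]
    }
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import (
    COMPLEX,
    PROTEIN,
    SET,
    SOLO,
    EntityNode,
    Pathway,
    PathwayDB,
    PathwayStructureError,
    StepEntity,
    build_pathway,
)

__all__ = [
    "node_to_dict",
    "node_from_dict",
    "entity_to_node",
    "save_pathway_db",
    "load_pathway_db",
    "read_gene_list",
    "export_gmt",
    "write_results_tsv",
    "read_results_tsv",
]

FORMAT_NAME = "stepenrich-pathways"
FORMAT_VERSION = 1


def node_to_dict(node: EntityNode) -> dict:
    if node.kind == PROTEIN:
        return {"kind": PROTEIN, "gene": node.gene}
    return {"kind": node.kind, "children": [node_to_dict(c) for c in node.children]}


def node_from_dict(data: Mapping) -> EntityNode:
    kind = data.get("kind")
    if kind == PROTEIN:
        return EntityNode.protein(data["gene"])
    if kind in (COMPLEX, SET):
        children = tuple(node_from_dict(c) for c in data.get("children", ()))
        node = EntityNode(kind, None, children)
        node.validate()
        return node
    raise PathwayStructureError(f"unknown node kind in pathway file: {kind!r}")


def entity_to_node(entity: StepEntity) -> EntityNode:
    """Express a flattened entity back as a raw node (solo->protein, set->set)."""
    if entity.kind == SOLO:
        (gene,) = entity.members
        return EntityNode.protein(gene)
    return EntityNode.set_of(EntityNode.protein(g) for g in sorted(entity.members))


def _pathway_enabler_nodes(pw: Pathway) -> tuple[EntityNode, ...]:
    if pw.raw_enablers is not None:
        return pw.raw_enablers
    return tuple(entity_to_node(e) for e in pw.entities)


def save_pathway_db(db: PathwayDB, path: str | Path) -> None:
    """Serialize to native JSON; byte-identical for identical inputs."""
    doc = {
        "format": FORMAT_NAME,
        "version": FORMAT_VERSION,
        "pathways": [
            {
                "id": pw.id,
                "title": pw.title,
                "enablers": [node_to_dict(n) for n in _pathway_enabler_nodes(pw)],
            }
            for pw in sorted(db.pathways, key=lambda p: p.id)
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n", encoding="utf-8")


def load_pathway_db(path: str | Path) -> PathwayDB:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if doc.get("format") != FORMAT_NAME:
        raise PathwayStructureError(f"{path}: not a {FORMAT_NAME} file")
    pathways = [
        build_pathway(
            entry["id"],
            entry.get("title", entry["id"]),
            [node_from_dict(n) for n in entry["enablers"]],
        )
        for entry in doc["pathways"]
    ]
    return PathwayDB.from_pathways(pathways)


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain-text gene list: one identifier per line, '#' comments.

    Identifiers are normalized; duplicates dropped, input order preserved.
    """
    from .model import normalize_gene_id

    seen: dict[str, None] = {}
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        seen.setdefault(normalize_gene_id(line), None)
    return list(seen)


def export_gmt(db: PathwayDB, path: str | Path) -> None:
    """Write expanded gene lists as GMT (id <tab> title <tab> genes...)."""
    lines = []
    for pw in sorted(db.pathways, key=lambda p: p.id):
        genes = "\t".join(sorted(pw.gene_list))
        lines.append(f"{pw.id}\t{pw.title}\t{genes}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def _config_hash(params: Mapping) -> str:
    blob = json.dumps({k: str(v) for k, v in sorted(params.items())}, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def write_results_tsv(
    results: Iterable,
    path: str | Path,
    params: Mapping | None = None,
) -> None:
    """Write enrichment results as UTF-8 TSV with a provenance header."""
    from . import __version__

    rows = [
        {
            "pathway_id": r.pathway_id,
            "title": r.title,
            "method": r.method,
            "k": r.k,
            "n": r.n,
            "N": r.N,
            "M": r.M,
            "p_raw": r.p_raw,
            "p_adj": r.p_adj,
            "member_hits": r.member_hits,
        }
        for r in results
    ]
    df = pd.DataFrame(
        rows,
        columns=["pathway_id", "title", "method", "k", "n", "N", "M", "p_raw", "p_adj", "member_hits"],
    )
    params = dict(params or {})
    header = [
        f"# stepenrich v{__version__}",
        f"# config_hash={_config_hash(params)}",
    ]
    header.extend(f"# {k}={v}" for k, v in sorted(params.items()))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_results_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
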