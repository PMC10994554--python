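"""Ingestion of GO-CAM causal activity models into pathway records.

A GO-CAM model is an RDF/OWL document whose individuals represent molecular
activities (typed with GO molecular-function classes) linked by causal
relations; each activity may be "enabled by" (RO:0002333) a molecular entity
— a protein or a Reactome-style complex/set class.  Ingestion:

1. parse each Turtle document into a :class:`RawModel`;
2. keep models with >= 3 activities linked by >= 2 causal edges and in
   production state (Reactome-derived models, which are distributed before
   official release, bypass the production check);
3. resolve each enabler reference through the Reacto ontology into an
   :class:`~stepenrich.model.EntityNode` tree with protein leaves, dropping
   ions and other non-protein chemicals;
4. optionally map non-human genes to human orthologs through a local TSV
   table (unmapped genes are dropped and counted);
5. flatten into pathways and build the shared background.

Activity-node detection treats every individual typed with a GO-namespace
class as a step; in full release models this can also pick up biological
process or cellular component context individuals, which slightly relaxes
the step-count filter but does not affect enabler extraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from rdflib import Graph, Namespace, RDF, RDFS, OWL, URIRef

from .model import (
    EntityNode,
    Pathway,
    PathwayDB,
    PathwayStructureError,
    build_pathway,
)

__all__ = [
    "RawModel",
    "GocamParseError",
    "ReactoResolutionError",
    "ConfigurationError",
    "NoPathwaysError",
    "parse_gocam",
    "filter_models",
    "ReactoOntology",
    "load_ortholog_table",
    "map_orthologs",
    "build_pathway_db",
]

logger = logging.getLogger(__name__)

OBO = Namespace("http://purl.obolibrary.org/obo/")
ENABLED_BY = OBO.RO_0002333
IN_TAXON = OBO.RO_0002162
HAS_PART = OBO.BFO_0000051
HAS_MEMBER = OBO.RO_0002351
MODEL_STATE = URIRef("http://geneontology.org/lego/modelstate")
DC_TITLE = URIRef("http://purl.org/dc/elements/1.1/title")
GO_PREFIX = str(OBO) + "GO_"
UNIPROT_PREFIX = "http://identifiers.org/uniprot/"
CHEBI_PREFIX = str(OBO) + "CHEBI_"
TAXON_HUMAN = str(OBO) + "NCBITaxon_9606"

# causal relations linking one activity to another (RO causally-related-to family)
CAUSAL_PREDICATES = frozenset(
    OBO[f"RO_{code}"]
    for code in (
        "0002411",  # causally upstream of
        "0002412",  # immediately causally upstream of
        "0002413",  # provides input for
        "0002418",  # causally upstream of or within
        "0002629",  # directly positively regulates
        "0002630",  # directly negatively regulates
        "0002406",
        "0002407",
        "0002409",
        "0002304",
        "0002305",
        "0002212",  # negatively regulates
        "0002213",  # positively regulates
    )
)


class GocamParseError(ValueError):
    """Unparseable or structurally invalid GO-CAM document."""


class ReactoResolutionError(KeyError):
    """Entity IRI absent from the ontology."""


class ConfigurationError(ValueError):
    """Invalid ingestion configuration (e.g. mouse models without a table)."""


class NoPathwaysError(ValueError):
    """No model survived filtering/resolution."""


@dataclass(frozen=True)
class RawModel:
    model_id: str
    title: str
    state: str
    taxa: frozenset[str]
    mf_nodes: tuple[str, ...]
    causal_edges: tuple[tuple[str, str], ...]
    enabler_map: Mapping[str, str]  # mf node -> entity reference IRI

    @property
    def n_mf(self) -> int:
        return len(self.mf_nodes)

    @property
    def n_causal_edges(self) -> int:
        return len(self.causal_edges)

    @property
    def is_reactome(self) -> bool:
        return any(tag in self.model_id for tag in ("R-HSA-", "R-MMU-", "R-NUL-"))


def parse_gocam(source: str | Path, fmt: str = "turtle") -> RawModel:
    """Parse one GO-CAM document (path, or raw Turtle text)."""
    graph = Graph()
    try:
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists()):
            graph.parse(location=str(source), format=fmt)
        else:
            graph.parse(data=source, format=fmt)
    except Exception as exc:  # rdflib raises assorted parser exceptions
        raise GocamParseError(f"cannot parse GO-CAM document: {exc}") from exc

    ontology_nodes = sorted(str(s) for s in graph.subjects(RDF.type, OWL.Ontology))
    if not ontology_nodes:
        raise GocamParseError("document has no owl:Ontology node (missing model id)")
    model_iri = URIRef(ontology_nodes[0])
    model_id = ontology_nodes[0]
    title = str(next(graph.objects(model_iri, DC_TITLE), model_id))
    state = str(next(graph.objects(model_iri, MODEL_STATE), "unknown"))
    taxa = frozenset(str(t) for t in graph.objects(model_iri, IN_TAXON))

    mf_nodes = sorted(
        {
            str(s)
            for s, _, o in graph.triples((None, RDF.type, None))
            if isinstance(o, URIRef) and str(o).startswith(GO_PREFIX)
        }
    )
    mf_set = set(mf_nodes)
    causal_edges = tuple(
        sorted(
            (str(s), str(o))
            for p in CAUSAL_PREDICATES
            for s, o in graph.subject_objects(p)
            if str(s) in mf_set and str(o) in mf_set
        )
    )
    enabler_map: dict[str, str] = {}
    for s, o in graph.subject_objects(ENABLED_BY):
        if str(s) not in mf_set:
            continue
        # the enabler is an individual; its reference is its non-OWL type IRI
        types = sorted(
            str(t)
            for t in graph.objects(o, RDF.type)
            if isinstance(t, URIRef) and not str(t).startswith(str(OWL))
        )
        enabler_map[str(s)] = types[0] if types else str(o)
    return RawModel(
        model_id=model_id,
        title=title,
        state=state,
        taxa=taxa,
        mf_nodes=tuple(mf_nodes),
        causal_edges=causal_edges,
        enabler_map=enabler_map,
    )


def filter_models(
    models: Iterable[RawModel],
    min_mf: int = 3,
    min_causal_edges: int = 2,
    require_production: bool = True,
) -> list[RawModel]:
    """Keep models with enough steps and causal structure.

    Defaults: at least 3 molecular functions linked by 2 causal edges, in
    production state.  Reactome-derived conversions bypass the state check.
    """
    kept = []
    for m in models:
        if m.n_mf < min_mf or m.n_causal_edges < min_causal_edges:
            continue
        if require_production and not m.is_reactome and m.state != "production":
            continue
        kept.append(m)
    return kept


class ReactoOntology:
    """Class structure for Reactome entities: complexes, sets, proteins.

    Complexes declare their subunits via ``has part`` (BFO:0000051)
    restrictions, sets their members via ``has member`` (RO:0002351); protein
    leaves are identifiers.org/uniprot IRIs, and CHEBI leaves (ions, small
    molecules) are discarded.
    """

    def __init__(self, graph: Graph):
        self.graph = graph

    @classmethod
    def load(cls, path: str | Path, fmt: str | None = None) -> "ReactoOntology":
        graph = Graph()
        fmt = fmt or ("xml" if str(path).endswith((".owl", ".xml", ".rdf")) else "turtle")
        graph.parse(location=str(path), format=fmt)
        return cls(graph)

    def _restriction_fillers(self, class_iri: URIRef, prop: URIRef) -> list[URIRef]:
        fillers = []
        for restriction in self.graph.objects(class_iri, RDFS.subClassOf):
            if (restriction, OWL.onProperty, prop) in self.graph:
                fillers.extend(self.graph.objects(restriction, OWL.someValuesFrom))
        return sorted(set(fillers), key=str)

    def resolve(self, entity_iri: str) -> EntityNode | None:
        """Recursively resolve an entity IRI into an EntityNode tree.

        Returns None for non-protein chemicals and for complexes/sets left
        childless after dropping them; raises for IRIs absent from the
        ontology altogether.
        """
        iri = str(entity_iri)
        if iri.startswith(UNIPROT_PREFIX):
            accession = iri[len(UNIPROT_PREFIX):].split("-")[0]  # strip isoform suffix
            return EntityNode.protein(accession)
        if iri.startswith(CHEBI_PREFIX):
            return None
        ref = URIRef(iri)
        members = self._restriction_fillers(ref, HAS_MEMBER)
        parts = self._restriction_fillers(ref, HAS_PART)
        if not members and not parts:
            if (ref, None, None) in self.graph or (None, None, ref) in self.graph:
                logger.warning("entity class %s has no protein structure; dropped", iri)
                return None
            raise ReactoResolutionError(iri)
        children_iris = members if members else parts
        children = [self.resolve(str(c)) for c in children_iris]
        children = [c for c in children if c is not None]
        if not children:
            return None
        if members:
            return EntityNode.set_of(children)
        return EntityNode.complex(children)


def load_ortholog_table(path: str | Path) -> dict[str, str]:
    """Load a two-column TSV (source gene -> target ortholog), header optional."""
    table: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
            if lineno == 1:
                continue  # tolerate a header row
            raise ConfigurationError(f"{path}:{lineno}: malformed ortholog row {raw!r}")
        src, dst = parts[0].strip().upper(), parts[1].strip().upper()
        if lineno == 1 and (src in ("SOURCE", "GENE", "FROM")):
            continue
        table[src] = dst
    return table


def map_orthologs(genes: Sequence[str], table: Mapping[str, str]) -> tuple[list[str], int]:
    """Substitute orthologs; unmapped genes are dropped with a counted warning."""
    mapped: list[str] = []
    dropped = 0
    for g in genes:
        key = g.strip().upper()
        if key in table:
            mapped.append(table[key])
        else:
            dropped += 1
            logger.warning("no ortholog for %s; dropped", g)
    return mapped, dropped


def _map_node_orthologs(node: EntityNode, table: Mapping[str, str]) -> tuple[EntityNode | None, int]:
    if node.kind == "protein":
        if node.gene in table:
            return EntityNode.protein(table[node.gene]), 0
        logger.warning("no ortholog for %s; dropped", node.gene)
        return None, 1
    dropped = 0
    children = []
    for child in node.children:
        mapped, d = _map_node_orthologs(child, table)
        dropped += d
        if mapped is not None:
            children.append(mapped)
    if not children:
        return None, dropped
    return EntityNode(node.kind, None, tuple(children)), dropped


def build_pathway_db(
    model_dir: str | Path,
    ontology: ReactoOntology | None = None,
    ortholog_table: Mapping[str, str] | None = None,
    min_mf: int = 3,
    min_causal_edges: int = 2,
    require_production: bool = True,
    target_taxon: str = TAXON_HUMAN,
) -> tuple[PathwayDB, dict]:
    """Parse -> filter -> resolve -> ortholog-map -> build pathways + background.

    Returns the database plus an ingestion report (counts of models parsed
    and kept, pathways, entities, sets, genes, dropped genes).
    """
    paths = sorted(Path(model_dir).glob("*.ttl"))
    models = [parse_gocam(p) for p in paths]
    kept = filter_models(models, min_mf, min_causal_edges, require_production)
    pathways: list[Pathway] = []
    unmapped_total = 0
    for m in kept:
        enablers: list[EntityNode] = []
        for mf in m.mf_nodes:
            ref = m.enabler_map.get(mf)
            if ref is None:
                continue  # enabler-less step contributes nothing
            if ontology is not None:
                node = ontology.resolve(ref)
            elif ref.startswith(UNIPROT_PREFIX):
                node = EntityNode.protein(ref[len(UNIPROT_PREFIX):])
            elif ref.startswith(CHEBI_PREFIX):
                node = None
            else:
                node = EntityNode.protein(ref.rsplit("/", 1)[-1].rsplit("#", 1)[-1])
            if node is not None:
                enablers.append(node)
        if m.taxa and target_taxon not in m.taxa:
            if ortholog_table is None:
                raise ConfigurationError(
                    f"model {m.model_id} is non-target taxon {sorted(m.taxa)} "
                    "but no ortholog table was provided"
                )
            mapped_enablers = []
            for node in enablers:
                mapped, d = _map_node_orthologs(node, ortholog_table)
                unmapped_total += d
                if mapped is not None:
                    mapped_enablers.append(mapped)
            enablers = mapped_enablers
        if not enablers:
            logger.warning("model %s has no resolvable enablers; skipped", m.model_id)
            continue
        pathways.append(build_pathway(m.model_id, m.title, enablers))
    if not pathways:
        raise NoPathwaysError(f"no pathways survived ingestion from {model_dir}")
    db = PathwayDB.from_pathways(pathways)
    n_sets = sum(1 for e in db.background.entities if e.kind == "set")
    report = {
        "models_parsed": len(models),
        "models_kept": len(kept),
        "pathways": len(db.pathways),
        "entities": db.background.M_entities,
        "set_entities": n_sets,
        "genes": db.background.M_genes,
        "unmapped_genes_dropped": unmapped_total,
    }
    return db, report
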