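"""Input/output and core containers: gene network, ontology, association tables.

The propagation substrate is an undirected simple graph over opaque gene
identifiers.  Edge weights are optional (default 1.0); the degree used for
normalization is the weighted degree.  The adjacency is symmetrically
normalized as W'_ij = w_ij / sqrt(d_i * d_j), which bounds the spectral
radius by 1 and guarantees convergence of restart walks for any restart
probability in (0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import obonet
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "GeneNetwork",
    "NormalizedAdjacency",
    "Ontology",
    "AssociationSet",
    "DiseaseMeta",
    "NetworkFormatError",
    "OntologyError",
    "AssociationFormatError",
    "read_network",
    "write_network",
    "normalize_adjacency",
    "read_ontology",
    "read_associations",
]

INHERITANCE_VALUES = ("AD", "AR", "other", "unknown")
ONSET_VALUES = (
    "congenital",
    "neonatal",
    "infantile",
    "childhood",
    "juvenile",
    "adult",
    "unknown",
)
PROGRESSION_VALUES = ("nonprogressive", "slow", "progressive", "rapid", "unknown")
FREQUENCY_VALUES = ("hallmark", "typical", "occasional", "unknown")


class NetworkFormatError(ValueError):
    """Malformed edge-list input."""


class OntologyError(ValueError):
    """Cyclic or disconnected ontology input."""


class AssociationFormatError(ValueError):
    """Association table missing a mandatory column."""


# ---------------------------------------------------------------------------
# Gene network


class GeneNetwork:
    """Undirected simple graph of gene products (the interactome).

    Thin wrapper over :class:`networkx.Graph` enforcing the simple-graph
    contract: no self-loops, parallel edges collapsed keeping the maximum
    weight, every weight strictly positive.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()

    # -- construction ------------------------------------------------------
    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str] | tuple[str, str, float]]
    ) -> "GeneNetwork":
        net = cls()
        for edge in edges:
            if len(edge) == 2:
                a, b = edge  # type: ignore[misc]
                w = 1.0
            else:
                a, b, w = edge  # type: ignore[misc]
            net.add_edge(str(a), str(b), float(w))
        return net

    def add_node(self, gene: str) -> None:
        self.graph.add_node(gene)

    def add_edge(self, a: str, b: str, weight: float = 1.0) -> bool:
        """Add an edge, enforcing invariants.  Returns False if skipped/merged."""
        if weight <= 0:
            raise NetworkFormatError(f"non-positive edge weight {weight!r} on {a}-{b}")
        if a == b:
            return False
        if self.graph.has_edge(a, b):
            if weight > self.graph[a][b]["weight"]:
                self.graph[a][b]["weight"] = weight
            return False
        self.graph.add_edge(a, b, weight=weight)
        return True

    # -- views -------------------------------------------------------------
    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def node_list(self) -> list[str]:
        """Fixed total ordering of nodes (sorted) used for matrix views."""
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> set[frozenset[str]]:
        return {frozenset((a, b)) for a, b in self.graph.edges}

    def degree(self, gene: str) -> int:
        return self.graph.degree[gene]

    def weighted_degree(self, gene: str) -> float:
        return self.graph.degree(weight="weight")[gene]

    def neighbors(self, gene: str) -> set[str]:
        return set(self.graph.neighbors(gene))

    def has_edge(self, a: str, b: str) -> bool:
        return self.graph.has_edge(a, b)

    def subgraph_copy(self) -> "GeneNetwork":
        return GeneNetwork(self.graph.copy())

    def __contains__(self, gene: str) -> bool:
        return gene in self.graph

    def __repr__(self) -> str:  # pragma: no cover
        return f"GeneNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


def read_network(path: str | Path, min_component: bool = False) -> GeneNetwork:
    """Read a two/three-column TSV edge list into a :class:`GeneNetwork`.

    Lines are ``gene_a<TAB>gene_b[<TAB>weight]``; ``#`` comment lines and
    blank lines are skipped.  Self-loops are dropped and duplicate edges are
    collapsed to the maximum weight; counts of both are logged.  With
    ``min_component`` only the largest connected component is kept.
    """
    path = Path(path)
    net = GeneNetwork()
    n_self, n_dup = 0, 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:  # tolerate space-separated input
                parts = line.split()
            if len(parts) < 2:
                raise NetworkFormatError(f"{path}:{lineno}: expected >=2 columns, got {line!r}")
            a, b = parts[0].strip(), parts[1].strip()
            if not a or not b:
                raise NetworkFormatError(f"{path}:{lineno}: empty gene identifier")
            weight = 1.0
            if len(parts) >= 3 and parts[2].strip():
                try:
                    weight = float(parts[2])
                except ValueError as exc:
                    raise NetworkFormatError(
                        f"{path}:{lineno}: weight {parts[2]!r} is not a number"
                    ) from exc
                if weight <= 0:
                    raise NetworkFormatError(f"{path}:{lineno}: non-positive weight {weight}")
            if a == b:
                n_self += 1
                net.add_node(a)
                continue
            if net.graph.has_edge(a, b):
                n_dup += 1
            net.add_edge(a, b, weight)
    if net.n_nodes == 0:
        logger.warning("network file %s is empty", path)
    if min_component and net.n_nodes:
        components = list(nx.connected_components(net.graph))
        largest = max(components, key=len)
        if len(components) > 1:
            logger.info("keeping largest component: %d of %d nodes", len(largest), net.n_nodes)
            net = GeneNetwork(net.graph.subgraph(largest).copy())
    logger.info(
        "read network %s: %d nodes, %d edges (%d self-loops dropped, %d duplicates collapsed)",
        path,
        net.n_nodes,
        net.n_edges,
        n_self,
        n_dup,
    )
    return net


def write_network(net: GeneNetwork, path: str | Path) -> None:
    """Write the edge list back out as ``gene_a<TAB>gene_b<TAB>weight``."""
    path = Path(path)
    with path.open("w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in net.graph.edges):
            w = net.graph[a][b]["weight"]
            fh.write(f"{a}\t{b}\t{w:g}\n")


# ---------------------------------------------------------------------------
# Normalized adjacency


@dataclass(frozen=True)
class NormalizedAdjacency:
    """Symmetrically degree-normalized adjacency W' = D^-1/2 W D^-1/2.

    ``matrix`` is CSR over the fixed ``nodes`` ordering; rows and columns of
    isolated nodes are identically zero.  The largest eigenvalue is <= 1,
    which makes (I - (1-gamma) W') invertible for gamma in (0, 1].
    """

    matrix: sp.csr_matrix
    nodes: tuple[str, ...]
    index: Mapping[str, int] = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.nodes)

    def entry(self, a: str, b: str) -> float:
        return float(self.matrix[self.index[a], self.index[b]])


def normalize_adjacency(net: GeneNetwork) -> NormalizedAdjacency:
    """PRINCE-style symmetric normalization of the weighted adjacency.

    W'_ij = w_ij / sqrt(d_i * d_j) with d the weighted degree.  Isolated
    nodes contribute all-zero rows/columns by contract.
    """
    if net.n_nodes == 0:
        raise ValueError("cannot normalize an empty network")
    order = net.node_list()
    index = {g: i for i, g in enumerate(order)}
    adj = nx.to_scipy_sparse_array(net.graph, nodelist=order, weight="weight", format="coo")
    deg = np.asarray(adj.sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
    data = adj.data * inv_sqrt[adj.row] * inv_sqrt[adj.col]
    mat = sp.csr_matrix((data, (adj.row, adj.col)), shape=adj.shape)
    return NormalizedAdjacency(matrix=mat, nodes=tuple(order), index=index)


# ---------------------------------------------------------------------------
# Ontology


class Ontology:
    """Rooted DAG of phenotype terms linked by is-a edges.

    ``parents`` maps each term to its (possibly multiple) parents; the root
    is the unique parentless term.  Ancestor closure is cached per term.
    """

    def __init__(
        self,
        parents: Mapping[str, set[str]],
        names: Mapping[str, str] | None = None,
    ):
        self.parents: dict[str, set[str]] = {t: set(ps) for t, ps in parents.items()}
        # make sure referenced parents exist as terms
        for ps in list(self.parents.values()):
            for p in ps:
                self.parents.setdefault(p, set())
        self.names: dict[str, str] = dict(names or {})
        self._validate()
        self.children: dict[str, set[str]] = {t: set() for t in self.parents}
        for t, ps in self.parents.items():
            for p in ps:
                self.children[p].add(t)
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    def _validate(self) -> None:
        dg = nx.DiGraph()
        dg.add_nodes_from(self.parents)
        for t, ps in self.parents.items():
            dg.add_edges_from((t, p) for p in ps)
        if not nx.is_directed_acyclic_graph(dg):
            cycle = nx.find_cycle(dg)
            raise OntologyError(f"ontology parent graph has a cycle: {cycle}")
        roots = sorted(t for t, ps in self.parents.items() if not ps)
        if not roots:
            raise OntologyError("ontology has no root term")
        if len(roots) > 1:
            raise OntologyError(
                f"orphan terms cannot reach a single root: {roots[1:]} (root candidate {roots[0]})"
            )
        self.root = roots[0]

    @property
    def terms(self) -> set[str]:
        return set(self.parents)

    def __contains__(self, term: str) -> bool:
        return term in self.parents

    def ancestors(self, term: str, include_self: bool = False) -> frozenset[str]:
        """All terms reachable via parent links (excluding *term* unless asked)."""
        if term not in self.parents:
            raise KeyError(term)
        cached = self._ancestor_cache.get(term)
        if cached is None:
            out: set[str] = set()
            stack = list(self.parents[term])
            while stack:
                p = stack.pop()
                if p not in out:
                    out.add(p)
                    stack.extend(self.parents[p])
            cached = frozenset(out)
            self._ancestor_cache[term] = cached
        return frozenset(cached | {term}) if include_self else cached

    def descendants(self, term: str, include_self: bool = False) -> frozenset[str]:
        out: set[str] = set()
        stack = list(self.children[term])
        while stack:
            c = stack.pop()
            if c not in out:
                out.add(c)
                stack.extend(self.children[c])
        return frozenset(out | {term}) if include_self else frozenset(out)

    def is_ancestor(self, anc: str, term: str) -> bool:
        return anc in self.ancestors(term)

    def top_classes(self, term: str, subroot: str) -> frozenset[str]:
        """Most general ancestors of *term* strictly below *subroot* (its classes)."""
        anc = self.ancestors(term, include_self=True)
        return frozenset(t for t in anc if subroot in self.parents.get(t, set()))

    def __repr__(self) -> str:  # pragma: no cover
        return f"Ontology(n_terms={len(self.parents)}, root={self.root!r})"


def read_ontology(path: str | Path, dialect: str = "auto") -> Ontology:
    """Read an ontology from OBO (is-a links only) or a child/parent TSV.

    ``dialect`` is ``obo``, ``tsv`` or ``auto`` (by file extension).  Non
    is-a relationship lines in OBO input are ignored with a warning.
    """
    path = Path(path)
    if dialect == "auto":
        dialect = "obo" if path.suffix.lower() == ".obo" else "tsv"
    if dialect == "obo":
        graph = obonet.read_obo(str(path))
        parents: dict[str, set[str]] = {t: set() for t in graph.nodes}
        names = {t: data.get("name", t) for t, data in graph.nodes(data=True)}
        dropped = 0
        for child, parent, key in graph.edges(keys=True):
            if key == "is_a":
                parents[child].add(parent)
            else:
                dropped += 1
        if dropped:
            logger.warning("ignored %d non is-a relationship edges in %s", dropped, path)
        return Ontology(parents, names)
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        missing = {"child", "parent"} - set(df.columns)
        if missing:
            raise AssociationFormatError(f"{path}: missing column(s) {sorted(missing)}")
        parents = {}
        for child, parent in df.itertuples(index=False):
            parents.setdefault(str(child), set()).add(str(parent))
        return Ontology(parents)
    raise ValueError(f"unknown ontology dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Associations


@dataclass
class DiseaseMeta:
    """Per-disease clinical metadata used for stratified evaluation."""

    inheritance: str = "unknown"
    onset: frozenset[str] = frozenset({"unknown"})
    progression: str = "unknown"


@dataclass
class AssociationSet:
    """Disease-centric annotation tables.

    ``disease_signs`` maps disease -> {term: frequency class}; frequency is
    one of hallmark/typical/occasional/unknown on a decreasing prevalence
    scale.
    """

    disease_genes: dict[str, set[str]] = field(default_factory=dict)
    disease_signs: dict[str, dict[str, str]] = field(default_factory=dict)
    disease_meta: dict[str, DiseaseMeta] = field(default_factory=dict)
    gene_functions: dict[str, set[str]] | None = None

    @property
    def diseases(self) -> set[str]:
        return set(self.disease_genes) | set(self.disease_signs) | set(self.disease_meta)

    def genes(self) -> set[str]:
        out: set[str] = set()
        for gs in self.disease_genes.values():
            out |= gs
        return out


def _norm_inheritance(value: str) -> str:
    v = value.strip().lower()
    if not v or v in {"unknown", "na", "nan", "-"}:
        return "unknown"
    if v in {"ad"} or "dominant" in v:
        return "AD"
    if v in {"ar"} or "recessive" in v:
        return "AR"
    return "other"


def _norm_enum(value: str, allowed: tuple[str, ...], what: str) -> str:
    v = value.strip().lower()
    if not v or v in {"na", "nan", "-"}:
        return "unknown"
    for a in allowed:
        if v == a or v.startswith(a):
            return a
    logger.warning("unrecognized %s value %r mapped to 'unknown'", what, value)
    return "unknown"


def read_associations(
    gene_path: str | Path,
    sign_path: str | Path | None = None,
    meta_path: str | Path | None = None,
    function_path: str | Path | None = None,
) -> AssociationSet:
    """Read disease->gene, disease->sign, disease metadata and gene->function TSVs.

    All files are headered TSVs; enumerated columns (inheritance, onset,
    progression, frequency) are normalized to their controlled vocabularies,
    with unrecognized values mapped to ``unknown`` plus a warning.  Onset may
    hold several ``;``-separated values.
    """

    def _load(path, required: list[str]) -> pd.DataFrame:
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        missing = set(required) - set(df.columns)
        if missing:
            raise AssociationFormatError(f"{path}: missing column(s) {sorted(missing)}")
        return df

    assoc = AssociationSet()
    genes_df = _load(gene_path, ["disease_id", "gene_id"])
    for row in genes_df.itertuples(index=False):
        assoc.disease_genes.setdefault(row.disease_id, set()).add(row.gene_id)

    if sign_path is not None:
        signs_df = _load(sign_path, ["disease_id", "term_id"])
        has_freq = "frequency" in signs_df.columns
        for row in signs_df.itertuples(index=False):
            freq = "unknown"
            if has_freq:
                freq = _norm_enum(row.frequency, FREQUENCY_VALUES[:3], "frequency")
            assoc.disease_signs.setdefault(row.disease_id, {})[row.term_id] = freq

    if meta_path is not None:
        meta_df = _load(meta_path, ["disease_id"])
        for row in meta_df.itertuples(index=False):
            d = row.disease_id
            inh = _norm_inheritance(getattr(row, "inheritance", ""))
            onset_raw = getattr(row, "onset", "")
            onsets = frozenset(
                _norm_enum(part, ONSET_VALUES[:6], "onset")
                for part in str(onset_raw).split(";")
                if part.strip()
            ) or frozenset({"unknown"})
            prog = _norm_enum(getattr(row, "progression", ""), PROGRESSION_VALUES[:4], "progression")
            assoc.disease_meta[d] = DiseaseMeta(inheritance=inh, onset=onsets, progression=prog)

    if function_path is not None:
        fn_df = _load(function_path, ["gene_id", "function_term"])
        assoc.gene_functions = {}
        for row in fn_df.itertuples(index=False):
            assoc.gene_functions.setdefault(row.gene_id, set()).add(row.function_term)

    geneless = assoc.diseases - set(assoc.disease_genes)
    if geneless:
        logger.info("%d diseases have signs/metadata but no causal gene", len(geneless))
    return assoc
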