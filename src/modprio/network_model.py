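"""Domain types and readers/writers for the heterogeneous module network.

The central object is a graph with two node types (diseases and genes), two
edge types (disease-gene associations and gene-gene interactions, the latter
standing in for protein-protein interactions), and module annotations (protein
complexes, i.e. named gene sets). Identifiers are opaque strings; the disease
and gene namespaces must be disjoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping


class ParseError(ValueError):
    """Raised for malformed input lines; carries the offending line number."""


def _norm_edge(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class GeneGraph:
    """Undirected gene-gene interaction graph.

    No self-loops, no duplicate edges; edges are stored as sorted id pairs.
    """

    nodes: set[str] = field(default_factory=set)
    edges: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.edges = {_norm_edge(a, b) for a, b in self.edges}
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on node {a!r}")
            self.nodes.add(a)
            self.nodes.add(b)

    def add_edge(self, a: str, b: str) -> None:
        if a == b:
            raise ValueError(f"self-loop on node {a!r}")
        self.nodes.update((a, b))
        self.edges.add(_norm_edge(a, b))

    def has_edge(self, a: str, b: str) -> bool:
        return _norm_edge(a, b) in self.edges

    def neighbors(self) -> dict[str, set[str]]:
        """Adjacency map covering every node (isolated nodes map to empty sets)."""
        adj: dict[str, set[str]] = {n: set() for n in self.nodes}
        for a, b in self.edges:
            adj[a].add(b)
            adj[b].add(a)
        return adj

    def degree(self, node: str) -> int:
        return sum(1 for e in self.edges if node in e)

    def copy(self) -> "GeneGraph":
        return GeneGraph(set(self.nodes), set(self.edges))


@dataclass
class AssociationSet:
    """Set of (disease-id, gene-id) association pairs."""

    pairs: set[tuple[str, str]] = field(default_factory=set)

    @property
    def diseases(self) -> set[str]:
        return {d for d, _ in self.pairs}

    @property
    def genes(self) -> set[str]:
        return {g for _, g in self.pairs}

    def genes_of(self, disease: str) -> set[str]:
        return {g for d, g in self.pairs if d == disease}

    def by_disease(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for d, g in self.pairs:
            out.setdefault(d, set()).add(g)
        return out


@dataclass
class ModuleSet:
    """Mapping module-id -> member gene set (protein complexes).

    A gene may belong to several modules. Singleton modules are legal on load
    but flagged with a warning, since they carry no cooperative signal.
    """

    modules: dict[str, set[str]] = field(default_factory=dict)

    @property
    def member_genes(self) -> set[str]:
        out: set[str] = set()
        for members in self.modules.values():
            out |= members
        return out

    def assignment(self) -> dict[str, str]:
        """Deterministic gene -> module-id map.

        Multi-module genes are assigned to their lexicographically smallest
        module id, so downstream token substitution is reproducible.
        """
        assign: dict[str, str] = {}
        for mid in sorted(self.modules):
            for g in self.modules[mid]:
                if g not in assign or mid < assign[g]:
                    assign[g] = mid
        return assign


@dataclass
class HeteroModuleNetwork:
    """Heterogeneous module network G = (V, E).

    V = V_d (diseases) union V_g (genes), disjoint; E = E_dg union E_gg.
    Genes referenced only by associations or modules are kept as isolated
    gene nodes so the label set is never silently shrunk.
    """

    genes: GeneGraph
    associations: AssociationSet
    modules: ModuleSet

    @property
    def gene_nodes(self) -> set[str]:
        return self.genes.nodes

    @property
    def disease_nodes(self) -> set[str]:
        return self.associations.diseases

    @property
    def all_nodes(self) -> set[str]:
        return self.gene_nodes | self.disease_nodes

    def hetero_edges(self) -> set[tuple[str, str]]:
        """All edges of the heterogeneous graph (gene-gene and disease-gene)."""
        return set(self.genes.edges) | {_norm_edge(d, g) for d, g in self.associations.pairs}

    def hetero_adjacency(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {n: set() for n in self.all_nodes}
        for a, b in self.genes.edges:
            adj[a].add(b)
            adj[b].add(a)
        for d, g in self.associations.pairs:
            adj[d].add(g)
            adj[g].add(d)
        return adj


def build_network(
    genes: GeneGraph, assoc: AssociationSet, modules: ModuleSet
) -> HeteroModuleNetwork:
    """Assemble the heterogeneous module network.

    Gene endpoints of associations or module members missing from the PPI
    graph are added as isolated gene nodes. An id appearing both as a disease
    and as a gene is a hard error (the namespaces must be disjoint).
    """
    genes = genes.copy()
    for _, g in assoc.pairs:
        genes.nodes.add(g)
    for members in modules.modules.values():
        genes.nodes.update(members)
    clash = assoc.diseases & genes.nodes
    if clash:
        raise ValueError(
            f"ids appear both as disease and gene: {sorted(clash)[:5]}"
        )
    return HeteroModuleNetwork(genes=genes, associations=assoc, modules=modules)


# ---------------------------------------------------------------------------
# File formats: TSV edge lists and a GMT-like gene-set dialect.
# ---------------------------------------------------------------------------

#: comment directive used to round-trip isolated nodes through edge lists
_NODE_DIRECTIVE = "#node"


def _iter_fields(path: str) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or (line.startswith("#") and not line.startswith(_NODE_DIRECTIVE)):
                continue
            yield lineno, line.split()


def load_gene_graph(path: str) -> GeneGraph:
    """Read an undirected edge list (two whitespace-separated ids per line).

    Duplicate edges (in either orientation) are merged; self-loop lines are
    dropped with a warning reporting their count.
    """
    graph = GeneGraph()
    self_loops = 0
    for lineno, fields in _iter_fields(path):
        if fields[0] == _NODE_DIRECTIVE:
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: '#node' directive takes one id")
            graph.nodes.add(fields[1])
            continue
        if len(fields) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
        a, b = fields
        if a == b:
            self_loops += 1
            continue
        graph.add_edge(a, b)
    if self_loops:
        warnings.warn(f"{path}: dropped {self_loops} self-loop line(s)")
    return graph


def load_associations(path: str) -> AssociationSet:
    """Read disease-gene pairs, one `disease TAB gene` per line."""
    pairs: set[tuple[str, str]] = set()
    for lineno, fields in _iter_fields(path):
        if fields[0] == _NODE_DIRECTIVE:
            continue
        if len(fields) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
        pairs.add((fields[0], fields[1]))
    return AssociationSet(pairs)


def load_modules(path: str) -> ModuleSet:
    """Read gene sets, one `module-id TAB member TAB member...` per line.

    Duplicate members within a line are deduplicated with a warning; a
    repeated module id is an error. Singleton modules are flagged.
    """
    modules: dict[str, set[str]] = {}
    for lineno, fields in _iter_fields(path):
        if fields[0] == _NODE_DIRECTIVE:
            continue
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: module line needs an id and >=1 member")
        mid, members = fields[0], fields[1:]
        if mid in modules:
            raise ParseError(f"{path}:{lineno}: duplicate module id {mid!r}")
        member_set = set(members)
        if len(member_set) < len(members):
            warnings.warn(f"{path}:{lineno}: duplicate members in module {mid!r}")
        if len(member_set) < 2:
            warnings.warn(f"{path}:{lineno}: module {mid!r} has fewer than 2 members")
        modules[mid] = member_set
    return ModuleSet(modules)


def write_gene_graph(graph: GeneGraph, path: str, provenance: Mapping[tuple[str, str], str] | None = None) -> None:
    """Write a sorted edge list; optional third provenance column per edge."""
    with open(path, "w") as fh:
        for a, b in sorted(graph.edges):
            if provenance is not None:
                fh.write(f"{a}\t{b}\t{provenance.get((a, b), 'original')}\n")
            else:
                fh.write(f"{a}\t{b}\n")
        connected = {n for e in graph.edges for n in e}
        for n in sorted(graph.nodes - connected):
            fh.write(f"{_NODE_DIRECTIVE}\t{n}\n")


def write_associations(assoc: AssociationSet, path: str) -> None:
    with open(path, "w") as fh:
        for d, g in sorted(assoc.pairs):
            fh.write(f"{d}\t{g}\n")


def write_modules(modules: ModuleSet, path: str) -> None:
    with open(path, "w") as fh:
        for mid in sorted(modules.modules):
            members = "\t".join(sorted(modules.modules[mid]))
            fh.write(f"{mid}\t{members}\n")
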