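"""Bipartite reaction knowledge graph and its monopartite projections.

The central object is a directed bipartite graph with two node kinds:
molecules (keyed by canonical SMILES) and reactions (keyed by their
reagent-blind reaction key).  A molecule->reaction edge records reactant
participation, a reaction->molecule edge product formation; since every
clean reaction has exactly one product, reaction out-degree is identically
one.  Reagents never enter the graph.

Two projections are derived: the molecule graph (directed reactant->product
links, parallel edges collapsed with a multiplicity count) and the reaction
graph (undirected links between reactions sharing any molecule).  The
reaction projection turns every molecule of bipartite degree ``d`` into a
``d``-clique and can explode around hub molecules, so an optional
per-molecule degree cap guards materialization.
"""

from __future__ import annotations

import logging
import math
import warnings
from collections.abc import Sequence
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import networkx as nx

from .etl import CleanReaction

logger = logging.getLogger(__name__)

__all__ = [
    "MOLECULE",
    "REACTION",
    "ReactionNetwork",
    "MoleculeGraph",
    "ReactionGraphView",
    "GraphSummary",
    "build_bipartite",
    "project_molecule_graph",
    "project_reaction_graph",
    "summarize",
    "edge_to_node_ratio",
    "save_network",
    "load_network",
]

MOLECULE = "molecule"
REACTION = "reaction"


@dataclass
class ReactionNetwork:
    """Directed bipartite molecule/reaction graph."""

    graph: nx.DiGraph
    provenance: str = "synthetic"

    def nodes_of(self, kind: str) -> list[str]:
        return [n for n, k in self.graph.nodes(data="kind") if k == kind]

    @property
    def n_molecules(self) -> int:
        return sum(1 for _, k in self.graph.nodes(data="kind") if k == MOLECULE)

    @property
    def n_reactions(self) -> int:
        return sum(1 for _, k in self.graph.nodes(data="kind") if k == REACTION)


@dataclass
class MoleculeGraph:
    """Directed reactant->product projection; parallel edges collapsed."""

    graph: nx.DiGraph  # edge attribute 'multiplicity'


@dataclass
class ReactionGraphView:
    """Undirected reaction-reaction projection (shared-molecule links)."""

    graph: nx.Graph
    capped_molecules: int = 0  # molecules skipped by the degree guard


@dataclass
class GraphSummary:
    n_molecule_nodes: int
    n_reaction_nodes: int
    n_product_edges: int
    n_reactant_edges: int
    edge_to_node_ratio: float
    avg_total_degree: float

    def as_dict(self) -> dict:
        return {
            "n_molecule_nodes": self.n_molecule_nodes,
            "n_reaction_nodes": self.n_reaction_nodes,
            "n_product_edges": self.n_product_edges,
            "n_reactant_edges": self.n_reactant_edges,
            "n_nodes_total": self.n_molecule_nodes + self.n_reaction_nodes,
            "n_edges_total": self.n_product_edges + self.n_reactant_edges,
            "edge_to_node_ratio": self.edge_to_node_ratio,
            "avg_total_degree": self.avg_total_degree,
        }


def edge_to_node_ratio(n_nodes: int, n_edges: int) -> float:
    """Total edges over total nodes; NaN (with a warning) on an empty graph."""
    if n_nodes == 0:
        warnings.warn("edge-to-node ratio undefined on an empty graph", stacklevel=2)
        return math.nan
    return n_edges / n_nodes


def build_bipartite(
    clean_reactions: Sequence[CleanReaction],
    provenance: str = "synthetic",
) -> ReactionNetwork:
    """Assemble the bipartite graph from deduplicated clean reactions.

    One reaction node per distinct reaction key, one molecule node per
    distinct canonical structure appearing as reactant or product, one
    reactant edge per distinct (molecule, reaction) pair and exactly one
    product edge per reaction.  Duplicate keys in the input violate the
    deduplication contract and raise.
    """
    g = nx.DiGraph()
    seen_keys: set[str] = set()
    for rxn in clean_reactions:
        if rxn.reaction_key in seen_keys:
            raise ValueError(f"duplicate reaction key in input: {rxn.reaction_key!r}")
        seen_keys.add(rxn.reaction_key)
        g.add_node(rxn.reaction_key, kind=REACTION, n_grouped=rxn.n_grouped)
        for smi in set(rxn.reactants):
            if smi not in g:
                g.add_node(smi, kind=MOLECULE)
            g.add_edge(smi, rxn.reaction_key, role="reactant")
        if rxn.product not in g:
            g.add_node(rxn.product, kind=MOLECULE)
        g.add_edge(rxn.reaction_key, rxn.product, role="product")
    return ReactionNetwork(graph=g, provenance=provenance)


def project_molecule_graph(net: ReactionNetwork) -> MoleculeGraph:
    """Collapse each reaction into reactant->product molecule edges."""
    mg = nx.DiGraph()
    bip = net.graph
    for node, kind in bip.nodes(data="kind"):
        if kind == MOLECULE:
            mg.add_node(node)
    for rxn, kind in bip.nodes(data="kind"):
        if kind != REACTION:
            continue
        products = list(bip.successors(rxn))
        reactants = list(bip.predecessors(rxn))
        for p in products:
            for r in reactants:
                if r == p:
                    continue
                if mg.has_edge(r, p):
                    mg[r][p]["multiplicity"] += 1
                else:
                    mg.add_edge(r, p, multiplicity=1)
    return MoleculeGraph(graph=mg)


def project_reaction_graph(
    net: ReactionNetwork,
    degree_cap: int | None = None,
) -> ReactionGraphView:
    """Link reactions sharing at least one molecule (undirected).

    A molecule incident to ``d`` reactions contributes a ``d``-clique;
    ``degree_cap`` skips molecules above the cap (logged) to bound the
    quadratic blow-up around hubs.
    """
    rg = nx.Graph()
    bip = net.graph
    capped = 0
    for node, kind in bip.nodes(data="kind"):
        if kind == REACTION:
            rg.add_node(node)
    for mol, kind in bip.nodes(data="kind"):
        if kind != MOLECULE:
            continue
        incident = set(bip.successors(mol)) | set(bip.predecessors(mol))
        if degree_cap is not None and len(incident) > degree_cap:
            capped += 1
            continue
        for a, b in combinations(sorted(incident), 2):
            rg.add_edge(a, b)
    if capped:
        logger.warning("reaction projection skipped %d molecules above degree cap %s", capped, degree_cap)
    return ReactionGraphView(graph=rg, capped_molecules=capped)


def summarize(net: ReactionNetwork) -> GraphSummary:
    """Node/edge counts and connectivity ratio of the bipartite graph."""
    g = net.graph
    n_mol = net.n_molecules
    n_rxn = net.n_reactions
    n_prod = sum(1 for _, _, role in g.edges(data="role") if role == "product")
    n_reac = sum(1 for _, _, role in g.edges(data="role") if role == "reactant")
    n_nodes = n_mol + n_rxn
    ratio = edge_to_node_ratio(n_nodes, n_prod + n_reac)
    avg_deg = 2.0 * (n_prod + n_reac) / n_nodes if n_nodes else math.nan
    return GraphSummary(
        n_molecule_nodes=n_mol,
        n_reaction_nodes=n_rxn,
        n_product_edges=n_prod,
        n_reactant_edges=n_reac,
        edge_to_node_ratio=ratio,
        avg_total_degree=avg_deg,
    )


# ---------------------------------------------------------------------------
# Plain-text serialization
# ---------------------------------------------------------------------------


def save_network(net: ReactionNetwork, outdir: str | Path) -> None:
    """Write ``nodes.tsv`` (id, kind) and ``edges.tsv`` (src, dst, role)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "nodes.tsv", "w", encoding="utf-8") as fh:
        fh.write("node_id\tkind\n")
        for node, kind in net.graph.nodes(data="kind"):
            fh.write(f"{node}\t{kind}\n")
    with open(outdir / "edges.tsv", "w", encoding="utf-8") as fh:
        fh.write("src\tdst\trole\n")
        for src, dst, role in net.graph.edges(data="role"):
            fh.write(f"{src}\t{dst}\t{role}\n")


def load_network(indir: str | Path, provenance: str = "file") -> ReactionNetwork:
    indir = Path(indir)
    g = nx.DiGraph()
    with open(indir / "nodes.tsv", encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            node, kind = line.rstrip("\n").split("\t")
            g.add_node(node, kind=kind)
    with open(indir / "edges.tsv", encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            src, dst, role = line.rstrip("\n").split("\t")
            g.add_edge(src, dst, role=role)
    return ReactionNetwork(graph=g, provenance=provenance)
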