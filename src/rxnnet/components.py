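"""Core / periphery / island decomposition of the bipartite network.

The decomposition reads two component structures off the directed
bipartite graph: strongly connected components (mutual directed
reachability) and connected components of the undirected skeleton.  The
*central component* is the largest connected component; the *core* is the
largest strongly connected component, recognised only when it dominates
(at least ``dominance_ratio`` times the runner-up SCC) and is non-trivial
(at least ``min_core_size`` nodes).  The *periphery* is the central
component minus the core, and *islands* are everything outside the central
component.

"Significantly larger" has no canonical operationalisation; the 10x / 10-node
rule used here is a declared convention, exposed as configuration.  A corpus
without directed cycles (no molecule is ever regenerated downstream of
itself) has only singleton SCCs and therefore no core, while its central
component remains meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx

from .graphs import MOLECULE, ReactionNetwork

logger = logging.getLogger(__name__)

__all__ = ["ComponentLabeling", "decompose", "component_size_spectrum"]


@dataclass
class ComponentLabeling:
    """Per-node core/periphery/island assignment with its evidence."""

    label: dict  # node -> {'core', 'periphery', 'island'}
    scc_sizes: list[int]  # descending
    cc_sizes: list[int]  # descending
    core_exists: bool
    proportions: dict[str, float]  # label -> percent of all nodes

    def molecule_labels(self, net: ReactionNetwork) -> dict:
        """Restriction of the labeling to molecule nodes."""
        g = net.graph
        return {n: lab for n, lab in self.label.items() if g.nodes[n]["kind"] == MOLECULE}


def component_size_spectrum(net: ReactionNetwork) -> tuple[list[int], list[int]]:
    """Descending SCC and CC size lists; CC sizes sum to the node count."""
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    scc_sizes = sorted((len(c) for c in nx.strongly_connected_components(g)), reverse=True)
    cc_sizes = sorted((len(c) for c in nx.connected_components(g.to_undirected(as_view=True))), reverse=True)
    return scc_sizes, cc_sizes


def decompose(
    net: ReactionNetwork,
    dominance_ratio: float = 10.0,
    min_core_size: int = 10,
) -> ComponentLabeling:
    """Label every bipartite node as core, periphery or island.

    The core is accepted only when the largest SCC both reaches
    ``min_core_size`` nodes and is at least ``dominance_ratio`` times the
    second largest; it is additionally verified to lie inside the central
    (largest) connected component — if it does not, the core is rejected
    with a warning, since the periphery is defined relative to the central
    component.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")

    sccs = sorted(nx.strongly_connected_components(g), key=len, reverse=True)
    ccs = sorted(nx.connected_components(g.to_undirected(as_view=True)), key=len, reverse=True)
    scc_sizes = [len(c) for c in sccs]
    cc_sizes = [len(c) for c in ccs]

    central = ccs[0]
    if len(ccs) > 1 and cc_sizes[0] < dominance_ratio * cc_sizes[1]:
        logger.warning(
            "largest connected component (%d nodes) does not dominate the runner-up "
            "(%d nodes); taking it as central regardless",
            cc_sizes[0],
            cc_sizes[1],
        )

    core: set = set()
    core_exists = scc_sizes[0] >= min_core_size and (
        len(scc_sizes) == 1 or scc_sizes[0] >= dominance_ratio * scc_sizes[1]
    )
    if core_exists:
        core = set(sccs[0])
        if not core <= central:
            logger.warning(
                "largest SCC (%d nodes) is not contained in the central component; "
                "no core is assigned",
                scc_sizes[0],
            )
            core = set()
            core_exists = False

    label: dict = {}
    for node in g.nodes():
        if node in core:
            label[node] = "core"
        elif node in central:
            label[node] = "periphery"
        else:
            label[node] = "island"

    n = g.number_of_nodes()
    proportions = {
        "periphery": 100.0 * sum(1 for v in label.values() if v == "periphery") / n,
        "islands": 100.0 * sum(1 for v in label.values() if v == "island") / n,
    }
    if core_exists:
        proportions["core"] = 100.0 * len(core) / n

    return ComponentLabeling(
        label=label,
        scc_sizes=scc_sizes,
        cc_sizes=cc_sizes,
        core_exists=core_exists,
        proportions=proportions,
    )
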