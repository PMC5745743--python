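"""Construction of the three analysis graphs.

* the tripartite ingredient–target–pathway network (edges only between
  adjacent classes: ingredient–target interactions and target–pathway
  memberships),
* the key-pathway core subnetwork (one pathway, its member targets, and the
  ingredients hitting those targets), and
* the pathway-based protein association projection (two proteins connected
  iff they share at least one pathway; isolated proteins excluded).

All graphs are simple and undirected; shared-pathway counts are kept as an
edge annotation only, never as weights in metric computation.
"""

from __future__ import annotations

import itertools
import logging

import networkx as nx
import pandas as pd

from .exceptions import ComputationError, ValidationError
from .io_formats import PathwayCollection, ROLES

logger = logging.getLogger(__name__)


def build_tripartite(interactions: pd.DataFrame,
                     memberships: PathwayCollection) -> nx.Graph:
    """Build the ingredient–target–pathway network.

    Nodes are the distinct ingredients and targets of *interactions* plus the
    pathways of *memberships*; edges are the interaction pairs and the
    (target, pathway) membership pairs. Membership entries for proteins that
    never appear as interaction targets are dropped with a log line, keeping
    the graph restricted to the screened target set. Raises
    :class:`ValidationError` if one id would carry two roles.
    """
    graph = nx.Graph()
    ingredients = list(dict.fromkeys(interactions["compound_id"]))
    targets = list(dict.fromkeys(interactions["target_id"]))
    target_set = set(targets)
    pathway_ids = [p.pathway_id for p in memberships]

    _check_role_collisions(ingredients, targets, pathway_ids)

    graph.add_nodes_from(ingredients, role="ingredient")
    graph.add_nodes_from(targets, role="target")
    graph.add_nodes_from(pathway_ids, role="pathway")
    graph.add_edges_from(interactions.itertuples(index=False, name=None))

    dropped = 0
    for pathway in memberships:
        for member in sorted(pathway.members):
            if member in target_set:
                graph.add_edge(member, pathway.pathway_id)
            else:
                dropped += 1
    if dropped:
        logger.info("build_tripartite: dropped %d membership links to proteins "
                    "outside the screened target set", dropped)
    return graph


def _check_role_collisions(ingredients, targets, pathways) -> None:
    sets = {"ingredient": set(ingredients), "target": set(targets),
            "pathway": set(pathways)}
    for a, b in itertools.combinations(ROLES, 2):
        clash = sets[a] & sets[b]
        if clash:
            raise ValidationError(
                f"id(s) used both as {a} and {b}: {sorted(clash)[:5]}")


def node_roles(graph: nx.Graph) -> dict[str, list]:
    """Nodes grouped by role (insertion order preserved)."""
    out: dict[str, list] = {role: [] for role in ROLES}
    for node, data in graph.nodes(data=True):
        role = data.get("role")
        if role in out:
            out[role].append(node)
    return out


def max_degree_pathway(graph: nx.Graph) -> str:
    """The pathway node of maximal degree (ties by ascending id): the
    operational reading of 'most important biological pathway'."""
    pathways = node_roles(graph)["pathway"]
    if not pathways:
        raise ComputationError("graph has no pathway nodes")
    return min(pathways, key=lambda p: (-graph.degree(p), str(p)))


def extract_core_subnetwork(graph: nx.Graph, pathway_id: str | None = None
                            ) -> nx.Graph:
    """Extract the core subnetwork of one pathway from a tripartite graph.

    Node set: the pathway, the targets adjacent to it (T), and the
    ingredients adjacent to at least one member of T. Edge set: the
    pathway–T edges plus the ingredient–T edges; no other pathway is
    included. When *pathway_id* is None the maximal-degree pathway is used.
    """
    if pathway_id is None:
        pathway_id = max_degree_pathway(graph)
    if pathway_id not in graph or graph.nodes[pathway_id].get("role") != "pathway":
        raise LookupError(f"{pathway_id!r} is not a pathway node of the graph")

    targets = {t for t in graph.neighbors(pathway_id)
               if graph.nodes[t].get("role") == "target"}
    core = nx.Graph()
    core.add_node(pathway_id, role="pathway")
    core.add_nodes_from(targets, role="target")
    core.add_edges_from((pathway_id, t) for t in targets)
    for t in targets:
        for neighbor in graph.neighbors(t):
            if graph.nodes[neighbor].get("role") == "ingredient":
                core.add_node(neighbor, role="ingredient")
                core.add_edge(neighbor, t)
    return core


def project_protein_association(memberships: PathwayCollection,
                                targets=None) -> nx.Graph:
    """Project pathway memberships onto a protein–protein graph.

    Two proteins are connected iff they are both members of at least one
    common pathway; the edge attribute ``shared_pathways`` counts the common
    pathways. Proteins sharing a pathway with nobody (isolated nodes) are
    excluded. *targets*, when given, restricts memberships first.
    """
    if targets is not None:
        memberships = memberships.restrict(targets)
    graph = nx.Graph()
    for pathway in memberships:
        for u, v in itertools.combinations(sorted(pathway.members), 2):
            if graph.has_edge(u, v):
                graph[u][v]["shared_pathways"] += 1
            else:
                graph.add_edge(u, v, shared_pathways=1)
    # nodes enter only via edges, so no isolated nodes can exist
    for node in graph.nodes:
        graph.nodes[node]["role"] = "target"
    return graph
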