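"""Rooted is-a hierarchies and the graph algebra the class-effect statistics need.

A hierarchy here is a rooted directed acyclic graph of ``(child, parent)``
is-a edges over term identifiers — an adverse-event ontology subset, or a
drug ingredient/mechanism-of-action classification.  Multi-parent terms are
permitted; roots are the terms with no parent.

Two conventions used throughout:

* "descendants" walk *down* the is-a edges (more specific terms),
  "ancestors" walk *up* (more general terms).
* A drug class is always resolved to its member set at call time:
  ``class_members`` intersects the downward closure of the class node with
  the ingredient universe under analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

__all__ = ["Hierarchy", "HierarchyError", "class_members", "propagate_ae"]


class HierarchyError(ValueError):
    """Structural problem in a hierarchy (cycle, unknown node, dangling id)."""


@dataclass(frozen=True)
class Hierarchy:
    """Rooted DAG of is-a edges, stored child -> parent.

    Parameters
    ----------
    graph
        Directed graph whose edges point from child term to parent term.
    labels
        Optional term-id -> human-readable-label map.
    """

    graph: nx.DiGraph
    labels: Mapping[str, str] = field(default_factory=dict)

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        nodes: Iterable[str] | None = None,
        labels: Mapping[str, str] | None = None,
    ) -> "Hierarchy":
        """Build and validate a hierarchy from ``(child, parent)`` pairs.

        When ``nodes`` is given, every edge endpoint must belong to it;
        a parent id absent from ``nodes`` is reported as dangling.
        """
        g = nx.DiGraph()
        known = set(nodes) if nodes is not None else None
        if known is not None:
            g.add_nodes_from(known)
        for child, parent in edges:
            if known is not None:
                if parent not in known:
                    raise HierarchyError(f"dangling parent id: {parent!r}")
                if child not in known:
                    raise HierarchyError(f"dangling child id: {child!r}")
            g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            path = " -> ".join(str(u) for u, _ in cycle) + f" -> {cycle[-1][1]}"
            raise HierarchyError(f"hierarchy contains a cycle: {path}")
        return cls(graph=g, labels=dict(labels or {}))

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges)

    @property
    def roots(self) -> set[str]:
        # edges point child -> parent, so a root has no outgoing edge
        return {n for n in self.graph.nodes if self.graph.out_degree(n) == 0}

    @property
    def leaves(self) -> set[str]:
        """Terms with no children (the most specific level, e.g. ingredients)."""
        return {n for n in self.graph.nodes if self.graph.in_degree(n) == 0}

    def children(self, node: str) -> set[str]:
        """Direct children of a term."""
        self._require(node)
        return set(self.graph.predecessors(node))

    def parents(self, node: str) -> set[str]:
        """Direct parents of a term."""
        self._require(node)
        return set(self.graph.successors(node))

    def _require(self, node: str) -> None:
        if node not in self.graph:
            raise HierarchyError(f"unknown node: {node!r}")

    def descendants(self, node: str, include_self: bool = False) -> set[str]:
        """Transitive closure downward (all more-specific terms)."""
        self._require(node)
        # downward = against the child->parent edge direction
        out = nx.ancestors(self.graph, node)
        if include_self:
            out = out | {node}
        return out

    def ancestors(self, node: str, include_self: bool = False) -> set[str]:
        """Transitive closure upward (all more-general terms)."""
        self._require(node)
        out = nx.descendants(self.graph, node)
        if include_self:
            out = out | {node}
        return out

    def label(self, node: str) -> str:
        return self.labels.get(node, node)


def class_members(h: Hierarchy, class_id: str, universe: Iterable[str]) -> set[str]:
    """Ingredients of ``universe`` that fall under ``class_id`` (inclusive).

    An ingredient may belong to several classes; memberships overlap freely.
    """
    return set(universe) & h.descendants(class_id, include_self=True)


def propagate_ae(
    assoc: Mapping[str, set[str]],
    ae_h: Hierarchy,
    include_roots: bool = False,
) -> dict[str, set[str]]:
    """Close each ingredient's AE set under is-a ancestors.

    A drug associated with a specific AE (e.g. diarrhea) is thereby
    associated with every more general AE class above it (e.g. digestive
    system AE), so class-level statistics can be computed at any hierarchy
    level.  By default the global root term itself ("adverse event") is
    excluded: against the universal root every drug with any AE scores
    PCR = 1, which is uninformative.

    The operation is idempotent and never removes an association.
    """
    roots = ae_h.roots
    cache: dict[str, set[str]] = {}
    out: dict[str, set[str]] = {}
    for ingredient, aes in assoc.items():
        closed: set[str] = set(aes)  # originals are never removed
        for ae in aes:
            if ae not in cache:
                anc = ae_h.ancestors(ae, include_self=False)
                cache[ae] = anc if include_roots else anc - roots
            closed |= cache[ae]
        out[ingredient] = closed
    return out
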