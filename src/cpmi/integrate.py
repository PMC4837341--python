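"""Layer integration and path-based target prioritization.

The integration strategy: the component-target layer (CTPI) is combined
with the protein-protein layer into NATPI, which is combined with the
metabolite-pathway-protein layer (MPPI) into the full component-protein-
metabolite network (CPMI).  A candidate target is retained only if it
connects an active component with a metabolite biomarker: components are
the initial nodes, metabolites the terminal nodes, and the path in between
runs exclusively through protein nodes (targets and pathway proteins)
before a final pathway-metabolite edge.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass

from .model import (
    EDGE_COMPONENT_TARGET,
    EDGE_PATHWAY_METABOLITE,
    EDGE_PROTEIN_PROTEIN,
    ROLE_COMPONENT,
    ROLE_METABOLITE,
    ROLE_PATHWAY_PROTEIN,
    ROLE_TARGET,
    LayeredNetwork,
    ValidationError,
)

logger = logging.getLogger(__name__)

STRATUM_HIGH = "high"
STRATUM_MIDDLE = "middle"
STRATUM_LOW = "low"


def union_networks(a: LayeredNetwork, b: LayeredNetwork) -> LayeredNetwork:
    """Union of two layers: node role sets merge, edges deduplicate on
    (endpoints, edge_type) with provenance unioned."""
    out = a.copy()
    for node_id, roles in b.nodes.items():
        out.add_node(node_id, *roles)
    for edge in b.edges:
        out.add_edge(edge)
    out.validate()
    return out


@dataclass(frozen=True)
class TargetEvidence:
    target: str
    components: tuple[str, ...]          # linked components, sorted
    witness_path: tuple[str, ...]        # target ... metabolite
    crosses_target_nodes: bool           # witness path uses another target-role node


@dataclass(frozen=True)
class PrioritizationResult:
    retained_targets: tuple[str, ...]
    per_target_evidence: dict[str, TargetEvidence]
    network_stats: dict


def prioritize_targets(cpmi: LayeredNetwork) -> PrioritizationResult:
    """Retain the candidate targets that connect components to metabolites.

    A target t is retained iff (i) at least one component-target edge
    touches t and (ii) some metabolite is reachable from t by traversing
    protein-protein edges among protein-role nodes (targets and pathway
    proteins) followed by a single pathway-metabolite edge.  A target that
    itself carries the pathway-protein role and sits on a pathway-metabolite
    edge satisfies (ii) with a length-1 path.

    Retention is decided by reachability; one witness path per target is
    recorded for explainability, found by breadth-first search with
    lexicographically ordered neighbor expansion (deterministic, shortest).
    Output is ordered by descending component-degree, ties lexicographic.
    """
    counts = cpmi.role_counts()
    for role in (ROLE_COMPONENT, ROLE_TARGET, ROLE_PATHWAY_PROTEIN, ROLE_METABOLITE):
        if counts[role] == 0:
            raise ValidationError(f"network has no node with role {role!r}")

    protein_nodes = {
        n for n, roles in cpmi.nodes.items()
        if roles & {ROLE_TARGET, ROLE_PATHWAY_PROTEIN}
    }
    ppi_adj: dict[str, list[str]] = {n: [] for n in protein_nodes}
    for e in cpmi.edges_of_type(EDGE_PROTEIN_PROTEIN):
        if e.source in protein_nodes and e.target_node in protein_nodes:
            ppi_adj[e.source].append(e.target_node)
            ppi_adj[e.target_node].append(e.source)
    for n in ppi_adj:
        ppi_adj[n].sort()

    metab_links: dict[str, list[str]] = {}
    for e in cpmi.edges_of_type(EDGE_PATHWAY_METABOLITE):
        src_roles, dst_roles = cpmi.roles_of(e.source), cpmi.roles_of(e.target_node)
        if ROLE_METABOLITE in src_roles:
            protein, metab = e.target_node, e.source
        elif ROLE_METABOLITE in dst_roles:
            protein, metab = e.source, e.target_node
        else:  # pragma: no cover - validated networks always mark metabolites
            continue
        metab_links.setdefault(protein, []).append(metab)
    for n in metab_links:
        metab_links[n].sort()

    comp_links: dict[str, set[str]] = {}
    for e in cpmi.edges_of_type(EDGE_COMPONENT_TARGET):
        if ROLE_COMPONENT in cpmi.roles_of(e.source):
            comp, tgt = e.source, e.target_node
        else:
            comp, tgt = e.target_node, e.source
        comp_links.setdefault(tgt, set()).add(comp)

    candidates = sorted(
        t for t in comp_links
        if ROLE_TARGET in cpmi.roles_of(t)
    )

    evidence: dict[str, TargetEvidence] = {}
    for t in candidates:
        path = _bfs_witness(t, ppi_adj, metab_links)
        if path is None:
            continue
        crosses = any(
            ROLE_TARGET in cpmi.roles_of(n) for n in path[1:-1]
        )
        evidence[t] = TargetEvidence(
            target=t,
            components=tuple(sorted(comp_links[t])),
            witness_path=path,
            crosses_target_nodes=crosses,
        )

    retained = sorted(evidence, key=lambda t: (-len(evidence[t].components), t))
    stats = {
        "n_nodes": cpmi.n_nodes(),
        "n_edges": cpmi.n_edges(),
        "role_counts": counts,
        "n_retained_targets": len(retained),
    }
    return PrioritizationResult(
        retained_targets=tuple(retained),
        per_target_evidence=evidence,
        network_stats=stats,
    )


def _bfs_witness(
    start: str,
    ppi_adj: dict[str, list[str]],
    metab_links: dict[str, list[str]],
) -> tuple[str, ...] | None:
    """Shortest deterministic path start -> ... -> metabolite, or None."""
    if start not in ppi_adj:
        return None
    parent: dict[str, str | None] = {start: None}
    queue = deque([start])
    while queue:
        node = queue.popleft()
        if node in metab_links:
            path = [metab_links[node][0], node]
            up = parent[node]
            while up is not None:
                path.append(up)
                up = parent[up]
            return tuple(reversed(path))
        for nb in ppi_adj[node]:
            if nb not in parent:
                parent[nb] = node
                queue.append(nb)
    return None


def degree_stratify(ctpi: LayeredNetwork) -> dict[str, str]:
    """Classify targets by their component-degree in the CTPI.

    The degree of a target is the number of distinct component-target edges
    touching it.  Strata: 1-9 low, 10-19 middle, >= 20 high (degrees above
    the band observed in any particular dataset still map to high).  Targets
    with degree 0 are excluded with a warning.
    """
    degree: dict[str, int] = {}
    for node, roles in ctpi.nodes.items():
        if ROLE_TARGET in roles:
            degree[node] = 0
    for e in ctpi.edges_of_type(EDGE_COMPONENT_TARGET):
        for endpoint in (e.source, e.target_node):
            if endpoint in degree:
                degree[endpoint] += 1
    out = {}
    for target, d in sorted(degree.items()):
        if d == 0:
            logger.warning("target %r is isolated (degree 0); excluded from strata", target)
            continue
        if d >= 20:
            out[target] = STRATUM_HIGH
        elif d >= 10:
            out[target] = STRATUM_MIDDLE
        else:
            out[target] = STRATUM_LOW
    return out


def build_cpmi(
    ctpi: LayeredNetwork,
    ppi: LayeredNetwork,
    mppi: LayeredNetwork,
) -> LayeredNetwork:
    """CTPI + PPI -> NATPI; NATPI + MPPI -> CPMI."""
    natpi = union_networks(ctpi, ppi)
    return union_networks(natpi, mppi)
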