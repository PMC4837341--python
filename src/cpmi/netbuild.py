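"""Construction of the three evidence layers.

* CTPI — component-target protein interactions from docking (positive-control
  cutoff rule) merged with curated text-mining edges.
* PPI — protein-protein interactions kept above a confidence threshold
  (STRING-style "high confidence" > 0.8).
* MPPI — metabolite biomarkers linked to the proteins of their significantly
  enriched pathways, extended to those proteins' nearest PPI neighbors.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import pandas as pd

from .model import (
    EDGE_COMPONENT_TARGET,
    EDGE_PATHWAY_METABOLITE,
    EDGE_PROTEIN_PROTEIN,
    ROLE_COMPONENT,
    ROLE_METABOLITE,
    ROLE_PATHWAY_PROTEIN,
    ROLE_TARGET,
    DockRecord,
    LayeredNetwork,
    TypedEdge,
    ValidationError,
)

logger = logging.getLogger(__name__)

GREATER_BETTER = "greater_better"
LESSER_BETTER = "lesser_better"


def apply_dock_cutoff(
    records: Iterable[DockRecord],
    orientation: Mapping[str, str],
    tolerance: float = 0.0,
) -> list[TypedEdge]:
    """Emit a component-target edge for every dock score that beats the
    protein's positive-control score.

    The positive control is the co-crystallized ligand of the protein
    structure; its score defines a per-protein cutoff.  A component passes
    only if its score *strictly* beats the cutoff in the engine's favorable
    direction (``greater_better`` engines maximize, ``lesser_better``
    minimize).  ``tolerance`` >= 0 loosens the comparison for engines with
    coarse score grids: a score within ``tolerance`` of the cutoff on the
    unfavorable side still passes.  Default 0 keeps the comparison strict.
    """
    if tolerance < 0:
        raise ValueError(f"tolerance must be >= 0, got {tolerance}")
    records = list(records)
    unknown = {r.engine for r in records} - set(orientation)
    if unknown:
        raise ValidationError(f"no score orientation declared for engines {sorted(unknown)}")
    bad_orient = {e: o for e, o in orientation.items() if o not in (GREATER_BETTER, LESSER_BETTER)}
    if bad_orient:
        raise ValidationError(f"invalid orientations: {bad_orient}")
    missing = sorted(
        {r.protein_id for r in records
         if r.positive_control_score is None or pd.isna(r.positive_control_score)}
    )
    if missing:
        raise ValidationError(f"missing positive-control score for proteins {missing}")

    edges: list[TypedEdge] = []
    for r in records:
        if orientation[r.engine] == GREATER_BETTER:
            hit = r.score > r.positive_control_score - tolerance
        else:
            hit = r.score < r.positive_control_score + tolerance
        if hit:
            edges.append(
                TypedEdge(
                    source=r.component_id,
                    target_node=r.protein_id,
                    edge_type=EDGE_COMPONENT_TARGET,
                    provenance=frozenset({"dock"}),
                )
            )
    return edges


def merge_ctpi(
    dock_edges: Iterable[TypedEdge],
    text_edges: Iterable[TypedEdge],
    catalog_ids: set[str] | None = None,
) -> LayeredNetwork:
    """Merge docking and text-mining evidence into the CTPI network.

    Duplicate (component, protein) pairs collapse to a single edge whose
    provenance is the union — a pair supported by both sources carries
    {text, dock}, the "found by both" class.  Edge ids are authoritative:
    a component id absent from the supplied catalog is included with a
    logged warning rather than dropped.
    """
    net = LayeredNetwork()
    for edge in list(dock_edges) + list(text_edges):
        if edge.edge_type != EDGE_COMPONENT_TARGET:
            raise ValidationError(
                f"merge_ctpi expects component-target edges, got {edge.edge_type!r}"
            )
        if catalog_ids is not None and edge.source not in catalog_ids:
            logger.warning(
                "component %r not in catalog; edge kept (ids are authoritative)",
                edge.source,
            )
        net.add_edge(edge)
        net.add_node(edge.source, ROLE_COMPONENT)
        net.add_node(edge.target_node, ROLE_TARGET)
    net.validate()
    return net


def filter_ppi(edges: pd.DataFrame, min_conf: float = 0.8) -> LayeredNetwork:
    """Build the PPI layer, retaining edges with confidence strictly above
    ``min_conf``.

    ``edges`` needs columns ``protein_a, protein_b, combined_score``.
    Scores must lie in (0, 1]; STRING exports on the 0-1000 scale are
    rescaled by :func:`cpmi.io.read_ppi_table` before reaching here.
    """
    required = {"protein_a", "protein_b", "combined_score"}
    if not required <= set(edges.columns):
        raise ValidationError(f"PPI table needs columns {sorted(required)}")
    bad = edges[(edges["combined_score"] <= 0) | (edges["combined_score"] > 1)]
    if len(bad):
        raise ValidationError(
            f"confidence outside (0, 1] in rows {list(bad.index)}: "
            f"{bad['combined_score'].tolist()}"
        )
    net = LayeredNetwork()
    kept = edges[edges["combined_score"] > min_conf]
    for row in kept.itertuples(index=False):
        net.add_edge(
            TypedEdge(
                source=str(row.protein_a),
                target_node=str(row.protein_b),
                edge_type=EDGE_PROTEIN_PROTEIN,
                confidence=float(row.combined_score),
            )
        )
    net.validate()
    return net


def build_mppi(
    metabolite_pathways: pd.DataFrame,
    memberships: pd.DataFrame,
    ppi: LayeredNetwork,
    alpha: float = 0.05,
    neighbor_depth: int = 1,
) -> LayeredNetwork:
    """Build the metabolite-pathway-protein interaction network.

    For every (metabolite, pathway) enrichment row with p strictly below
    ``alpha``, the pathway's member proteins join as pathway-protein nodes
    linked to the metabolite.  Each member is then extended to its PPI
    neighbors up to ``neighbor_depth`` hops (default 1, matching the
    "add nearest interactors" convention); neighbors join as
    pathway-protein nodes linked through the corresponding PPI edges.
    Metabolites with no surviving pathway are absent from the result.
    """
    for col in ("metabolite", "pathway", "p"):
        if col not in metabolite_pathways.columns:
            raise ValidationError(f"enrichment table missing column {col!r}")
    for col in ("pathway", "protein"):
        if col not in memberships.columns:
            raise ValidationError(f"membership table missing column {col!r}")
    pvals = metabolite_pathways["p"]
    if ((pvals < 0) | (pvals > 1)).any():
        raise ValidationError("enrichment p-values must lie in [0, 1]")

    members_by_pathway = {
        pw: sorted(set(group["protein"].astype(str)))
        for pw, group in memberships.groupby("pathway")
    }
    net = LayeredNetwork()
    significant = metabolite_pathways[metabolite_pathways["p"] < alpha]
    for row in significant.itertuples(index=False):
        members = members_by_pathway.get(row.pathway)
        if not members:
            logger.warning(
                "pathway %r enriched (p=%g) but has no membership rows; skipped",
                row.pathway, row.p,
            )
            continue
        metabolite = str(row.metabolite)
        net.add_node(metabolite, ROLE_METABOLITE)
        for protein in members:
            net.add_node(protein, ROLE_PATHWAY_PROTEIN)
            net.add_edge(
                TypedEdge(
                    source=metabolite,
                    target_node=protein,
                    edge_type=EDGE_PATHWAY_METABOLITE,
                    provenance=frozenset({"curated"}),
                )
            )
            # extend to PPI neighbors, breadth-first up to neighbor_depth hops
            frontier = [protein]
            seen = {protein}
            for _ in range(neighbor_depth):
                next_frontier = []
                for node in frontier:
                    for nb in ppi.neighbors(node, EDGE_PROTEIN_PROTEIN):
                        conf = _ppi_confidence(ppi, node, nb)
                        net.add_node(nb, ROLE_PATHWAY_PROTEIN)
                        net.add_edge(
                            TypedEdge(
                                source=node,
                                target_node=nb,
                                edge_type=EDGE_PROTEIN_PROTEIN,
                                confidence=conf,
                            )
                        )
                        if nb not in seen:
                            seen.add(nb)
                            next_frontier.append(nb)
                frontier = next_frontier
    net.validate()
    return net


def _ppi_confidence(ppi: LayeredNetwork, a: str, b: str) -> float:
    edge = ppi._edges[(frozenset((a, b)), EDGE_PROTEIN_PROTEIN)]
    return edge.confidence
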