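"""End-to-end convenience wrapper: tables in, prioritized targets out."""

from __future__ import annotations

from dataclasses import dataclass

from .integrate import PrioritizationResult, build_cpmi, prioritize_targets
from .model import EDGE_COMPONENT_TARGET, LayeredNetwork, TypedEdge
from .netbuild import apply_dock_cutoff, build_mppi, filter_ppi, merge_ctpi
from .synthdata import FixtureBundle


@dataclass
class PipelineResult:
    ctpi: LayeredNetwork
    ppi: LayeredNetwork
    mppi: LayeredNetwork
    cpmi: LayeredNetwork
    prioritization: PrioritizationResult


def text_edges_from_frame(df) -> list[TypedEdge]:
    """Curated text-mining edge list (component_id, protein_id) -> TypedEdges."""
    return [
        TypedEdge(
            source=str(row.component_id),
            target_node=str(row.protein_id),
            edge_type=EDGE_COMPONENT_TARGET,
            provenance=frozenset({"text"}),
        )
        for row in df.itertuples(index=False)
    ]


def dock_records_from_frame(df):
    from .model import DockRecord

    return [
        DockRecord(
            component_id=str(row.component_id),
            protein_id=str(row.protein_id),
            score=float(row.score),
            positive_control_score=float(row.positive_control_score),
            engine=str(row.engine),
        )
        for row in df.itertuples(index=False)
    ]


def run_pipeline(
    bundle: FixtureBundle,
    min_conf: float = 0.8,
    alpha: float = 0.05,
    neighbor_depth: int = 1,
) -> PipelineResult:
    """Run dock cutoff -> CTPI merge -> PPI filter -> MPPI -> CPMI ->
    prioritization on a fixture bundle with the standard thresholds."""
    dock_edges = apply_dock_cutoff(dock_records_from_frame(bundle.dock), bundle.orientation)
    ctpi = merge_ctpi(
        dock_edges,
        text_edges_from_frame(bundle.text_edges),
        catalog_ids=set(bundle.components["id"]),
    )
    ppi = filter_ppi(bundle.ppi, min_conf=min_conf)
    mppi = build_mppi(
        bundle.metabolite_pathways, bundle.memberships, ppi,
        alpha=alpha, neighbor_depth=neighbor_depth,
    )
    cpmi = build_cpmi(ctpi, ppi, mppi)
    return PipelineResult(
        ctpi=ctpi, ppi=ppi, mppi=mppi, cpmi=cpmi,
        prioritization=prioritize_targets(cpmi),
    )
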