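"""Evidence-layer construction: dock cutoff, CTPI merge, PPI filter, MPPI."""

import pandas as pd
import pytest

from cpmi.model import (
    EDGE_COMPONENT_TARGET,
    EDGE_PROTEIN_PROTEIN,
    DockRecord,
    TypedEdge,
    ValidationError,
)
from cpmi.netbuild import (
    GREATER_BETTER,
    LESSER_BETTER,
    apply_dock_cutoff,
    build_mppi,
    filter_ppi,
    merge_ctpi,
)

ORIENT = {"libdock": GREATER_BETTER, "vina": LESSER_BETTER}


def _rec(score, control, engine="libdock", comp="c1", prot="t1"):
    return DockRecord(component_id=comp, protein_id=prot, score=score,
                      positive_control_score=control, engine=engine)


class TestDockCutoff:
    @pytest.mark.parametrize(
        "score,control,engine,expected",
        [
            (62.0, 55.0, "libdock", True),   # beats the positive control
            (55.0, 55.0, "libdock", False),  # ties are not hits (strict)
            (54.9, 55.0, "libdock", False),
            (-9.1, -8.0, "vina", True),      # minimizing engine, orientation flip
            (-8.0, -8.0, "vina", False),
            (-7.0, -8.0, "vina", False),
        ],
    )
    def test_strict_positive_control_rule(self, score, control, engine, expected):
        edges = apply_dock_cutoff([_rec(score, control, engine)], ORIENT)
        assert bool(edges) is expected
        if edges:
            assert edges[0].provenance == frozenset({"dock"})

    def test_unknown_engine_rejected(self):
        with pytest.raises(ValidationError, match="mystery"):
            apply_dock_cutoff([_rec(1.0, 0.0, "mystery")], ORIENT)

    def test_missing_positive_control_names_protein(self):
        rec = _rec(60.0, float("nan"), prot="TNF")
        with pytest.raises(ValidationError, match="TNF"):
            apply_dock_cutoff([rec], ORIENT)

    def test_invariant_under_order_preserving_affine_rescale(self, rng):
        records = [
            _rec(float(rng.uniform(40, 80)), float(rng.uniform(40, 80)), prot=f"t{i}")
            for i in range(30)
        ]
        base = {(e.source, e.target_node) for e in apply_dock_cutoff(records, ORIENT)}
        a, b = 2.5, -7.0  # positive slope preserves order
        scaled = [
            DockRecord(r.component_id, r.protein_id, a * r.score + b,
                       a * r.positive_control_score + b, r.engine)
            for r in records
        ]
        rescaled = {(e.source, e.target_node) for e in apply_dock_cutoff(scaled, ORIENT)}
        assert base == rescaled

    def test_tolerance_loosens_comparison(self):
        assert not apply_dock_cutoff([_rec(54.5, 55.0)], ORIENT)
        assert apply_dock_cutoff([_rec(54.5, 55.0)], ORIENT, tolerance=1.0)


def _ct(comp, prot, prov):
    return TypedEdge(comp, prot, EDGE_COMPONENT_TARGET, provenance=frozenset(prov))


class TestMergeCtpi:
    def test_dock_and_text_union_to_both(self):
        net = merge_ctpi([_ct("c1", "t1", {"dock"})], [_ct("c1", "t1", {"text"})])
        assert net.n_edges() == 1
        assert net.edges[0].provenance == frozenset({"dock", "text"})

    def test_merge_is_commutative_and_idempotent(self):
        dock = [_ct("c1", "t1", {"dock"}), _ct("c2", "t1", {"dock"})]
        text = [_ct("c1", "t2", {"text"}), _ct("c1", "t1", {"text"})]

        def signature(net):
            return {(e.key, e.provenance) for e in net.edges}

        ab = merge_ctpi(dock, text)
        ba = merge_ctpi(text, dock)
        twice = merge_ctpi(dock + dock, text + text)
        assert signature(ab) == signature(ba) == signature(twice)

    def test_duplicates_within_one_source_deduplicate(self):
        net = merge_ctpi([_ct("c1", "t1", {"dock"})] * 3, [])
        assert net.n_edges() == 1

    def test_disjoint_node_count_is_union_arithmetic(self):
        edges = [_ct(f"c{i}", f"t{j}", {"dock"}) for i in range(4) for j in range(3)]
        net = merge_ctpi(edges, [])
        assert net.n_nodes() == 4 + 3

    def test_non_component_target_edge_rejected(self):
        ppi_edge = TypedEdge("a", "b", EDGE_PROTEIN_PROTEIN, confidence=0.9)
        with pytest.raises(ValidationError):
            merge_ctpi([ppi_edge], [])

    def test_component_missing_from_catalog_kept_with_warning(self, caplog):
        net = merge_ctpi([_ct("ghost", "t1", {"dock"})], [], catalog_ids={"c1"})
        assert "ghost" in net.nodes
        assert any("ghost" in r.message for r in caplog.records)


class TestFilterPpi:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["protein_a", "protein_b", "combined_score"])

    def test_strictly_above_threshold_retained(self):
        net = filter_ppi(self._frame([("a", "b", 0.9), ("b", "c", 0.8), ("c", "d", 0.79)]))
        assert {frozenset((e.source, e.target_node)) for e in net.edges} == {
            frozenset(("a", "b"))
        }

    def test_empty_input_gives_empty_network(self):
        net = filter_ppi(self._frame([]))
        assert net.n_nodes() == 0 and net.n_edges() == 0

    def test_out_of_range_confidence_rejected(self):
        with pytest.raises(ValidationError, match="confidence"):
            filter_ppi(self._frame([("a", "b", 1.5)]))
        with pytest.raises(ValidationError, match="confidence"):
            filter_ppi(self._frame([("a", "b", 0.0)]))

    def test_raising_threshold_is_monotone(self, rng):
        rows = [(f"a{i}", f"b{i}", float(rng.uniform(0.01, 1.0))) for i in range(50)]
        frame = self._frame(rows)
        previous = None
        for min_conf in (0.2, 0.5, 0.8, 0.95):
            kept = {e.key for e in filter_ppi(frame, min_conf=min_conf).edges}
            if previous is not None:
                assert kept <= previous
            previous = kept


class TestBuildMppi:
    def _inputs(self):
        met = pd.DataFrame(
            [("m1", "pw1", 0.04), ("m1", "pw2", 0.05), ("m2", "pw3", 0.2)],
            columns=["metabolite", "pathway", "p"],
        )
        members = pd.DataFrame(
            [("pw1", "A"), ("pw2", "B"), ("pw3", "C")], columns=["pathway", "protein"]
        )
        ppi = filter_ppi(pd.DataFrame([("A", "N", 0.95)],
                                      columns=["protein_a", "protein_b", "combined_score"]))
        return met, members, ppi

    def test_alpha_is_strict_and_neighbors_extend(self):
        met, members, ppi = self._inputs()
        net = build_mppi(met, members, ppi)
        # pw1 at p=0.04 survives; pw2 at exactly 0.05 and pw3 at 0.2 do not
        assert "A" in net.nodes and "B" not in net.nodes and "C" not in net.nodes
        assert "m2" not in net.nodes
        # A's PPI neighbor N joins as pathway protein linked to A
        assert "N" in net.nodes
        assert "pathway_protein" in net.roles_of("N")
        assert (frozenset(("A", "N")), EDGE_PROTEIN_PROTEIN) in {e.key for e in net.edges}

    def test_enriched_pathway_without_membership_skipped_with_warning(self, caplog):
        met = pd.DataFrame([("m1", "orphan", 0.01)], columns=["metabolite", "pathway", "p"])
        members = pd.DataFrame([], columns=["pathway", "protein"])
        net = build_mppi(met, members, filter_ppi(pd.DataFrame(
            [], columns=["protein_a", "protein_b", "combined_score"])))
        assert net.n_nodes() == 0
        assert any("orphan" in r.message for r in caplog.records)

    def test_neighbor_depth_zero_adds_no_neighbors(self):
        met, members, ppi = self._inputs()
        net = build_mppi(met, members, ppi, neighbor_depth=0)
        assert "N" not in net.nodes

    def test_lowering_alpha_is_monotone(self):
        met, members, ppi = self._inputs()
        previous = None
        for alpha in (0.5, 0.1, 0.05, 0.01):
            net = build_mppi(met, members, ppi, alpha=alpha)
            nodes = set(net.nodes)
            if previous is not None:
                assert nodes <= previous
            previous = nodes

    def test_invalid_pvalues_rejected(self):
        met = pd.DataFrame([("m1", "pw1", 1.2)], columns=["metabolite", "pathway", "p"])
        members = pd.DataFrame([("pw1", "A")], columns=["pathway", "protein"])
        with pytest.raises(ValidationError, match="p-values"):
            build_mppi(met, members, filter_ppi(pd.DataFrame(
                [], columns=["protein_a", "protein_b", "combined_score"])))
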