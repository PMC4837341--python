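"""Core domain types shared across the toolkit.

The central container is :class:`LayeredNetwork`, a role-annotated undirected
multigraph used for every evidence layer (component-target, protein-protein,
metabolite-pathway-protein) as well as their integrated unions.  Nodes carry a
*set* of roles because a protein can legitimately be both a candidate drug
target and a member of a metabolite's enriched pathway.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

# Node roles
ROLE_COMPONENT = "component"
ROLE_TARGET = "target"
ROLE_PATHWAY_PROTEIN = "pathway_protein"
ROLE_METABOLITE = "metabolite"
ROLES = frozenset({ROLE_COMPONENT, ROLE_TARGET, ROLE_PATHWAY_PROTEIN, ROLE_METABOLITE})

# Edge types
EDGE_COMPONENT_TARGET = "component-target"
EDGE_PROTEIN_PROTEIN = "protein-protein"
EDGE_PATHWAY_METABOLITE = "pathway-metabolite"
EDGE_TYPES = frozenset({EDGE_COMPONENT_TARGET, EDGE_PROTEIN_PROTEIN, EDGE_PATHWAY_METABOLITE})

# Evidence provenance tags
PROVENANCES = frozenset({"text", "dock", "curated"})

HERB_CLASSES = frozenset({"S", "J", "H", "Z"})

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ValidationError(ValueError):
    """Raised when an input record or network violates a documented invariant."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a molecular formula like ``C34H47NO11`` into element counts.

    Raises :class:`ValidationError` if the string contains anything other
    than element symbols with optional positive counts.
    """
    if not formula or not isinstance(formula, str):
        raise ValidationError(f"empty or non-string formula: {formula!r}")
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValidationError(f"unparseable formula {formula!r} at position {pos}")
        if not m.group(0):
            break
        n = int(m.group(2)) if m.group(2) else 1
        if n <= 0:
            raise ValidationError(f"non-positive atom count in formula {formula!r}")
        counts[m.group(1)] = counts.get(m.group(1), 0) + n
        pos = m.end()
    if pos != len(formula) or not counts:
        raise ValidationError(f"unparseable formula {formula!r}")
    return counts


@dataclass(frozen=True)
class Component:
    """An active compound from the herb catalog.

    ``herb_class`` is the one-letter chemotype code embedded in the serial
    id: S alkaloids, J gingerols, H flavones, Z saponins.
    """

    id: str
    name: str
    formula: str
    herb_class: str
    structure: str | None = None

    def __post_init__(self) -> None:
        if self.herb_class not in HERB_CLASSES:
            raise ValidationError(
                f"component {self.id!r}: herb_class {self.herb_class!r} "
                f"not one of {sorted(HERB_CLASSES)}"
            )
        parse_formula(self.formula)


@dataclass(frozen=True)
class DescriptorVector:
    """The seven physicochemical descriptors used for chemical-space mapping."""

    mw: float
    n_aromatic_rings: int
    n_hbd: int
    n_hba: int
    psa: float
    n_rotatable: int
    alogp: float

    FIELDS = ("mw", "n_aromatic_rings", "n_hbd", "n_hba", "psa", "n_rotatable", "alogp")

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValidationError(f"molecular weight must be positive, got {self.mw}")
        if self.psa < 0:
            raise ValidationError(f"polar surface area must be >= 0, got {self.psa}")
        for name in ("n_aromatic_rings", "n_hbd", "n_hba", "n_rotatable"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValidationError(f"{name} must be a non-negative integer, got {v}")


@dataclass(frozen=True)
class StatComparison:
    descriptor_name: str
    ks_statistic: float
    ks_p: float
    ranksum_statistic: float
    ranksum_p: float


@dataclass(frozen=True)
class SimilarityMatch:
    query_id: str
    library_id: str
    tanimoto: float


@dataclass(frozen=True)
class DockRecord:
    """One component-vs-protein docking score paired with the per-protein
    positive-control (co-crystallized ligand) score that defines the cutoff."""

    component_id: str
    protein_id: str
    score: float
    positive_control_score: float
    engine: str

    def __post_init__(self) -> None:
        if not self.engine:
            raise ValidationError(
                f"dock record {self.component_id}-{self.protein_id}: empty engine tag"
            )


@dataclass(frozen=True)
class TypedEdge:
    """Undirected, typed, provenance-tagged edge."""

    source: str
    target_node: str
    edge_type: str
    provenance: frozenset[str] = frozenset()
    confidence: float | None = None

    def __post_init__(self) -> None:
        if self.edge_type not in EDGE_TYPES:
            raise ValidationError(f"unknown edge type {self.edge_type!r}")
        if self.source == self.target_node:
            raise ValidationError(f"self-edge on {self.source!r} is not allowed")
        if not self.provenance <= PROVENANCES:
            raise ValidationError(
                f"unknown provenance tags {set(self.provenance) - PROVENANCES}"
            )
        if self.edge_type == EDGE_COMPONENT_TARGET and not self.provenance:
            raise ValidationError(
                f"component-target edge {self.source}-{self.target_node} "
                "must carry non-empty provenance"
            )
        if self.edge_type == EDGE_PROTEIN_PROTEIN:
            if self.confidence is None:
                raise ValidationError(
                    f"protein-protein edge {self.source}-{self.target_node} "
                    "must carry a confidence"
                )
        if self.confidence is not None and not (0.0 < self.confidence <= 1.0):
            raise ValidationError(
                f"edge {self.source}-{self.target_node}: confidence "
                f"{self.confidence} outside (0, 1]"
            )

    @property
    def key(self) -> tuple[frozenset[str], str]:
        """Deduplication key: unordered endpoints plus edge type."""
        return (frozenset((self.source, self.target_node)), self.edge_type)


@dataclass
class LayeredNetwork:
    """Role-annotated undirected network.

    ``nodes`` maps a case-sensitive node id to its role set; ``edges`` holds
    typed edges deduplicated on (endpoints, edge_type).  Merging the same
    edge twice unions provenance and keeps the maximum confidence.
    """

    nodes: dict[str, set[str]] = field(default_factory=dict)
    _edges: dict[tuple[frozenset[str], str], TypedEdge] = field(default_factory=dict)

    @property
    def edges(self) -> list[TypedEdge]:
        return list(self._edges.values())

    def add_node(self, node_id: str, *roles: str) -> None:
        bad = set(roles) - ROLES
        if bad:
            raise ValidationError(f"unknown roles {bad} for node {node_id!r}")
        self.nodes.setdefault(node_id, set()).update(roles)

    def add_edge(self, edge: TypedEdge) -> None:
        for endpoint in (edge.source, edge.target_node):
            self.nodes.setdefault(endpoint, set())
        prior = self._edges.get(edge.key)
        if prior is not None:
            provenance = prior.provenance | edge.provenance
            confs = [c for c in (prior.confidence, edge.confidence) if c is not None]
            edge = replace(prior, provenance=provenance,
                           confidence=max(confs) if confs else None)
        self._edges[edge.key] = edge

    def roles_of(self, node_id: str) -> set[str]:
        return self.nodes.get(node_id, set())

    def n_nodes(self) -> int:
        return len(self.nodes)

    def n_edges(self) -> int:
        return len(self._edges)

    def role_counts(self) -> dict[str, int]:
        counts = {role: 0 for role in sorted(ROLES)}
        for roles in self.nodes.values():
            for role in roles:
                counts[role] += 1
        return counts

    def edges_of_type(self, edge_type: str) -> list[TypedEdge]:
        return [e for e in self._edges.values() if e.edge_type == edge_type]

    def neighbors(self, node_id: str, edge_type: str | None = None) -> list[str]:
        """Sorted neighbor list, optionally restricted to one edge type."""
        out = set()
        for e in self._edges.values():
            if edge_type is not None and e.edge_type != edge_type:
                continue
            if e.source == node_id:
                out.add(e.target_node)
            elif e.target_node == node_id:
                out.add(e.source)
        return sorted(out)

    def copy(self) -> "LayeredNetwork":
        out = LayeredNetwork()
        out.nodes = {k: set(v) for k, v in self.nodes.items()}
        out._edges = dict(self._edges)
        return out

    def validate(self) -> None:
        """Check the structural invariants; raise ValidationError on breach."""
        for key, edge in self._edges.items():
            for endpoint in key[0]:
                if endpoint not in self.nodes:
                    raise ValidationError(
                        f"edge endpoint {endpoint!r} missing from node table"
                    )
        for node_id, roles in self.nodes.items():
            if not roles <= ROLES:
                raise ValidationError(f"node {node_id!r} has unknown roles {roles - ROLES}")

    def to_networkx(self):
        """Export to a networkx.Graph with role/type attributes."""
        import networkx as nx

        g = nx.Graph()
        for node_id, roles in self.nodes.items():
            g.add_node(node_id, roles=",".join(sorted(roles)))
        for e in self._edges.values():
            attrs = {"edge_type": e.edge_type, "provenance": ",".join(sorted(e.provenance))}
            if e.confidence is not None:
                attrs["confidence"] = e.confidence
            g.add_edge(e.source, e.target_node, **attrs)
        return g


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric over-representation result for one annotation term."""

    term_id: str
    term_name: str
    k: int
    K: int
    n: int
    N: int
    p: float
    key: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.K, self.n)):
            raise ValidationError(
                f"term {self.term_id}: overlap k={self.k} exceeds min(K={self.K}, n={self.n})"
            )
        if not (0.0 <= self.p <= 1.0):
            raise ValidationError(f"term {self.term_id}: p={self.p} outside [0, 1]")


@dataclass(frozen=True)
class BindingFit:
    """Fitted 1:1 steady-state binding model R(C) = rmax * C / (kd + C)."""

    kd: float
    rmax: float
    residual_sse: float
    n_points: int

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValidationError(f"kd must be positive, got {self.kd}")
        if self.rmax <= 0:
            raise ValidationError(f"rmax must be positive, got {self.rmax}")
        if self.residual_sse < 0:
            raise ValidationError(f"residual SSE must be >= 0, got {self.residual_sse}")
        if self.n_points < 3:
            raise ValidationError(f"need >= 3 points, got {self.n_points}")
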