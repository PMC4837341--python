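"""Independent brute-force oracles used to check the implementation.

These deliberately avoid the code paths they verify: reachability is done
by exhaustive simple-path enumeration, the hypergeometric tail by direct
subset enumeration, molar mass by atomic-weight summation over a parsed
formula, and rank-sum p-values by enumerating every rank assignment.
"""

from __future__ import annotations

import itertools
import math
import re

import numpy as np

from cpmi.model import (
    EDGE_COMPONENT_TARGET,
    EDGE_PATHWAY_METABOLITE,
    EDGE_PROTEIN_PROTEIN,
    ROLE_COMPONENT,
    ROLE_METABOLITE,
    ROLE_PATHWAY_PROTEIN,
    ROLE_TARGET,
    LayeredNetwork,
    TypedEdge,
)

ATOMIC_WEIGHTS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}


def molar_mass(formula: str) -> float:
    """Sum of standard atomic weights over a CxHyNzOw formula."""
    total = 0.0
    for sym, count in re.findall(r"([A-Z][a-z]?)(\d*)", formula):
        if sym:
            total += ATOMIC_WEIGHTS[sym] * (int(count) if count else 1)
    return total


def simple_path_retained_targets(net: LayeredNetwork) -> set[str]:
    """Targets connecting a component to a metabolite, by exhaustive
    enumeration of simple protein paths (no BFS reuse)."""
    protein_nodes = {
        n for n, roles in net.nodes.items()
        if roles & {ROLE_TARGET, ROLE_PATHWAY_PROTEIN}
    }
    adj: dict[str, set[str]] = {n: set() for n in protein_nodes}
    for e in net.edges:
        if e.edge_type == EDGE_PROTEIN_PROTEIN:
            if e.source in protein_nodes and e.target_node in protein_nodes:
                adj[e.source].add(e.target_node)
                adj[e.target_node].add(e.source)
    terminal = set()
    for e in net.edges:
        if e.edge_type == EDGE_PATHWAY_METABOLITE:
            for a, b in ((e.source, e.target_node), (e.target_node, e.source)):
                if ROLE_METABOLITE in net.roles_of(b) and a in protein_nodes:
                    terminal.add(a)
    has_component = set()
    for e in net.edges:
        if e.edge_type == EDGE_COMPONENT_TARGET:
            for a, b in ((e.source, e.target_node), (e.target_node, e.source)):
                if ROLE_COMPONENT in net.roles_of(a) and ROLE_TARGET in net.roles_of(b):
                    has_component.add(b)

    def reaches(start: str) -> bool:
        # depth-first enumeration of all simple paths from start
        stack = [(start, {start})]
        while stack:
            node, visited = stack.pop()
            if node in terminal:
                return True
            for nb in adj[node]:
                if nb not in visited:
                    stack.append((nb, visited | {nb}))
        return False

    return {t for t in has_component if t in protein_nodes and reaches(t)}


def random_layered_network(rng: np.random.Generator, max_nodes: int = 40) -> LayeredNetwork:
    """A random four-role network with occasional dual-role proteins."""
    n_c = int(rng.integers(1, 6))
    n_t = int(rng.integers(1, 9))
    n_p = int(rng.integers(1, 9))
    n_m = int(rng.integers(1, 4))
    assert n_c + n_t + n_p + n_m <= max_nodes
    comps = [f"c{i}" for i in range(n_c)]
    targets = [f"t{i}" for i in range(n_t)]
    prots = [f"p{i}" for i in range(n_p)]
    metabs = [f"m{i}" for i in range(n_m)]
    net = LayeredNetwork()
    for c in comps:
        net.add_node(c, ROLE_COMPONENT)
    for t in targets:
        net.add_node(t, ROLE_TARGET)
        if rng.random() < 0.2:  # dual-role like GATM
            net.add_node(t, ROLE_PATHWAY_PROTEIN)
    for p in prots:
        net.add_node(p, ROLE_PATHWAY_PROTEIN)
    for m in metabs:
        net.add_node(m, ROLE_METABOLITE)
    for c, t in itertools.product(comps, targets):
        if rng.random() < 0.4:
            net.add_edge(TypedEdge(c, t, EDGE_COMPONENT_TARGET,
                                   provenance=frozenset({"dock"})))
    proteins = targets + prots
    for a, b in itertools.combinations(proteins, 2):
        if rng.random() < 0.15:
            net.add_edge(TypedEdge(a, b, EDGE_PROTEIN_PROTEIN,
                                   confidence=float(rng.uniform(0.81, 0.99))))
    for p, m in itertools.product(proteins, metabs):
        if rng.random() < 0.1:
            if ROLE_PATHWAY_PROTEIN not in net.roles_of(p):
                net.add_node(p, ROLE_PATHWAY_PROTEIN)
            net.add_edge(TypedEdge(p, m, EDGE_PATHWAY_METABOLITE,
                                   provenance=frozenset({"curated"})))
    return net


def hypergeom_upper_tail_by_enumeration(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), by summing the pmf computed
    from binomial coefficients."""
    if k <= 0:
        return 1.0
    total = 0
    for i in range(k, min(K, n) + 1):
        total += math.comb(K, i) * math.comb(N - K, n - i)
    return total / math.comb(N, n)


def hypergeom_upper_tail_by_subsets(N: int, K: int, n: int, k: int) -> float:
    """Same tail, by enumerating every n-subset of an N-universe."""
    if k <= 0:
        return 1.0
    universe = list(range(N))
    annotated = set(range(K))
    hits = sum(
        1 for subset in itertools.combinations(universe, n)
        if len(annotated.intersection(subset)) >= k
    )
    return hits / math.comb(N, n)


def ranksum_p_by_enumeration(a: list[float], b: list[float]) -> float:
    """Two-sided Mann-Whitney p by enumerating all rank assignments of the
    pooled sample (assumes no ties across the pool)."""
    pooled = sorted(a + b)
    n_a = len(a)
    u_obs = _u_stat(a, b)
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        a_vals = [pooled[i] for i in combo]
        b_vals = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = _u_stat(a_vals, b_vals)
        n_ab = len(a_vals) * len(b_vals)
        if min(u, n_ab - u) <= min(u_obs, len(a) * len(b) - u_obs):
            count += 1
        total += 1
    return count / total


def _u_stat(a, b) -> float:
    return sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in a for y in b)


def ks_stat_by_enumeration(a: list[float], b: list[float]) -> float:
    """Max absolute ECDF difference evaluated at every pooled point."""
    points = sorted(set(a) | set(b))
    best = 0.0
    for x in points:
        fa = sum(v <= x for v in a) / len(a)
        fb = sum(v <= x for v in b) / len(b)
        best = max(best, abs(fa - fb))
    return best
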