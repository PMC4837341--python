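"""Packaged catalog and seeded synthetic input bundles.

Two jobs: load the transcribed 48-compound herb catalog that ships with
the package, and generate complete synthetic input bundles (catalog, dock
table, text-mining edges, PPI, metabolite-pathway enrichment, pathway
membership, annotations) with a *planted* set of connected targets.  The
planted truth is enforced constructively: connected targets are wired to
a metabolite through the pathway-protein backbone, decoy targets are
wired so that they miss either the component edge or the metabolite path,
and random extra edges are only drawn inside groups that cannot create an
accidental component-to-metabolite route.  The generated bundle therefore
exercises every pipeline stage with a known answer.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import Component, ValidationError
from .netbuild import GREATER_BETTER, LESSER_BETTER

ENGINE_ORIENTATION = {"libdock": GREATER_BETTER, "vina": LESSER_BETTER}

_HERB_CYCLE = ("S", "J", "H", "Z")


def load_table1() -> pd.DataFrame:
    """Load the packaged 48-compound catalog.

    Columns: id, name, formula, herb_class, structure (structure is a
    SMILES string where a vetted one is available, else empty).  The
    herb-class letter is the serial-number prefix: S alkaloids, J
    gingerols, H flavones, Z saponins.
    """
    ref = importlib.resources.files("cpmi.data") / "table1_components.tsv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return df


def components_from_frame(df: pd.DataFrame) -> list[Component]:
    """Validate a catalog DataFrame into Component records."""
    if df["id"].duplicated().any():
        dupes = sorted(df.loc[df["id"].duplicated(), "id"])
        raise ValidationError(f"duplicate component ids: {dupes}")
    return [
        Component(
            id=row.id, name=row.name_, formula=row.formula,
            herb_class=row.herb_class, structure=row.structure or None,
        )
        for row in df.rename(columns={"name": "name_"}).itertuples(index=False)
    ]


@dataclass(frozen=True)
class FixtureConfig:
    """Shape of a synthetic input bundle.

    Defaults mirror the layer sizes of the motivating study: 48 components,
    61 candidate targets of which 25 connect through to a metabolite, 44
    pathway proteins and 13 metabolite biomarkers.  ``dock_hit_rate`` and
    ``text_hit_rate`` are the per-(component, target) probabilities that
    docking respectively text mining supply an edge (a pair may get both).
    """

    n_components: int = 48
    n_targets: int = 61
    n_pathway_proteins: int = 44
    n_metabolites: int = 13
    n_connected_targets: int = 25
    dock_hit_rate: float = 0.12
    text_hit_rate: float = 0.10
    ppi_density: float = 0.04
    confidence_range: tuple[float, float] = (0.81, 0.99)
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_components, self.n_targets, self.n_pathway_proteins,
               self.n_metabolites, self.n_connected_targets) < 0:
            raise ValidationError("all layer sizes must be >= 0")
        if self.n_components < 1:
            raise ValidationError("need at least one component")
        if self.n_connected_targets > self.n_targets:
            raise ValidationError(
                f"n_connected_targets ({self.n_connected_targets}) exceeds "
                f"n_targets ({self.n_targets})"
            )
        for name in ("dock_hit_rate", "text_hit_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if not (0.0 < self.ppi_density <= 1.0):
            raise ValidationError(f"ppi_density must be in (0, 1], got {self.ppi_density}")
        lo, hi = self.confidence_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValidationError(f"confidence_range {self.confidence_range} not within (0, 1]")
        if self.n_connected_targets > 0:
            if self.n_metabolites == 0:
                raise ValidationError(
                    "infeasible: connected targets require at least one metabolite"
                )
            if self.n_pathway_proteins == 0:
                raise ValidationError(
                    "infeasible: connected targets require at least one pathway protein"
                )
        if self.n_metabolites > 0 and self.n_pathway_proteins < self.n_metabolites:
            raise ValidationError(
                "infeasible: each metabolite pathway needs at least one member protein "
                f"({self.n_pathway_proteins} proteins < {self.n_metabolites} metabolites)"
            )


@dataclass
class FixtureBundle:
    """A complete synthetic input set plus its planted ground truth."""

    components: pd.DataFrame
    dock: pd.DataFrame
    text_edges: pd.DataFrame
    ppi: pd.DataFrame
    metabolite_pathways: pd.DataFrame
    memberships: pd.DataFrame
    annotations: pd.DataFrame
    truth: frozenset[str]
    orientation: dict[str, str] = field(default_factory=lambda: dict(ENGINE_ORIENTATION))


def _structure_pool() -> list[tuple[str, str, str]]:
    """(name, formula, smiles) pool of real parseable structures drawn from
    the packaged catalog; keeps synthetic components chemspace-testable."""
    t1 = load_table1()
    rows = t1[t1["structure"] != ""]
    return list(rows[["name", "formula", "structure"]].itertuples(index=False, name=None))


def generate_fixture(config: FixtureConfig) -> FixtureBundle:
    """Generate a deterministic synthetic bundle for ``config``.

    Exactly ``n_connected_targets`` targets end up with both a component
    edge and a protein path to a metabolite; the remaining targets are
    decoys that miss one of the two.  Running the full pipeline (dock
    cutoff, CTPI merge, PPI filter at 0.8, MPPI at alpha 0.05, unions,
    prioritization) on the bundle recovers the planted set exactly; this
    is verified before returning.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    pool = _structure_pool()

    comp_ids = [f"C{i + 1:03d}" for i in range(config.n_components)]
    components = pd.DataFrame(
        {
            "id": comp_ids,
            "name": [f"synthetic-{pool[i % len(pool)][0]}-{i + 1}" for i in range(len(comp_ids))],
            "formula": [pool[i % len(pool)][1] for i in range(len(comp_ids))],
            "herb_class": [_HERB_CYCLE[i % 4] for i in range(len(comp_ids))],
            "structure": [pool[i % len(pool)][2] for i in range(len(comp_ids))],
        }
    )

    target_ids = [f"T{i + 1:03d}" for i in range(config.n_targets)]
    shuffled = list(target_ids)
    rng.shuffle(shuffled)
    connected = sorted(shuffled[: config.n_connected_targets])
    decoys = sorted(shuffled[config.n_connected_targets:])
    path_possible = config.n_metabolites > 0 and config.n_pathway_proteins > 0
    decoys_no_path = [d for i, d in enumerate(decoys) if i % 2 == 0 or not path_possible]
    decoys_no_component = [d for i, d in enumerate(decoys) if i % 2 == 1 and path_possible]

    pathway_ids = [f"P{i + 1:03d}" for i in range(config.n_pathway_proteins)]
    metab_ids = [f"M{i + 1:02d}" for i in range(config.n_metabolites)]

    # --- pathways: one enriched pathway per metabolite plus one decoy pathway
    met_rows, member_rows = [], []
    for j, met in enumerate(metab_ids):
        enr = f"PW_enr{j + 1:02d}"
        met_rows.append((met, enr, round(float(rng.uniform(0.001, 0.045)), 4)))
        members = [p for i, p in enumerate(pathway_ids) if i % config.n_metabolites == j]
        member_rows.extend((enr, p) for p in members)
        bg = f"PW_bg{j + 1:02d}"
        met_rows.append((met, bg, round(float(rng.uniform(0.06, 0.95)), 4)))
        bg_members = sorted(rng.choice(pathway_ids, size=min(3, len(pathway_ids)), replace=False))
        member_rows.extend((bg, p) for p in bg_members)
    metabolite_pathways = pd.DataFrame(met_rows, columns=["metabolite", "pathway", "p"])
    memberships = pd.DataFrame(member_rows, columns=["pathway", "protein"])

    # --- component-target edges (dock and/or text provenance)
    ct_targets = sorted(connected + decoys_no_path)
    dock_hits: set[tuple[str, str]] = set()
    text_hits: set[tuple[str, str]] = set()
    for t in ct_targets:
        for c in comp_ids:
            d = rng.random() < config.dock_hit_rate
            x = rng.random() < config.text_hit_rate
            if d:
                dock_hits.add((c, t))
            if x:
                text_hits.add((c, t))
    # every component-edge target needs at least one component
    for t in ct_targets:
        if not any((c, t) in dock_hits or (c, t) in text_hits for c in comp_ids):
            dock_hits.add((comp_ids[int(rng.integers(len(comp_ids)))], t))
    # every component needs at least one target so the full catalog shows up
    if ct_targets:
        for c in comp_ids:
            if not any((c, t) in dock_hits or (c, t) in text_hits for t in ct_targets):
                anchor = connected if connected else ct_targets
                text_hits.add((c, anchor[int(rng.integers(len(anchor)))]))

    # --- dock score table: hits beat the per-protein positive control,
    # misses (including every no-component decoy's records) fall short
    engines = {t: ("libdock" if rng.random() < 0.5 else "vina") for t in target_ids}
    controls = {
        t: round(float(rng.uniform(40, 80)), 2) if engines[t] == "libdock"
        else round(float(rng.uniform(-10, -6)), 2)
        for t in target_ids
    }
    dock_rows = []

    def _score(t: str, hit: bool) -> float:
        margin = float(rng.uniform(1, 30)) if engines[t] == "libdock" else float(rng.uniform(0.2, 3))
        sign = 1.0 if engines[t] == "libdock" else -1.0
        return round(controls[t] + (sign * margin if hit else -sign * margin), 2)

    for (c, t) in sorted(dock_hits):
        dock_rows.append((c, t, engines[t], _score(t, True), controls[t]))
    for t in sorted(decoys_no_component):
        for c in comp_ids:
            if rng.random() < max(config.dock_hit_rate, 0.05):
                dock_rows.append((c, t, engines[t], _score(t, False), controls[t]))
    for t in ct_targets:  # sub-cutoff noise on ordinary targets too
        for c in comp_ids:
            if (c, t) not in dock_hits and rng.random() < config.dock_hit_rate / 2:
                dock_rows.append((c, t, engines[t], _score(t, False), controls[t]))
    dock = pd.DataFrame(
        dock_rows,
        columns=["component_id", "protein_id", "engine", "score", "positive_control_score"],
    )
    text = pd.DataFrame(sorted(text_hits), columns=["component_id", "protein_id"])

    # --- PPI: a backbone edge from every path-carrying target to a pathway
    # protein, plus random edges confined to groups that cannot leak a path
    # to the no-path decoys
    lo, hi = config.confidence_range

    def _conf() -> float:
        return round(float(rng.uniform(lo, hi)), 3)

    ppi_rows: dict[tuple[str, str], float] = {}

    def _add_ppi(a: str, b: str) -> None:
        if a != b:
            key = tuple(sorted((a, b)))
            ppi_rows.setdefault(key, _conf())

    for t in sorted(connected + decoys_no_component):
        if pathway_ids:
            _add_ppi(t, pathway_ids[int(rng.integers(len(pathway_ids)))])
    group_a = sorted(set(connected) | set(decoys_no_component) | set(pathway_ids))
    for i, a in enumerate(group_a):
        for b in group_a[i + 1:]:
            if rng.random() < config.ppi_density:
                _add_ppi(a, b)
    for i, a in enumerate(decoys_no_path):
        for b in decoys_no_path[i + 1:]:
            if rng.random() < config.ppi_density:
                _add_ppi(a, b)
    ppi = pd.DataFrame(
        [(a, b, c) for (a, b), c in sorted(ppi_rows.items())],
        columns=["protein_a", "protein_b", "combined_score"],
    )

    # --- annotations over targets + pathway proteins
    genes = sorted(set(target_ids) | set(pathway_ids))
    ann_rows = [(g, "TERM_ALL", "annotated gene", "component") for g in genes]
    namespaces = ["process", "function", "pathway", "disease"]
    for i in range(8):
        size = int(rng.integers(3, max(4, len(genes) // 3)))
        chosen = sorted(rng.choice(genes, size=min(size, len(genes)), replace=False))
        ann_rows.extend(
            (g, f"TERM_{i + 1:02d}", f"synthetic term {i + 1}", namespaces[i % 4])
            for g in chosen
        )
    annotations = pd.DataFrame(ann_rows, columns=["gene", "term_id", "term_name", "namespace"])

    bundle = FixtureBundle(
        components=components,
        dock=dock,
        text_edges=text,
        ppi=ppi,
        metabolite_pathways=metabolite_pathways,
        memberships=memberships,
        annotations=annotations,
        truth=frozenset(connected),
    )
    _verify_planted_truth(bundle, config)
    return bundle


def _verify_planted_truth(bundle: FixtureBundle, config: FixtureConfig) -> None:
    """Self-consistency: the pipeline must recover exactly the planted set."""
    if config.n_metabolites == 0 or config.n_pathway_proteins == 0:
        return  # prioritization is undefined without all four roles
    from .pipeline import run_pipeline

    result = run_pipeline(bundle)
    found = set(result.prioritization.retained_targets)
    if found != set(bundle.truth):
        raise ValidationError(
            "planted-truth violation: pipeline retained "
            f"{sorted(found ^ set(bundle.truth))} inconsistently"
        )


def write_bundle(bundle: FixtureBundle, out_dir: str | Path) -> None:
    """Write every table of the bundle as TSV plus ``truth.txt``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.components.to_csv(out / "components.tsv", sep="\t", index=False)
    bundle.dock.to_csv(out / "dock.tsv", sep="\t", index=False)
    bundle.text_edges.to_csv(out / "text_edges.tsv", sep="\t", index=False)
    bundle.ppi.to_csv(out / "ppi.tsv", sep="\t", index=False)
    bundle.metabolite_pathways.to_csv(out / "metabolite_pathways.tsv", sep="\t", index=False)
    bundle.memberships.to_csv(out / "memberships.tsv", sep="\t", index=False)
    bundle.annotations.to_csv(out / "annotations.tsv", sep="\t", index=False)
    (out / "truth.txt").write_text("\n".join(sorted(bundle.truth)) + "\n")
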