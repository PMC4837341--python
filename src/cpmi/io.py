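"""Readers and writers for the TSV dialects and network export formats.

Networks export as SIF (``source<TAB>edge_type<TAB>target``) and GraphML
for Cytoscape import.  STRING-style PPI exports on the 0-1000 combined
score scale are auto-detected and rescaled to (0, 1].
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .model import LayeredNetwork, ValidationError

logger = logging.getLogger(__name__)


def read_components(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"id", "name", "formula", "herb_class"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"component table {path}: missing columns {sorted(missing)}")
    if "structure" not in df.columns:
        df["structure"] = ""
    return df


def read_dock_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"component_id", "protein_id", "engine", "score", "positive_control_score"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"dock table {path}: missing columns {sorted(missing)}")
    return df


def read_text_edges(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"component_id", "protein_id"} - set(df.columns)
    if missing:
        raise ValidationError(f"text-edge table {path}: missing columns {sorted(missing)}")
    return df


def read_ppi_table(path: str | Path) -> pd.DataFrame:
    """Read a PPI edge list; combined scores on the STRING 0-1000 integer
    scale (any value > 1) are divided by 1000 with a log message."""
    df = pd.read_csv(path, sep="\t")
    missing = {"protein_a", "protein_b", "combined_score"} - set(df.columns)
    if missing:
        raise ValidationError(f"PPI table {path}: missing columns {sorted(missing)}")
    if (df["combined_score"] > 1).any():
        logger.info("PPI table %s looks 0-1000 scaled; dividing by 1000", path)
        df = df.assign(combined_score=df["combined_score"] / 1000.0)
    return df


def read_enrichment_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"metabolite", "pathway", "p"} - set(df.columns)
    if missing:
        raise ValidationError(f"enrichment table {path}: missing columns {sorted(missing)}")
    return df


def read_membership_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"pathway", "protein"} - set(df.columns)
    if missing:
        raise ValidationError(f"membership table {path}: missing columns {sorted(missing)}")
    return df


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"gene", "term_id", "term_name", "namespace"} - set(df.columns)
    if missing:
        raise ValidationError(f"annotation table {path}: missing columns {sorted(missing)}")
    return df


def read_structure_library(path: str | Path) -> list[tuple[str, str]]:
    """Structure library: either one SMILES per line (ids LIB0001...) or a
    two-column TSV ``id<TAB>smiles`` (no header)."""
    entries = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) >= 2:
            entries.append((parts[0], parts[1]))
        else:
            entries.append((f"LIB{i + 1:04d}", parts[0]))
    return entries


def write_sif(network: LayeredNetwork, path: str | Path) -> None:
    lines = [
        f"{e.source}\t{e.edge_type}\t{e.target_node}"
        for e in sorted(network.edges, key=lambda e: (e.source, e.edge_type, e.target_node))
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_graphml(network: LayeredNetwork, path: str | Path) -> None:
    import networkx as nx

    nx.write_graphml(network.to_networkx(), str(path))
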