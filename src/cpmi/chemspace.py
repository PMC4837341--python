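"""Chemical-space mapping and drug-likeness analysis.

Computes the seven physicochemical descriptors used to compare herbal
components with approved drugs (molecular weight, aromatic ring count,
H-bond donors/acceptors, topological polar surface area, rotatable bonds
and logP), projects descriptor tables with PCA, compares two compound sets
descriptor-by-descriptor with Kolmogorov-Smirnov and rank-sum tests, and
screens a compound catalog against a structure library by Tanimoto
fingerprint similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import Component, DescriptorVector, SimilarityMatch, StatComparison

logger = logging.getLogger(__name__)

DESCRIPTOR_NAMES = list(DescriptorVector.FIELDS)


class StructureParseError(ValueError):
    """A structure string could not be parsed into a molecule."""


def _mol_from_smiles(structure: str):
    from rdkit import Chem

    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise StructureParseError(f"unparseable structure: {structure!r}")
    return mol


def compute_descriptors(structure: str) -> DescriptorVector:
    """Compute the seven-descriptor vector from a SMILES string.

    The logP field is the toolkit's native Crippen logP (atom-contribution
    parameterizations differ across software; the value is labeled as the
    toolkit's own rather than any specific commercial ALogP).
    """
    from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

    mol = _mol_from_smiles(structure)
    return DescriptorVector(
        mw=Descriptors.MolWt(mol),
        n_aromatic_rings=rdMolDescriptors.CalcNumAromaticRings(mol),
        n_hbd=rdMolDescriptors.CalcNumHBD(mol),
        n_hba=rdMolDescriptors.CalcNumHBA(mol),
        psa=rdMolDescriptors.CalcTPSA(mol),
        n_rotatable=rdMolDescriptors.CalcNumRotatableBonds(mol),
        alogp=Crippen.MolLogP(mol),
    )


def descriptor_table(components: list[Component]) -> pd.DataFrame:
    """Descriptor DataFrame (index = component id) for all components with a
    parseable structure; components lacking one are skipped with a warning."""
    rows = {}
    for c in components:
        if not c.structure:
            logger.warning("component %s has no structure; skipped in chemspace", c.id)
            continue
        d = compute_descriptors(c.structure)
        rows[c.id] = {name: getattr(d, name) for name in DESCRIPTOR_NAMES}
    return pd.DataFrame.from_dict(rows, orient="index", columns=DESCRIPTOR_NAMES)


@dataclass(frozen=True)
class PCAResult:
    scores: pd.DataFrame          # n x p component scores
    loadings: pd.DataFrame        # descriptors x p orthonormal loadings
    explained_variance_ratio: np.ndarray


def pca_chemspace(matrix: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """PCA of a descriptor table on centered, unit-variance-scaled columns.

    Columns are autoscaled because the descriptors carry incommensurate
    units (g/mol vs counts vs A^2).  Constant columns are left centered but
    unscaled.  Each loading vector is oriented so that its largest-magnitude
    entry is positive, which fixes the sign indeterminacy of PCA.

    Raises ValueError with a row/column report if the table contains missing
    values — no silent imputation.
    """
    if matrix.shape[0] < 2:
        raise ValueError(f"PCA needs at least 2 rows, got {matrix.shape[0]}")
    if matrix.isna().any().any():
        bad = matrix.isna()
        rows = list(matrix.index[bad.any(axis=1)])
        cols = list(matrix.columns[bad.any(axis=0)])
        raise ValueError(f"missing values in rows {rows}, columns {cols}")

    x = matrix.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    sd_safe = np.where(sd > 0, sd, 1.0)
    x = x / sd_safe

    from sklearn.decomposition import PCA

    p = min(matrix.shape) if n_components is None else n_components
    pca = PCA(n_components=p)
    scores = pca.fit_transform(x)
    loadings = pca.components_.T  # columns are orthonormal directions

    # deterministic sign convention
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
            scores[:, j] = -scores[:, j]

    pc_names = [f"PC{i + 1}" for i in range(loadings.shape[1])]
    total_var = pca.explained_variance_.sum()
    evr = pca.explained_variance_ / total_var if total_var > 0 else pca.explained_variance_ratio_
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=pc_names),
        loadings=pd.DataFrame(loadings, index=matrix.columns, columns=pc_names),
        explained_variance_ratio=evr,
    )


def compare_druglikeness(set_a: pd.DataFrame, set_b: pd.DataFrame) -> list[StatComparison]:
    """Per-descriptor two-sample comparison of two compound sets.

    For every shared descriptor column, runs the two-sided two-sample
    Kolmogorov-Smirnov test (distribution shape) and the two-sided
    Wilcoxon rank-sum / Mann-Whitney test (location).  Exact null
    distributions are used for small samples (n <= 20 per side), the
    asymptotic/continuity-corrected approximations above that.
    """
    if len(set_a) < 3 or len(set_b) < 3:
        raise ValueError(
            f"need >= 3 observations per set, got {len(set_a)} and {len(set_b)}"
        )
    out = []
    for name in set_a.columns:
        if name not in set_b.columns:
            continue
        a = set_a[name].to_numpy(dtype=float)
        b = set_b[name].to_numpy(dtype=float)
        small = max(len(a), len(b)) <= 20
        ks = stats.ks_2samp(a, b, method="exact" if small else "asymp")
        mw = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="exact" if small else "asymptotic"
        )
        out.append(
            StatComparison(
                descriptor_name=name,
                ks_statistic=float(ks.statistic),
                ks_p=float(ks.pvalue),
                ranksum_statistic=float(mw.statistic),
                ranksum_p=float(mw.pvalue),
            )
        )
    return out


def tanimoto(fp_a, fp_b) -> float:
    """Tanimoto coefficient |A & B| / |A | B| between two bit sets.

    Accepts RDKit ExplicitBitVects or any iterable of 0/1 bits; two empty
    fingerprints have similarity 1 by convention (identical sets).
    """
    try:
        from rdkit import DataStructs
        from rdkit.DataStructs.cDataStructs import ExplicitBitVect

        if isinstance(fp_a, ExplicitBitVect) and isinstance(fp_b, ExplicitBitVect):
            return DataStructs.TanimotoSimilarity(fp_a, fp_b)
    except ImportError:  # pragma: no cover
        pass
    a = {i for i, bit in enumerate(fp_a) if bit}
    b = {i for i, bit in enumerate(fp_b) if bit}
    union = a | b
    if not union:
        return 1.0
    return len(a & b) / len(union)


def morgan_fingerprint(structure: str, radius: int = 2, n_bits: int = 2048):
    """Circular (Morgan/ECFP-like) fingerprint, the de-facto standard for
    similarity screening."""
    from rdkit.Chem import rdFingerprintGenerator

    mol = _mol_from_smiles(structure)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return gen.GetFingerprint(mol)


@dataclass(frozen=True)
class ScreenReport:
    matches: list[SimilarityMatch]
    errors: list[tuple[str, str]]  # (record id, message)


def tanimoto_screen(
    queries: list[Component],
    library: list[tuple[str, str]],
    threshold: float = 0.85,
    radius: int = 2,
    n_bits: int = 2048,
) -> ScreenReport:
    """Screen catalog components against a (id, structure) library.

    Returns matches with Tanimoto similarity at or above ``threshold``
    (inclusive), sorted descending by similarity, ties broken by
    (query_id, library_id).  Unparseable structures on either side are
    collected into the error report; the remaining records are processed.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")

    query_fps = {}
    errors: list[tuple[str, str]] = []
    for c in queries:
        if not c.structure:
            errors.append((c.id, "missing structure"))
            continue
        try:
            query_fps[c.id] = morgan_fingerprint(c.structure, radius, n_bits)
        except StructureParseError as exc:
            errors.append((c.id, str(exc)))
    lib_fps = {}
    for lib_id, structure in library:
        try:
            lib_fps[lib_id] = morgan_fingerprint(structure, radius, n_bits)
        except StructureParseError as exc:
            errors.append((lib_id, str(exc)))

    matches = [
        SimilarityMatch(query_id=qid, library_id=lid, tanimoto=tanimoto(qfp, lfp))
        for qid, qfp in query_fps.items()
        for lid, lfp in lib_fps.items()
        if tanimoto(qfp, lfp) >= threshold
    ]
    matches.sort(key=lambda m: (-m.tanimoto, m.query_id, m.library_id))
    return ScreenReport(matches=matches, errors=errors)
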