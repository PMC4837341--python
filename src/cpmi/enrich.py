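"""Local over-representation analysis (ORA).

Given a query protein/gene set and a flat annotation table, computes the
upper-tail hypergeometric probability of observing at least the overlap
seen between the query and each annotation term — the classical ORA test
used by enrichment servers.  Terms below the significance level are
flagged as "key".  Raw p-values are reported by default; an optional
Benjamini-Hochberg correction is available as an extension.
"""

from __future__ import annotations

import logging
from typing import Iterable

import pandas as pd
from scipy import stats

from .model import EnrichmentResult, ValidationError

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ("gene", "term_id", "term_name", "namespace")
NAMESPACES = frozenset({"process", "component", "function", "pathway", "disease"})


def _validate_annotations(annotations: pd.DataFrame) -> pd.DataFrame:
    if annotations is None or len(annotations) == 0:
        raise ValidationError("annotation table is empty")
    missing = set(ANNOTATION_COLUMNS) - set(annotations.columns)
    if missing:
        raise ValidationError(f"annotation table missing columns {sorted(missing)}")
    dupes = annotations.duplicated(subset=["gene", "term_id"])
    if dupes.any():
        annotations = annotations[~dupes]
    return annotations


def hypergeom_enrich(
    query: Iterable[str],
    annotations: pd.DataFrame,
    alpha: float = 0.05,
    background: Iterable[str] | None = None,
    bh_correction: bool = False,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of ``query`` against each term.

    For a term annotating K of the N background genes, with n query genes
    of which k carry the term, the p-value is the upper tail
    P(X >= k) with X ~ Hypergeometric(N, K, n).  The background defaults to
    all distinct genes in the annotation table; pass ``background``
    explicitly to widen or narrow the universe.  Query genes outside the
    background are dropped with a warning.  Results are sorted ascending by
    p, ties broken by term id; results with p strictly below ``alpha`` are
    flagged ``key``.  ``bh_correction`` additionally applies a
    Benjamini-Hochberg adjustment before flagging (off by default: the
    conventional ORA report uses raw p-values).
    """
    annotations = _validate_annotations(annotations)
    if background is None:
        universe = set(annotations["gene"].astype(str))
    else:
        universe = set(map(str, background))
    query_set = set(map(str, query))
    dropped = query_set - universe
    if dropped:
        logger.warning("query genes outside the background dropped: %s", sorted(dropped))
    query_set &= universe
    if not query_set:
        raise ValidationError("query is empty after restricting to the background")

    N = len(universe)
    n = len(query_set)
    rows = annotations[annotations["gene"].astype(str).isin(universe)]
    results = []
    for (term_id, term_name), group in rows.groupby(["term_id", "term_name"], sort=True):
        genes = set(group["gene"].astype(str))
        K = len(genes)
        k = len(genes & query_set)
        # upper tail P(X >= k); sf(k-1) has mass at exactly k included
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        p = min(p, 1.0)
        results.append(
            EnrichmentResult(
                term_id=str(term_id), term_name=str(term_name),
                k=k, K=K, n=n, N=N, p=p,
            )
        )
    results.sort(key=lambda r: (r.p, r.term_id))

    if bh_correction and results:
        from statsmodels.stats.multitest import multipletests

        flags, _, _, _ = multipletests([r.p for r in results], alpha=alpha, method="fdr_bh")
        results = [
            EnrichmentResult(**{**r.__dict__, "key": bool(f)})
            for r, f in zip(results, flags)
        ]
    else:
        results = [
            EnrichmentResult(**{**r.__dict__, "key": r.p < alpha}) for r in results
        ]
    return results


# STRING-style ORA and the one-sided Fisher exact test coincide for
# over-representation; expose the alias under the more familiar name.
fisher_enrich = hypergeom_enrich


def stratified_enrich(
    strata: dict[str, str],
    annotations: pd.DataFrame,
    alpha: float = 0.05,
    background: Iterable[str] | None = None,
) -> dict[str, list[EnrichmentResult]]:
    """Run :func:`hypergeom_enrich` independently per stratum.

    ``strata`` maps gene -> stratum label (e.g. the high/middle/low
    component-degree bands).  Every stratum is tested against the same
    background.  An empty stratum yields an empty list (logged).
    """
    if not strata:
        raise ValidationError("strata mapping is empty")
    by_stratum: dict[str, set[str]] = {}
    for gene, label in strata.items():
        by_stratum.setdefault(label, set()).add(gene)
    out: dict[str, list[EnrichmentResult]] = {}
    for label in sorted(by_stratum):
        genes = by_stratum[label]
        if not genes:
            logger.warning("stratum %r is empty", label)
            out[label] = []
            continue
        try:
            out[label] = hypergeom_enrich(genes, annotations, alpha=alpha, background=background)
        except ValidationError as exc:
            logger.warning("stratum %r: %s", label, exc)
            out[label] = []
    return out


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id, "term_name": r.term_name,
                "k": r.k, "K": r.K, "n": r.n, "N": r.N, "p": r.p, "key": r.key,
            }
            for r in results
        ]
    )
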