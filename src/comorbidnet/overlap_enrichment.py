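"""Sibling-group selection, the multi-disorder gene set, and process-based candidates.

The multi-disorder gene set (MDAG) comprises focal-disorder genes shared with
at least one sibling disorder (same cluster at the k-cut). Enrichment of the
MDAG in biological processes uses the hypergeometric upper tail (one-sided
Fisher exact) against a configurable gene universe with the classic
pre-filters (minimum hit count 2, raw p <= 0.1) followed by
Benjamini-Hochberg adjustment. Process-based candidates (PBC) are genes of
enriched processes found in sibling lists but absent from the focal list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from comorbidnet.io_model import AnnotationTable, CandidateRecord, DisorderGeneTable
from comorbidnet.comorbidity_clustering import ClusterAssignment

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MdagSet:
    """Focal genes shared with >= 1 sibling, with per-gene sibling membership."""

    genes: frozenset[str]
    membership: dict[str, frozenset[str]]


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int  # hits in query
    n: int  # query size (within universe)
    K: int  # term size in universe
    N: int  # universe size
    p: float  # hypergeometric upper-tail probability
    adjusted: float
    enriched: bool


def select_sibling_group(assignment: ClusterAssignment, focal: str) -> list[str]:
    """Members of the focal disorder's cluster, focal excluded."""
    if focal not in assignment.labels:
        raise ValueError(f"focal disorder {focal!r} not in cluster assignment")
    cluster = assignment.labels[focal]
    siblings = sorted(d for d, c in assignment.labels.items() if c == cluster and d != focal)
    if not siblings:
        logger.warning("focal disorder %r sits in a singleton cluster; no siblings", focal)
    return siblings


def compute_mdag(tables: DisorderGeneTable, siblings: list[str]) -> MdagSet:
    """Focal genes also present in >= 1 sibling list, with membership recorded."""
    unknown = set(siblings) - set(tables.entries)
    if unknown:
        raise ValueError(f"unknown sibling disorders: {sorted(unknown)}")
    if tables.focal in siblings:
        raise ValueError("focal disorder cannot be its own sibling")
    if not siblings:
        logger.warning("empty sibling list; MDAG is empty")
        return MdagSet(frozenset(), {})
    membership: dict[str, frozenset[str]] = {}
    for gene in tables.focal_genes:
        found = frozenset(s for s in siblings if gene in tables.entries[s])
        if found:
            membership[gene] = found
    return MdagSet(frozenset(membership), membership)


def hypergeometric_pvalue(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(n, K)):
        raise ValueError(f"invalid hypergeometric configuration k={k}, N={N}, K={K}, n={n}")
    return float(hypergeom.sf(k - 1, N, K, n))


def fdr_adjust(pvals: list[float] | np.ndarray, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    if method != "bh":
        raise ValueError(f"unknown method {method!r}")
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    N = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * N / np.arange(1, N + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    out = np.empty(N)
    out[order] = adjusted_sorted
    return out


def hypergeometric_enrichment(
    query: frozenset[str] | set[str],
    annotation: AnnotationTable,
    restrict_universe_to: frozenset[str] | set[str] | None = None,
    min_count: int = 2,
    max_p: float = 0.1,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric upper-tail enrichment of ``query`` in each annotation term.

    The universe is the annotation universe, optionally intersected with
    ``restrict_universe_to`` (typically the union of all disorder gene lists).
    Every term with annotated genes in the universe counts as a tested
    hypothesis: BH adjustment runs over all of them. Terms with fewer than
    ``min_count`` hits or raw p above ``max_p`` are then dropped from the
    report (the classic functional-annotation display thresholds);
    ``enriched`` flags adjusted < ``alpha``. Results are sorted by raw p
    (ties by term id).
    """
    universe = annotation.universe
    if restrict_universe_to is not None:
        universe = universe & frozenset(restrict_universe_to)
    q = frozenset(query) & universe
    if not q:
        raise ValueError("query does not intersect the annotation universe")
    N, n = len(universe), len(q)
    tested: list[tuple[str, int, int, float]] = []
    for term in sorted(annotation.terms):
        term_genes = annotation.terms[term] & universe
        K = len(term_genes)
        if K == 0:
            continue
        k = len(q & term_genes)
        tested.append((term, k, K, hypergeometric_pvalue(k, N, K, n)))
    if not tested:
        return []
    adjusted = fdr_adjust([r[3] for r in tested])
    results = [
        EnrichmentResult(term=t, k=k, n=n, K=K, N=N, p=p, adjusted=float(a), enriched=bool(a < alpha))
        for (t, k, K, p), a in zip(tested, adjusted)
        if k >= min_count and p <= max_p
    ]
    results.sort(key=lambda r: (r.p, r.term))
    return results


def derive_pbc(
    enriched: list[EnrichmentResult],
    annotation: AnnotationTable,
    tables: DisorderGeneTable,
    siblings: list[str],
    min_siblings: int = 1,
) -> list[CandidateRecord]:
    """Process-based candidates: genes of enriched terms present in sibling
    lists but absent from the focal list.

    One record per gene (non-redundant), carrying all enriched terms that
    contain it and the sibling disorders whose lists contain it. A
    ``min_siblings`` >= 2 mode restricts to genes in at least that many
    sibling lists (default 1).
    """
    focal_genes = tables.focal_genes
    terms_by_gene: dict[str, set[str]] = {}
    for res in enriched:
        if not res.enriched:
            continue
        for gene in annotation.terms[res.term]:
            terms_by_gene.setdefault(gene, set()).add(res.term)
    records = []
    for gene in sorted(terms_by_gene):
        if gene in focal_genes:
            continue
        occ = frozenset(s for s in siblings if gene in tables.entries[s])
        if len(occ) < max(min_siblings, 1):
            continue
        records.append(
            CandidateRecord(
                gene=gene,
                source="pbc",
                enriched_terms=frozenset(terms_by_gene[gene]),
                sibling_occurrence=occ,
            )
        )
    return records
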