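"""Differential-expression validation of candidate genes.

Candidates are tested per dataset with two-sample Welch t-statistics
(unequal sample sizes and variances are the norm in case/control microarray
cohorts), two-sided p-values, and q-values for FDR control. The hypothesis
universe of each dataset is the set of candidates actually present on that
array, so multiple-testing correction is performed within each restricted
candidate panel, not genome-wide.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import make_smoothing_spline

from comorbidnet.io_model import ExpressionDataset
from comorbidnet.overlap_enrichment import fdr_adjust

logger = logging.getLogger(__name__)

STOREY_LAMBDAS = np.arange(0.05, 0.96, 0.05)  # 0.05, 0.10, ..., 0.95


@dataclass(frozen=True)
class DEResult:
    """Per-dataset differential-expression table for the tested candidates.

    ``table`` is indexed by gene with columns t, df, p, q, significant;
    ``untested`` lists candidates absent from the array or excluded
    (missing values / degenerate variance). ``n_hypotheses`` is the number
    of genes actually tested, i.e. the multiple-testing universe.
    """

    dataset_id: str
    table: pd.DataFrame
    untested: frozenset[str]
    n_hypotheses: int
    alpha: float

    @property
    def significant(self) -> frozenset[str]:
        return frozenset(self.table.index[self.table["significant"]])


def log2_quantile_normalize(dataset: ExpressionDataset, log2: bool = True) -> ExpressionDataset:
    """Log2-transform (optional) then quantile-normalize columns.

    After normalization every column has the same sorted values: the mean of
    the order statistics across columns. Tied values within a column receive
    the mean of the tied ranks' reference values.
    """
    m = dataset.matrix.to_numpy(dtype=float)
    if log2:
        if (m <= 0).any():
            raise ValueError("nonpositive values cannot be log2-transformed")
        m = np.log2(m)
    sorted_cols = np.sort(m, axis=0)
    reference = sorted_cols.mean(axis=1)
    out = np.empty_like(m)
    for j in range(m.shape[1]):
        ranks = stats.rankdata(m[:, j], method="average")  # 1-based, ties averaged
        out[:, j] = np.interp(ranks - 1.0, np.arange(len(reference)), reference)
    return ExpressionDataset(
        dataset_id=dataset.dataset_id,
        matrix=pd.DataFrame(out, index=dataset.matrix.index, columns=dataset.matrix.columns),
        groups=dict(dataset.groups),
        probe_map=dataset.probe_map,
    )


def collapse_probes(dataset: ExpressionDataset) -> ExpressionDataset:
    """Collapse probe-level rows to gene level via the probe map.

    For genes measured by several probes the probe with the highest mean
    intensity across samples is kept (ties break by lexicographically
    smallest probe id). Probes without a gene mapping are dropped with a
    logged count. Without a probe map the dataset is returned unchanged
    (rows are assumed to already be genes).
    """
    if dataset.probe_map is None:
        return dataset
    means = dataset.matrix.mean(axis=1)
    best: dict[str, str] = {}  # gene -> probe
    unmapped = 0
    for probe in dataset.matrix.index:
        gene = dataset.probe_map.get(probe)
        if gene is None:
            unmapped += 1
            continue
        cur = best.get(gene)
        # higher mean wins; on exactly equal means the smaller probe id wins
        if cur is None or means[probe] > means[cur] or (means[probe] == means[cur] and probe < cur):
            best[gene] = probe
    if unmapped:
        logger.info("%s: dropped %d unmapped probe(s)", dataset.dataset_id, unmapped)
    genes = sorted(best)
    matrix = dataset.matrix.loc[[best[g] for g in genes]].copy()
    matrix.index = pd.Index(genes)
    return ExpressionDataset(
        dataset_id=dataset.dataset_id, matrix=matrix, groups=dict(dataset.groups), probe_map=None
    )


def welch_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Welch two-sample t statistic and Welch-Satterthwaite degrees of freedom.

    t = (mean x - mean y) / sqrt(s2x/nx + s2y/ny). Requires >= 2 samples per
    group; both groups with zero variance is degenerate and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each group needs at least two samples")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        raise ValueError("degenerate: zero variance in both groups")
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return float(t), float(df)


def two_sided_p(t: float, df: float) -> float:
    """Two-sided tail probability 2 * P(T_df >= |t|)."""
    return float(2.0 * stats.t.sf(abs(t), df))


@lru_cache(maxsize=1)
def _smoother_penalty(df: float = 3.0) -> float:
    """Smoothing-spline penalty giving ``df`` effective degrees of freedom.

    The lambda grid and precision weights are fixed, so the penalty is a
    constant of the design, found once by bisecting on the trace of the
    smoother matrix.
    """
    lam = STOREY_LAMBDAS
    w = (1.0 - lam) * lam.size / (1.0 - lam).sum()

    def eff_df(pen: float) -> float:
        S = np.column_stack(
            [make_smoothing_spline(lam, e, w=w, lam=pen)(lam) for e in np.eye(lam.size)]
        )
        return float(np.trace(S))

    lo, hi = 1e-8, 1e4
    for _ in range(80):
        mid = float(np.sqrt(lo * hi))
        if eff_df(mid) > df:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def _storey_pi0(p: np.ndarray) -> float:
    """Storey's null-proportion estimate over the lambda grid.

    pi0(lambda) = #{p > lambda} / (N (1 - lambda)) is smoothed by a cubic
    smoothing spline (3 effective df, precision weights proportional to
    1 - lambda since var(pi0(lambda)) grows like 1/(N (1 - lambda))) and
    read off at the top of the grid (lambda -> 1). With fewer than 100
    tests the single estimate at lambda = 0.5 is used instead.
    """
    N = p.size
    if N < 100:
        pi0 = (p > 0.5).sum() / (N * 0.5)
    else:
        lam = STOREY_LAMBDAS
        pi0_lam = np.array([(p > L).sum() / (N * (1.0 - L)) for L in lam])
        w = (1.0 - lam) * lam.size / (1.0 - lam).sum()
        spline = make_smoothing_spline(lam, pi0_lam, w=w, lam=_smoother_penalty())
        pi0 = float(spline(lam[-1]))
    if pi0 <= 0.0:
        floor = 1.0 / N
        warnings.warn(f"pi0 estimate {pi0:.4g} <= 0; clamped to {floor:.4g}", stacklevel=2)
        pi0 = floor
    return min(pi0, 1.0)


def qvalues(pvals: np.ndarray | list[float], method: str = "storey") -> np.ndarray:
    """q-values for a vector of p-values.

    ``storey`` scales the BH step-up by the estimated null proportion pi0;
    ``bh`` forces pi0 = 1 and therefore reproduces BH adjustment exactly.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bh":
        pi0 = 1.0
    elif method == "storey":
        pi0 = _storey_pi0(p)
    else:
        raise ValueError(f"unknown q-value method {method!r}")
    return np.minimum(pi0 * fdr_adjust(p), 1.0)


def validate_candidates(
    dataset: ExpressionDataset,
    candidates: frozenset[str] | set[str],
    alpha: float = 0.05,
    method: str = "storey",
) -> DEResult:
    """Welch-t / q-value differential expression of candidates in one dataset.

    Only candidates present among the matrix rows are tested; the q-value
    correction runs within that restricted hypothesis set. Candidates absent
    from the array, or excluded for missing values or zero variance in both
    groups, are reported as untested rather than non-significant.
    """
    dataset = collapse_probes(dataset)
    case_cols = dataset.samples_in("case")
    control_cols = dataset.samples_in("control")
    present = sorted(frozenset(candidates) & set(dataset.matrix.index))
    if not present:
        raise ValueError(f"{dataset.dataset_id}: no candidate present on the array")
    untested = set(candidates) - set(present)
    rows = []
    tested_genes = []
    n_missing = n_degenerate = 0
    for gene in present:
        x = dataset.matrix.loc[gene, case_cols].to_numpy(dtype=float)
        y = dataset.matrix.loc[gene, control_cols].to_numpy(dtype=float)
        if np.isnan(x).any() or np.isnan(y).any():
            n_missing += 1
            untested.add(gene)
            continue
        try:
            t, df = welch_t(x, y)
        except ValueError:
            n_degenerate += 1
            untested.add(gene)
            continue
        rows.append((t, df, two_sided_p(t, df)))
        tested_genes.append(gene)
    if n_missing or n_degenerate:
        logger.info(
            "%s: excluded %d gene(s) with missing values, %d with degenerate variance",
            dataset.dataset_id,
            n_missing,
            n_degenerate,
        )
    if not tested_genes:
        raise ValueError(f"{dataset.dataset_id}: no testable candidate on the array")
    table = pd.DataFrame(rows, index=pd.Index(tested_genes, name="gene"), columns=["t", "df", "p"])
    table["q"] = qvalues(table["p"].to_numpy(), method=method)
    table["significant"] = table["q"] < alpha
    return DEResult(
        dataset_id=dataset.dataset_id,
        table=table,
        untested=frozenset(untested),
        n_hypotheses=len(tested_genes),
        alpha=alpha,
    )
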