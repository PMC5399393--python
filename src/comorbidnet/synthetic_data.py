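"""Synthetic inputs with planted, recoverable structure.

Generates all four input kinds the pipeline consumes — disorder gene lists
with planted group structure and a shared focal-group core, annotation terms
enriched in that core, per-sibling interaction networks in which planted
candidate genes neighbor core genes, and case/control expression matrices
with planted differentially expressed candidates under unequal group sizes
and variances — together with truth objects so every downstream stage can be
tested for recovery without any download.

All generators are pure functions of (scenario, seed): the same seed yields
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from comorbidnet.io_model import DisorderGeneTable, AnnotationTable, ExpressionDataset, InteractionNetwork


@dataclass(frozen=True)
class SyntheticScenario:
    """Study conditions for the synthetic generators.

    Defaults are a scaled-down analogue of a multi-disorder comorbidity
    study: three disorder groups of six, a 60-gene shared core per group with
    12 private genes per disorder, candidates planted into 3-5 focal-group
    siblings, and expression cohorts of 20 cases vs 15 controls with a
    2-unit log2 shift against per-gene noise sigma in [0.3, 0.6].
    """

    n_groups: int = 3
    disorders_per_group: int = 6
    core_size: int = 60
    private_size: int = 12
    share_prob: float = 0.85
    n_planted_candidates: int = 30
    n_null_candidates: int = 30
    effect_size: float = 2.0
    sigma_range: tuple[float, float] = (0.3, 0.6)
    n_case: int = 20
    n_control: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 1 or self.disorders_per_group < 1:
            raise ValueError("n_groups and disorders_per_group must be positive")
        if self.core_size < 2:
            raise ValueError("core_size must be >= 2 (clustering signal undefined below that)")
        if self.private_size < 0 or self.n_planted_candidates < 0 or self.n_null_candidates < 0:
            raise ValueError("sizes must be nonnegative")
        if not 0.0 < self.share_prob <= 1.0:
            raise ValueError("share_prob must lie in (0, 1]")
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("need at least two samples per group")
        lo, hi = self.sigma_range
        if not 0.0 < lo <= hi:
            raise ValueError("sigma_range must be a positive interval")
        n_candidates = self.n_planted_candidates + self.n_null_candidates
        if n_candidates > 0 and self.disorders_per_group < 4:
            raise ValueError("planting candidates into >=3 siblings needs >=4 disorders per group")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth planted by the generators."""

    focal: str
    groups: dict[str, int]  # disorder -> group index
    cores: dict[int, frozenset[str]]  # group -> core gene pool
    planted_candidates: frozenset[str]  # survive every filter incl. DE
    null_candidates: frozenset[str]  # planted structurally but never DE
    candidate_siblings: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def all_candidates(self) -> frozenset[str]:
        return self.planted_candidates | self.null_candidates


def _sibling_names(scenario: SyntheticScenario) -> list[str]:
    return [f"G1D{j}" for j in range(2, scenario.disorders_per_group + 1)]


def generate_disorder_tables(
    scenario: SyntheticScenario, seed: int | None = None
) -> tuple[DisorderGeneTable, SyntheticTruth]:
    """Disorder gene lists with planted group structure.

    Each group owns a disjoint core gene pool; each disorder draws core genes
    with probability ``share_prob`` and adds ``private_size`` unique genes.
    The first disorder of group 1 is the focal disorder ("ASD"). Planted and
    null candidate genes are each inserted into 3-5 focal-group sibling lists
    and never into the focal list.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    cores = {
        g: frozenset(f"G{g + 1}C{i:03d}" for i in range(scenario.core_size))
        for g in range(scenario.n_groups)
    }
    entries: dict[str, set[str]] = {}
    groups: dict[str, int] = {}
    for g in range(scenario.n_groups):
        core_list = sorted(cores[g])
        for j in range(scenario.disorders_per_group):
            name = "ASD" if (g == 0 and j == 0) else f"G{g + 1}D{j + 1}"
            groups[name] = g
            keep = rng.random(len(core_list)) < scenario.share_prob
            gene_set = {c for c, k in zip(core_list, keep) if k}
            if not gene_set:  # guarantee a non-empty list
                gene_set.add(core_list[int(rng.integers(len(core_list)))])
            gene_set.update(f"{name}_P{i:02d}" for i in range(scenario.private_size))
            entries[name] = gene_set
    planted = frozenset(f"CAND{i:03d}" for i in range(scenario.n_planted_candidates))
    nulls = frozenset(f"NCAND{i:03d}" for i in range(scenario.n_null_candidates))
    siblings = _sibling_names(scenario)
    candidate_siblings: dict[str, frozenset[str]] = {}
    for gene in sorted(planted | nulls):
        m = int(rng.integers(3, min(5, len(siblings)) + 1))
        chosen = rng.choice(siblings, size=m, replace=False)
        for s in chosen:
            entries[s].add(gene)
        candidate_siblings[gene] = frozenset(chosen.tolist())
    table = DisorderGeneTable({d: frozenset(gs) for d, gs in entries.items()}, focal="ASD")
    truth = SyntheticTruth(
        focal="ASD",
        groups=groups,
        cores=cores,
        planted_candidates=planted,
        null_candidates=nulls,
        candidate_siblings=candidate_siblings,
    )
    return table, truth


def generate_annotations(
    tables: DisorderGeneTable,
    truth: SyntheticTruth,
    n_enriched_terms: int = 8,
    n_background_terms: int = 40,
    seed: int = 0,
    enriched_term_size: int = 25,
    background_term_size: int = 30,
) -> tuple[AnnotationTable, frozenset[str]]:
    """Annotation terms over the observed genes, some enriched in the focal core.

    Enriched terms draw predominantly from focal-group core genes present in
    the focal list (hence from the multi-disorder set), salted with the
    planted candidate genes (the planted process-based candidates, absent
    from the focal list by construction). Background terms draw uniformly
    from the universe. Returns the table and the planted PBC gene set.
    """
    rng = np.random.default_rng(seed)
    universe = sorted(tables.gene_union())
    focal_core = sorted(truth.cores[0] & tables.focal_genes)
    candidates = sorted(truth.all_candidates)
    terms: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    if n_enriched_terms > 0:
        assignment: dict[int, set[str]] = {i: set() for i in range(n_enriched_terms)}
        for gene in candidates:  # every candidate lands in >= 1 enriched term
            n_terms = int(rng.integers(1, min(2, n_enriched_terms) + 1))
            for t in rng.choice(n_enriched_terms, size=n_terms, replace=False):
                assignment[int(t)].add(gene)
        for i in range(n_enriched_terms):
            size = min(enriched_term_size, len(focal_core))
            members = set(rng.choice(focal_core, size=size, replace=False).tolist())
            members |= assignment[i]
            members.update(rng.choice(universe, size=5, replace=False).tolist())
            terms[f"TERM_E{i:02d}"] = frozenset(members)
            names[f"TERM_E{i:02d}"] = f"planted enriched process {i}"
    for i in range(n_background_terms):
        size = min(background_term_size, len(universe))
        terms[f"TERM_B{i:02d}"] = frozenset(rng.choice(universe, size=size, replace=False).tolist())
        names[f"TERM_B{i:02d}"] = f"background process {i}"
    if not terms:
        raise ValueError("no terms requested")
    annotation = AnnotationTable(terms=terms, names=names, universe=frozenset(universe))
    planted_pbc = frozenset(candidates) if n_enriched_terms > 0 else frozenset()
    return annotation, planted_pbc


def generate_networks(
    tables: DisorderGeneTable,
    truth: SyntheticTruth,
    n_planted_neighbors: int | None = None,
    n_decoy_nodes: int = 10,
    seed: int = 0,
    edge_prob: float = 0.05,
) -> tuple[list[InteractionNetwork], frozenset[str]]:
    """Connected random interaction networks per focal-group sibling.

    Each sibling gets an Erdos-Renyi background over its gene list with a
    random-chain connectivity floor. Planted candidate genes receive a
    guaranteed edge to a core gene shared with the focal list (an MDAG-truth
    gene) in every sibling whose list contains them; decoy nodes attach only
    to non-core genes. Returns the networks and the planted NBC gene set.
    """
    rng = np.random.default_rng(seed)
    siblings = sorted(d for d, g in truth.groups.items() if g == 0 and d != truth.focal)
    candidates = sorted(truth.all_candidates)
    if n_planted_neighbors is not None:
        candidates = candidates[:n_planted_neighbors]
    planted_nbc = frozenset(candidates)
    networks = []
    for s in siblings:
        nodes = sorted(tables.entries[s])
        g_edges: set[tuple[str, str]] = set()
        order = rng.permutation(nodes)
        for a, b in zip(order, order[1:]):  # connectivity floor: random chain
            g_edges.add((min(a, b), max(a, b)))
        n = len(nodes)
        mask = rng.random((n, n)) < edge_prob
        for i in range(n):
            for j in range(i + 1, n):
                if mask[i, j]:
                    g_edges.add((nodes[i], nodes[j]))
        core_shared = sorted(truth.cores[0] & tables.focal_genes & tables.entries[s])
        for c in candidates:
            if c in tables.entries[s] and core_shared:
                anchor = core_shared[int(rng.integers(len(core_shared)))]
                g_edges.add((min(c, anchor), max(c, anchor)))
        non_core = sorted(set(nodes) - truth.cores[0] - planted_nbc)
        for i in range(n_decoy_nodes):
            if not non_core:
                break
            decoy = f"DECOY_{s}_{i:02d}"
            anchor = non_core[int(rng.integers(len(non_core)))]
            g_edges.add((min(decoy, anchor), max(decoy, anchor)))
        networks.append(InteractionNetwork.from_edges(s, sorted(g_edges)))
    return networks, planted_nbc


def generate_expression(
    candidates: list[str] | frozenset[str],
    scenario: SyntheticScenario,
    de_genes: frozenset[str] | None = None,
    seed: int = 0,
    dataset_id: str = "synthetic",
) -> tuple[ExpressionDataset, frozenset[str]]:
    """Case/control expression matrix over the given genes.

    Every gene draws Normal(baseline_g, sigma_g) intensities on the log2
    scale in both groups, with per-gene baseline ~ U(6, 10) and sigma ~
    U(sigma_range). Genes in ``de_genes`` receive an additional mean shift of
    ``effect_size`` (random sign) in cases. Group sizes are deliberately
    unequal (n_case vs n_control) to exercise the Welch path. When
    ``de_genes`` is None, ``n_planted_candidates`` genes are drawn at random.
    """
    rng = np.random.default_rng(seed)
    genes = sorted(candidates)
    if not genes:
        raise ValueError("no genes to simulate")
    if de_genes is None:
        n_de = min(scenario.n_planted_candidates, len(genes))
        de_genes = frozenset(rng.choice(genes, size=n_de, replace=False).tolist())
    else:
        de_genes = frozenset(de_genes) & frozenset(genes)
    n_case, n_control = scenario.n_case, scenario.n_control
    baselines = rng.uniform(6.0, 10.0, size=len(genes))
    sigmas = rng.uniform(*scenario.sigma_range, size=len(genes))
    signs = rng.choice([-1.0, 1.0], size=len(genes))
    data = np.empty((len(genes), n_case + n_control))
    for i, gene in enumerate(genes):
        shift = signs[i] * scenario.effect_size if gene in de_genes else 0.0
        data[i, :n_case] = rng.normal(baselines[i] + shift, sigmas[i], size=n_case)
        data[i, n_case:] = rng.normal(baselines[i], sigmas[i], size=n_control)
    samples = [f"{dataset_id}_case{i + 1}" for i in range(n_case)] + [
        f"{dataset_id}_ctrl{i + 1}" for i in range(n_control)
    ]
    groups = {s: ("case" if i < n_case else "control") for i, s in enumerate(samples)}
    dataset = ExpressionDataset(
        dataset_id=dataset_id,
        matrix=pd.DataFrame(data, index=pd.Index(genes, name="gene"), columns=samples),
        groups=groups,
    )
    return dataset, de_genes
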