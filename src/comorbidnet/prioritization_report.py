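"""Evidence combination, filtering, cross-dataset overlap and pipeline orchestration.

Process-based and network-based candidate lists are intersected, thinned to
genes with evidence from at least ``min_siblings`` sibling disorders, tested
for differential expression per dataset, and intersected across datasets to
yield the final prioritized candidate list. ``run_pipeline`` executes the
whole analysis from a config mapping and writes every stage's artifact plus
a manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd

from comorbidnet import io_model
from comorbidnet import comorbidity_clustering as cc
from comorbidnet import overlap_enrichment as oe
from comorbidnet import network_nbc as nn
from comorbidnet import expression_validation as ev
from comorbidnet import synthetic_data as sd
from comorbidnet.io_model import CandidateRecord

logger = logging.getLogger(__name__)

DEFAULT_PARAMS = {
    "k": 6,
    "linkage": "average",
    "B": 1000,
    "fdr_alpha": 0.05,
    "q_alpha": 0.05,
    "q_method": "storey",
    "min_siblings": 3,
    "occurrence_mode": "union",
    "min_count": 2,
    "max_p": 0.1,
    "universe": "observed",
    "min_score": None,
    "expression": True,
}


@dataclass
class PrioritizationOutput:
    """Nested candidate sets: pbc ⊇ both ⊆ nbc, both ⊇ filtered ⊇ per-dataset ⊇ final."""

    pbc: frozenset[str]
    nbc: frozenset[str]
    both: frozenset[str]
    filtered: frozenset[str]
    per_dataset_significant: dict[str, frozenset[str]] = field(default_factory=dict)
    final: frozenset[str] = frozenset()
    venn: dict[str, int] = field(default_factory=dict)
    records: dict[str, CandidateRecord] = field(default_factory=dict)
    validated: bool = False

    def check_invariants(self, focal_genes: frozenset[str] = frozenset()) -> None:
        assert self.both <= self.pbc and self.both <= self.nbc
        assert self.filtered <= self.both
        for sig in self.per_dataset_significant.values():
            assert sig <= self.filtered
            assert self.final <= sig
        assert not (self.final & focal_genes)


def intersect_sources(
    pbc_records: list[CandidateRecord],
    nbc_records: list[CandidateRecord],
    occurrence_mode: str = "union",
) -> list[CandidateRecord]:
    """Merge candidates predicted by both strategies (source = both).

    ``occurrence_mode`` controls the merged sibling occurrence: ``union`` of
    gene-list (PBC) and network (NBC) evidence, or restricted to ``pbc`` /
    ``nbc`` evidence alone.
    """
    if occurrence_mode not in ("union", "pbc", "nbc"):
        raise ValueError(f"unknown occurrence mode {occurrence_mode!r}")
    pbc_by_gene = {r.gene: r for r in pbc_records}
    nbc_by_gene = {r.gene: r for r in nbc_records}
    merged = []
    for gene in sorted(set(pbc_by_gene) & set(nbc_by_gene)):
        p, n = pbc_by_gene[gene], nbc_by_gene[gene]
        if occurrence_mode == "pbc":
            occ = p.sibling_occurrence
        elif occurrence_mode == "nbc":
            occ = n.sibling_occurrence
        else:
            occ = p.sibling_occurrence | n.sibling_occurrence
        merged.append(
            CandidateRecord(
                gene=gene,
                source="both",
                enriched_terms=p.enriched_terms,
                mdag_interactors=n.mdag_interactors,
                sibling_occurrence=occ,
            )
        )
    return merged


def filter_min_siblings(records: list[CandidateRecord], min_siblings: int = 3) -> list[CandidateRecord]:
    """Keep records with sibling occurrence in at least ``min_siblings`` disorders."""
    if min_siblings < 1:
        raise ValueError("min_siblings must be >= 1")
    return [r for r in records if len(r.sibling_occurrence) >= min_siblings]


def cross_dataset_overlap(
    de_results: list[ev.DEResult], records: list[CandidateRecord]
) -> PrioritizationOutput:
    """Per-dataset significant subsets of the filtered records and their intersection.

    Attaches per-dataset stats to each record, computes the final overlap
    across all datasets, and emits Venn region counts (genes significant in
    exactly each dataset combination).
    """
    if not de_results:
        raise ValueError("need at least one differential-expression result")
    genes = frozenset(r.gene for r in records)
    by_gene = {r.gene: r for r in records}
    per_dataset: dict[str, frozenset[str]] = {}
    for de in de_results:
        sig = de.significant & genes
        per_dataset[de.dataset_id] = sig
        for gene, row in de.table.iterrows():
            if gene in by_gene:
                by_gene[gene].dataset_stats[de.dataset_id] = {
                    "t": float(row["t"]),
                    "df": float(row["df"]),
                    "p": float(row["p"]),
                    "q": float(row["q"]),
                    "significant": bool(row["significant"]),
                }
    final = frozenset.intersection(*per_dataset.values())
    venn: dict[str, int] = {}
    union = frozenset().union(*per_dataset.values())
    ids = sorted(per_dataset)
    for gene in union:
        region = "&".join(d for d in ids if gene in per_dataset[d])
        venn[region] = venn.get(region, 0) + 1
    out = PrioritizationOutput(
        pbc=genes,
        nbc=genes,
        both=genes,
        filtered=genes,
        per_dataset_significant=per_dataset,
        final=final,
        venn=venn,
        records=by_gene,
        validated=True,
    )
    return out


def annotate_final_table(final_records: list[CandidateRecord]) -> pd.DataFrame:
    """One row per final gene: sibling disorders (alphabetical) and their count."""
    rows = []
    for r in sorted(final_records, key=lambda r: r.gene):
        sibs = sorted(r.sibling_occurrence)
        rows.append({"gene": r.gene, "sibling_disorders": ", ".join(sibs), "n_disorders": len(sibs)})
    return pd.DataFrame(rows, columns=["gene", "sibling_disorders", "n_disorders"])


def pathway_overlap_percent(hits: int, term_size: int) -> float:
    """100 * hits / term_size, rounded half-up to one decimal place."""
    if term_size <= 0:
        raise ValueError("term_size must be positive")
    pct = Decimal(100 * hits) / Decimal(term_size)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Pipeline orchestration
# ---------------------------------------------------------------------------


def _sub_seed(seed: int, offset: int) -> int:
    return (int(seed) + offset) % (2**31 - 1)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _records_frame(records: list[CandidateRecord]) -> pd.DataFrame:
    rows = []
    for r in sorted(records, key=lambda r: r.gene):
        rows.append(
            {
                "gene": r.gene,
                "source": r.source,
                "enriched_terms": ",".join(sorted(r.enriched_terms)),
                "mdag_interactors": ",".join(sorted(r.mdag_interactors)),
                "siblings": ",".join(sorted(r.sibling_occurrence)),
                "n_siblings": len(r.sibling_occurrence),
            }
        )
    cols = ["gene", "source", "enriched_terms", "mdag_interactors", "siblings", "n_siblings"]
    return pd.DataFrame(rows, columns=cols)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict, outdir: str | Path | None = None) -> PrioritizationOutput:
    """Run the full cross-disorder prioritization pipeline.

    ``config`` holds either a ``synthetic`` section (scenario parameters; all
    inputs generated with planted truth) or an ``inputs`` section (file
    paths), plus optional parameter overrides (k, B, linkage, alphas,
    min_siblings, occurrence_mode, universe policy). Deterministic given
    config and seed. When ``outdir`` is given every stage's artifact is
    written there along with ``manifest.json``.
    """
    params = {**DEFAULT_PARAMS, **{k: v for k, v in config.items() if k in DEFAULT_PARAMS}}
    seed = int(config.get("seed", 0))
    counts: dict[str, object] = {}

    # --- stage: inputs -----------------------------------------------------
    truth = None
    if "synthetic" in config:
        syn = dict(config["synthetic"])
        n_enriched = syn.pop("n_enriched_terms", 8)
        n_background = syn.pop("n_background_terms", 40)
        n_datasets = syn.pop("n_datasets", 3)
        n_bg_expression = syn.pop("n_background_expression_genes", 200)
        scenario = sd.SyntheticScenario(**{**syn, "seed": seed})
        tables, truth = sd.generate_disorder_tables(scenario)
        annotation, _ = sd.generate_annotations(
            tables, truth, n_enriched, n_background, seed=_sub_seed(seed, 1)
        )
        networks, _ = sd.generate_networks(tables, truth, seed=_sub_seed(seed, 2))
    elif "inputs" in config:
        inp = config["inputs"]
        tables = io_model.read_gene_sets(
            inp["gene_sets"],
            format=inp.get("format", "gmt"),
            kind="disorders",
            focal=inp.get("focal", "ASD"),
        )
        annotation = io_model.read_gene_sets(
            inp["annotation"], format=inp.get("annotation_format", "gmt"), kind="annotation"
        )
        networks = [io_model.read_edge_list(p) for p in inp.get("networks", [])]
    else:
        raise ValueError("config needs a 'synthetic' or 'inputs' section")
    counts["n_disorders"] = len(tables.entries)
    counts["n_focal_genes"] = len(tables.focal_genes)

    # --- stage: clustering -------------------------------------------------
    try:
        matrix = cc.build_matrix(tables)
        d = cc.dissimilarity(matrix)
        tree = cc.hierarchical_cluster(d, params["linkage"])
        k = min(int(params["k"]), len(tables.entries))
        assignment = cc.cut_tree(tree, k)
        stability = cc.bootstrap_stability(
            matrix, k, B=int(params["B"]), linkage=params["linkage"], seed=_sub_seed(seed, 5)
        )
        stability_labels = cc.classify_stability(stability)
        mds = cc.classical_mds(d, dims=2)
    except Exception as exc:
        raise RuntimeError(f"clustering stage failed: {exc}") from exc

    # --- stage: sibling group and MDAG ------------------------------------
    try:
        siblings = oe.select_sibling_group(assignment, tables.focal)
        mdag = oe.compute_mdag(tables, siblings)
    except Exception as exc:
        raise RuntimeError(f"MDAG stage failed: {exc}") from exc
    counts["n_siblings"] = len(siblings)
    counts["n_mdag"] = len(mdag.genes)
    logger.info("sibling group: %d disorders; MDAG: %d genes", len(siblings), len(mdag.genes))

    # --- stage: enrichment and PBC -----------------------------------------
    try:
        restrict = tables.gene_union() if params["universe"] == "observed" else None
        enrichment = oe.hypergeometric_enrichment(
            mdag.genes,
            annotation,
            restrict_universe_to=restrict,
            min_count=int(params["min_count"]),
            max_p=float(params["max_p"]),
            alpha=float(params["fdr_alpha"]),
        )
        pbc_records = oe.derive_pbc(enrichment, annotation, tables, siblings)
    except Exception as exc:
        raise RuntimeError(f"enrichment stage failed: {exc}") from exc
    counts["n_enriched_terms"] = sum(1 for e in enrichment if e.enriched)
    counts["n_pbc"] = len(pbc_records)

    # --- stage: networks and NBC -------------------------------------------
    try:
        sibling_networks = [n for n in networks if n.disorder in siblings]
        nbc_records = nn.derive_nbc(
            sibling_networks, mdag, tables.focal_genes, min_score=params["min_score"]
        )
        histogram = nn.sibling_occurrence_histogram(nbc_records)
    except Exception as exc:
        raise RuntimeError(f"network stage failed: {exc}") from exc
    counts["n_nbc"] = len(nbc_records)

    # --- stage: intersection and sibling filter ----------------------------
    both_records = intersect_sources(pbc_records, nbc_records, params["occurrence_mode"])
    filtered_records = filter_min_siblings(both_records, int(params["min_siblings"]))
    counts["n_both"] = len(both_records)
    counts["n_filtered"] = len(filtered_records)
    logger.info(
        "PBC %d, NBC %d, both %d, >=%d siblings %d",
        len(pbc_records),
        len(nbc_records),
        len(both_records),
        params["min_siblings"],
        len(filtered_records),
    )

    # --- stage: expression validation --------------------------------------
    pbc_set = frozenset(r.gene for r in pbc_records)
    nbc_set = frozenset(r.gene for r in nbc_records)
    both_set = frozenset(r.gene for r in both_records)
    filtered_set = frozenset(r.gene for r in filtered_records)
    de_results: list[ev.DEResult] = []
    if params["expression"]:
        datasets: list[io_model.ExpressionDataset] = []
        if truth is not None:
            rng_pool = sorted(tables.gene_union() - truth.all_candidates)
            bg_rng = np.random.default_rng(_sub_seed(seed, 3))
            n_bg = min(n_bg_expression, len(rng_pool))
            background = bg_rng.choice(rng_pool, size=n_bg, replace=False).tolist()
            expr_genes = sorted(truth.all_candidates | set(background))
            for i in range(n_datasets):
                ds, _ = sd.generate_expression(
                    expr_genes,
                    scenario,
                    de_genes=truth.planted_candidates,
                    seed=_sub_seed(seed, 10 + i),
                    dataset_id=f"synth_ds{i + 1}",
                )
                datasets.append(ds)
        else:
            for spec_ds in config["inputs"].get("expression", []):
                ds = io_model.read_expression(
                    spec_ds["matrix"],
                    spec_ds["groups"],
                    spec_ds.get("probe_map"),
                    dataset_id=spec_ds.get("id"),
                )
                if spec_ds.get("normalize", False):
                    ds = ev.log2_quantile_normalize(ds, log2=spec_ds.get("log2", False))
                datasets.append(ds)
        try:
            for ds in datasets:
                de_results.append(
                    ev.validate_candidates(
                        ds, filtered_set, alpha=float(params["q_alpha"]), method=params["q_method"]
                    )
                )
        except Exception as exc:
            raise RuntimeError(f"expression stage failed: {exc}") from exc

    # --- stage: final overlap ----------------------------------------------
    if de_results:
        overlap = cross_dataset_overlap(de_results, filtered_records)
        output = PrioritizationOutput(
            pbc=pbc_set,
            nbc=nbc_set,
            both=both_set,
            filtered=filtered_set,
            per_dataset_significant=overlap.per_dataset_significant,
            final=overlap.final,
            venn=overlap.venn,
            records={r.gene: r for r in filtered_records},
            validated=True,
        )
        counts["per_dataset_significant"] = {d: len(s) for d, s in overlap.per_dataset_significant.items()}
        counts["n_final"] = len(overlap.final)
    else:
        logger.info("expression stage omitted: candidates are filtered but unvalidated")
        output = PrioritizationOutput(
            pbc=pbc_set,
            nbc=nbc_set,
            both=both_set,
            filtered=filtered_set,
            records={r.gene: r for r in filtered_records},
            validated=False,
        )
    output.check_invariants(tables.focal_genes)

    # --- stage: artifacts ---------------------------------------------------
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "dendrogram.nwk").write_text(cc.to_newick(tree) + "\n", encoding="utf-8")
        stab_rows = [
            {
                "cluster": c,
                "members": ",".join(sorted(stability.clusters[c])),
                "mean_jaccard": stability.stability[c],
                "dissolved_runs": stability.dissolved[c],
                "label": stability_labels[c],
            }
            for c in sorted(stability.clusters)
        ]
        _write_tsv(pd.DataFrame(stab_rows), outdir / "stability.tsv")
        mds_df = pd.DataFrame(mds.coords, columns=["dim1", "dim2"])
        mds_df.insert(0, "disorder", mds.labels)
        _write_tsv(mds_df, outdir / "mds.tsv")
        mdag_rows = [
            {"gene": g, "siblings": ",".join(sorted(mdag.membership[g]))} for g in sorted(mdag.genes)
        ]
        _write_tsv(pd.DataFrame(mdag_rows, columns=["gene", "siblings"]), outdir / "mdag.tsv")
        enr_rows = [
            {
                "term": e.term,
                "k": e.k,
                "n": e.n,
                "K": e.K,
                "N": e.N,
                "p": e.p,
                "adjusted": e.adjusted,
                "enriched": e.enriched,
            }
            for e in enrichment
        ]
        _write_tsv(
            pd.DataFrame(enr_rows, columns=["term", "k", "n", "K", "N", "p", "adjusted", "enriched"]),
            outdir / "enrichment.tsv",
        )
        _write_tsv(_records_frame(pbc_records), outdir / "pbc.tsv")
        _write_tsv(_records_frame(nbc_records), outdir / "nbc.tsv")
        hist_df = pd.DataFrame(
            [{"min_siblings": t, "n_genes": c} for t, c in sorted(histogram.items())]
        )
        _write_tsv(hist_df, outdir / "nbc_histogram.tsv")
        _write_tsv(_records_frame(filtered_records), outdir / "filtered_candidates.tsv")
        for de in de_results:
            table = de.table.reset_index()
            _write_tsv(table, outdir / f"de_{de.dataset_id}.tsv")
        final_records = [output.records[g] for g in sorted(output.final)]
        _write_tsv(annotate_final_table(final_records), outdir / "final_candidates.tsv")
        artifacts = sorted(p.name for p in outdir.glob("*.tsv")) + ["dendrogram.nwk"]
        manifest = {
            "seed": seed,
            "parameters": {k: params[k] for k in sorted(params)},
            "counts": counts,
            "venn": output.venn,
            "validated": output.validated,
            "artifacts": {name: _sha256(outdir / name) for name in artifacts},
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n", encoding="utf-8"
        )
    return output
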