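"""Data types, gene-symbol normalization, and readers/writers.

Gene identifiers are plain uppercased symbols; no alias resolution is
attempted (an optional user-supplied alias map may be applied at load).
Canonical gene-set format is GMT; a two-column TSV (set-name, gene) is
accepted for convenience.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

GROUP_LABELS = ("case", "control")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


def normalize_symbol(raw: str, alias: Mapping[str, str] | None = None) -> str:
    """Normalize a raw gene token: strip whitespace, uppercase, optionally remap.

    Normalization is idempotent; two raw strings differing only in case or
    surrounding whitespace map to the same symbol. Empty tokens are rejected.
    """
    sym = raw.strip().upper()
    if not sym:
        raise ValueError("empty gene symbol")
    if alias:
        sym = alias.get(sym, sym)
    return sym


@dataclass(frozen=True)
class DisorderGeneTable:
    """Named disorders, each mapped to a non-empty set of gene symbols.

    ``focal`` names the disorder whose multi-disorder subcomponent is the
    object of study (default ``"ASD"``).
    """

    entries: dict[str, frozenset[str]]
    focal: str = "ASD"

    def __post_init__(self) -> None:
        if self.focal not in self.entries:
            raise ValueError(f"focal disorder {self.focal!r} not among entries")
        for name, genes in self.entries.items():
            if not genes:
                raise ValueError(f"disorder {name!r} has an empty gene set")

    @property
    def disorders(self) -> list[str]:
        return list(self.entries)

    @property
    def focal_genes(self) -> frozenset[str]:
        return self.entries[self.focal]

    def gene_union(self) -> frozenset[str]:
        return frozenset().union(*self.entries.values())


@dataclass(frozen=True)
class AnnotationTable:
    """Biological-process annotation: term-id -> gene set, plus the universe.

    ``universe`` is the set of all annotated genes; every term is a subset.
    """

    terms: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)
    universe: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        universe = self.universe
        if not universe:
            universe = frozenset().union(*self.terms.values()) if self.terms else frozenset()
        object.__setattr__(self, "universe", frozenset(universe))
        for tid, genes in self.terms.items():
            if not genes:
                raise ValueError(f"annotation term {tid!r} is empty")
            if not genes <= self.universe:
                raise ValueError(f"term {tid!r} not contained in the universe")


@dataclass(frozen=True)
class InteractionNetwork:
    """Undirected gene-interaction network for one disorder.

    Edges are unordered symbol pairs stored once; optional confidence scores
    lie in [0, 1]. Self-loops are forbidden.
    """

    disorder: str
    graph: nx.Graph

    def __post_init__(self) -> None:
        for u, v, data in self.graph.edges(data=True):
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
            score = data.get("score")
            if score is not None and not 0.0 <= score <= 1.0:
                raise ValueError(f"edge score {score} outside [0, 1]")

    @classmethod
    def from_edges(
        cls, disorder: str, edges: Iterable[tuple[str, str] | tuple[str, str, float]]
    ) -> "InteractionNetwork":
        g = nx.Graph()
        dropped_loops = 0
        for edge in edges:
            a, b = normalize_symbol(edge[0]), normalize_symbol(edge[1])
            score = float(edge[2]) if len(edge) > 2 and edge[2] is not None else None
            if a == b:
                dropped_loops += 1
                continue
            if score is not None and not 0.0 <= score <= 1.0:
                raise ParseError(f"edge score {score} outside [0, 1] on ({a}, {b})")
            if g.has_edge(a, b):
                prev = g.edges[a, b].get("score")
                if score is not None and (prev is None or score > prev):
                    g.edges[a, b]["score"] = score
            else:
                g.add_edge(a, b, **({"score": score} if score is not None else {}))
        if dropped_loops:
            logger.info("%s: dropped %d self-loop(s)", disorder, dropped_loops)
        return cls(disorder, g)

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass(frozen=True)
class ExpressionDataset:
    """Gene-by-sample expression matrix with two-group labels.

    Rows are probes or genes (unique ids), columns are samples. Every sample
    column must carry a ``case`` or ``control`` label and both groups must be
    non-empty. ``probe_map`` optionally maps probe ids to gene symbols.
    """

    dataset_id: str
    matrix: pd.DataFrame
    groups: dict[str, str]
    probe_map: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.matrix.index.has_duplicates:
            raise ValueError("duplicate row ids in expression matrix")
        samples = set(self.matrix.columns)
        labelled = set(self.groups)
        if samples - labelled:
            raise ValueError(f"samples without group labels: {sorted(samples - labelled)}")
        if labelled - samples:
            raise ValueError(f"labelled samples absent from matrix: {sorted(labelled - samples)}")
        bad = {lbl for lbl in self.groups.values() if lbl not in GROUP_LABELS}
        if bad:
            raise ValueError(f"group labels must be in {GROUP_LABELS}, got {sorted(bad)}")
        for lbl in GROUP_LABELS:
            if not any(v == lbl for v in self.groups.values()):
                raise ValueError(f"group {lbl!r} is empty")

    def samples_in(self, label: str) -> list[str]:
        return [s for s in self.matrix.columns if self.groups[s] == label]


@dataclass
class CandidateRecord:
    """A candidate gene with its evidence trail.

    ``source`` is one of ``pbc`` (process-based), ``nbc`` (network-based) or
    ``both``; PBC records carry enriched terms, NBC records carry the MDAG
    genes they interact with; ``sibling_occurrence`` is the set of sibling
    disorders providing evidence. Per-dataset differential-expression stats
    are attached by the validation stage.
    """

    gene: str
    source: str
    enriched_terms: frozenset[str] = frozenset()
    mdag_interactors: frozenset[str] = frozenset()
    sibling_occurrence: frozenset[str] = frozenset()
    dataset_stats: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.source not in ("pbc", "nbc", "both"):
            raise ValueError(f"unknown source {self.source!r}")
        if self.source == "pbc" and not self.enriched_terms:
            raise ValueError("pbc record without enriched terms")
        if self.source == "nbc" and not self.mdag_interactors:
            raise ValueError("nbc record without MDAG interactors")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _parse_gmt(path: Path, alias: Mapping[str, str] | None) -> dict[str, tuple[str, frozenset[str]]]:
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs name, description and >=1 gene")
            name, desc = parts[0].strip(), parts[1].strip()
            if not name:
                raise ParseError(f"{path}:{lineno}: empty set name")
            genes = frozenset(normalize_symbol(tok, alias) for tok in parts[2:] if tok.strip())
            if not genes:
                raise ParseError(f"{path}:{lineno}: set {name!r} has no genes")
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = (desc, genes)
    if not sets:
        raise ParseError(f"{path}: empty gene-set file")
    return sets


def _parse_two_column(path: Path, alias: Mapping[str, str] | None) -> dict[str, tuple[str, frozenset[str]]]:
    acc: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected two tab-separated columns")
            name = parts[0].strip()
            if not name:
                raise ParseError(f"{path}:{lineno}: empty set name")
            acc.setdefault(name, set()).add(normalize_symbol(parts[1], alias))
    if not acc:
        raise ParseError(f"{path}: empty gene-set file")
    return {name: ("", frozenset(genes)) for name, genes in acc.items()}


def read_gene_sets(
    path: str | Path,
    format: str = "gmt",
    kind: str = "disorders",
    focal: str = "ASD",
    alias: Mapping[str, str] | None = None,
) -> DisorderGeneTable | AnnotationTable:
    """Read a GMT or two-column TSV gene-set file.

    ``kind="disorders"`` returns a :class:`DisorderGeneTable` with the given
    focal disorder; ``kind="annotation"`` returns an :class:`AnnotationTable`
    whose universe is the union of all terms.
    """
    path = Path(path)
    if format == "gmt":
        sets = _parse_gmt(path, alias)
    elif format == "tsv":
        sets = _parse_two_column(path, alias)
    else:
        raise ValueError(f"unknown gene-set format {format!r}")
    if kind == "disorders":
        return DisorderGeneTable({name: genes for name, (_, genes) in sets.items()}, focal=focal)
    if kind == "annotation":
        return AnnotationTable(
            terms={name: genes for name, (_, genes) in sets.items()},
            names={name: desc for name, (desc, _) in sets.items()},
        )
    raise ValueError(f"unknown kind {kind!r}")


def write_gene_sets(obj: DisorderGeneTable | AnnotationTable, path: str | Path) -> None:
    """Write gene sets as GMT (sorted genes, so output is deterministic)."""
    path = Path(path)
    if isinstance(obj, DisorderGeneTable):
        items = [(name, "", genes) for name, genes in obj.entries.items()]
    else:
        items = [(tid, obj.names.get(tid, ""), genes) for tid, genes in obj.terms.items()]
    with open(path, "w", encoding="utf-8") as fh:
        for name, desc, genes in items:
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def read_edge_list(
    path: str | Path, disorder: str | None = None, alias: Mapping[str, str] | None = None
) -> InteractionNetwork:
    """Read a TSV edge list (geneA, geneB[, score]) into an interaction network.

    Self-loops are dropped (count logged); duplicate pairs in either
    orientation collapse keeping the maximum score. Scores must lie in [0, 1].
    """
    path = Path(path)
    edges: list[tuple[str, str, float | None]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 3):
                raise ParseError(f"{path}:{lineno}: expected 2 or 3 columns")
            score = None
            if len(parts) == 3 and parts[2].strip():
                try:
                    score = float(parts[2])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad score {parts[2]!r}") from exc
                if not 0.0 <= score <= 1.0:
                    raise ParseError(f"{path}:{lineno}: score {score} outside [0, 1]")
            edges.append((normalize_symbol(parts[0], alias), normalize_symbol(parts[1], alias), score))
    name = disorder if disorder is not None else path.stem
    return InteractionNetwork.from_edges(name, edges)


def write_edge_list(network: InteractionNetwork, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u, v, data in sorted(network.graph.edges(data=True)):
            score = data.get("score")
            cols = [u, v] + ([f"{score:.6g}"] if score is not None else [])
            fh.write("\t".join(cols) + "\n")


def read_expression(
    matrix_path: str | Path,
    groups_path: str | Path,
    probe_map_path: str | Path | None = None,
    dataset_id: str | None = None,
) -> ExpressionDataset:
    """Read an expression matrix (TSV, header = sample ids) plus group labels.

    The groups file is a two-column TSV ``sample<TAB>label`` with labels in
    {case, control}; every matrix sample must be labelled and vice versa.
    """
    matrix_path = Path(matrix_path)
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    matrix.index = matrix.index.astype(str)
    matrix.columns = matrix.columns.astype(str)
    groups: dict[str, str] = {}
    with open(groups_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{groups_path}:{lineno}: expected sample<TAB>label")
            sample, label = parts[0].strip(), parts[1].strip().lower()
            if label not in GROUP_LABELS:
                raise ParseError(f"{groups_path}:{lineno}: label {label!r} not in {GROUP_LABELS}")
            groups[sample] = label
    probe_map = None
    if probe_map_path is not None:
        probe_map = {}
        with open(probe_map_path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ParseError(f"{probe_map_path}:{lineno}: expected probe<TAB>gene")
                probe_map[parts[0].strip()] = normalize_symbol(parts[1])
    return ExpressionDataset(
        dataset_id=dataset_id or matrix_path.stem,
        matrix=matrix,
        groups=groups,
        probe_map=probe_map,
    )
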