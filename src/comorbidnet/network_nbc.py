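"""Network-based candidates: first neighbors of the multi-disorder gene set.

In each sibling disorder's interaction network, the first neighbors of MDAG
genes that are absent from the focal seed list become network-based
candidates (NBC); each candidate records its MDAG interactors and the set of
sibling networks in which it was found.
"""

from __future__ import annotations

from comorbidnet.io_model import CandidateRecord, InteractionNetwork
from comorbidnet.overlap_enrichment import MdagSet


def first_neighbors(network: InteractionNetwork, seeds: frozenset[str] | set[str]) -> frozenset[str]:
    """All nodes adjacent to at least one seed, seeds themselves excluded."""
    g = network.graph
    out: set[str] = set()
    for s in seeds:
        if s in g:
            out.update(g.neighbors(s))
    return frozenset(out - set(seeds))


def derive_nbc(
    networks: list[InteractionNetwork],
    mdag: MdagSet,
    focal_list: frozenset[str] | set[str],
    min_score: float | None = None,
) -> list[CandidateRecord]:
    """Network-based candidates over all sibling networks.

    Per network, genes adjacent to >= 1 MDAG gene; the union over networks,
    minus the focal seed list. Edge confidence scores are ignored unless
    ``min_score`` is given, in which case only edges with a score at or above
    it count. One record per gene with its MDAG interactors and the sibling
    networks where it was found.
    """
    interactors: dict[str, set[str]] = {}
    occurrence: dict[str, set[str]] = {}
    for net in networks:
        g = net.graph
        for seed in mdag.genes:
            if seed not in g:
                continue
            for nbr in g.neighbors(seed):
                if nbr in mdag.genes or nbr in focal_list:
                    continue
                if min_score is not None:
                    score = g.edges[seed, nbr].get("score")
                    if score is None or score < min_score:
                        continue
                interactors.setdefault(nbr, set()).add(seed)
                occurrence.setdefault(nbr, set()).add(net.disorder)
    return [
        CandidateRecord(
            gene=gene,
            source="nbc",
            mdag_interactors=frozenset(interactors[gene]),
            sibling_occurrence=frozenset(occurrence[gene]),
        )
        for gene in sorted(interactors)
    ]


def sibling_occurrence_histogram(records: list[CandidateRecord]) -> dict[int, int]:
    """Cumulative counts: threshold -> number of genes occurring in >= threshold siblings."""
    counts = [len(r.sibling_occurrence) for r in records]
    if not counts:
        return {}
    max_occ = max(counts)
    # one threshold past the maximum so the first zero count is visible
    return {t: sum(1 for c in counts if c >= t) for t in range(1, max_occ + 2)}
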