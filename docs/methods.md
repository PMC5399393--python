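# Methods

## Model and assumptions

The pipeline treats each disorder as a set of associated gene symbols and
asks three questions in sequence: which disorders resemble the focal
disorder in their gene associations (clustering); which genes mediate that
resemblance (the multi-disorder gene set, MDAG, and its enriched
processes); and which genes just outside the focal list are implicated by
that shared biology (process-based and network-based candidates), with
case/control expression data as the final arbiter.

The underlying assumptions are: (i) gene–disorder association is binary —
list membership, with no weighting by evidence strength; (ii) the Jaccard
index is the right similarity for such binary profiles because shared
*absence* of a gene carries no information about relatedness; (iii)
interaction-network adjacency to shared-biology genes is evidence of
candidacy (one step only — first neighbors); and (iv) differential
expression on the log2 scale is approximately Gaussian per gene, with no
assumption of equal variances or equal group sizes between cases and
controls (hence Welch's statistic).

## Pipeline parameters

| parameter | default | meaning |
|---|---|---|
| `linkage` | average | agglomeration rule (UPGMA); complete/single available |
| `k` | 6 | clusters in the dendrogram cut; the focal disorder's cluster defines the siblings |
| `B` | 1000 | bootstrap resamples for clusterwise stability |
| stability thresholds | 0.6 / 0.5 | stable above 0.6; unstable at or below 0.5; borderline between |
| `fdr_alpha` | 0.05 | BH-adjusted enrichment significance |
| `min_count`, `max_p` | 2, 0.1 | report filters on enrichment rows (hits ≥ 2, raw p ≤ 0.1) |
| `universe` | observed | enrichment universe = annotation universe ∩ union of disorder lists |
| `min_siblings` | 3 | minimum sibling occurrence for a combined candidate |
| `q_alpha`, `q_method` | 0.05, storey | per-dataset differential-expression cutoff and FDR method |
| `occurrence_mode` | union | sibling occurrence merges gene-list (PBC) and network (NBC) evidence |

All are YAML-configurable; the defaults are the pipeline's reference
operating point.

## Design choices where the design was open

**Linkage.** No single agglomeration rule is canonical for set-overlap
profiles; average linkage (UPGMA) is the default because it weighs all
pairwise overlaps rather than extremes, and the acceptance surface of the
clustering stage is stability recovery, not exact tree shape. Ties in
merge order are broken deterministically by index order.

**Bootstrap scoring.** Cluster matching follows Hennig's clusterwise
stability: each original cluster is matched to the bootstrap cluster
maximizing the Jaccard similarity of their membership (computed on the
unique disorders drawn); a resample that misses a cluster entirely scores
0 for that run. This makes stability a strict mean over B runs, never an
average over "runs where the cluster appeared".

**Enrichment correction universe.** Every annotation term with genes in
the universe is a tested hypothesis, and BH adjustment runs over all of
them; the classic display thresholds (≥ 2 hits, raw p ≤ 0.1) are applied
to the *reported* rows afterwards. Filtering before adjustment would
shrink the correction universe to the smallest null p-values and flag
pure-background terms as enriched — measurably so in the null simulation
(15/20 seeds falsely enriched when ordered the wrong way).

**Enrichment universe policy.** The default universe is the annotation
universe intersected with the union of all disorder gene lists — the
conservative analogue of testing against the observed gene background. The
full annotation universe is available by configuration.

**Storey π̂0.** π0(λ) = #{p > λ} / (N(1 − λ)) is computed on the grid
λ = 0.05, 0.10, …, 0.95 and smoothed by a cubic smoothing spline with 3
effective degrees of freedom, evaluated at the top of the grid (λ → 1).
The spline uses precision weights proportional to 1 − λ, because
var(π̂0(λ)) grows like 1/(N(1 − λ)); an unweighted fit extrapolated past
the grid is dominated by the noisiest right-edge points and can
under-estimate π0 by 0.2 or more on null data. Below 100 tests the single
estimate at λ = 0.5 is used. π̂0 is clamped to (0, 1]; with π0 forced to 1
the q-values reproduce BH exactly (a tested identity).

**Probe collapsing.** When a probe→gene map is supplied, the probe with
the highest mean intensity across samples represents the gene (ties break
by smallest probe id). Probes without a mapping are dropped with a logged
count. Rows with missing values in either group, or zero variance in both
groups, are excluded from testing and reported as *untested*, never as
non-significant.

**Per-dataset hypothesis universes.** q-values are computed within the set
of candidates present on each array, separately per dataset and separately
for each candidate panel — a pooled genome-wide correction would dilute
the prior-knowledge design the pipeline exists to exploit.

**Sibling occurrence.** A combined (PBC ∩ NBC) candidate's occurrence
defaults to the union of its gene-list and network evidence; restricted
modes (`pbc`, `nbc`) are available since the two evidence channels need
not name the same siblings. The PBC derivation itself requires ≥ 1 sibling
list by default, with an optional ≥ 2 mode.

**Rounding.** Pathway overlap percentages round half-up to one decimal
(`Decimal` arithmetic, not binary-float rounding).

## The synthetic benchmark

The generators emulate the statistical structure the analysis assumes, at
a deliberately small scale chosen once: 3 disorder groups × 6 disorders, a 60-gene
disjoint core per group sampled into each member with probability 0.85,
12 private genes per disorder, 30 *planted* candidates threaded through
every filter (inserted into 3–5 focal-group sibling lists, salted into the
enriched annotation terms, wired by a guaranteed edge to a core gene in
every sibling network containing them, and mean-shifted by 2 log2 units in
cases) plus 30 *null* candidates planted identically except for the
expression shift. Expression cohorts are 20 cases vs 15 controls with
per-gene σ drawn from [0.3, 0.6] — deliberately unequal group sizes to
exercise the Welch path. Annotation terms draw predominantly from the
focal-group core (8 enriched + 40 background terms of ~25–30 genes);
networks are Erdős–Rényi (p = 0.05) over each sibling's gene list with a
random-chain connectivity floor, plus decoy nodes attached only to
non-core genes.

What the benchmark does *not* emulate: probe-level microarray artifacts,
batch effects, correlated genes, text-mining noise in the input lists, or
scale (real disease gene lists span hundreds of genes per disorder and
interaction networks thousands of edges). Passing tests therefore demonstrate
correctness of the machinery and recoverability of planted signal under
the model's own assumptions, not performance on any real cohort.

Problem sizes in the test-suite and acceptance script (18 disorders,
B = 200 bootstrap for stability checks, B = 30–50 inside repeated
end-to-end runs, 500-gene expression panels, 5–10 seeds per estimate) are
the package's benchmark operating point; all complete in seconds.

## Numerical notes and degenerate inputs

- Jaccard of two empty sets is undefined and raises; the profile matrix
  guarantees non-empty rows upstream.
- Classical MDS clamps negative eigenvalues among the retained dimensions
  to zero with a logged warning (Jaccard distances are metric but not
  always Euclidean-embeddable); eigenvalues are reported nonincreasing and
  coordinates are exactly centered.
- `cut_tree` renumbers clusters by first appearance so labels are stable
  across runs; bootstrap resampling reuses the precomputed distance matrix
  (subsetting rows/columns) rather than recomputing set overlaps.
- Quantile normalization resolves ties by averaging tied ranks' reference
  values (interpolating the mean order-statistic curve at average ranks).
- Edge lists drop self-loops (logged) and collapse duplicate orientations
  keeping the maximum confidence score; scores outside [0, 1] are errors,
  and scores are ignored for neighbor determination unless a minimum score
  filter is requested.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; reruns of any generator, the bootstrap, or
  the whole pipeline with the same seed are byte-identical (manifest
  hashes are compared in tests).

## Known limitations

- Gene identifiers are uppercased symbols with no alias resolution; an
  optional alias map can be applied at load, but cross-source symbol
  reconciliation is the user's responsibility.
- Enrichment takes the annotation table as given: no ontology traversal,
  no term-redundancy trimming, no parent/child filtering.
- No moderated (empirical-Bayes) t statistics, batch correction, or paired
  designs in the expression stage; raw-array preprocessing (RMA) is out of
  scope — inputs are normalized matrices, with optional log2 + quantile
  normalization.
- Network analysis is strictly first-neighbor; no modules, centrality, or
  edge-evidence decomposition.
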