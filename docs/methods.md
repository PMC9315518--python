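# Methods

## Model

The unit of analysis is the pathway *edge*: an unordered gene pair connected
in a pathway graph, stored canonically (lexicographically smaller symbol
first) everywhere in the package. A reference cohort of `n` normal samples
fixes each edge's Pearson correlation `PCC_n`. For one tumor sample the
correlation is recomputed over the reference plus that single sample
(`PCC_{n+1}`) and the edge score is

    edge_score = (PCC_{n+1} − PCC_n) · (n − 1) / (1 − PCC_n²).

The denominator is the approximate standard deviation of the one-sample
correlation increment, so under the null (the added sample drawn from the
reference distribution) the score is approximately standard normal; the
approximation is good for n in the tens and above and is checked empirically
(5,000 null replicates at n = 200, correlations up to |ρ| = 0.8: |mean|
< 0.1, sd within [0.8, 1.2]). The statistic diverges as |PCC_n| → 1, so
edges with |PCC_n| ≥ 1 − ε (ε = 1e−8), a zero-variance reference profile,
or a gene absent from the expression matrix are excluded — not clipped —
and reported with a reason, keeping downstream edge universes reproducible.
The edge universe is the union over pathways, computed once; an edge shared
by several pathways has one score row.

Correlations use the n−1 sample-variance convention throughout. The score
matrix is computed incrementally from per-edge reference sums (exact
algebra, with per-gene centering for conditioning); a brute-force
recomputation from raw vectors agrees to 1e−12.

## Per-sample enrichment

Each sample's valid edges are ranked by score, descending, ties broken by
canonical edge id. For a pathway edge set of effective size k in a
universe of N ranked edges, the running sum increments by |score|^p
(normalized over the set) at hits and decrements by 1/(N − k) at misses;
the enrichment score ES is the signed maximum deviation and the peak is its
1-based position. Defaults and their reasons:

- weighting exponent p = 1 — the GSEA convention; p = 0 reduces exactly to
  the classical unweighted KS statistic (asserted in tests);
- permutation null: same-size random edge sets from the ranked universe,
  n_perm = 1000 — with a single ranked sample there is no phenotype to
  permute, so a set-size-matched null is the only available one; p-values
  use the add-one estimator on |ES| (two-sided; the sign is reported
  separately as the direction);
- FDR: Benjamini–Hochberg across the pathways tested within one sample,
  significance at q < 0.05;
- min_set_size = 5 (smaller sets give unstable ES), min_edges = 1 for a
  reported subpathway; both configurable.

Core-enrichment (leading-edge) edges are the set members at or before a
positive peak, or at or after a negative peak. Per pathway with q < 0.05
they induce the sample's subpathway; subpathways are never merged across
pathways, so a shared edge can appear in several of one sample's
subpathways.

## Downstream analyses

Gene degrees are computed on the union of a sample's subpathway edges (each
distinct pair once); top-k lists (k = 5, 10, 20, 30) break degree ties by
symbol. Overlap rates divide by the number of top-k genes actually
returned, so samples with few subpathway genes are handled. Potential
disease genes are mutated top-5 high-degree genes recurring in ≥ 10
samples; their cohort mutation ratio is compared against 1000 same-size
random draws from the mutated-gene universe with the add-one empirical
p-value. Because the observed set can be redrawn under the null, the
smallest achievable p is governed by the tie probability, not 1/(R+1);
the test suite checks the empirical p against exhaustive enumeration on a
6-gene universe and verifies the p-values are not anti-conservative under
the null (one-sided Kolmogorov test over 200 replications).

Recurrence uses a one-sided exact binomial upper tail with p0 = 0.5; a
unit must additionally be present in more than half the samples. High-
frequency mutation genes are those mutated in strictly more than 5% of
samples. The univariate Cox screen keeps features with Wald p < 0.05 with
no multiple-testing correction — deliberately, as this mirrors the
published screening procedure. The Cox solver is a Newton–Raphson
maximizer of the partial likelihood with Efron tie handling, written
in-package so that screening hundreds of candidate features per cohort is
fast; it is cross-checked against lifelines (with and without ties) and
against a grid-search maximizer of an independently coded partial
likelihood on an 8-subject fixture (agreement within 1e−4). Non-convergent
fits (constant or separable features) are dropped from the signature with
a warning rather than aborting the run.

The risk score is the coefficient-weighted sum of feature values (edge
scores for edge signatures, expression values for gene signatures, used
unscaled). The median split assigns the median-valued sample to the low
group (a deterministic rule the procedure needs but that is otherwise
arbitrary); all-equal scores are a degenerate-split error. Kaplan–Meier
curves and the two-group log-rank test come from lifelines.

**In-sample versus validation evaluation.** Screening features, refitting
a risk score and log-rank-testing its median split *on the same cohort* is
anti-conservative: the selection step guarantees inflated rejection rates
even when no feature is truly prognostic. `risk_pipeline` therefore
accepts an independent validation cohort on which the stratification is
evaluated with coefficients frozen from the discovery cohort — the
standard design of validating a discovery-cohort signature on an
independent cohort. The calibration and power experiments use this
split; in-sample
evaluation remains available and is what single-cohort analyses report.

## Synthetic cohorts

The generator emulates the study design: a reference cohort with stable
pathway-edge correlations and tumor samples that are each one draw from a
sample-specific distribution in which a fraction of a planted pathway's
edges is rewired. Defaults (the package's study conditions):

- 10 pathway graphs, 40 nodes each, random trees. Trees are the default
  because an arbitrary per-edge correlation assignment — including
  per-sample sign flips and decorrelation — extends *exactly* to a
  positive-definite Gaussian Markov field, so planted edges carry exactly
  the advertised correlations. Erdős–Rényi (conditioned on connectivity)
  and Barabási–Albert models are available; their correlation patterns are
  generally indefinite, so a Higham-style nearest-PD repair is applied and
  the achieved (post-repair) edge correlations are recorded in the ground
  truth for tolerance checks. Forty-node pathways (39 edges) are a
  scaled-down stand-in for curated pathway graphs, which average a few
  hundred edges;
- base edge correlation ρ = 0.7 — strongly co-regulated pathway partners
  on the log2 scale; expression is Gaussian with mean 8 and unit variance
  (no count-level realism: library size and overdispersion are out of
  scope for a correlation-based method);
- one planted pathway per tumor sample with 60% of its edges sign-flipped
  (mode `decorrelate` sets them to 0 instead); a range such as
  `planted_per_sample=(0, 4)` makes the per-sample perturbation load vary;
- mutations: per-gene Bernoulli at 2% background, ×10 on hub genes (top
  fifth by degree) of the sample's planted pathways;
- survival: exponential with baseline hazard 0.01/day and hazard
  h0·exp(γ·load_z), where load_z is the standardized count of the sample's
  perturbed edges and γ = 1; a configured fraction (20%) of samples is
  censored at a uniform fraction of the event time.

Everything is deterministic given the mandatory seed.

## Validation experiments and problem sizes

`subpathx.validation` (asserted in `tests/test_acceptance.py`, reported by
`scripts/acceptance.py`):

- **Null calibration** — 5,000 bivariate-normal replicates at n = 200.
- **Planted recovery** — default cohort, 20 tumor samples, n_perm = 1000:
  fraction of samples whose planted pathway attains the smallest FDR
  (observed 0.95–1.0 across seeds) and mean core-edge coverage of the
  planted perturbed edges (observed ≈ 0.5, see limitations).
- **Cox recovery** — 100 replicates of h(t|x) = h0·e^{0.8x}, n = 300, 20%
  censoring; fraction of estimates in [0.6, 1.0].
- **Survival pipeline** — replicates of 6 pathways × 12 nodes, 60
  reference and 240 tumor samples split 120/120 into discovery and
  validation, 0–4 planted pathways per sample; rejection rate of the
  validation log-rank at α = 0.05 with γ = 1 (power, 50 replicates) and
  γ = 0 (level, 200 replicates).
- **Permutation-test calibration** — 200 null replications of the
  random-gene mutation-ratio test on a 60-gene universe.

These sizes keep the full suite under a minute of compute; they are small
relative to real cohorts (hundreds of tumors, ~75k edges), so the
experiments demonstrate correctness and calibration, not field-scale
power.

## Known limitations

- **Core-edge coverage of planted perturbations plateaus near 0.5.** A
  planted edge is observed only through the one added sample; when that
  sample's pair of values lands near the reference centroid (roughly half
  of draws from the flipped distribution), the flipped and reference
  distributions assign it nearly equal likelihood, its edge score is close
  to zero, and it ranks mid-list — the leading edge then correctly excludes
  it. This is an information limit of single-sample perturbation scoring,
  not an implementation artifact: pathway-level recovery is near-perfect at
  the same settings, and lowering the weighting exponent to 0 trades
  coverage (~0.79) against recovery (~0.7).
- The reference correlations are never recomputed with sample exclusions;
  the fixed reference cohort is used for every tumor sample.
- Synthetic expression is Gaussian on the log scale with homogeneous
  means; passing tests demonstrates the statistics are correct under the
  stated model, not robustness to RNA-seq count noise, batch effects or
  probe-level artifacts.
- No multivariate or penalized Cox models, no time-dependent covariates;
  the gene-expression risk model uses unscaled log2 values.
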