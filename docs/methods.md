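# Methods

## Network model and conventions

All networks are simple undirected graphs over gene symbols. Symbol identity
is a case-sensitive exact string match after trimming and uppercasing at
file-reading time; no alias or identifier mapping is attempted. Edge lists
may carry a confidence score either on the unit scale or on the 0–1000
integer scale used by STRING combined scores; the scale is an explicit flag
(`unit` / `string1000`) and never auto-detected, because silently mistaking
one for the other is the classic failure mode with STRING exports. Self-loop
rows are dropped and duplicate pairs merged keeping the maximum confidence
before the retention threshold (default 0.9) is applied.

Centralities follow the conventions of the Cytoscape NetworkAnalyzer family
of tools, which this kind of analysis typically reports:

- **degree** — incident edge count;
- **betweenness** — Brandes pair-dependency sums, endpoints excluded,
  normalized by (n−1)(n−2)/2;
- **closeness** — the reachable-average form, (number of reachable
  nodes)/(sum of distances to them), 0 for isolated nodes. On connected
  graphs this equals the classical closeness; on disconnected graphs it
  scores nodes within their component rather than zeroing them.

The topology summary reports, for any graph: mean local clustering
coefficient over nodes with degree ≥ 2 (the coefficient is undefined below
degree 2 and such nodes are excluded rather than counted as zero — the
reporting tools are ambiguous here and this choice is stated rather than
hidden); diameter and radius as the extreme eccentricities of the largest
connected component (ties between equal-sized components break to the one
with the lexicographically smallest member); degree centralization
(n/(n−2))·(max_k/(n−1) − density), clipped to [0,1] and reported as 0 with a
warning when n < 3; the count of ordered node pairs at finite distance
(n(n−1) exactly when connected); the mean distance over those pairs; and
heterogeneity sd(k)/mean(k) with the population standard deviation, which is
0 iff the graph is regular. All-pairs distances are computed with
`scipy.sparse.csgraph` on the adjacency matrix, which keeps the 4313-node
check in seconds.

The scale-free diagnostic is an ordinary least-squares fit of ln(count) on
ln(k) over the raw degree histogram (k ≥ 1, count > 0, at least three
points): no binning, no cumulative transform, no maximum-likelihood
estimation. This is deliberately the straight-line log–log fit that network
plugins print as *y = a·x^b*; it is a descriptive diagnostic, not a rigorous
power-law test, and γ = −b is reported positive for *P(k) ∝ k^(−γ)*.

## Screening stage

Expression matrices are handled on the log2 scale throughout. Quantile
normalization equalizes the column distributions to the per-rank
cross-column means, with within-column ties receiving the mean of the values
their ranks span; the operation is idempotent. Probe collapsing drops probes
annotated to zero or to several genes and represents each gene by its
highest-mean probe (ties to the lexicographically smallest probe ID).

The per-gene test is a **Welch two-sample t-test with a per-group variance
floor** (default 1e−8, so constant genes give p = 1 instead of NaN), with
Benjamini–Hochberg adjustment across genes and the thresholds adj. p < 0.05,
|log₂FC| ≥ 0.5. This is a deliberate stand-in for moderated-statistics
pipelines: the thresholds are the screening rule this stage exists to apply,
and the plain Welch test makes the stage's operating characteristics exactly
computable. The cost is power at small n: at |log₂FC| = 2, σ = 1 and 10
samples per group the noncentral-t power at the self-consistent BH threshold
is ≈ 0.86, and observed recall on planted simulations is ≈ 0.83–0.85 with
empirical FDR ≈ 0.05. Variance-shrinkage methods would sit closer to 0.9;
the test suite checks the Welch test against its own theoretical power
rather than against an aspiration it cannot reach.

## Critical-network filtering and hubs

The filter is conjunctive and strict: a node survives a pass only if degree
AND betweenness AND closeness each strictly exceed that metric's median over
the current graph (even-length medians are means of the middle two). The
published description of this procedure does not say whether the combination
is AND or OR nor whether the comparison is strict; AND with strict `>` is
implemented as the plain reading and leaves vertex-transitive graphs (where
nothing exceeds its own median) correctly degenerate, with an error naming
the constant metrics. Centralities are recomputed on the filtered graph
before every pass, and each pass keeps the largest connected component by
default, because reported path counts of n(n−1) imply connected networks.
If a later pass empties the graph or drops it below 3 nodes, iteration stops
and the previous graph is returned with a warning; only first-pass emptiness
is an error. The per-pass report (node/edge counts and the applied medians)
makes every pass re-verifiable after the fact.

Hub genes are the intersection of the three top-k lists (default k = 10).
Ties at the rank-k boundary are all included, which makes the selection
deterministic and invariant under node relabeling; the resulting hub set may
be smaller than k (the intersection is usually much smaller) or empty.

## MCODE

Implemented from the published three-stage definition. The vertex weight is
k_max(H) × density(K), where H is the closed neighborhood of the vertex,
k_max its highest core order and K that highest k-core; vertices below the
degree cutoff (default 2) get weight 0. Complex prediction seeds from the
highest-weight unvisited vertex (ties lexicographic, for reproducibility)
and grows breadth-first over unvisited neighbors whose weight is ≥
seed_weight × (1 − node_score_cutoff); the comparison is ≥, i.e. threshold
ties are included, reading the cutoff as the allowed deviation from the
seed. Post-processing discards complexes without a 2-core, applies the
haircut (iterative removal of members with fewer than two intra-module
neighbors — this only prunes pendant trees and therefore preserves
connectivity), recomputes loop-free density 2E/(n(n−1)), scores modules as
density × n and keeps those strictly above 5.

One consequence of the published weighting is worth knowing: two equally
dense regions joined by a single bridge edge merge into one complex, because
each bridge endpoint inherits the full weight of its dense neighborhood
core and therefore clears the opposite seed's inclusion threshold. The test
suite pins this behavior on a pair of bridged 5-cliques rather than
pretending the algorithm separates them. Fluff (off by default, as in the
plugin) appends post-haircut neighbors whose closed-neighborhood density
exceeds the node score cutoff; fluffed modules may overlap, so the
disjointness guarantee applies only with fluff off.

## Over-representation analysis

For query size n within a universe N, term size K and overlap k, the p-value
is the hypergeometric upper tail P[X ≥ k], delegated to
`scipy.stats.hypergeom.sf` (log-space internally) and cross-checked in the
tests against exact rational enumeration for all parameters ≤ 25. The
universe defaults to the union of the collection's genes, since screening
pipelines rarely state their background; a caller-provided background is
supported and genes outside it are ignored on both the query and term side.
Terms pass only if BH-adjusted p AND a Storey-style q both fall below 0.05.
The q-values use π₀ estimated at a single λ = 0.5, floored at 1/m and capped
at 1 (at which point q reduces exactly to BH), then monotonized; this
mirrors the p.adjust/qvalue pair of the common R tooling without importing
its exact spline-based π₀ estimate. Results are sorted by adjusted p (ties:
larger overlap, then term id) and the top 10 reported.

## Synthetic data: what it emulates, and what it does not

Every generator is driven by one integer seed through named, decoupled
streams (graph / modules / expression / targets / gmt), so regenerating one
input family never perturbs the others, and identical seeds give
byte-identical files.

- `gen_scale_free` grows a preferential-attachment graph from an
  (m+1)-clique: connected, m(n−m−1)+C(m+1,2) edges, degree exponent in the
  high-1 to low-3 range that the log–log fit should recover (r² ≥ 0.7).
- `gen_planted_modules` embeds near-cliques (default exactly cliques) on
  fresh vertices in a sparse Erdős–Rényi background, attached by a stated
  number of bridge edges. The module-recovery benchmark (cliques of 8/7/6
  in a 300-node background at p = 0.01) is the ground-truth test for MCODE:
  all three planted sets must come back with Jaccard ≥ 0.8 and rank in size
  order.
- `gen_expression` plants ±lfc shifts (half up, half down) on a designated
  fraction of genes in group 1, on top of Normal(7,1) baselines and
  Normal(0,σ) noise — all on the log2 scale directly; there is no
  raw-intensity, probe-affinity or heteroscedastic noise model, so passing
  screening tests demonstrate threshold logic and calibration, not
  robustness to real microarray artifacts.
- `gen_target_sets` gives every database pair exactly the configured overlap
  via a common core, and designates a known shared subset recoverable by the
  union/intersection algebra.
- `gen_gmt` plants terms that fully contain designated gene sets, so the
  planted term must rank first for the matching query.

`SimSpec`/`generate_bundle` tie the families together into one coherent
study over a 3000-symbol universe: the 300 designated shared genes are all
planted as DE, the interaction graph is built over those genes plus a
100-gene halo (m = 4) with three cliques of 12/10/9 planted among the shared
genes, and the GMT contains one planted term per clique. These sizes were
chosen so that the pipeline's double median filter retains a workable
critical network (a few dozen nodes) across seeds; whether a specific
planted clique survives both filtering passes still varies with the seed,
which is the expected behavior of a selective filter, not a defect — the
guaranteed module-recovery claim is the direct benchmark above.

## Numerical and degenerate-input choices

- BH adjustment via `statsmodels.multipletests`; p-values clipped into
  (0, 1].
- Betweenness tolerance against the exhaustive path-enumeration oracle is
  1e−9 (floating accumulation), degree and closeness are exact.
- Empty induced subgraphs, empty intersections, all-isolated degree
  histograms, < 3 power-law points, and sub-k hub graphs raise errors;
  unknown symbols in a keep-list, disconnected graphs in path statistics,
  single-sample normalization and n < 3 centralization degrade with logged
  warnings instead.
- Pipeline stages communicate only via files; the manifest is JSON with
  sorted keys and no timestamps, so identical configurations and inputs
  produce identical manifests.

## Known limitations

- The screening stand-in trades power for transparency (see above); it also
  assumes two groups and no batch structure.
- The power-law fit is descriptive OLS, not a likelihood-based test of
  scale-freeness.
- MCODE merges bridge-connected dense regions (inherent to the published
  weighting) and its greedy expansion is order-dependent beyond the
  lexicographic tie-break.
- ORA treats terms as flat sets: no ontology-graph propagation, no
  redundancy reduction between overlapping terms.
- The synthetic expression model is Gaussian and homoscedastic on the log2
  scale; conclusions about real GEO series require the real data.
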