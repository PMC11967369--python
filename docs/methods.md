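# Methods

## The adjusted binomial association test

For a gene-disease pair the evidence is three report counts: `np` studies
finding a positive association, `nn` finding a negative one, and `n0`
whose direction is inconclusive. Writing `n_raw = np + nn + n0`, the test
asks whether the *dominant* direction — the larger of `np` and `nn` — is
over-represented relative to a null proportion `p0`, after inflating the
sample by hypothesised uncovered studies `nx = alpha * n_raw` that the
literature search missed. With the default `alpha = 1` the adjusted total
is `N = 2 * n_raw`.

Two limiting hypotheses about the uncovered studies bracket the truth:

* **Case 1** — uncovered studies mirror the observed distribution, so the
  dominant count is scaled to `s = (1 + alpha) * n_dom`. In the
  equal-count configuration `np = nn = n0 = c` the adjusted dominant
  proportion is `(1+alpha)c / (3(1+alpha)c) = 1/3` for every `alpha`;
  since a dominant direction must strictly exceed this bound, `p0` is the
  smallest two-decimal value strictly above it, **0.34**.
* **Case 2** — uncovered studies are all null, so `s = n_dom` while the
  total still doubles. The equal-count bound is `1 / (3(1+alpha))`, i.e.
  1/6 at `alpha = 1`, giving `p0 = `**0.17** after two-decimal rounding.

The p-value is the upper binomial tail `P(X >= s)` for
`X ~ Binomial(N, p0)`, computed as `binom.sf(s - 1, N, p0)`. Both cases
are always computed; the final p-value is their maximum by default (the
conservative choice — which single case underlies any published gene list
is generally not knowable), with `case1`/`case2` selectable. Tied pairs
(`np = nn > 0`) have no dominant finding: they receive `p = 1`, polarity
unknown, and are never significant. Pairs with `n_raw = 0` carry no
evidence and are excluded from testing altogether.

Benjamini-Hochberg correction is applied per disease across that
disease's covered pairs only; including uncovered genes would dilute the
family with non-tests. Pairs with `q <= 0.05` (configurable) are called
significant, with polarity equal to the dominant direction. General
`alpha` values round the adjusted totals to the nearest integer; `alpha`
is exposed purely for sensitivity analysis.

## Cross-disease overlap

Per-disease significant gene sets are compared pairwise against a fixed
universe (default 19,924 genes, the size of a whole-genome literature
screen). The 2x2 table is `a = |A∩B|`, `b = |A\B|`, `c = |B\A|`,
`d = U − |A∪B|`; significance is the one-sided (greater) Fisher exact
tail — enrichment of the overlap is the directional claim of interest;
a two-sided alternative is available — and the effect size is the sample
cross-product odds ratio `ad/bc`, with an optional Haldane–Anscombe +0.5
correction on zero cells so infinity is never produced (NaN is returned
for an undefined uncorrected ratio). Conditional-MLE odds ratios are out
of scope.

## Network metrics

Interaction networks are simple directed graphs with integer edge
weights (supporting-reference counts); duplicate edge rows merge by
summing weights. Conventions, fixed once:

* **density** uses the directed denominator `n(n−1)` — for sparse
  literature-derived networks this is the only convention under which
  reported (nodes, edges, density) triples such as (15, 87, 0.41),
  (22, 201, 0.44) and (33, 411, 0.39) are internally consistent; the
  undirected denominator gives 0.83 for the first triple and is kept in
  the test suite as a negative control;
* **average path length, diameter, clustering** are computed on the
  undirected, unweighted projection of the largest connected component
  (directed reachability in sparse digraphs is routinely broken and would
  make these undefined or inflated); nodes of degree < 2 contribute 0 to
  mean clustering;
* **centralities** are unweighted: in/out-degree normalised by `n−1`
  (hence in [0, 1]), betweenness on the directed graph with standard pair
  normalisation, eigenvector centrality on the undirected projection via
  power iteration (tolerance 1e−10, ≤ 1000 iterations; non-convergence
  raises naming the component) rescaled so the maximum is 1. Edge weights
  enter only the total-weight statistic, since reported normalised degree
  values ≤ 1 imply unweighted normalisation.

Hubs are a rank consensus: nodes are ranked under each of the four
centralities (rank 1 highest, ties averaged) and the top `k` (default 5)
by mean rank are returned, mean-rank ties broken lexicographically for
determinism.

## Term-set enrichment

Standard hypergeometric over-representation of a query set against any
GMT term collection: `P(X >= k)` for `k` query genes in a term of `K`
universe genes, fold enrichment `(k/n)/(K/N)`, BH q-values across tested
terms, terms without query members skipped, term memberships intersected
with the universe. The EASE variant (decrement `k` by one before the
tail) is offered because annotation web services use it; the classical
tail is the default for textbook verifiability. Published enrichment
values from web services depend on service-side backgrounds and catalogs
and are treated as non-reproducible context, not targets.

## Signed pathway graphs

Significant associations become edges between typed nodes (disease or
gene), oriented by an explicit `(gene, disease) -> orientation` map —
no orientation rule is derivable from counts, so on synthetic runs the
pipeline assigns orientations reproducibly from the run seed. Edge
polarity is the association's direction; ties map to unknown. A gene `g`
mediates disease A to disease B when edges `A→g` and `g→B` both exist;
the composed sign follows the product rule (+·+ = −·− = +, +·− = −) with
unknown absorbing — the simplest algebra consistent with three-valued
edge colours; it is commutative and associative over {+, −}. The two
orientations of a disease pair are independent queries.

## Synthetic corpus generator

The generator emulates the structure, not the content, of a mined
literature corpus over `n_genes` genes (default 19,924) and a disease
panel. Per disease, `round(planted_fraction * n_genes)` pairs are truly
associated; `shared_planted_fraction` of genes is planted jointly in all
diseases to create cross-disease overlap structure. Planted pairs draw
their dominant-direction count from Poisson(`lambda_signal`), the
minority direction and inconclusive counts from Poisson(`lambda_noise`)
and Poisson(`lambda_incon`); the dominant direction is positive with
probability `positive_polarity_prob` (default 0.8, so negative-polarity
calling is exercised too). Covered null pairs draw all three counts from
the noise/inconclusive rates. Zero-inflation is explicit: only
`coverage_fraction` of pairs carries any literature; planted pairs are
always covered (an association with no reports would be undetectable by
construction, so `coverage_fraction >= planted_fraction` is required),
and covered pairs' count triplets are truncated at zero (all-zero draws
resampled) so the realised coverage matches the configured fraction
exactly rather than drifting by the Poisson zero mass.

Defaults (`lambda_signal = 5`, `lambda_noise = 0.8`, `lambda_incon = 0.5`,
`coverage_fraction = 0.25`, `planted_fraction = 0.02`) were chosen once to
resemble a corpus where a significant gene is supported by a handful of
references and a quarter of the genome has any literature; the empirical
reference-count distribution of real corpora is unpublished, so these are
plausibility choices, not estimates. PPI edges are independent Bernoulli
draws per ordered pair (no self-loops) with weights `1 +
Poisson(weight_lambda)` and uniform random signs; term sets are uniform
random draws without replacement. Everything is driven by
`numpy.random.default_rng(seed)` (default seed 20250320) and serialises
byte-identically under a fixed configuration.

What the generator does **not** model: citation dependence between
reports, per-gene heterogeneity in literature volume, topical correlation
between term sets and planted genes, degree heterogeneity or modularity in
the interaction network, and publication metadata. Passing tests
therefore demonstrate correctness of the statistical machinery and
calibration under independent-report assumptions, not performance on real
literature corpora.

## Verification design

Every non-trivial computation has an independent oracle in the test
suite: adjusted binomial p-values against brute-force pmf summation over
all count triples with `n_raw <= 50` (relative error <= 1e−10), Fisher
and hypergeometric tails against exhaustive enumeration (universes up to
200 and 500), BH against a naive quadratic step-up, eigenvector
centrality against dense eigendecomposition (n <= 50, 1e−8). Statistical
acceptance checks run at the stated study conditions: 20 null corpora of
2,000 genes for calibration (empirical significant-call rate within
0.05 + 3 SE; the test is in fact conservative, because the max-rule
combined p-value and the adjustment algebra both bound the null tail),
recall >= 0.9 of planted genes at `lambda_signal = 20` vs noise 1, and
detection of a 5% shared planted structure at Fisher p < 0.05 in >= 95 of
100 seeds. These sizes keep the full suite under a minute of compute
while leaving Monte-Carlo standard errors far below the tested margins.

## Known limitations

* The max-rule combined p-value is conservative; calibration is well
  below the nominal FDR on null corpora rather than at it.
* Cross-product odds ratios on overlap tables are not comparable across
  different universes, and reported odds ratios in literature tables are
  often irrecoverable from their own counts; this package reports the
  defined cross-product quantity only.
* Edge orientation and sign in pathway graphs are inputs, not inferences;
  nothing here is causal.
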