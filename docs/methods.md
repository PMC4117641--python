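# Methods

This note describes the statistical procedures the package implements, the
parameters that matter, what the synthetic data generator does and does not
emulate, and the design choices made where the design was genuinely open.

## The question

A genetic modifier screen in a model organism and a human GWAS produce two
gene lists that typically share no members. The hypothesis behind the
package is that convergence, if any, happens at the level of network
neighbourhoods: the products of the two lists may interact with the same
proteins even when the lists themselves are disjoint. The unit of
comparison is therefore the **+1 interactome** — a gene set together with
every gene whose product physically interacts with at least one member
(first-degree neighbourhood; seeds are always members; self-loops are kept
as metadata but never counted as neighbours, since the seed rule already
includes every gene in its own neighbourhood).

## Orthology mapping and enrichment

Each worm gene may have several candidate human orthologues annotated with
percent amino-acid identity and a consistency score in [0, 1] (1 = the call
is supported by every source database). Selection keeps the candidate with
the highest identity at or above `min_identity` (default 25%, inclusive),
breaking ties by consistency score and then by the lexicographically
smallest human symbol. The residual lexicographic tie-break is our
addition: the consistency score can itself tie, and a deterministic rule is
required for reproducible runs; residual ties are logged.

Whether screen hits are enriched for orthologue-bearing genes is an exact
one-sided binomial test: with a universe of 7970 orthologue-bearing genes
out of ~20000, observing k mapped hits among n is scored as
P(X ≥ k), X ~ Binomial(n, 7970/20000), evaluated exactly through the
regularised incomplete beta function (no normal approximation). The
packaged screen lists give k = 61 of n = 78 and p ≈ 5.7e-12. Note the
packaged orthologue fixture lists 63 human symbols while the mapping count
used in the enrichment test is 61; the two counts come from different
stages of the original curation and both are shipped as-is.

## Size-matched Monte Carlo overlap test

Per-gene question: is the overlap between gene g's +1 interactome and the
reference (GWAS) +1 interactome larger or smaller than chance? Screen hits
are strongly hub-biased, and a hub's neighbourhood overlaps anything by
sheer size, so the null must be **size-matched**:

1. Compute s = |+1 interactome of g| and the observed overlap with the
   fixed reference member set (the reference +1 interactome is computed
   once and reused).
2. Grow a random +1 interactome of exactly s genes: draw universe genes
   (human genes with worm orthologues, restricted to network members)
   uniformly without replacement; union each drawn gene's +1 members into
   the accumulator; when the final gene's contribution would overshoot,
   add its new members in random order and stop at s (equivalently, a
   uniform random subset of the right size). Exhausting the universe first
   is an error that reports the achieved size.
3. Repeat `n_sim` times (default 1000); count n_right = #{overlap ≥
   observed} and n_left = #{overlap ≤ observed}. Equality counts in both
   tails, exactly as the procedure is defined; this makes the p-value
   conservative. An optional mid-p variant (half weight on ties) is
   provided but off by default.
4. p = min(n_right, n_left)/n_sim, floored at 1/n_sim so that p is always
   in {1/n_sim, …, 1} (the floor matters only when the observed overlap
   lies outside every simulated value). Direction is "larger" when
   n_right ≤ n_left; the exact tie n_right = n_left is assigned "larger"
   and logged.

The test suite validates the whole construction against exhaustive
enumeration on a 12-gene toy network: every achievable draw order is
enumerated with exact rational arithmetic, the truncation step marginalised
analytically as a hypergeometric draw, and the empirical tails at
n_sim = 5000 must fall within three standard errors of the exact tails.

**Calibration.** Because p is the minimum of two overlapping one-sided
tails, its null rejection rate at threshold α is bounded by 2α but pulled
below that by the discreteness of overlap counts. On the synthetic null
network the measured per-gene rate at α = 0.05 is ~0.04, inside the
expected [0.01, 0.12] band.

**List-level significance** repeats the per-gene screen on `n_lists`
random lists of `list_size` universe genes (defaults 100 × 60) and
reports the mean number of significant genes per list, a
normal-approximation 95% CI half-width (1.96·sd/√n_lists), and the
fraction of lists with at least k significant genes, k being the observed
count.

## Connectivity-bias analysis

All network genes are ranked by interactor count (descending, ties broken
lexicographically) and split into `n_bins` (default 10) contiguous rank
intervals each containing the same number of **universe** genes (remainder
spread one per bin over the earliest bins; the last bin absorbs the
ranking tail). By construction a random universe list lands uniformly
across bins. A gene list's per-bin fractions (denominator = full list
size; genes absent from the ranking are logged) are summarised by an OLS
fit of log₁₀(fraction) on log₁₀(bin boundary). Zero-count bins are
excluded from the fit (their log is undefined); fewer than two usable
points is an error. The x-coordinate is the **upper** rank boundary of each
bin by default; the lower-boundary variant is available via an option, and
the choice shifts the intercept but leaves a flat profile at slope 0 and
barely moves non-flat slopes.

Significance: `n_lists` random lists of the experimental list's size are
drawn from the universe and fitted; the Monte Carlo slope sample is tested
against the experimental slope with a one-sample Student's *t*-test
(scipy). We chose the orientation "MC slopes are the sample, the
experimental slope the reference value" because a single experimental fit
yields no within-list variance of its own. `tails="one"` tests whether the
experimental slope is significantly more negative than random (the
hub-bias direction); `tails="two"` is the default. MC replicates whose fit
fails are dropped with a warning; fewer than 10 survivors is an error.

## Synthetic data

`generate_network` grows an undirected simple graph by degree-proportional
attachment: a fully connected nucleus of m+1 genes, then each new gene
attaches to m distinct existing genes with probability proportional to
current degree (so the edge count is exactly m(m+1)/2 + m(n−m−1)). This is
the simplest generative rule producing the heavy-tailed degree structure
that makes hub bias reproducible; the exact degree exponent is not a
contract. Default sizes are deliberately scaled down from a real
interactome — 2000 genes, a 40% universe (800 genes), 60-gene GWAS and
hit lists — so whole-pipeline tests run in seconds.

`plant_lists` draws the universe and GWAS list uniformly, then builds a hit
list in which each hit is, with probability π (`enrichment`), a planted
"enriched" gene. Candidate enriched genes are the top decile of
non-GWAS universe genes ranked by +1 overlap with the GWAS +1 interactome
normalised by their own +1 size (so hubs are not trivially favoured). Two
empirical facts shaped the rest of the design:

- **Selection alone cannot plant a recoverable signal.** A gene's
  empirical overlap p is a deterministic property of the network, and on a
  null network only a few percent of genes are genuinely anomalous; no
  ranking of a top-decile pool can make 80% of it detectable at α = 0.05.
  Planting is therefore **structural**: each enriched hit is additionally
  wired to randomly chosen non-seed members of the GWAS +1 interactome
  until its own +1 neighbourhood has ≥ 60 members of which ≥ 90% are
  reference members (reference membership itself is unchanged, since new
  edges never touch the GWAS seeds). The input network is modified in
  place, and the fixture bundle serialises the post-planting graph.
- **Planted prevalence must stay small relative to the universe.** Planted
  hits are universe genes, so the size-matched null redraws their boosted
  neighbourhoods; at 60 planted genes in an 800-gene universe (7.5%) the
  null right tail gains ~7% mass and α = 0.05 power saturates around 0.6
  regardless of signal strength. The real screen's prevalence is 60/7970
  ≈ 0.75%. Power and monotonicity experiments therefore use 24 planted
  hits (3% prevalence) at the otherwise-default scaled conditions, where
  measured power at π = 1, n_sim = 1000 is ≥ 0.95 across seeds.

What the generator does **not** emulate: real interactome size (13940
genes), literature-driven ascertainment bias in interaction reporting,
correlated false positives in GWAS candidate lists, or any biology of the
planted genes. Passing tests demonstrate that the statistical machinery is
correct and calibrated under a known-truth heavy-tailed network, not that
any particular biological conclusion follows from real data.

## Numerical and procedural choices

- Gene identity is case-insensitive; symbols are uppercased at ingest.
- Default interaction filters: taxid 9606, physical interactions only;
  both are configurable, and the BioGRID reader resolves columns by header
  name to survive TAB2/TAB3 dialect drift.
- A single run seed is forked per stage by fixed string labels
  (CRC32-keyed `SeedSequence`), so adding a stage never perturbs another
  stage's draws; identical seeds give byte-identical report files.
- Results tables are sorted by ascending p, ties by gene symbol.
- The overlap count is over genes, not interactions, and a gene that is
  itself a reference member counts in the overlap.
- Problem sizes in the test suite and acceptance script (n_sim 200–5000,
  50 × 60 calibration draws, 24 planted hits) were chosen as the smallest
  sizes at which the sampling error of each check is well below its
  acceptance band.

## Known limitations

- The empirical p resolution is 1/n_sim; genes with p at the floor should
  be reported as "p ≤ 1/n_sim".
- The min-of-two-tails construction is conservative and its rejection rate
  is not exactly α; the mid-p option trades conservatism for calibration.
- The random +1 interactome null fixes the network and randomises seeds;
  it is not a degree-preserving edge-rewiring null, and no multiple-testing
  correction is applied across genes.
- Orthologue selection consumes precomputed identities; no sequence
  alignment is performed, and no identifier alias resolution beyond case
  normalisation is attempted.
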