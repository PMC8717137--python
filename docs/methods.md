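# Methods

`ohcnet` analyzes patient-forum post records the way observational studies
of online health communities (OHCs) do: descriptive statistics and
parametric fits of engagement counts, a directed reply network and its
small-world / scale-free structure, temporal posting profiles, and a
keyword co-occurrence ("weighted knowledge") network mined from the post
text. This note documents the models, the conventions chosen where several
are defensible, and what the synthetic-data generator does and does not
emulate.

## Data model

A *post* is either a thread root or a reply to a thread. Crawled forum data
expose read and reply counts on roots only, so `PostRecord` carries
`n_reads`/`n_replies` as optional fields that are `None` on replies. There
is no reply-to-reply parent field in this data model; a reply is always
attributed to the thread's root author.

## Reply network

Users are nodes. A reply by user *u* to a thread authored by *v* (with
*u* ≠ *v*) contributes to the directed edge *u* → *v*; the edge weight is
the number of such replies, and the reply timestamps are stored on the edge
for windowed snapshots. Self-replies create no edge. Direction is
configurable (`author_to_replier` transposes the graph); total degrees,
which drive all the headline results, are unaffected by the choice.

Yearly snapshots use only posts timestamped within the calendar year, and a
user counts as active in a year if they posted in it. Retention ratios are
reported as later-year / earlier-year counts in percent.

## Topological statistics

All topology is computed on the binary adjacency; edge weights are ignored.

* **Local clustering** of node *k*: let the neighborhood be the union of
  in- and out-neighbors (size *n*); the coefficient is the number of
  directed links among those neighbors divided by *n*(*n*−1), and 0 by
  convention when *n* < 2. On a symmetric adjacency this reduces exactly to
  Watts–Strogatz clustering (which is how it is cross-checked against
  networkx); on directed graphs it intentionally differs from Fagiolo's
  directed clustering, so the test oracle is a brute-force enumeration of
  neighbor pairs.
* **Average path length** *L*: shortest-path distances *d<sub>ij</sub>*
  with *d<sub>ij</sub>* = 0 when *i* = *j* or *j* is unreachable. The
  default ("all_pairs") mode divides the sum of finite distances by
  *N*(*N*−1) over ordered pairs, so unreachable pairs deflate *L* on
  fragmented graphs; a "reachable" mode averaging over finite positive
  distances only is provided because directed reply graphs are rarely
  strongly connected. The identity
  *L*<sub>all_pairs</sub> = *L*<sub>reachable</sub> × (fraction of reachable
  pairs) holds exactly and is tested.
* **Small-world σ**: against Erdős–Rényi equivalents with the observed node
  and edge counts and modality (directed stays directed). Each null is a
  uniform draw of exactly *M* distinct non-loop edges — equivalent to
  repeatedly linking a uniformly chosen currently-unlinked pair. Per
  replicate *i*, σ<sub>i</sub> = (C/C<sub>r,i</sub>)/(L/L<sub>r,i</sub>);
  the mean and SD over replicates (default 50) are reported. Replicates
  with zero null clustering are unusable and skipped; all-unusable raises.
  A triangle-free observed graph legitimately yields σ = 0.

Distances come from `scipy.sparse.csgraph` BFS and clustering from dense
neighborhood submatrices below 4000 nodes, which keeps 50-replicate σ on a
~2000-node graph under a minute on one CPU.

## Distribution characterization

* `describe`: quartiles by linear interpolation, sample SD (n−1), CV =
  SD/mean (flagged undefined when the mean is 0 with positive SD), adjusted
  Fisher–Pearson sample skewness. Printed values round half-up.
* `fit_gamma_ks`: two-parameter gamma by maximum likelihood (location fixed
  at 0), then a one-sample Kolmogorov–Smirnov test against the fitted
  gamma; H = 1 iff p < α (default 0.05). Estimating parameters from the
  same sample makes the plain K-S test conservative — the type-I rate sits
  below the nominal α, which the acceptance suite verifies by simulation
  (≤ 10% rejections on gamma data).
* `fit_histogram_curve`: ordinary least squares in the log domain —
  log₁₀y on log₁₀x for the power law *y* = *c·x*<sup>−*r*</sup>, ln y on x
  for the exponential *y* = *a·e*<sup>*bx*</sup> — with adjusted
  R² = 1 − (1−R²)(n−1)/(n−p−1), p = 2. Nonpositive frequencies are dropped
  (counted and reported); fewer than three surviving points is an error.
  Log-domain OLS is an estimator for multiplicative error; additive noise
  in a decayed tail will bias it, which is why the histogram inputs are
  raw frequencies rather than tail-extended densities.
* `fit_power_law` (raw samples): aggregates the sample histogram into
  logarithmically growing integer bins and fits bin densities by the same
  log-log OLS. Per-integer-degree OLS underestimates a Zipf(2.0) exponent
  by roughly 1.0 because singleton tail bins dominate the regression;
  log-binning recovers it within about ±0.15 at n = 20,000. A discrete
  maximum-likelihood estimate (zeta-normalized likelihood) is provided as
  an independent cross-check, never as the reported fit.

## Temporal profiles

Weekday profiles start on Monday; hour bins truncate (09:59 → bin 9).
Profiles are percentages summing to 100 and are compared by Spearman rank
correlation with average ranks for ties and a two-tailed p-value. Replies
are binned by their own timestamp, not their parent thread's. All
timestamps are naive local datetimes; no timezone arithmetic.

## Phrase mining and the weighted knowledge network

For adjacent word pairs within a post (bigrams never span posts):

* PMI = log₂ [ p(x,y) / (p(x)·p(y)) ], with p(x) the token's share of all
  tokens and p(x,y) the pair's share of all adjacency slots. Pairs that
  never occur adjacently are excluded from candidacy rather than assigned
  −∞.
* Left/right branch entropy: Shannon entropy (base 2) of the empirical
  distribution of words immediately beside the unit. For a candidate pair
  the concatenated pair is treated as the unit. No context on a side
  (corpus-edge occurrences only) gives 0 by convention.
* Phrase score = PMI + E_L + E_R (a `pmi_only` scoring exists for
  sensitivity checks). Candidates below `min_frequency` (default 2) are
  dropped because singleton adjacencies have degenerate entropies. Ranking
  is by score, then frequency, then lexicographic pair — fully
  deterministic. Stopword removal and synonym merging are user-supplied
  lists applied before counting (defaults empty).

The WKN treats each keyword of the selected top-K phrases as a node with
weight m(k)/M (its occurrence share within the selected phrases) and each
phrase as an undirected edge with weight n(e)/N (its share of phrase
occurrences). Both weight sets sum to 1 exactly; self-pairs (x, x) cannot
form an edge and are excluded before normalization so the invariant holds.
Keywords are classified into the eight standard OHC topic categories via a
CSV lexicon; multi-category keywords resolve first-match-wins in file
order. Period comparison splits posts at a cut instant (boundary goes to
the later period), builds one WKN per period, and reports per-period node
weights with new/disappeared/shared status — a descriptive comparison, no
test attached. Ego networks keep parent weights without renormalization.

## Synthetic forum generator

The generator emulates the statistical regularities this kind of analysis
assumes, at a desk scale of 2000 users and 5000 threads by default:

* **Reads per thread**: gamma draws rounded to integer counts and floored
  at 1. Default (shape 1.2, scale 900) gives a mean near 1100 with strong
  right skew. The shape is kept slightly above 1 so that integer rounding
  stays negligible against the K-S tolerance; crawled forums show CVs up to
  ~2 (shape < 1), a regime where integer reads near zero would break the
  continuous-gamma test, so the generator trades some skew for
  self-consistency of the count data model.
* **Replies per thread**: exponential draws (mean 12) rounded and realized
  as actual reply records, so record-level and count-level views agree
  exactly.
* **Activity heterogeneity**: each user has a power-law propensity
  (zipf, default exponent 1.5) winsorized at the population size — the
  natural finite-size cutoff; without it a single extreme draw absorbs
  nearly all activity. Reply *authors* are drawn proportional to this
  propensity: uniform authorship would give every user ≈R/n expected
  replies, i.e. a Poisson out-degree hump instead of the power-law
  involvement real forums show.
* **Preferential attachment**: thread-root authors are chosen with
  probability ∝ (replies already received + attachment_strength × base
  propensity). Rich-get-richer accumulation produces the scale-free reply
  network: at the defaults the total-degree fit gives exponent ≈ 1.4 and
  adjusted R² ≈ 0.99, with ~33% of active users at degree 1 — inside the
  envelope reported for real disease forums.
* **Followers**: independent zipf draws (default exponent 1.8).
* **Timestamps**: days weighted by a weekday profile (weekdays > weekends),
  hour of day by a 24-bin profile with peaks at 10:00, 16:00 and 21:00 and
  mealtime dips at 12:00 and 18:00; minutes and seconds uniform.
* **Text**: uniform background tokens per post with planted collocation
  pairs inserted adjacently a configured number of times; the planted
  frequency is a construction guarantee, not an expectation.

Everything derives from one integer seed through per-component seeds
(stable SHA-256 hashing of component names), so identical (config, seed)
pairs give byte-identical serialized datasets, and changing one component
never perturbs another's randomness.

What the generator does **not** emulate: any correlation between reads and
replies (an optional rank-coupling knob exists, default off, because the
joint distribution is unknown); reply timing relative to the parent thread;
user churn; natural-language structure beyond planted adjacencies; reads
accumulating over time. Passing tests therefore demonstrate that the
analysis recovers the marginal and structural properties it targets — not
that it would be robust to, e.g., correlated engagement metrics or
segmentation noise in real Chinese-language forums.

## Problem sizes

The test suite and the acceptance script run the generator at its default
scale (2000 users / 5000 threads, ~65k posts), σ calibration at 500 nodes /
3000 edges over 20 seeds × 50 replicates, the small-world reference
construction at 1000 nodes, and the fitting recovery experiments at
2000–20,000 samples — sizes at which every estimate is stable yet a full
run completes in minutes on a single CPU.

## Known limitations

* The "all_pairs" path-length convention deflates L on fragmented directed
  graphs; use `mode="reachable"` when comparing against strongly connected
  references.
* Log-binned OLS exponent recovery degrades for exponents ≳ 2.5 (bias up
  to ~−0.25 at n = 20,000); the MLE cross-check does not.
* The K-S gamma decision is conservative with estimated parameters; a
  Lilliefors-corrected variant is deliberately not used, to match the plain
  test conventionally reported.
* Tokenization is out of scope: the package consumes pre-tokenized text
  and exposes stopword/synonym hooks only.
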