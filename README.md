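# ohcnet

Social-network and content analysis of **online health communities**
(OHCs) — patient forums where people discuss a disease, ask for advice and
support each other. Given post records (thread roots and replies, with
author, timestamp, read/reply counts and tokenized text), the package
answers the questions observational OHC studies ask:

* How are engagement counts distributed? Reads per thread are summarized
  and tested against a **gamma** law (maximum likelihood + one-sample K-S
  decision *H*); reply counts against an **exponential** *y = a·e^{bx}*;
  follower counts, thread involvement and user degrees against a **power
  law** *P(k) = c·k^{−r}*, fitted by log-domain least squares with adjusted
  R².
* Is the reply network **small-world** and **scale-free**? Users are nodes
  and a reply by *u* to a thread of *v* is a directed edge *u → v*. The
  small-world coefficient σ = (C/C_r)/(L/L_r) compares the observed average
  clustering C and path length L to Erdős–Rényi equivalents with the same
  node and edge counts, replicated 50 times; σ > 1 indicates a small world.
* When do users post? Weekday and hour-of-day profiles, compared across
  post kinds and forums by Spearman rank correlation.
* What do users talk about? Adjacent word pairs are scored by
  **PMI + left/right branch entropy**; the top-K phrases form a **weighted
  knowledge network** (WKN) with keyword node weights *q(k) = m(k)/M* and
  co-occurrence edge weights *q(e) = n(e)/N*, keyword topic classification
  via a lexicon, period splits, and ego networks.

Crawled forum data are rarely shareable, so the package ships a seeded
**synthetic forum generator** that reproduces the statistical structure
these analyses assume — gamma reads, exponential replies, power-law
activity with preferential attachment, diurnal profiles with mealtime dips,
and planted collocations — making every stage testable end to end.

## Worked example

```python
from ohcnet.synth import SynthConfig, generate_forum
from ohcnet import network, netstats, distfit, temporal, phrases, wkn

ds = generate_forum(SynthConfig(n_users=800, n_threads=2000, seed=7))

g = network.build_reply_graph(ds)
sw = netstats.small_world_sigma(g, n_replicates=50, seed=1)
gam = distfit.fit_gamma_ks([p.n_reads for p in ds.thread_roots()])
summ = network.degree_summary(g)
fit = distfit.fit_power_law(summ.frame["total_degree"].to_numpy())
ranked = phrases.extract_key_phrases(ds.posts, top_k=200)
kg = wkn.build_wkn(ranked, forum=ds.forum_name)
```

Output of the session above:

```
posts: 26021 threads: 2000
nodes/edges: 565 5745
avg clustering: 0.551 | L: 0.316 | diameter: 5
sigma: 287.15 +- 7.27
gamma shape/scale: 1.22 854.0 H: 0
degree power law: r = 1.389  adj R2 = 0.986
degree shares: {'exact': 30.4, 'high': 7.3, 'low': 65.3}
top-3 hours: [9, 16, 21]
top phrase: ('blood', 'glucose') score 25.56 freq 120
WKN: 282 keywords, 200 edges
```

Reading the numbers: the 565 active users form a directed reply network
whose clustering is orders of magnitude above its random-graph null at a
comparable path length, hence σ ≈ 287 ≫ 1 — a small world. The K-S test
keeps the gamma family for reads (*H* = 0, recovering the generating shape
1.2/scale 900), and the total-degree histogram is an excellent power law
(adjusted R² ≈ 0.99) with ~30% of users at degree 1 — most users touch the
forum once while a few hubs accumulate hundreds of contacts. The planted
collocation "blood glucose" tops the phrase ranking and anchors the WKN.

The same stages are available from a CLI (`ohcnet simulate | network |
netstats | distfit | temporal | phrases | wkn | run | report`), with the
full pipeline driven by a YAML config:

```bash
ohcnet simulate --out data --seed 7 --n-users 800 --n-threads 2000
ohcnet netstats data/posts.csv --replicates 50 --seed 1
```

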