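# Methods

## The analysis model

`netpharm` treats a herbal preparation as a bipartite-plus relation: a set
of chemical ingredients, the proteins those ingredients are predicted to
bind, and the annotated pathways those proteins belong to. The analysis
assumes the interaction and membership tables are given (harvested from
target-prediction and pathway databases, or simulated); the package's job
is the screening, testing, graph construction and graph statistics that
turn those tables into a ranking of ingredients and proteins.

All graphs are **simple and undirected**. The centrality and path formulas
used here assume unweighted edges, so shared-pathway multiplicities in the
protein projection are kept only as an edge annotation (`shared_pathways`)
and never enter any metric.

## Screening

The rule-of-five filter keeps a compound iff MW < 500 g/mol, HBD ≤ 5,
HBA ≤ 10 and MlogP ≤ 5. The asymmetry (strict bound on MW, inclusive on
the rest) follows the way the criteria are conventionally printed; the
boundary tests pin this down (MW = 500 rejected, HBD = 5 kept). The
historical name "rule of five" notwithstanding, there are four criteria;
no fifth rule is applied. Physicochemical properties are *inputs* — the
package never computes them from structures.

The support filter keeps a target iff it has interaction rows from at
least `min_support` **distinct** compounds (default 5, i.e. "fewer than
five" removed). The default cascade order is rule-of-five → restrict
interactions to drug-like compounds → support filter → drop targetless
compounds. Whether the support filter should run before or after the
drug-likeness restriction is genuinely ambiguous in this kind of study;
the order is therefore explicit in `screen()` and each filter is also
callable on its own. All filters partition their input exactly
(kept + rejected = input), are idempotent, and are insensitive to row
order.

## Pathway over-representation

The test statistic is the one-sided hypergeometric upper tail
P(X ≥ k), k = |query ∩ pathway|, the field-standard choice for annotation
sets. It is computed by **exact big-integer combinatorics**: the integer
sum Σ_{j≥k} C(K,j)·C(N−K, n−j) divided by C(N, n). At this package's
problem sizes (universes of a few hundred to a few thousand proteins) the
sum costs microseconds and is exact up to one float conversion, which is
both simpler and strictly more accurate than log-space accumulation. The
acceptance suite verifies agreement with an independently coded rational
(per-term `Fraction`) oracle to 1e−12 relative error and cross-checks
`scipy.stats.hypergeom`.

Decisions:

* **Background universe** defaults to the union of all pathway members and
  the query, because no external universe is available offline; it is
  overridable everywhere (`background=` / `--background` /
  `background_path`). With the default background equal to the query the
  test is degenerate (every tail is 1) — this is the correct behaviour,
  not a bug, and the study-bundle worked example shows it.
* **No multiplicity correction by default**: significance is called on the
  raw p at α = 0.01, matching how a single-threshold pathway screen is
  usually reported; Benjamini–Hochberg is available by flag. Both the
  number of annotated pathways and the number passing the threshold are
  reported, since "N pathways involved" claims are ambiguous between the
  two.
* Pathway sets are intersected with the background before testing;
  pathways emptied by the restriction are skipped, and duplicate
  memberships are deduplicated (sets, with a log line).

## Network construction

* **Tripartite network**: nodes are ingredients, targets and pathways;
  edges are interaction pairs and (target, pathway) membership pairs. Role
  collisions (one id used as two roles) are an error. Ingredient–pathway
  edges cannot exist by construction.
* **Core subnetwork**: given a key pathway, take its member targets T, the
  ingredients adjacent to at least one member of T, the pathway–T edges
  and the ingredient–T edges — no other pathway. The key pathway defaults
  to the pathway node of **maximal degree** (ties by ascending id), the
  operational reading of "most important pathway"; it can be named
  explicitly. Note the admission rule for ingredients (edges into T only)
  is one of two defensible readings; it is the one consistent with the
  bundled case study's 59-node/150-edge core.
* **Protein association projection**: edge (u, v) iff u and v share ≥ 1
  pathway; members of singleton pathways that share with nobody are
  excluded ("isolated nodes removed") — structurally, nodes only ever
  enter via edges.

## Graph statistics

* ⟨k⟩ = 2E/N is an exact rational identity, asserted against the per-node
  degree mean in tests.
* **L and D** are computed by BFS over all pairs; on disconnected graphs
  they are taken over *connected* pairs only and the report carries a
  `connected` flag. L ≥ 1 and D ≥ L on any graph with ≥ 2 nodes.
* **Clustering**: C_i = 2e_i/(k_i(k_i−1)) with e_i the number of edges
  among i's neighbours. The formula is undefined for k_i < 2; C_i = 0 is
  used there so the per-node distribution is total, and the report carries
  both the all-node mean and the k ≥ 2-only mean.
* **Betweenness** uses Brandes' accumulation (networkx); the raw value
  sums over unordered pairs. Because reported Cb values in this field are
  usually normalized, the per-node table carries both `Cb_raw` and
  `Cb` = raw/((N−1)(N−2)/2). The exhaustive geodesic-enumeration oracle
  exists only in the test suite, where it validates the fast
  implementation on hundreds of random graphs.
* **Closeness** is computed per connected component with the component
  size in place of N (`wf_improved=False` semantics); singleton components
  get 0. The formula silently assumes connectivity; this is the standard
  repair.
* **Power-law fit**: least squares on (log₁₀ k, log₁₀ P(k)) over nonzero
  entries with k ≥ 1, γ = −slope, requiring ≥ 3 support points.
  Maximum-likelihood (Clauset-style) fitting is deliberately out of scope:
  the log–log regression is what the qualitative "approximately
  scale-free" claim in this analysis style rests on, and the acceptance
  suite shows it recovers a planted γ = 2.5 within ±0.4 at N = 2000.
* **Small-world comparison**: baselines are uniform G(N, E) graphs with
  matched node and edge counts (default 100 replicates, seeded); C_rand
  and L_rand are replicate means, path length on the largest component
  when a replicate is disconnected; σ = (C̄/C_rand)/(L/L_rand). A bare
  "short L, high C" claim is not testable without a baseline; σ makes it
  one.
* **Rankings** break ties by ascending node id, for determinism across
  runs and platforms.
* **Centrality outliers**: per axis (Cd, Cb, Cc), robust z =
  0.6745·(x − median)/MAD, flagging z > threshold (default 2) on ≥ 1 axis —
  only the high side, since the analysis seeks unusually central nodes.
  A zero-MAD axis falls back to the mean absolute deviation; if every axis
  is fully degenerate a warning is issued and only strict per-axis maxima
  can be flagged. This replaces the visual identification of outliers in a
  3-D centrality scatter with a reproducible numeric rule.

## Synthetic data

The generators define the conditions the analysis is tested under:

| parameter | default | meaning |
|---|---|---|
| `n_compounds` | 91 | compounds identified in the mixture |
| `druglike_fraction` | 0.87 | share passing the rule of five (→ 79 of 91) |
| `n_targets` | 191 | candidate protein targets |
| `n_pathways` | 70 | annotated pathways |
| `hub_fraction` | 0.05 | share of compounds that are hubs |
| `hub_target_range` | (90, 110) | targets per hub compound |
| `nonhub_target_range` | (0, 12) | targets per ordinary compound |
| `dominant_pathway_coverage` | 0.26 | share of targets in the dominant pathway (→ 50 of 191) |

The defaults mirror the bundled essential-oil case study: two hub
ingredients reaching ~100 targets each, one pathway touching about a
quarter of all targets, and a drug-like fraction of 87%. Target
popularity is Zipf-weighted (weight ∝ rank^−0.8) so per-target support is
heavy-tailed; an enforcement step guarantees, for n_targets ≥ 10, at least
one target below and one at/above the default support threshold, so the
support filter is always exercised (the enforcement never creates links
for compounds the range left isolated). Abundances are decorative —
positive, summing to ≤ 100 — because the analysis is unweighted. All
randomness flows through one seeded `numpy.random.Generator` per dataset;
identical config + seed gives byte-identical serialized output.

`graph_from_degree_table` realizes a degree-frequency table as a concrete
simple graph: Erdős–Gallai graphicality check, stub pairing (configuration
model), then degree-preserving double-edge swaps to remove self-loops and
parallel edges, re-drawing the pairing with a fresh sub-seed if a repair
stalls (bounded restarts, then an explicit error). The realized degree
sequence equals the requested one exactly.

The deterministic `study_shaped_bundle()` reproduces the case study's
composition *exactly* (91/79/44 compounds, 191 targets, 70 pathways, 879
tripartite links, hub degrees 106 and 96, a 50-protein dominant pathway
whose core subnetwork is 8 + 50 + 1 nodes with 150 edges). Two caveats it
makes explicit rather than hiding: (a) the bundle represents
*post-collection* data — a ≥ 5-compound support filter over 191 targets
would require ≥ 955 interaction edges, more than the 879 total tripartite
links, so the support filter must have been applied at harvest time and
pipeline runs on the bundle use `min_support=1`; (b) the real pathway
membership lists behind the case study's 142-node protein projection are
not public, so the bundle's own projection (191 nodes here) does **not**
reproduce it — that network is instead rebuilt from its transcribed
degree-frequency table (`ofte_table1`, 31 rows, Σf = 142, Σk·f = 4204).

What passing tests on synthetic data do and do not show: they verify the
*algorithms* (filters, tests, constructions, statistics) and the printed
arithmetic identities of the case study; they do not validate
target-prediction quality, pathway annotation coverage, or any biological
claim about a real mixture. Physicochemical properties are sampled
numbers, not computed descriptors; no spectra or structures are simulated.

## Problem sizes and numerics

Tests and the acceptance script use sizes chosen to keep exhaustive
oracles exact and cheap: brute-force geodesic enumeration on graphs of
≤ 30 nodes (200 graphs), quadratic projection oracles on ≤ 200 proteins
(50 collections), exponent recovery at N = 2000, and 1000-parameter-set
tail verification. Internal computation keeps full float precision;
rounding (round-half-even) happens only at report serialization — 2
decimals for global statistics, 3 for centralities, matching conventional
reporting precision. Degenerate inputs are defined rather than crashed:
empty graphs report null globals, singleton components get Cc = 0,
uniform distributions fit γ ≈ 0, and non-graphical degree sequences raise
a named error citing the Erdős–Gallai condition.

## Known limitations

* No directed, weighted, or multi-relational graphs; no `*Arcs`/`*Matrix`
  Pajek sections; no GraphML.
* No eigenvector/PageRank/Katz centrality; no ML power-law fitting.
* No live database access; identifier harmonization is the caller's job.
* The hypergeometric test assumes exchangeable sampling of the query from
  the background; a biased query universe biases the p-values, which no
  offline default background can fix.
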