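# Methods

## The analysis in one paragraph

Mark–resight histories of individually ringed birds are reduced to
*dispersal events*: movements of breeding adults greater than a threshold
distance between successive breeding-season locations (or from the natal
nest for the first qualifying resighting). Events aggregate into directed
population-by-population count networks, one per temporal class and one
overall. The symmetrized between-population flows are hierarchically
clustered; the dendrogram cut with maximal weighted Newman–Girvan
modularity defines the population clusters, validated by the cophenetic
correlation coefficient. Directional imbalance of flows is tested by
permutation χ² tests, temporal trends in node strength by a permutation
F-test, and distance/density/conspecific effects by Mantel-type matrix
permutation tests.

## Event extraction

* **Threshold.** Strictly greater than `threshold_km` (default 5 km, the
  foraging range of a breeder around its nest; movements below it are
  nest-site noise, not dispersal). Distances are haversine great-circle
  distances (R = 6371.0088 km). Ringing archives usually treat distances as
  planar (Euclidean) values read off projected maps; at the 300–600 km
  scale of inter-population distances the planar/spherical difference is a
  few km and the spherical form is the reproducible choice. It is
  deliberately not configurable.
* **Breeding window.** Month/day window, inclusive, default April 15 –
  July 15 (latest laying to earliest fledging). Resightings outside it are
  ignored.
* **Age.** Calendar-year age: observation year − ringing year ≥
  `min_age_years` (default 4). Birds are ringed as nestlings, so ring year
  equals hatch year. Younger, non-breeding birds move erratically and are
  excluded by this filter alone.
* **Reference chain.** The reference location starts at the natal nest
  (events from it are *natal*) and advances to every qualifying resighting
  — including moves at or below the threshold. The bird's current nest is
  always the baseline for next season's comparison; a nest-anchored rule
  would double-count slow drift. Each observed transition yields at most
  one event; multi-year gaps are one event, not annualized.
* **Deduplication.** Multiple within-window resightings of one individual
  in one year collapse to the earliest dated one (reproducible, and
  insensitive to reporting multiplicity).
* **Population membership.** Either trusted labels (`rule="label"`) or
  nearest centroid by great-circle distance, ties to the first-listed
  population. True boundary polygons are out of scope; both rules are
  approximations and the generator's geometry (σ ≪ centroid separation)
  makes them agree.

## Clustering and modularity

The similarity matrix is `S = W + Wᵀ` with a zero diagonal; within-population
events never enter it. Agglomerative clustering uses average linkage on
similarities (UPGMA): the pair of clusters with the largest mean cross-pair
similarity merges first, so merge heights are non-increasing. Ties break
toward the lexicographically smallest pair of cluster labels, making the
tree deterministic. Single and complete linkage are available behind a flag
for sensitivity analysis; the average-linkage default is the standard for
association-type matrices in animal social-network tools.

Every cut of the dendrogram (all-singletons through one cluster) is scored
with the weighted Newman–Girvan modularity Q = Σₖ(e_kk − a_k²); the cut with
maximal Q is reported, ties resolving to fewer clusters (the one-cluster
partition scores exactly 0, so Q_max ≥ 0). Restricting the search to
dendrogram cuts — rather than free Louvain-style optimisation — keeps Q and
the CCC referring to the same tree. Two consequences worth knowing:

* With a zero diagonal, a uniform matrix's block partition scores *below*
  zero (e_kk = 2/12 vs a_k² = 1/4 for dyads), so "no structure" collapses
  to the single cluster, not to an arbitrary split.
* Absorbing a weakly attached singleton into its most-similar cluster
  almost never lowers Q (the sum of merge gains over clusters is 2a_s²).
  A genuinely peripheral population therefore stays outside clusters only
  when its attachment is weaker than the between-cluster background, which
  is exactly the regime the planted two-cluster generator creates.

The CCC is the Pearson correlation between off-diagonal similarities and
the merge heights at which pairs first join; zero variance in either vector
is reported as undefined (None), never as silent NaN. Out/In ratios use
*outgoing* directed events: In = events to own-cluster members, Out = events
to everything else; this convention is the one under which the published
In/Out table, its χ² of 13.94 and the edge χ² values 46.43 = (78−13)²/91 and
14.22 = (52−20)²/72 are mutually consistent. Populations left as singletons
by the cut are excluded; In = 0 makes the ratio undefined (reported as
such), Out = 0 gives 0.

## Permutation tests

All tests use the add-one estimator p = (1 + #{perm ≥ obs})/(1 + n_perm)
(never exactly zero, unbiased for the exact conditional p) with 10,000
permutations by default and a mandatory seed.

* **Edge asymmetry.** χ² = (a−b)²/(a+b); null: each of the a+b events flips
  direction with probability ½. The statistic is scheme-independent; the
  null is the minimal exchangeable one for "no asymmetry". Zero events is
  degenerate (statistic 0, p 1, warning).
* **Table asymmetry.** Pearson χ² of independence on an r×2 In/Out table;
  null redraws each row's first column Binomial(row total, pooled
  fraction), conditional on row totals. Permuted tables with an empty
  column (possible but rare) score 0, which is conservative.
* **Strength trend.** OLS of node strength on temporal-class index pooled
  over populations; F = (n−2)·r²/(1−r²); null permutes each population's
  strengths across classes, preserving population identity. The exact
  response and design of the published trend test are not recoverable, so
  this is an explicit reconstruction; F/r² values are reported but not
  treated as reproduction targets.
* **Mantel Z.** Pearson correlation of lower-triangle entries of two
  symmetric matrices (|Z| ≤ 1, invariant to positive affine rescaling);
  null jointly permutes rows/columns of the second matrix; two-sided by
  default. The exchange matrix correlated against distance or density
  difference is the symmetrized count matrix (Mantel requires symmetry).
* **Attractiveness/repulsiveness.** Internal-activity, arrival and
  departure matrices are populations × temporal classes (rectangular), so
  the classical Mantel scheme does not apply; the null permutes population
  rows of the second matrix. This scheme is interpretive, chosen as the
  minimal exchangeability assumption that preserves temporal-class
  profiles.

## Synthetic generator

The generator emulates a two-decade volunteer ringing programme:

* Populations are Gaussian clouds (σ = 30 km default) around centroids a
  few hundred km apart; pair counts grow geometrically per population.
* Nestlings are ringed with year-varying effort (default declines 0.95 →
  0.45 across 1988–2008, emulating marking effort falling behind population
  growth); breeders are resighted with constant probability 0.8 (a stable
  observer network), at most once per breeding season.
* Survival is geometric with yearly rate 0.78 (a typical adult survival
  for large long-lived birds; the analysis itself never models survival,
  but the generator needs it to bound record counts).
* Yearly movement follows a row-stochastic flow matrix: with the diagonal
  probability the bird stays (relocating locally by a point-mass-plus-
  Lomax-tail kernel, truncated at 150 km; the tail is what produces
  within-population dispersal events), otherwise it settles near the
  destination population's centroid.
* One seeded generator is threaded through all draws in a fixed order:
  identical config + seed ⇒ byte-identical record tables.

Two stock configurations:

* `default_study_config` — calibrated once to the published corpus scale:
  five populations (W, S, C, NE, NW) with the reported relative sizes and
  ≈352 km mean centroid separation, flows tuned so a typical run yields
  ≈1400–1550 events (≈1250 within, ≈230–260 between, NE→C ≈ 80–90,
  NW→W ≈ 45).
* `two_cluster_config` — same geometry, block flows (NE→C, NW→W) an order
  of magnitude above background and the southern population nearly
  isolated (its attachment below the between-block background, see the
  modularity note above), with ringing effort fixed at 0.45 to keep
  100-seed Monte-Carlo runs around a minute and a half.

What the generator does **not** emulate: migration-route geometry and the
north–south settlement axis, wintering grounds, density-dependent dispersal
decisions, boundary polygons, observer heterogeneity, or misread rings.
Passing tests therefore demonstrate that the pipeline recovers planted flow
structure from realistically sized, realistically filtered record tables —
not that any biological conclusion about a real system is correct.

## Problem sizes used in tests and the acceptance script

Monte-Carlo checks use: 100 generator seeds for planted-cluster recovery
(40 in the acceptance script), 200 seeds for asymmetry power and for
symmetric-flow calibration on a two-population scenario (≈100 breeding
pairs per population, 11 years, ≈40–55 events on the focal edge), 1000
replicates for the type-I calibration of the edge test at 91 events, and
10,000–50,000 permutations where a test is compared against exact
enumeration. These sizes give binomial Monte-Carlo error comfortably inside
the asserted bands while keeping the whole suite in a few minutes.

## Known limitations

* The clustering-and-modularity procedure is one concrete reading of the
  SOCPROG-style "maximum modularity on the dendrogram" analysis; on the
  published total count matrix it yields Q ≈ 0.25–0.27, well below the
  published 0.507, so the published Max. Mod./CCC values evidently derive
  from a different similarity index and are not reproduction targets here.
* Ringing-effort decline is not corrected for; the analysis assumes
  resighting effort (the probability a breeder is re-read) stays constant,
  which is the usual justification in long-running volunteer schemes.
* The XLSX importer is best-effort column matching, for exploration only;
  the canonical input is the observation CSV.
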