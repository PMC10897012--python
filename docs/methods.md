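# Methods

## Model and procedure

The pipeline treats each hospitalization case as one observation of a set
of binary disease indicators. For one stratum (an age-bracket × sex × SES
cell) with N cases:

1. **Test universe.** Every unordered pair of observed diseases that
   co-occurs in at least one case (k ≥ 1) is tested. Pairs that never
   co-occur cannot form an edge under the co-occurrence definition of
   comorbidity, and excluding them from the multiple-testing universe
   keeps the Benjamini–Hochberg denominator aligned with the edges that
   are actually possible. This choice is configuration in spirit — it
   changes the BH denominator — and is stated here because it is a
   genuine free parameter of the procedure.
2. **Test.** One-sided upper-tail hypergeometric: conditional on the
   marginals n_A, n_B and the stratum size N, the co-occurrence count
   under independence is X ~ Hypergeom(N, n_A, n_B), and
   p = P(X ≥ k). Under-representation is deliberately not an edge:
   comorbidity is excess co-occurrence. The tail is computed with the
   scipy survival function (log-space stable; never naive factorials).
3. **FDR.** BH step-up within the stratum at α = 0.05 (strata are
   analyzed independently; no cross-stratum pooling). Monotone q-values
   come from the cumulative minimum from the largest p. The rejection
   rule is the canonical step-up, equivalently q ≤ α. The boundary case
   q = α is measure-zero for real data; this package resolves it toward
   the canonical step-up because that is what the textbook procedure
   (largest i with p(i) ≤ iα/m) rejects.
4. **Weights.** Each significant edge carries the plug-in mutual
   information of the two indicators in natural-log units (nats),
   MI = Σ p(x,y) ln[p(x,y)/(p(x)p(y))], with 0·ln 0 ≡ 0, clamped at 0
   against floating-point jitter, and exactly 0 whenever the empirical
   2×2 table factorizes (n11·n00 = n10·n01). MI is computed for every
   tested pair (the full table is exported) but stored as a weight only
   on significant edges.
5. **Network.** Undirected, no self-loops; nodes are exactly the union of
   significant-edge endpoints, so there are no isolated nodes.

## Centrality and topology conventions

- **PageRank** is the one weighted score: transition probabilities are
  proportional to incident edge MI, teleportation is uniform, damping
  0.85 (the de-facto default of the standard network tooling; exposed as
  a parameter). Dense power iteration, convergence when the L1 change of
  the score vector falls below 1e-10, hard failure (carrying the last
  iterate and residual) after 200 sweeps. Scores sum to 1; with uniform
  weights the result equals unweighted PageRank.
- **Betweenness** and **closeness** use hop counts, not MI-derived
  distances — there is no canonical monotone weight-to-distance
  transform for MI, and topology statistics on the unweighted graph are
  the standard summary. Betweenness is normalized by (N−1)(N−2)/2;
  closeness is computed per connected component as
  (n_comp − 1)/Σ distances.
- **Clustering** is the mean local clustering coefficient with
  degree < 2 nodes counted as 0; **centralization** is Freeman's
  Σ(d_max − d_i)/((N−1)(N−2)) (0 for fewer than 3 nodes);
  **avg_neighbors** is defined as 2·links/nodes exactly, and **density**
  as 2·links/(nodes·(nodes−1)).
- Rankings break score ties lexicographically by code; MI ranks use
  competition ranking (tied edges share the lowest applicable rank).

## Synthetic cohorts

The generator emulates the data model of a cardiology referral hospital's
discharge records: per-stratum cohorts over an ICD-10 code universe, at
most 6 codes per case, and stratum demographics set directly from the
stratum cell (ages uniform within the bracket — downstream analysis only
uses the bracket, so the within-bracket law is irrelevant; open-ended
brackets sample a 20-year span).

Disease indicators are independent Bernoulli draws except for planted
pairs (A, B, ρ), which are drawn from the 2×2 joint table with
P(A ∧ B) = ρ·p_A·p_B and preserved margins. Config validation rejects
tables that are not valid probability distributions
(ρ·p_A·p_B ≤ min(p_A, p_B) and P(neither) ≥ 0) and planted pairs that
share a code within a stratum — pair-table planting keeps the ground
truth exact without copula machinery, at the cost of disallowing
overlapping enrichments.

Two deliberate departures from resampling purity, both reported by the
generation report:

- Cases drawing more codes than the cap lose the excess uniformly at
  random (never preferentially planted codes); a truncation rate above 1%
  triggers a warning because capping attenuates planted enrichments and
  induces mild negative dependence between indicators.
- Cases drawing zero codes are emitted with an empty code set rather than
  resampled, keeping cohort size exact; ingest excludes them the same way
  it excludes real records with no usable diagnosis. Conditioning on
  non-emptiness perturbs independence only at O(1/n).

What passing tests on these cohorts shows: the inference machinery
recovers known enrichments and controls false discoveries under the
generator's assumptions (cross-sectionally independent cases, no code
hierarchies, no disease progression, pairwise-only dependence). What it
does not show: robustness to repeat hospitalizations of the same person,
coding-practice artifacts, secular trends, or higher-order disease
interactions — none of which the generator emulates. The code-count
distribution of real populations is unknown to us; it is configuration
(per-code prevalences), not an assertion.

## Problem sizes and seeds

The simulation-based checks use cohorts a scientist would call small but
sufficient for their purpose: null FDR calibration uses 200 replicates of
500 cases × 30 diseases (prevalences 0.05–0.2), where the binomial
Monte-Carlo error on a 5% rate is about 1.5 percentage points; planted
recovery uses 100 replicates of 2,000 cases with ρ = 4 at 10% prevalence,
a regime where the expected co-occurrence (4% of cases) is far enough
from the null (1%) that power is essentially 1. Every stochastic path
flows from a single integer seed through `numpy.random.default_rng`; two
runs with the same config are byte-identical.

## Degenerate inputs and numerical notes

- Empty stratum → valid empty incidence matrix → valid empty network →
  all-zero topology summary; PageRank on an empty network is undefined
  and raises.
- Upper-tail p-values are clamped into (0, 1]: a feasible k always has a
  mathematically positive tail, so underflow to exactly 0 is replaced by
  the smallest positive double.
- The hypergeometric implementation is verified against exhaustive
  exact-rational pmf enumeration for every feasible (N ≤ 30, n_A, n_B, k)
  to 1e-12; BH against a hand step-up; MI against the sklearn
  mutual-information score; PageRank against the networkx implementation.

## Known limitations

- Case-level analysis: repeat hospitalizations of one person count as
  separate cases (no person-level key is modeled).
- SES arrives pre-binarized; the institutional composite score behind it
  is out of scope.
- ICD-10 codes are kept at recorded granularity; no hierarchy-aware
  aggregation, no cross-revision mapping.
- Association only: no directionality, no temporal order, no causal or
  mechanistic claims.
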