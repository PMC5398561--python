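# Methods

This note records the models, conventions, and numerical choices behind
`teamnet`, in enough detail to know what a passing test suite does and
does not establish.

## Claim streams and sequence preparation

A claim is a triple (patient, vertex, service day); the vertex is either
the provider or the organization identifier, both carried on every
claim.  Organization networks are built directly from the organization
field, not by aggregating the provider network.  Dates are handled at
day resolution and Δt is an integer day count — claims carry no time of
day.

**Same-day tie-break.**  Within a patient, claims are sorted ascending
by day with a *stable* sort, so same-day claims keep their input-file
order.  The choice matters only to the trace-route construction (which
looks at consecutive claims); it makes its output deterministic for a
fixed input ordering.  No ordering convention can make same-day pairs
visible to the directed rules, since both use the strict condition
0 < Δt.

**Duplicate claims.**  Identical (patient, provider, date) rows are
distinct claims by default — they are real in billing data and affect
visit-weighted edges — with an explicit `deduplicate()` available.

**Identifier validation** (10 digits, Luhn over the `80840`-prefixed
payload) is advisory: failures are counted and reported, never dropped,
matching its role as a QC signal.  The `drop_invalid` flag drops only
structurally unusable rows (unparseable dates, non-10-digit ids).

## Edge construction

Frame semantics are *pairwise*: an edge exists iff the claim pair's Δt
satisfies the rule — |Δt| ≤ τ for binning, 0 < Δt ≤ τ for the two
directed rules, with trace-route restricted to consecutive pairs.
Iteration-order descriptions of frame shifting add no further
constraint.  Consequences worth knowing:

* Same-day co-visits produce binning edges but are invisible to the
  sliding and trace-route rules.  This is why the vertex nesting
  V(sliding) ⊆ V(binning) ⊆ V(trace-route) — which otherwise follows
  from the triangle-like argument that any in-frame pair implies
  in-frame consecutive gaps — can fail on data with same-day claim
  pairs.  The containment tests therefore draw per-patient claim days
  without replacement; a dedicated test documents the same-day
  counterexample.
* A consecutive trace-route pair with Δt > τ produces no edge but does
  not break the chain: each consecutive pair is tested independently.
* Self-loops exist only in trace-route networks (consecutive same-
  provider visits, Δt > 0) and are tallied separately.

Both weight modes are always accumulated: `shared_patients` adds 1 per
contributing patient per edge; `total_visits` adds every qualifying
claim pair.  For every edge, patients ≤ visits.  Builders stream one
patient at a time; memory never exceeds one patient's claim list
squared.

## Censoring

`censor_network` removes edges with shared-patient weight ≤
`max_removed_weight` and then vertices left isolated.  The default is
11 (keep ≥ 12), matching the common analysis convention for released
Medicare teaming data; the prose form of the rule ("fewer than eleven
distinct beneficiaries") corresponds to `max_removed_weight=10` and is
one parameter away.  Censoring always keys on the shared-patients
weight even in visit-weighted networks, because de-identification
concerns distinct beneficiaries.

## Metric panel conventions

* Self-loops are excluded from degree, density, clustering,
  assortativity, and betweenness; they appear only in the loop
  fractions E_loop/E and V_loop/V.
* Density D = d·m/(n(n−1)), d = 1 directed / 2 undirected, m the
  non-loop edge count.
* Degree assortativity r and global clustering C are evaluated on the
  undirected simple skeleton (the defining r formula is undirected);
  r is NaN for degree-regular graphs, where the formula is 0/0.
* Reciprocity ρ is the fraction of directed non-loop edges whose
  reverse exists; 1 by definition for undirected networks.
* Diameter is the longest shortest geodesic within the largest (weakly
  connected, for directed graphs) component, unreachable ordered pairs
  excluded.
* Normalized betweenness C′β divides raw betweenness (endpoints
  excluded) by (N−1)(N−2) for directed and (N−1)(N−2)/2 for undirected
  networks, bounding it to [0, 1].  A product form of this
  normalization sometimes seen in print is a typo: only division bounds
  the statistic.

## Heavy-tailed degree fitting

Discrete (integer) formulation throughout.  The power-law fit scans
candidate cutoffs x_min over the unique degrees that leave ≥ 10 tail
observations (at most 150 candidates, quantile-subsampled), estimates α
at each by maximizing the Hurwitz-zeta likelihood (bounds 1.01–8), and
keeps the x_min minimizing the KS distance between empirical and fitted
tail CDFs.

**Goodness of fit** uses the semi-parametric bootstrap: each replicate
mixes parametric draws from the fitted tail (exact inverse-CDF zeta
sampling) with resamples of the body, is refit from scratch, and the
p-value is the fraction of replicates with KS ≥ observed.  The default
of 100 replicates is a desk-scale setting (±0.03 Monte-Carlo noise on
p; publication-grade work wants ≥ 1000).  The power law is accepted
when p > 0.1.

**Model selection** tests the power law against five alternatives on
the tail x ≥ x_min: power law with exponential cutoff (PLEC,
normalized via the Lerch transcendent, constrained to α ≥ 0 so the
density stays decreasing), geometric (discrete exponential, closed-form
MLE), discretized log-normal and Weibull (F(x+½)−F(x−½) on the tail),
and Yule (Γ(x)/Γ(x+α) with a zeta-corrected truncated normalizer).
LR = LL(power law) − LL(alternative).  Non-nested comparisons use the
Vuong normal approximation; the PLEC, which nests the power law, uses a
χ²₁ test on twice the log-likelihood gain.  A negative LR with p < 0.05
counts against the power law; among such alternatives the winner is the
one with the most negative *parsimony-penalized* LR (BIC-style,
(k−1)·ln n/2 per extra parameter, also required to stay negative).
Without the penalty, a family that nests another — Weibull contains the
exponential at shape 1 — wins ties on pure sampling noise.

**What the recovery harness shows.**  Exponent recovery uses the free
cutoff scan.  The family-selection harness fixes x_min = 1, the support
minimum of the generators: with a free scan, KS minimization slides the
cutoff to where *any* heavy-tailed sample is locally power-law-like
(for Yule data the fitted tail differs from a pure power law by ~0.005
nats per observation — no test can tell them apart there), so
discrimination is only a well-posed question at the generating cutoff.
Harness parameters were chosen once for identifiability at n = 10,000:
power law α = 2.5; PLEC α = 2, λ = 0.05; exponential λ = 0.3;
log-normal μ = 1, σ = 1; Weibull shape 0.5, scale 5; Yule α = 2.5.
Passing selection tests show the machinery distinguishes these families
in these regimes; they do not show that any two heavy-tailed families
are distinguishable from tail data, which is false in general.

Samplers used in the harness are generative mechanisms independent of
the likelihood code (inverse-CDF zeta draws; rejection from the power
law for PLEC; numpy geometric/log-normal/Weibull primitives rounded and
truncated; the exponential-geometric mixture construction of the Yule
process).  The power-law sampler's CDF grid is capped at 5×10⁶ values;
draws beyond it clip to the cap (probability < 10⁻⁷ per draw in the
regimes used).

## Communities and geography

Girvan–Newman runs on the undirected, unweighted, loop-free skeleton
(a weighted variant is behind a flag): repeatedly remove the edge of
highest edge-betweenness — ties broken by lexicographically smallest
(u, v), making output deterministic — and return the connected-
component partition of highest Newman modularity along the removal
sequence (the one-community partition, modularity 0, is the floor).
The operation refuses networks above 5,000 edges by default; restrict
to a state (both endpoints geocoded there) or censor first, which is
also how the computation is kept tractable in practice.

Edge distances use the haversine great-circle formula with Earth radius
3958.8 miles.  The default 16 contiguous bins run from "≤ 1 mile" to
"2000–4000 miles" with an open-ended final bin; bin upper bounds are
inclusive.  Self-loops land in the zero-distance bin (tallied as
loops); edges with an ungeocoded endpoint go to a separate reported
bucket, never silently dropped.

## Synthetic claims generator

The generator emulates the *structure* of outpatient claims files:
one row per claim, Poisson-distributed visits per patient (default mean
10/year), uniform i.i.d. visit dates, every claim carrying a provider
and an organization id (valid NPIs), providers geocoded to 2 decimal
places (~1 km).  Planted structure: providers Gaussian-scattered around
region centers in `n_communities` clusters; organizations never span
communities; each visit stays in the patient's home community with
probability `p_within_community` (default 0.9), else goes to a
uniformly random outside provider; snowbird patients (default fraction
0) draw December–February visits from the geographically farthest
region.  Community sizes are balanced by default, with a power-law
option for heavier-tailed degree work.

It does **not** model: weekday/seasonal visit rhythms (beyond the
snowbird mechanism), specialty mixes, referral intent, claim-line
codes, monetary fields, or realistic Medicare volumes.  Tests passing
on this generator establish algorithmic correctness and the advertised
structural invariants — not calibration to real claims.

**Recovery-harness conditions.**  The planted-community test uses 60
patients × 5 visits over 24 providers in 2 communities at
p_within = 0.95 and censoring at weight ≤ 1.  The scale matters: the
premise that censoring exposes the planted partition holds only when
cross-community pair weights (~0.4 expected shared patients) fall below
the censor while within-community weights (~6) stay above.  At higher
visit volumes the censored graph is a near-complete blob and no
community method can recover the partition — a genuine property of
weight-censored co-occurrence networks, not a failure of the detector.

## Problem sizes

Default test and acceptance-script sizes are desk-scale by design:
synthetic streams of 10²–10³ patients, oracle comparisons on ≤ 200-claim
datasets and ≤ 30-vertex graphs, degree-fit studies at n = 10,000 with
bootstrap 100.  All scale up by parameter only.
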