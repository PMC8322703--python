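# Methods

This note documents the statistical models, the defaults and why they were
chosen, the numerical decisions, and what the synthetic studies do and do
not demonstrate.

## Differential expression: empirical-Bayes moderated t

Each cohort is a genes × samples log2 matrix with a two-level case/control
design.  The per-gene pooled variance s²_g on df = n₁+n₂−2 degrees of
freedom is modelled hierarchically: s²_g | σ²_g ~ σ²_g·χ²_df/df with a
scaled-inverse-χ² prior σ²_g ~ d₀s₀²/χ²_d₀.  The hyperparameters are
fitted by method of moments on e_g = log s²_g − ψ(df/2) + log(df/2):
var(e) in excess of ψ′(df/2) identifies ψ′(d₀/2), inverted by Newton
iteration on the trigamma function (start 0.5 + 1/y; the step is taken on
1/ψ′, which is nearly linear in its argument).  The moderated t divides
the fold change by the posterior-variance standard error and gains d₀
extra degrees of freedom.

Degenerate branch (observed spread of log variances no larger than the
χ² sampling spread, d₀ = ∞):

* var(e) > 0 — shrink completely to the log-bias-adjusted common variance
  exp(mean e) (the method-of-moments estimate of a single shared σ²).
  This keeps the global-null type-I rate calibrated: the unadjusted
  geometric mean is biased low by Jensen's inequality and was measured to
  inflate the 5% rate to ≈6.9% at df = 8.
* var(e) = 0 exactly — all observed variances are identical, so there is
  no evidence of χ² sampling at all; shrink to the common observed s²
  itself.  This makes the moderated t reduce *exactly* to the ordinary
  pooled t in that case, which is both the intuitively right limit and a
  convenient invariant to test.

With d₀ = ∞ the reference distribution is normal.  Genes with zero
posterior variance cannot be tested and get p = 1 with a warning.
Cutoffs are raw p < 0.05 and |log2FC| > 0.5, strict inequalities; no
multiplicity correction is applied at the per-cohort stage because the
cross-cohort aggregation is what confers robustness.

## Probe handling and sample screening

Probes annotated to zero or to multiple gene symbols (separators `///`,
`;`, `,` across GEO platform dialects) are discarded; symbols measured by
several probes get the per-sample arithmetic mean.  Matrices whose maximum
exceeds 30 are treated as unlogged and transformed by log2(x+1) — log2
microarray intensities rarely exceed ~20, and the transform is idempotent
under that threshold (exposed in the config).

Heterogeneous samples are screened by a deterministic correlation rule
rather than a dendrogram cut, which would need an arbitrary height: a
sample is flagged when its mean Pearson correlation with all other samples
falls more than k (default 3) scaled median absolute deviations below the
median of those means.  The MAD carries the 1.4826 consistency factor so k
is a robust z-score; without it, k = 3 flags ~2% of perfectly homogeneous
samples.  Constant samples are flagged unconditionally.  Flagging is
advisory — the pipeline drops flagged samples only when configured to.

## Robust rank aggregation

Normalized ranks are position/universe-size, so partially overlapping
platforms are comparable; items missing from a list take the worst rank
r = 1, a conservative choice for incomplete rankings.  β_k is the binomial
upper tail P(Bin(m, r_k) ≥ k) — the exact CDF of the k-th uniform order
statistic — ρ the minimum over k, and the reported score the Bonferroni
correction m·ρ (one test per order statistic).  The score is monotone in
every rank entry and is a valid, conservative p-value under the
permutation null (verified by 10 000-draw Monte-Carlo in the tests).

A gene's aggregated fold change is the arithmetic mean of its per-cohort
log2FC over the cohorts that measure it; the robust-DEG cut is
score < 0.05 together with |mean log2FC| > 0.5.  Up and down lists are
ranked and aggregated separately; a gene passing in both directions is an
input inconsistency and raises.

## Network stages

Edge lists are (id, id, score) TSVs; scores with maximum > 1 are treated
as 0–1000-scaled and divided by 1000.  Edges are kept when confidence is
strictly greater than 0.4 (configurable), duplicates collapse to the
maximum confidence, self-loops are dropped, and the DEG-induced subgraph
discards isolated nodes by default.

**MCODE.**  A vertex is weighted by k·density of the highest-k core of
its *open* neighborhood (the vertex itself excluded; a K4 member therefore
weighs 2.0).  Vertices with fewer than 2 neighbors weigh 0.  Clusters grow
breadth-first from unvisited seeds in decreasing weight order, admitting
neighbors whose weight is at least (1 − 0.2)× the seed weight, then a
2-core haircut trims tails and clusters without a 2-core are discarded;
cluster score is density × size.  Defaults match the familiar plugin
defaults (degree cutoff 2, node score cutoff 0.2, k-core 2, haircut on,
fluff off).  One consequence worth knowing: two equally dense complexes
joined by a bridge between high-weight members merge into one cluster,
because the weight threshold does not stop the expansion; a low-weight
connector node does stop it.

**Centralities.**  The ten methods are implemented with the following
conventions, each pinned by brute-force oracles on every connected graph
with ≤ 7 nodes: MCC sums (|C|−1)! over maximal cliques of size ≥ 2
(isolated nodes 0); MNC/DMNC use the largest connected component of the
open neighborhood (DMNC = |E|/|V|^1.7 of it); Closeness is harmonic
(Σ 1/d, well-defined on disconnected graphs); EcCentricity is 1/ecc
within the component; Radiality sums (Δ_comp + 1 − d)/(n−1) with n the
whole graph's node count; Betweenness is unnormalized Brandes; BottleNeck
builds one BFS tree per root with ties broken toward the lexicographically
smaller parent and credits nodes whose proper descendants exceed a quarter
of the *tree* (= component) size — on connected graphs this equals the
whole-graph reading; EPC averages, over 1000 seeded realizations keeping
each edge with probability 0.5, the number of other nodes reachable.  EPC
is bit-reproducible given its seed; its Monte-Carlo parameters are exposed
because no published reference fixes them.

Hubs: per-method top-50 lists (ties broken by node id) are RRA-aggregated
over the universe of all network nodes; the hub cut score < 0.05 is a
configuration default, chosen because the aggregated score is already a
corrected p-value.

## ceRNA assembly

Rules, applied in one pass (no iteration): (1) keep miRNA→mRNA pairs
predicted by all three target sources; (2) keep a pair only when the
miRNA's differential direction is opposite to its target's (miRNAs
repress); (3) drop an mRNA when none of its validated miRNAs has any
circRNA partner; (4) retain a circRNA only when, for *every* remaining
mRNA, some miRNA links the two.  Coverage is evaluated against validated
pairs only.  The final network's miRNAs must touch both a retained
circRNA and a kept mRNA; node classes partition the graph and only
circ–miRNA and miRNA–mRNA edges exist (asserted).  The shipped
`table3.tsv` fixture (45 validated miRNA–mRNA relationships over 14 genes)
drives the worked example: removing circRNA support from the two miRNAs
that are sole regulators of their genes drops exactly those two genes,
leaving 12 mRNA nodes.

## Enrichment

Over-representation uses the hypergeometric upper tail (equal to one-sided
Fisher exact, cross-checked in tests) against a caller-supplied universe —
the genes actually measured, not the genome — with Benjamini–Hochberg
q-values reported alongside raw p.

## Synthetic studies and their limits

The generators are pure functions of their parameters and seed.

* **Expression**: five cohorts, 1000 genes, 20 case/20 control, 50+50
  planted genes shifted ±1.0 on the log2 scale, σ = 1, 10% of genes
  missing per cohort.  Gaussian, homoscedastic noise matches the
  assumptions of the moderated t; real microarrays add intensity-dependent
  variance, batch effects and correlated probes, so the measured recall
  (≈0.97 at these settings) is an upper bound on what identical settings
  would achieve on real data.  The cohort sizes are desk-scale stand-ins
  for the hundreds of samples in public asthma cohorts.
* **Interaction network**: Erdős–Rényi background (60 nodes, p = 0.05)
  plus planted K6 and K5 cliques whose members each attach to four random
  background nodes.  The attachment density is a deliberate design point:
  it makes planted nodes both locally dense and globally central, so the
  full ten-method ensemble — not just the clique-sensitive methods —
  ranks them top.  Real PPI networks have heavy-tailed degrees; the ER
  background only tests that the methods separate planted structure from
  unstructured noise.
* **ceRNA tables**: planted triplets appear in all three target sources
  with direction-consistent miRNAs and two circRNAs covering every planted
  mRNA; each decoy violates exactly one rule (absent from one source,
  same-direction miRNA, or subset-covering circRNA), so a surviving decoy
  identifies the broken filter.

## Numerical and interface choices

* Trigamma inversion: Newton on 1/ψ′, tolerance 1e-12, ≤ 100 iterations;
  y > 1e7 short-circuits to 1/√y.
* All stage outputs are plain TSV/JSON; the pipeline manifest records
  SHA-256 hashes, and reruns with the same config and seed are
  byte-identical.  One global seed is fanned out to stages by fixed
  offsets.
* Ties everywhere break by identifier ascending, making every ordering
  deterministic.
* Thresholds are validated against documented ranges and unknown config
  keys are rejected.

## Known limitations

* The RRA score treats lists as independent; cohorts sharing samples or
  platforms would violate that.
* Exact numerical agreement with other RRA implementations on *partial*
  lists is not claimed — handling of unranked items differs subtly between
  implementations; this one substitutes r = 1.
* BottleNeck and MCODE outcomes depend on documented tie-break rules;
  other tools using traversal-order tie-breaks can differ on symmetric
  graphs.
* Only plain two-group contrasts are supported — no covariates,
  multi-factor designs, or array weights.
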