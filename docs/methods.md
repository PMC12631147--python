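# Methods

This note documents the statistical models, defaults and design choices
behind `evimap`, and what the synthetic-data tests do and do not show.

## Effect sizes

Raw two-group summaries (means, SDs, group sizes) are converted to
Hedges' g with the small-sample correction J = 1 − 3/(4·df − 1),
df = n1 + n2 − 2. The exact-gamma form of J is not implemented; the two
differ by under 0.1% for df ≥ 10, which covers any group sizes a
meta-analysis would include. Identical constant groups (pooled SD zero)
raise a degenerate-input error rather than returning an infinite effect.

## Pooling

The sampling variance–covariance matrix V is block-diagonal by cluster
(study by default): within a cluster cov(i,j) = ρ·√(vi·vj), across
clusters zero. ρ defaults to 0.5 — a deliberate guesstimate standing in
for the usually unknown correlation between effects sharing a study; it
is overridable per call and should be informed by ancillary data when
available. V is positive definite for ρ ∈ [0, 1); ρ = 1 is excluded
because it makes V singular whenever a cluster holds two effects.

Three estimators share this V:

- **fixed_gls** — μ̂ = (1ᵀV⁻¹y)/(1ᵀV⁻¹1), se = √(1/(1ᵀV⁻¹1)), Wald 95%
  CI with z = 1.959964. At ρ = 0 this is exactly the inverse-variance
  weighted mean. Linear systems are solved (`numpy.linalg.solve`), never
  inverted, for numerical stability; a singular V raises an error that
  suggests lowering ρ.
- **random_dl** — DerSimonian–Laird method-of-moments τ², then IVW with
  weights 1/(v + τ²). Chosen over REML because it is closed-form,
  deterministic and therefore exactly testable; REML is out of scope.
- **robust** — the GLS point estimate with a cluster-robust sandwich
  variance using scalar weights w_i = row sums of V⁻¹:
  se² = m/(m−1) · Σ_c (Σ_{i∈c} w_i e_i)² / (Σ w_i)², with a t(m−1)
  reference for the CI. This is a CR1-type small-sample correction, an
  approximation to the fuller CR2/Satterthwaite machinery of the robust
  variance estimation literature; with few clusters (m < ~10) its
  intervals can still be somewhat liberal. With one cluster the sandwich
  is undefined and the call errors (the cell-pooling wrapper falls back
  to plain GLS there). Residuals that are exactly zero yield se = 0 and a
  `degenerate` flag rather than an error.

Critical values: z for fixed/random pooling, t(m−1) for the robust
estimator — the dominant convention for each. Per-species CIs use z for
consistency with the fixed-GLS default.

Single-effect groups (grid cells, species) pass the effect and √vi
through unchanged, labelled `single_effect`.

## Evidence maps

`cross_tabulate` counts distinct studies and effect rows at every
moderator intersection, keeping schema-declared empty cells — the gaps
are the point. A study contributing to several cells is counted in each
cell's study count, so cell study counts can sum to more than the number
of distinct studies. Missing moderator values become an explicit
`Unknown` level (never dropped) so flow plots can display missingness.
Level order is first-appearance (or user-declared), not alphabetical, so
outputs are stable for diffing. When a third moderator is mapped to cell
shape, mixed cells report the modal label plus a mixture flag
(ties broken toward the lexicographically larger label only through the
stable max over sorted labels).

## Phylogeny

Grafen heights: height(u) = (tips(u) − 1)/(tips(root) − 1), tips at 0,
root at 1, raised to the power parameter (default 1); branch length =
parent height − child height, giving an ultrametric tree. The Brownian
correlation between two tips is the root-to-MRCA depth, i.e.
1 − height(MRCA) after normalization; the matrix is PSD by construction.
Note the normalization depends on the tip count: dropping a tip and
recomputing matches the principal submatrix only on the unnormalized
(raw-height) covariance. Input branch lengths in Newick files are
ignored and recomputed. Polytomies are accepted.

Per-species means cluster the within-species VCV by study: effects of
one species coming from the same study are correlated at ρ, effects from
different studies are independent. The toolkit displays the correlation
matrix and per-species means; fitting a phylogenetic random-effects
model with that matrix is out of scope.

## Bibliometrics

Author identity is the normalized name string ("surname initials",
lower-cased, accents stripped) — no ORCID disambiguation, a documented
limitation: two "smith j" collapse, one author publishing under variant
initials splits. Reference keys are compared as exact normalized
strings; fuzzy citation matching is out of scope. Networks come from
binary incidence products, so weights are exact integer counts.
Multi-country papers contribute to every listed country by default
(`first_country_only` restricts to the first). Default clustering is
connected components — deterministic and parameter-free; Louvain is
available with a recorded seed, and the two can legitimately disagree
(components merge any two groups sharing one author). Leave-one-cluster-
out re-pools the complement and the held-out cluster with the configured
estimator.

## Altmetrics

The metric client is offline-first: a fixture CSV (doi, score,
policy_citations, patent_citations) and a JSON cache resolve every DOI;
unknown DOIs yield zero records flagged `not_found` instead of failing
the batch. The optional live path targets the public Altmetric details
endpoint keyed by DOI, uses only the score / policy-count / patent-count
fields, caches every response, and backs off exponentially at a default
1 request/second. All tests run offline. Bubble sizes above the
configurable overflow cap are flagged and drawn clamped, never to scale.

## Synthetic data

The generator encodes the structure the estimators assume: study-level
true effects θ_s ~ Normal(μ_cell, τ²); per effect, control ~ Normal(0,1)
and treatment ~ Normal(θ_s, 1) with per-arm sizes drawn from a range, so
Hedges' g recovers θ_s in expectation and the g computation is exercised
end-to-end. Defaults describe a mid-sized evidence base: 30 studies, 1–3
effects each, 20–40 participants per arm, μ = 0.5, τ² = 0, three author
clusters of 4–8 authors, a shared-reference rate of 0.5 and 80% country
dominance per cluster. One integer seed drives one named substream per
generator (effects / tree / bibliography / altmetrics), so adding a
generator never perturbs existing fixtures.

What the generator does **not** emulate: effects sharing a control group
(generated effects within a study are independent, so coverage checks
pool at ρ = 0 to match), publication bias, realistic citation-graph
topology, name ambiguity, or missing-at-random moderator patterns beyond
the explicit `Unknown` level. Passing tests therefore show estimator
correctness and calibration under the stated model, not robustness to
those real-data features.

Problem sizes used by the validation runs — 1,000 random GLS instances
(k ≤ 6), 1,000 coverage replicates of 30 studies, 200 network fixtures
of ≤ 30 papers, 100 random trees, 100 bibliography seeds — were chosen
to give stable Monte-Carlo estimates (coverage SE ≈ 0.7 percentage
points at n = 1,000) while completing in seconds.

## Rendering

Figures are matplotlib, SVG by default. Every renderer writes a JSON
sidecar listing each plotted value verbatim from its input table; tests
assert on sidecars, never on image bytes, because font and rasterizer
output is not deterministic across platforms. Bubble *area* (not radius)
scales linearly with the encoded count; chord arcs are proportional to
node strengths; grid gaps are drawn as outlined empty cells. The
renderers compute nothing.

## Known limitations

- CR1 robust intervals are approximate with few clusters.
- ρ is assumed, not estimated; results for correlated-effects data
  should be reported with a sensitivity range of ρ.
- Country attribution uses explicit country fields; affiliation-string
  parsing/geocoding is out of scope.
- No network meta-analysis, meta-regression, multilevel REML, or
  publication-bias testing — the pooling here summarizes cells and
  groups for display and sensitivity, not inference about moderators.
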