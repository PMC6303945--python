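# Methods

This note documents the models, numerical choices and design decisions
behind `drivernet`, and what its simulation-based validation does and
does not establish.

## Generative model

Expression follows a linear-Gaussian structural equation model over a
ground-truth DAG.  For gene *j* in sample *s*:

    x_js = Σ_{i ∈ pa(j)} β_ij x_is + γ_j L_js + ε_js,   ε_js ~ N(0, σ_j²)

where L is the allele dosage at the gene's mapped cis locus (one locus
per mapped gene; γ = 0 for unmapped genes).  The implied covariance is
(I − B)⁻ᵀ D (I − B)⁻¹ with B the weighted adjacency and D the diagonal
of exogenous variances — used for the calibration below and verified
against the sequential sampler in the test suite.

The DAG plants one high-out-degree regulator first in a random
topological order with exactly `regulator_out_degree` direct targets;
remaining ordered non-regulator pairs receive edges at `edge_density`.
The "module" is the regulator plus its descendants — the generative
analog of a disease-dysregulated co-expression module.

Generator defaults and why:

| parameter | default | rationale |
|---|---|---|
| genes p | 50 | desk-scale network with non-trivial depth |
| cohorts D | 8 | the consensus-correlation design expects eight datasets |
| samples | 500 control + 500 disease per cohort | typical bulk-cohort size; gives stable correlation estimates |
| edge density | 0.05 | sparse regulatory background (~1.2 extra parents/gene) |
| regulator out-degree | 10 | a clear hub, yet far from saturating the graph |
| β magnitude | U(0.5, 0.9), positive | coherent (sign-consistent) co-expression module; effects strong enough to be detectable at n = 500 |
| σ | U(0.5, 1.0) | heterogeneous per-gene noise, signal-to-noise ~1 |
| eQTL fraction / γ / MAF | 0.3 / 0.5 / U(0.05, 0.5) | cis effects detectable but not dominant; the regulator is always mapped, because the causal-test stage needs a genetic instrument at the hub to orient its edges |
| attenuation target | 0.71 | the fractional coordination loss the disease condition emulates |
| knockout clamp | log2(1.2)/0.3 ≈ 0.877 log2-units | ties the ground-truth relevance threshold (total path effect > 0.3) exactly to the 1.2-fold DEG gate, so "true DEG" and "≥1.2-fold in expectation" coincide |
| trait loadings λ | 0.5–0.6, severity coupling 0.7 | weak-to-moderate clinical correlations (|r| ~ 0.3–0.4), the regime cohort studies report |

### Disease attenuation

Disease samples replace every β by a·β with a single multiplier
a ∈ [0, 1].  a is calibrated by bisection so that the *population* mean
absolute pairwise correlation among module genes drops by the target
fraction (default 71%) relative to controls.  The calibration works on
the exact SEM-implied correlations rather than a Monte-Carlo pilot:
deterministic, free of pilot noise, and equivalent in its observable
contract (the realized reduction at n = 500/group lands within a few
points of the target; sampling bias of |r̂| near zero keeps the realized
value slightly below the population value).  Monotonicity of the loss
in a holds for the default all-positive-β generator and is tested.

### Knockout and ground-truth DEGs

A knockout clamps the target to a constant below its wildtype mean with
zero variance, outgoing edges intact, so the perturbation propagates
multiplicatively along paths.  The ground-truth signature is the set of
descendants whose total path effect (sum over directed paths of β
products, computed as (I − B)⁻¹ − I) exceeds the relevance threshold,
with signs.  Genetic effects are omitted from knockout samples — the
experiment emulates cultured cells from one genetic background.

### Traits

A latent severity mixes the standardized regulator expression with
independent noise; each trait is λ·severity + N(0, 1) mapped
monotonically onto its clinical scale by rank binning (CDR 0–5, Braak
0–6, CERAD 1–4 and MMSE 0–30 reversed, plaque/tangle densities via a
positive softplus transform).  Monotone binning preserves correlation
signs; it compresses magnitudes, which the closed-form tests account
for by checking the pre-binning scores.

## Preprocessing

TMM scaling factors follow the published trimmed-mean-of-M-values
recipe: reference = sample whose upper quartile of count fractions is
closest to the mean; M/A statistics over genes positive in both
libraries; 30%/5% two-sided trims; precision-weighted mean of surviving
M; factors rescaled to geometric mean 1.  The implementation is checked
against edgeR's `calcNormFactors` on a fixture.  Covariate adjustment
is per-gene least squares with categorical covariates (including batch)
as indicator contrasts; a mixed-model batch treatment is reserved
behind a flag and currently rejects rather than approximating silently.
Expression filtering keeps genes with ≥ `min_value` in at least
⌈`min_fraction`·n⌉ samples (defaults 1.0 and 10%, both inclusive).

## eQTL and the causal inference test

The eQTL scan is a per-(gene, locus) F-test of expression on additive
dosage with BH adjustment across all pairs.  CIT conditions 1–3 are
nested-model F-tests; condition 4 is the equivalence component: the
fitted values of G on L are kept, the residuals permuted (breaking
mediation while preserving the L–G association), and the conditional
L–T F-statistic is recomputed per permutation; p₄ is the fraction of
permuted statistics at or below the observed one (add-one corrected).
The omnibus is the max of the four components; both orientations share
one permutation-index matrix, which makes the test exactly
label-symmetric.  "Causal probability" for prior weighting is
operationalized as 1 − omnibus p.

Trio eligibility uses a raw association p < 0.01 per (gene, locus)
pair rather than the scan's BH flag: enumeration is a casting step and
the four-condition test supplies the error control, while the permissive
gate extends directed-prior coverage deep into regulatory cascades —
exactly where orientation anchors are scarcest.  Pairs per locus are
capped (default 200) for tractability.

## Network search

Each node's local model is a linear-Gaussian regression on its parents,
scored as −BIC/2 plus two adjustments:

* an **extended-BIC edge penalty** γ·|pa|·log p (default γ = 1.5).
  Plain BIC admits ≈1% of the ~p² candidate edges as false positives at
  n = 500; because the data are fixed, the same spurious edges recur in
  every chain and survive consensus averaging.  The EBIC term is the
  standard correction for model selection over an edge space that grows
  with p².
* a **prior bonus** κ per parent edge present in the structural prior
  set (default κ = 12).  CIT-called edges have already passed a
  four-condition causal test; κ above the per-edge score penalty
  (~9 log-units at the default scale) makes them effectively
  hard-to-overturn orientation constraints.  Because CIT priors are
  cone-respecting (mediation implies a directed path), a too-generous
  prior edge is at worst a transitive shortcut and does not distort
  downstream-reach statistics.

Chains are independent Metropolis–Hastings runs from sparse random
DAGs (~0.5 expected parents per node; dense random starts wedge
arbitrary edges into capped parent sets that single-edge moves cannot
displace).  Proposals add, delete or reverse one uniformly chosen edge;
cycle-creating and cap-violating moves are rejected; acceptance is
min(1, exp(Δscore)) without the proposal-asymmetry correction — the
sampler is used as a stochastic multi-start optimizer whose endpoints
feed consensus averaging, not as an exact posterior sampler, and the
score landscape is untouched by this simplification.  Defaults:
400,000 steps per chain and a parent cap of 5.  The step count gives
each of the ~3p² candidate moves dozens of visits (a few thousand steps
cannot even propose each move once at p = 50); the cap of 5 leaves
room above the true in-degrees so that true parents can enter beside
transient proxies, after which deleting the proxy raises the score.

Consensus keeps directed edges with occurrence frequency strictly above
the threshold (default 0.30).  The de-loop repeatedly removes the
minimum-weight edge inside any nontrivial strongly connected component
(ties: lexicographic by source then target), which is exactly the set
of edges lying on at least one directed cycle.  Neighborhood extraction
takes the ≤ depth-reachable induced subgraph (default 3 layers) and
optionally strips degree-1 non-root leaves iteratively.

## Key driver analysis

d(v) counts distinct nodes reachable from v within h directed steps
(default h = 6); drivers satisfy d(v) > μ + m·σ (default m = 2) with μ
and σ over the analyzed network's nodes.  With σ = 0 nothing is
flagged.  Ranks break ties by node id, so output is deterministic.

## Consensus correlation networks

Per dataset, every gene is Pearson-correlated with the seed gene on the
disease samples and flagged at BH q < 0.05 within that dataset.  The
directional vote counts, per gene, datasets with significant positive
(c⁺) and negative (c⁻) correlations separately; CGCCS(n) requires
sign-consistent support max(c⁺, c⁻) ≥ n (the combined-count variant is
available behind a flag).  Genes with c⁺ = c⁻ ≥ n enter with an
ambiguous sign.  Nesting CGCCS(n+1) ⊆ CGCCS(n) is immediate from the
counting rule and tested against brute-force evaluation.  Trait
correlations use pairwise-complete deletion, never imputation; strata
with fewer than 3 complete pairs are reported as undefined rather than
dropped silently.

## Signatures

The moderated t shrinks per-gene variances toward a pooled prior whose
scale and degrees of freedom come from moment matching on log s²
(trigamma inversion by Newton iteration); the moderated statistic
carries d + d₀ degrees of freedom, and with moderation off the caller
reduces exactly to the classical two-sample t — the testable contract,
since exact parity with any particular published implementation is not
claimed.  The fold-change gate is linear-scale (|log2FC| ≥ log2 1.2).
Enrichment reports FE = (k/|A|)/(|B|/N) with a one-sided upper-tail
hypergeometric p, checked against exact rational enumeration for all
small tables; the background universe is always explicit (defaulting to
the genes surviving preprocessing).  Projection assigns each network
gene to one of eight categories from its membership in the four
knockout up/down sets; up/down inconsistency within one contrast is an
input error, not a ninth category.

## Validation scales, determinism, limitations

All stochastic steps take explicit seeds (chain c uses seed + c; the
generator derives independent streams per purpose from the base seed),
and fixed seeds give byte-identical outputs.  The recovery validation
runs at p = 50 genes, n = 500 samples, 50 chains per seed, ten seeds —
sizes chosen so the whole suite runs on a single CPU in minutes while
leaving the statistical contrasts (hub vs. background reach, disease
vs. control coordination) far from degenerate.

What passing these tests shows: the pipeline recovers a planted hub
from data whose generative assumptions (linearity, Gaussian noise,
faithful sparse DAG, one cis locus per gene, multiplicative disease
attenuation) match the model class the methods assume.  What it does
not show: robustness to count overdispersion, nonlinear regulation,
hidden confounders, feedback loops, or read-level artifacts — none of
which the generator emulates.  The eight-category projection and the
enrichment statistics are exercised against the generator's ground
truth, not against any cohort-derived gene lists.

Known limitations: downstream-reach ranking is sensitive to single
mis-oriented edges near the hub (an inherited-subtree artifact can
promote a secondary ancestor above the true regulator in occasional
seeds); the mixed-model batch option is reserved but unimplemented; and
the CIT's permutation component, while calibrated under the pleiotropy
null tested here, inherits the usual sensitivity of mediation tests to
measurement error in the mediator.
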