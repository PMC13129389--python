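# Methods

## Contest model

The model treats a between-group conflict (BGC) as an N-player public goods
game with an ecological constraint. A group of census size *n* forages over
discrete food patches; once *n* exceeds a patch's carrying capacity the
group spreads over more patches, and mobilising everyone at a contested
patch costs more. The group-level coordination cost is a staircase of
sigmoid steps,

    c_g(n) = Σ_{i=1..m} C_i / (1 + exp(−k_i (n − n_i))),

with one step per patch: `C_i` the cost magnitude of recruiting the cluster
at patch *i* (cost units), `k_i` the steepness of that transition (per
individual), `n_i` its center (individuals). The cost is interpreted as a
*mean* per-capita burden once divided by *n*; the model deliberately
collapses the spatial heterogeneity of who sits where into that mean.

The contested patch has value *v* and each member a consumption capacity
*s*, so the group's gross gain is `min(s·n, v)` — all members share the
spoils whether or not they fought (the egalitarian case). Net individual
gain is `g = min(s·n, v)/n − c_g(n)/n`; participation probability is
`p = max(0, α·g)` with a species-level motivation α, and the realized
fighting-group size is `S = n·p`. Contest success depends on S, not census
size.

Defaults (also the shipped YAML schema): m = 4, C_i = 5, k_i = 1,
n_i = (10, 20, 30, 40), s = 1, v = 10, α = 0.7. Curve tabulation covers
α ∈ {0.4, 0.7, 1.0}.

Design choices where the formulation was genuinely open:

- `p` is additionally clamped at 1 so it remains a probability for
  arbitrary (s, v, α); at the defaults `g ≤ s = 1` and the cap never binds.
- α is accepted on (0, 1]: the boundary value 1 is a legitimate
  parameterization of maximal motivation and appears in the default curve
  sweep.
- Census size is a non-negative real for curve evaluation (the model is
  continuous) and a positive integer in the contest engine and phase
  diagram, where sizes are counts.
- Winner rule: the model only orders outcomes by S, so the default is the
  deterministic argmax with exact ties (including S₁ = S₂ = 0, "no
  contest") scored as draws; a Tullock-style smooth rule
  `S₁^β/(S₁^β + S₂^β)` is offered with β = 1 as a free sharpness parameter
  (β → ∞ recovers the deterministic rule).
- Sigmoids are evaluated through `scipy.special.expit`, which is stable for
  large |k (n − n_i)|.

### Thresholds

The satiation threshold is `v/s`. The maximum viable group size is the
largest root of the net gain above `v/s`; since there `sign(g) =
sign(v − c_g(n))`, the root is independent of α. It is located by a
unit-step scan up to `10 × max(n_i)` (configurable) followed by Brent
root-polishing to a default tolerance of 1e−6 individuals. A tail where
`c_g` only approaches `v` from below underflows to exactly zero in float64;
the scan therefore demands a genuinely negative excursion (1e−9·v) before
declaring a crossing, and otherwise reports that no upper limit exists in
range. At the defaults the paired-sigmoid symmetry σ(x) + σ(−x) = 1 makes
c_g(25) = 10 = v exactly, so the limit is 25.

A consequence worth flagging: because the first cost step is centered
exactly at the capacity `v/s = 10`, half of that step is already paid at
n = 10, so S peaks at n = 9 on the integer grid (S(9) ≈ 5.359 >
S(10) ≈ 5.250) and the "larger group always wins" regime holds on census
pairs within 1..9, flipping already at the boundary pair (9, 10).

## Literature-review summary

Each reviewed study is a single binary data point — did the authors find
that numerically larger groups win more often? — stratified by contest type
(resource vs territorial). The module validates the two-level codings,
aggregates counts, and reports percentages rounded to one decimal (the
resource-yes share is additionally meaningful at integer precision). The
packaged 33-study fixture is synthetic: only the marginal counts
(13 resource: 9 yes / 4 no; 20 territorial: 16 yes / 4 no) are encoded,
because those marginals are the only published quantities; species and
group sizes are placeholders. No inferential statistics are computed on the
review — the underlying data are study-level binaries.

## Synthetic data generator

The generator emulates the statistical structure of two vervet-monkey
datasets so the estimators can be validated by parameter recovery without
any field data.

**Spread observations** (default n = 5000): each record is one focal follow
of one of three groups (AK, NH, BD) whose census sizes are drawn from
normal laws (21.32 ± 1.5, 34.04 ± 4.88, 50.58 ± 2.64 individuals) with
group shares matching the observed observation counts (15.2/38.4/46.5%).
Season is Bernoulli(0.5) winter (the true seasonal split of the field data
is not published; a balanced design is the neutral choice and maximises
information on the season terms). The ordinal spread category (1: 0–20 m,
2: 20–50 m, 3: 50–100 m, 4: >100 m) is drawn from a cumulative-logit law
`P(Y ≤ j) = logistic(θ_j − η)` with equidistant thresholds
`θ_j = θ_base + (j−1)·δ` and linear predictor
`η = β_size·(size − sizē) + β_season·winter + β_int·(size − sizē)·winter`.
Defaults: β_size = 0.15, β_season = −0.03, β_int = 0.04 (the published
point estimates), θ_base = −1, δ = 2. Size is centered at the pooled mean
(≈39.8) because the real thresholds are unreported; with centered sizes the
default thresholds produce all four categories at realistic frequencies.
Slopes and the interaction are invariant to the centering constant.

**Contests** (default 71 records): dyad counts follow the study exactly
(AK–BD 34, AK–NH 16, BD–CR 10, BD–NH 11); an optional total count instead
draws dyads at those proportions. The spread-difference Δ (focal − rival
category) is uniform on {−3..3} \ {0} — identical-spread encounters are
excluded by design. Relative NDVI is Normal(0, 0.1) with a zero effect by
default, and season enters with a zero effect by default, matching the
absence of support for either in the original analysis. The win probability
is `logistic(intercept + β_dq·Δ + β_season·winter + β_ndvi·ndvi)` with
β_dq = −0.52 (the published posterior mean) and intercept 0.

What the generator does *not* emulate: random effects (focal individual,
date, dyad), temporal autocorrelation, NDVI–season dependence, and the real
category base rates (the fitted thresholds were not published). Passing
recovery tests therefore demonstrate that the estimators recover the
fixed-effects structure they are built for, not that the original
mixed-model estimates would be reproduced on the raw data.

## Inference

Both estimators are written directly against their likelihoods rather than
delegated, because the equidistant-threshold constraint and the
verification oracle are the point of the module.

**Ordinal model**: cumulative-logit likelihood with thresholds constrained
to `θ_j = θ_base + (j−1)·δ` (two threshold parameters for four categories).
Optimization is BFGS on the analytic gradient; slopes start at zero and
thresholds at logits of the empirical cumulative shares; convergence at
gradient norm 1e−6. Standard errors come from the numerically
differentiated observed information. With only two categories δ is
unidentified and dropped (the model then *is* binary logistic, which the
test suite exploits as a closed cross-check). Category probabilities are
clipped at 1e−300 before logging to keep degenerate tails finite.

**Logistic model**: Newton–Raphson on the exact gradient and Hessian,
Wald 95% intervals from the inverse information. Complete separation is
detected as coefficient divergence (|β| > 15 on the logit scale) and
returned as a flagged, unconverged fit rather than silently.

**Oracle**: `loglik_oracle` recomputes any fit's log-likelihood by a plain
per-record Python loop and must agree with the optimizer's value to 1e−8;
an empty dataset scores 0.

Fixed effects only, throughout: the estimators match the generator, so
recovery of the generating coefficients (±0.03 on the size slope at
n = 5000, ±0.02 on the interaction, ±0.10 on the spread-difference
log-odds at n = 2000, and 50-seed means within one Monte-Carlo standard
error) is a clean test of the machinery. Reproducing the original
mixed-model z-values or posterior intervals would require the raw data and
is out of scope. Season is dummy-coded with summer as reference.

## Problem sizes

Defaults used by the test suite and the acceptance script: 5000 ordinal
observations and 2000 contests per recovery fit; 50 seeds for the
consistency study; 20000–30000 records for distributional-oracle checks
(tolerance 3 standard errors); phase diagrams on integer grids up to 60.
These sizes give Monte-Carlo standard errors comfortably inside the stated
recovery tolerances.

## Known limitations

- The model is mean-field: no spatially explicit positions, no injury-risk
  or dominance asymmetries, no evolutionary dynamics of α or group size.
- Per-side parameter asymmetries are accepted by the contest engine but
  untested beyond the shared-ecology case.
- The review fixture encodes marginals only; per-study assignments within
  contest types are not reconstructed.
- The win rule's β is a free parameter: the model itself only states that
  the larger fighting party is more likely to win.
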