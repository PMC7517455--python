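# Methods

## Problem and model class

`specmed` quantifies the causal influence of *specific values* of a cause on
the *distribution* of an effect, in information-theoretic units, on discrete
causal Bayesian networks.  The canonical setting is the mediation DAG

```
        U (covariates, possibly unobserved, arbitrary dependence)
       /|\
      X → Z → Y        with the direct edge X → Y
```

where every variable takes values in a finite alphabet and the joint pmf
factorizes according to the causal Markov condition,
`p(x, z, y, u) = p(u) p(x|uX) p(z|x,uZ) p(y|x,z,uY)`.  Interventions follow
the truncated-factorization semantics of the do-operator: `do(X=x)` removes
X's incoming edges and replaces its CPD with a point mass.

All inference is exact, by full enumeration of the joint support as a dense
numpy array with one axis per variable.  The intended scale is models of up
to roughly ten variables with small alphabets; there is no approximate
inference, by design — the measures below are KL divergences between exactly
computed interventional distributions, and enumeration keeps every claimed
identity checkable to near machine precision.

## The measures

Writing `p(Y|x̂)` for the distribution of Y under `do(X=x)`, the package
computes (defaults in bits; `set_units("nats")` switches globally):

- **Specific mutual information** `I1(x;Y) = D(p(Y|X=x) ‖ p(Y))` —
  observational, defined only for `p(x) > 0`.  Its expectation over X is the
  mutual information `I(X;Y)`.  The second candidate
  `I2(x;Y) = H(Y|X=x) − H(Y)` is implemented exactly in this printed form;
  note that under this sign convention `E[I2] = −I(X;Y)`, and I2 can vanish
  while Y's distribution depends strongly on x (the two-node worked
  example).  I2 is provided for contrast only; every causal measure builds
  on I1.
- **STE** (specific total effect)
  `D(p(Y|x̂) ‖ Σ_x' p(x') p(Y|x̂'))` — how much forcing `X=x` moves Y's
  distribution away from what a naturally drawn X would have produced.
- **SCDE** (specific controlled direct effect)
  `D(p(Y|x̂,ẑ) ‖ Σ_x' p(x') p(Y|x̂',ẑ))` — the same comparison with the
  mediator clamped by intervention.
- **SNDE** (specific natural direct effect)
  `D(p(Y|x̂) ‖ Σ_{x',z'} p(x') p(z'|x̂) p(Y|x̂',z'))` — the mediator follows
  its distribution under `do(X=x)` while Y's mechanism is fed the natural
  x'.
- **SNIE** (specific natural indirect effect)
  `D(p(Y|x̂) ‖ Σ_{x',z'} p(x') p(z'|x̂') p(Y|x̂,z'))` — the roles of x and x'
  are swapped: Y's mechanism keeps the forced x while the mediator follows
  naturally drawn causes.
- **Conditional variants** condition every distribution in the formula —
  including the natural-X weights `p(x'|ũ)` — on a covariate context ũ.
- **Normalized variants**
  `M̄ = M / (M + H(Y | do-context, ũ))` map bits to [0, 1]: 0 iff the
  measure is 0, and 1 iff the measure is positive and the intervention
  determines Y (or the measure is infinite).

Baselines for comparison and cross-validation: the Ay–Polani information
flow `I(X→Y)` and its conditional version imposing a set V, and the Janzing
et al. causal strength `CS = D(p ‖ p_S)` through the post-cutting
distribution.

### Properties exercised by the test suite

- `E_p(x)[STE(x→Y)] = I(X→Y)` (information flow), including in confounded
  models.
- `Σ_{x,z} p(x)p(z) SCDE(x→Y;z) = I(X→Y|Ẑ)`, and with no covariates
  `Σ_{x,z} p(x,z) SCDE(x→Y;z) = CS(X→Y)`.
- In the two-node DAG, `STE(x→Y) = I1(x;Y)` and the reversed direction
  `STE(y→X) = 0`.
- No additivity between SNDE, SNIE, and STE is asserted anywhere: with
  non-negative magnitudes, complementary direct and indirect effects can
  each be large while the total effect is zero.  The suite contains the
  complementary-paths construction in which every STE is zero while the
  causal strength of the full edge set stays positive — a documented,
  intended divergence between the frameworks, not a defect.
- Mediator histories: on a Markov persistence chain E → T0 → T1 → T2 (with
  E → Ti), the SNDE of e on T2 is the same whether the mediator is T1 or
  the pair (T0, T1).  This is what licenses collapsing a temperature
  history to its most recent state in the case-study-style DAG.

## Infinity and degenerate inputs

KL divergence is `+inf` exactly when the first argument puts mass where the
second has none; `+inf` is a first-class value that propagates through
reports (serialized as `"inf"`) and normalizes to 1.0.  The conventions
`0·log 0 = 0` and `0·log(0/0) = 0` are fixed.  Conditioning on a
zero-probability event raises `UnsupportedEvidenceError` — never a silent
NaN; mixture constructions skip zero-weight contexts explicitly.  CPD rows
must sum to 1 within 1e-12; derived pmfs within 1e-10 (accumulated
rounding).  Values x with `p(x) = 0` still have a well-defined STE
(interventions on never-occurring values are legal); the observational SMI
for such values is an explicit error.

## Identifiability

Theorem-style gating: the specific effects of x on Y are observationally
identifiable when there exist subsets Ũ1, Ũ2 of the observed covariates
with X d-separated from Y given Ũ1, and from Z given Ũ2, in the graph with
X's outgoing edges removed.  `check_identifiability` searches subsets in
increasing cardinality (ties broken lexicographically by sorted node name),
so witnesses are minimal and deterministic.  d-separation itself delegates
to networkx; the test suite cross-checks it against exact
conditional-independence enumeration (threshold 1e-12 on conditional mutual
information) on random six-node models.

## Estimation

Plug-in estimators replace every distribution in a measure's formula with
its empirical (maximum-likelihood) frequency estimate, e.g.

```
STE̲(e→T)  = D(p̂(T|e) ‖ p̂(T))
SNDE̲(e→T) = D(p̂(T|e) ‖ Σ_{e',s'} p̂(e') p̂(s'|e) p̂(T|e',s'))
SNIE̲(e→T) = D(p̂(T|e) ‖ Σ_{e',s'} p̂(e') p̂(s'|e') p̂(T|e,s'))
STE̲(s→T|e) = D(p̂(T|e,s) ‖ p̂(T|e))
```

These observational forms are valid only when interventions are
exchangeable for observations, so each estimator first checks d-separation
of cause and effect (and, for natural effects, cause and mediator) in the
outgoing-edge-cut graph; `assume_identifiable=True` overrides explicitly.
Pure ML (pseudocount 0) is the default; an optional pseudocount
`(count + c) / (total + c·K)` is available because the natural-effect
mixtures touch every (x', z') cell.  An empty cell that carries positive
mixture weight raises `InestimableError` — estimates remain reproducible
from the printed formulas, never silently smoothed.  Estimation is
per-value: a cause value absent from the sample is undefined while other
values remain estimable.

A weighted-table pathway (full support enumeration with probability
weights) makes every plug-in estimator agree with its exact counterpart as
an algebraic identity; the suite uses it to separate estimator-formula
correctness from sampling error.

Normalized estimates use the empirical conditional entropy of the effect in
the relevant stratum as the denominator.  Continuous variables are out of
scope for estimation.

## Resampling

- **Bootstrap CI**: B whole-row resamples of size n with replacement;
  percentile interval (defaults 5th/95th, B = 10,000) of the replicate
  estimates.  Percentiles use the nearest-rank rule on sorted values — the
  source material names no interpolation rule, so a deterministic one was
  fixed.
- **Permutation null**: to break one causal link of the mediation triangle,
  the parent column of the broken edge is permuted within strata of the
  remaining third variable — breaking X→Y permutes X within Z-strata
  (preserving X→Z and Z→Y); breaking Z→Y permutes Z within X-strata.
  Shuffling the child column instead is offered as an option.  The
  significance threshold is the 95th percentile (configurable) of the null
  replicate estimates; because all measures are KL divergences, the null
  concentrates at and above zero and the test is one-sided by construction.
- Determinism: one seeded `numpy` generator per report; the bootstrap
  consumes one length-n index draw per replicate in order, the permutation
  test one shuffle per stratum (sorted order) per replicate.  Replicates on
  which the estimator is undefined are excluded and counted in the report.

## Synthetic mediation generator

The generator emulates the structure of a climate-teleconnection case
study — a three-phase driver E, a persistence mediator S (previous anomaly
category), and an outcome T (current anomaly category), wired E→S→T with a
direct E→T link — without any external data.  Defaults (own choices,
fixed once):

- `p(E) = (0.25, 0.50, 0.25)` over phases (−1, 0, +1): active phases rarer
  than neutral, symmetric.
- `p(S|E)` shifts mass toward the driver's sign (0.45/0.35/0.20 for the
  matching-sign category and mirrored for the opposite phase).
- `p(T|E,S) = 0.55 · persistence(S) + 0.45 · direct(E)`, with a
  persistence kernel putting 0.60 on repeating the previous category — so
  the persistence signal and direct link are stronger than the indirect
  path, the qualitative pattern the estimators should recover.

Continuous mode draws latent anomalies (phase mean + persistence term +
Gaussian noise, means −1.5/0.0/+1.8, sd 1.0, persistence coefficient 0.6)
and quantizes each raw series at its empirical terciles before any other
processing (ties to the lower bin), so each category holds a third of the
records by construction.

What the generator does *not* emulate: temporal autocorrelation beyond one
step, seasonality/trend confounding, spatial structure, or the
detrending pipeline real anomaly series require.  Passing tests therefore
demonstrate correctness of the measures and estimators under iid
categorical sampling from a known mediation law — not robustness to the
preprocessing choices real climate records need.

## Problem sizes used in the checks

Randomized identities run on 100 random mediation models (alphabets up to
4, Dirichlet(1) CPTs).  Estimator consistency uses 10⁵ generated records
with a 100-replicate bootstrap spread.  Calibration uses 200 outer trials
of n = 2000 with 500 resampling replicates each: 90% bootstrap CI coverage
is required within ±6 points of nominal, and the permutation test's type-I
rate within ±3 points of 5% under a direct-link-free null.  These sizes
keep the stochastic checks' Monte-Carlo error well inside their tolerance
bands.

## Known limitations

- Exact engine only: no factored or approximate inference, so large
  alphabets or many covariates are out of reach by design.
- Plug-in estimators are biased upward at small n (KL of estimated
  distributions); no bias correction is applied, matching the estimator
  definitions.  The bootstrap partially reflects, but does not remove,
  this bias.
- Conditional SCDE/SNDE/SNIE and the normalized SNDE/SNIE denominator
  follow the direct analogy with the conditional STE and normalized STE
  (every distribution conditioned on ũ; denominator
  `H(Y|do-context, ũ)`); for the SCDE the do-context includes the mediator
  clamp.  These are the package's design choices where no canonical
  published form was available, and are exercised by the property tests.
- The permutation scheme for breaking X→Z (permuting X within Y-strata)
  follows the same mechanical rule as the other two edges but conditions on
  a collider-side variable; it is provided for completeness and should be
  interpreted with care.
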