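# Methods

`phylocare` implements the comparative-phylogenetics toolchain used to ask
whether aposematism (conspicuous coloration plus skin alkaloids) in poison
frogs evolved in association with parental-care strategies — in particular
phytotelm-breeding, the deposition of tadpoles in small plant-held pools.
This note records the models, the numerical choices, and what the synthetic
data do and do not establish.

## Trait coding

Species records are coded deterministically:

- **Conspicuousness.** The body is divided into 11 skin segments, each scored
  1 if its coloration contrasts with a leaf-litter background and 0
  otherwise; the coloration score is the segment sum (0–11). A species is
  *conspicuous* iff the score is ≥ 6. Presence of dorsal/lateral stripes and
  flash markings is retained as metadata but does not enter the sum, because
  the score is defined as the sum over the 11 segments only.
- **Chemical defence.** Alkaloids are *present* iff the skin level exceeds
  10 µg per 100 mg of skin. The boundary value 10 codes as absent (strict
  `>`), matching the presence definition.
- **Caregiver sex** is binarized male/female. Species with no apparent
  parental care, and species with biparental care in which no dominant sex
  can be assigned, are excluded with machine-readable reasons rather than
  forced into a category.
- **Transporter sex** follows the observed majority (e.g. 5:1 male:female
  observations code male); exact ties are treated as missing because
  assignment is by clear majority only.
- **Deposition site** is phytotelm (1) vs non-phytotelm (0); species using
  both ponds and streams are non-phytotelm.
- **Continuous traits.** Sexual size dimorphism is female/male snout–vent
  length. Range-valued cells (`"lo-hi"`) reduce to the midpoint. Continuous
  traits are natural-log transformed (the base is a free choice; any fixed
  base is monotone-equivalent for the regressions). Egg size, clutch size and
  tadpole size are size-controlled by regressing on log female SVL under
  Brownian phylogenetic GLS (configurable to OLS); the residuals enter later
  analyses. PGLS is used because the rest of the pipeline conditions on the
  phylogeny; on a star tree it reduces exactly to OLS.

## Mk ancestral states

Single discrete characters are modelled with the equal-rates (ER) Mk chain:
one rate `q` (per unit branch length) for every ordered state pair, with the
closed-form transition probabilities `P(t) = 1/k + (I − 1/k) e^{−kqt}`. The
root prior defaults to the uniform distribution, which is also the ER
stationary distribution, so the choice is innocuous; it is configurable.
Likelihoods use Felsenstein pruning with per-node rescaling of partial
likelihoods (accumulated log-scalers) for underflow control; missing tip
states contribute all-ones partials (marginalised, not dropped), keeping one
common tree across traits. `q` is fitted by a bounded log-scale search
(coarse grid scan over `[1e-8, 1e3]` followed by 1-D refinement); monomorphic
data drive `q` to the boundary and are flagged. Marginal ancestral states use
the up–down (re-rooting) pass: the product of below-node and above-node
conditional likelihoods, normalised per node. Both the likelihood and the
marginals are tested against brute-force enumeration over internal-node
states on all trees with ≤ 5 tips.

## Correlated evolution of trait pairs

Two binary traits (an aposematism component A, phytotelm-breeding B) evolve
as a 4-state chain on (A,B) with states 1=(0,0), 2=(0,1), 3=(1,0), 4=(1,1)
and no simultaneous dual transitions. The *independent* model has 4 rates
(each trait's gain/loss); the *dependent* model frees all 8 single-change
rates; the *constrained* variant shares q34=q43=q12=q21 (all B transitions
equal across A backgrounds), leaving 5 rates. The independent model embeds in
the dependent one; the constrained model does **not** contain the independent
model unless B's gain and loss rates are equal — so the monotone chain of
maximised likelihoods (dependent ≥ constrained ≥ independent) is a theorem
only for dependent ≥ the others, and holds for constrained vs independent
only on data whose B process is near-symmetric. Transition matrices come
from one eigendecomposition of the generator per likelihood evaluation
(batched over branches), verified against the generator reconstruction with
a `scipy.linalg.expm` fallback.

ML fits use multi-start L-BFGS-B on log-rates within `[1e-7, 1e3]`; the
independent fit is always computed first and embedded as a start for the
richer models, which makes the nesting inequalities hold numerically.

Bayesian fits place independent uniform(0, 100) priors on each rate by
default (the convention of the standard tool for this test; an exponential
prior with mean 10 is available) and sample log-rates by random-walk
Metropolis. Adaptation — an isotropic Robbins–Monro scale for the first half
of burn-in, then empirical-covariance-shaped proposals — happens during
burn-in only, so the post-burn-in kernel is fixed and the chain valid.

## Stepping-stone evidence and Bayes factors

Log marginal likelihoods use stepping-stone sampling on the power ladder
`β_k = (k/K)^{1/0.4}` (Beta(0.4, 1) quantiles, concentrating stones near the
prior). Stone k averages `exp((β_{k+1} − β_k)·lnL)` under the power posterior
at β_k. Stones are sampled in *descending* β order: the first chain starts at
the maximum-likelihood point, and each stone warm-starts the next, so chains
never have to find the posterior mode from diffuse prior-side states;
each stone's proposal is additionally shaped by the covariance of the
previous stone's samples. The β=0 stone uses iid prior draws. The default
desk-scale run is 10 stones × 2,000 iterations; the paper-scale preset is
100 × 10,000. Schedules without the β=0 endpoint (fewer than 2 stones) are
rejected.

On a conjugate normal-mean toy model with closed-form evidence the estimator
is accurate to ~0.01 log units at 20 stones × 5,000 iterations. For the
4-state phylogenetic models at desk scale, the seed-to-seed standard
deviation of the log evidence is ≈ 0.5–0.8 for the 4–5-parameter models and
≈ 1–2 for the 8-parameter dependent model; desk-scale log Bayes factors are
therefore meaningful at the level of a few units, which is ample for the
interpretation bands used.

The log Bayes factor is reported as `logBF = 2·(lnML_dep − lnML_indep)` with
bands weak (< 2), positive (2–5), strong (5–10), very strong (> 10); because
both the doubled and the raw conventions appear in the literature, the raw
difference is reported alongside. Evidence estimates carry a fingerprint of
the data they were computed on, and Bayes factors refuse to compare
mismatched fingerprints. Posterior transition-rate summaries expand any model
class to all eight single-change rates and report the gain-vs-reversal
contrasts (q24:q42, q24:q31, ...).

A note on priors and power: with uniform(0, 100) priors, each extra free
rate costs roughly 3–5 nats of evidence. Dependence signals of ~10 nats of
maximised log-likelihood (typical for a constrained-model generator with
~12× gain asymmetry at 200–300 tips) therefore cannot make the 8-parameter
dependent model beat the independent one; strong dependent-vs-independent
Bayes factors require coupling in both traits' conditional rates, which is
what the strong-dependence simulation scenario uses.

## Phylogenetic regressions

- **PGLS** uses generalized least squares with the Brownian covariance
  (root-to-MRCA shared path lengths), scaled to unit height for conditioning
  — slopes and p-values are invariant to that scale. Pairwise trait
  comparisons fit every unordered pair on its complete cases and adjust the
  pooled p-values by Benjamini–Hochberg.
- **Logistic PGLMM.** The binary response follows a latent model
  `ψ = Xβ + u + e`, `u ~ N(0, σ²C)` (C the unit-height phylogenetic
  covariance), `e ~ N(0, 1)` an iid latent residual with variance fixed at 1
  (coefficients are reported on this latent logit scale), and
  `y = Bernoulli(logit⁻¹(ψ))`. σ² has an inverse-Gamma(0.001, 0.001) prior;
  posterior mass piling up near σ² = 0 is surfaced in the summary. Sampling
  uses Pólya-Gamma data augmentation (truncated sum-of-gammas sampler with a
  mean-matching tail correction, 100 terms), giving Gaussian conditionals
  for β, u and e and an inverse-Gamma conditional for σ²; this Gibbs sampler
  mixes far better per iteration than random-walk alternatives, which is why
  the desk preset uses 2 chains × 6,000 iterations (burn-in 1,000, thin 5)
  rather than the much longer chains a Metropolis sampler would need. The
  paper-scale preset reproduces the published 2×10⁷-iteration settings.
  Coefficient significance is the two-sided posterior tail probability
  pMCMC = 2·min(P(β>0), P(β<0)), floored at the Monte-Carlo resolution.
  Very large latent-scale coefficient magnitudes trigger a separation
  warning rather than being suppressed.
- **Convergence** is judged by the classic Gelman–Rubin potential scale
  reduction factor over ≥ 2 chains (identical chains give
  `sqrt((n−1)/n) ≈ 1`); effective sample sizes come from ArviZ.

## Synthetic data

All generators are seed-deterministic. Yule trees are simulated by
exponential waiting times with uniform lineage choice, optionally rescaled to
unit height (the scale on which all simulation rates here are expressed).
Discrete characters are realised by exact event-time (Gillespie) simulation
along each branch — no discretisation bias enters recovery tests. Brownian
traits are multivariate normal draws with covariance σ²·vcv; binary responses
add a phylogenetic normal effect and logistic noise to a linear predictor and
threshold at zero.

The dendrobatid-like fixture emulates the study's data shape: 220 species on
a unit-height Yule tree; (conspicuousness, phytotelm-breeding) generated
under the constrained dependent chain with strong gain asymmetry
(q24 = 6 vs q42 = 0.45, shared B rate 0.35, q13 = 0.18, q31 = 0.8 — chosen so
the expected marginal counts sit at the study's values of roughly 77
conspicuous and 52 phytotelm-breeding species out of 220); alkaloid presence
equal to conspicuousness with a 5% flip; male-biased caregiving and
transport; riparian habitat for a minority (~64 species); Brownian log body
sizes with allometric clutch/egg/tadpole traits and strong clutch-size
reduction in phytotelm breeders; and field-realistic missingness (roughly
half of the continuous fields unknown, alkaloid assays for ~30% of species).
Marginal counts are matched to within ±15% of the study's values by
rejection over generator sub-seeds — never by relabelling tips — so the
accepted dataset remains an exact draw from the generative model.

What passing tests on these data show: that the estimators recover the
parameters of their own generating models at realistic sizes, sparsity and
rate asymmetries. What they do not show: robustness to misspecification that
real data carry — literature-compiled trait errors, non-ultrametric or
misdated trees, state-dependent diversification, or sampling biased toward
well-studied aposematic clades.

## Problem sizes and presets

The test suite and the acceptance script run everything at "desk" scale,
chosen so the full 220-species pipeline finishes in a few minutes on one
CPU: stepping stone 10 stones × 1,000 iterations per model inside the
pipeline (10 × 2,000 as the library default), logistic-PGLMM chains
2 × 6,000, ML fits with 3–5 starts. Simulation studies use 10–25 replicates
at 200–500 tips. The `paper` preset switches the samplers to the published
settings (100 × 10,000 stones; 2×10⁷-iteration chains) and is hours-long.

## Known limitations

- Origin counts ("trait X evolved N times") are narrative readings of the
  marginal reconstructions; no thresholding rule is implemented, and none is
  reported.
- The constrained-vs-independent comparison is not a nested test; see above.
- The alkaloid "proxy" scale used in pairwise regressions is `log1p` of the
  µg/100 mg level, a pragmatic transform for a heavy-tailed non-negative
  measurement; the binarized presence/absence trait is the primary use.
- Rate estimates near the search bounds (monomorphic or near-monomorphic
  traits) are flagged, not silently truncated.
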