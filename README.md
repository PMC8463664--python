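# phylocare

Comparative-phylogenetics toolkit for testing whether **aposematism**
(conspicuous warning coloration plus skin alkaloids) in poison frogs
(Dendrobatidae) evolved in association with **parental-care strategies** —
above all phytotelm-breeding, the deposition of tadpoles in small plant-held
pools. It is aimed at evolutionary ecologists who have a time-calibrated
phylogeny and a species-by-trait table and want the full analysis chain as
reusable, tested Python: trait coding, ancestral state reconstruction,
phylogenetic regressions, and correlated-evolution tests with Bayes factors.

## What it computes

**Trait coding.** The study's definitions, exactly: an 11-segment
conspicuousness score (conspicuous ⇔ score ≥ 6), alkaloid presence
(> 10 µg/100 mg skin), male/female binarization of caregiver and
tadpole-transporter sex with documented exclusion rules, phytotelm vs
non-phytotelm deposition, SSD = female/male SVL, log transforms, medians of
reported ranges, and size-controlled residuals via phylogenetic GLS.

**Mk ancestral states.** Equal-rates Mk likelihood
(`P(t) = 1/k + (I − 1/k)e^{−kqt}`) with Felsenstein pruning, bounded ML
estimation of the rate `q`, and marginal ancestral state reconstruction by
the up–down pass (exact against enumeration on small trees).

**Correlated evolution (Pagel's test).** Two binary traits on the paired
4-state chain 1=(0,0), 2=(0,1), 3=(1,0), 4=(1,1) with no dual transitions:
the *independent* (4-rate), *dependent* (8-rate), and *constrained*
(`q34=q43=q12=q21`, 5-rate) models. Fitting by multi-start ML on log-rates or
by MCMC under uniform(0,100) rate priors; evidence by stepping-stone sampling
(`β_k = (k/K)^{1/0.4}`); model comparison by
`logBF = 2(lnML_dep − lnML_indep)` with the usual bands (<2 weak, 2–5
positive, 5–10 strong, >10 very strong).

**Phylogenetic regressions.** Pairwise PGLS under Brownian covariance with
Benjamini–Hochberg FDR across all trait pairs, and a Bayesian logistic
regression with a phylogenetic random effect
(`ψ = Xβ + u + e`, `u ~ N(0, σ²C)`, inverse-Gamma(0.001, 0.001) prior on σ²,
Pólya-Gamma Gibbs sampling, Gelman–Rubin diagnostics, pMCMC significance).

**Synthetic data.** Seed-deterministic Yule trees, exact (Gillespie) CTMC
trait simulation, Brownian and phylogenetic-logistic generators, and a
220-species dendrobatid-like fixture whose marginal trait counts match the
study's (77 conspicuous, 52 phytotelm-breeding, 92 male caregivers, ...)
with realistic missingness.

See `docs/methods.md` for models, priors, numerical choices, and limitations.

## Worked example

Generate the synthetic dataset and run the whole analysis at desk scale
(a few minutes on one CPU):

```bash
phylocare simulate --seed 1 --out-dir demo/
phylocare run-all --tree demo/tree.nwk --traits demo/traits.csv \
    --out-dir demo/results --preset desk --seed 1
```

`demo/results/` then contains the coded trait table with an exclusions
audit, one `asr_<trait>.csv` of marginal ancestral state probabilities per
discrete trait, `pairwise_regressions.csv` (pairwise PGLS slopes with FDR-adjusted
p-values), `logistic_regressions.csv` (logistic-PGLMM coefficients with pMCMC and
R-hat per binary response), `transition_rates.csv` (posterior means of the
eight transition rates of the constrained model), and `bayes_factors.json`.
For the conspicuousness / phytotelm-breeding pair of the seed-1 dataset the
Bayes-factor report reads (abridged):

```json
{
  "conspicuous__vs__phytotelm_breeder": {
    "n_species": 220,
    "logBF_dependent_vs_independent": 30.84,
    "band_dependent_vs_independent": "very strong",
    "logBF_constrained_vs_independent": 43.99,
    "band_constrained_vs_independent": "very strong",
    "ratio_q24/q31": 27.64
  }
}
```

Read: the models in which coloration evolution depends on breeding site beat
the independent model decisively (logBF far above the "very strong"
threshold of 10) — as they should, since the fixture is simulated under the
constrained dependent model — and the posterior rate of gaining conspicuous
coloration while phytotelm-breeding (`q24`) is about 28× the reversal rate
when it is absent (`q31`), recovering the generator's built-in asymmetry.

The same machinery is available as a library:

```python
from phylocare import ml_fit, stepping_stone_ml, log_bayes_factor
fit = ml_fit(tree, conspicuous, phytotelm, "constrained")
bf = log_bayes_factor(
    stepping_stone_ml(tree, conspicuous, phytotelm, "dependent", seed=1),
    stepping_stone_ml(tree, conspicuous, phytotelm, "independent", seed=2),
)
```

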