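"""Phylogenetic regressions.

Three tools live here:

* :func:`pgls` — generalized least squares with Brownian-motion covariance
  (reduces to ordinary least squares on a star phylogeny), used for the
  pairwise continuous-trait comparisons;
* :func:`pairwise_pgls_matrix` — all unordered trait pairs with
  Benjamini-Hochberg FDR adjustment over the pooled p-values;
* :func:`pglmm_logistic` — Bayesian logistic regression of a binary trait on
  continuous predictors with a species-level random effect whose covariance is
  sigma^2 times the phylogenetic covariance (scaled to unit tree height),
  plus an iid latent residual with variance fixed at 1.  Coefficients are
  therefore reported on the latent logit scale.  Sampling uses Polya-Gamma
  data augmentation, which gives fully Gaussian/inverse-Gamma conditionals and
  mixes far better than a random-walk on this posterior.

Convergence is judged with the Gelman-Rubin potential scale reduction factor
across independent chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.linalg import cho_factor, cho_solve, cholesky
from statsmodels.stats.multitest import multipletests

from .trees import PhyloTree, prune_to_taxa, vcv

__all__ = [
    "PglsResult",
    "pgls",
    "pairwise_pgls_matrix",
    "gelman_rubin",
    "PglmmSpec",
    "RegressionResult",
    "pglmm_logistic",
]


# ---------------------------------------------------------------------------
# PGLS
# ---------------------------------------------------------------------------


@dataclass
class PglsResult:
    slope: float
    intercept: float
    slope_se: float
    p_value: float
    n: int
    loglik: float


def _brownian_cov(tree: PhyloTree, taxa) -> np.ndarray:
    sub = prune_to_taxa(tree, list(taxa)) if set(taxa) != set(tree.tip_labels) else tree
    C = vcv(sub)
    order = [C.taxa.index(t) for t in taxa]
    return C.matrix[np.ix_(order, order)]


def pgls(y, x, tree: PhyloTree, taxa=None) -> PglsResult:
    """Phylogenetic GLS of ``y`` on ``x`` under Brownian covariance.

    ``taxa`` gives the species order of the value vectors (defaults to the
    tree's tip order).  Missing pairs must be removed by the caller; fewer
    than 4 complete pairs is rejected.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    taxa = list(tree.tip_labels) if taxa is None else [str(t) for t in taxa]
    if y.size != x.size or y.size != len(taxa):
        raise ValueError("y, x and taxa must have equal length")
    if np.any(np.isnan(y)) or np.any(np.isnan(x)):
        raise ValueError("missing values must be dropped before pgls")
    if y.size < 4:
        raise ValueError("pgls needs at least 4 complete pairs")
    C = _brownian_cov(tree, taxa)
    C = C / np.max(np.diag(C))  # unit height; slope/p invariant to this scale
    X = sm.add_constant(x)
    if np.linalg.matrix_rank(X) < 2:
        raise ValueError("singular design (constant predictor)")
    fit = sm.GLS(y, X, sigma=C).fit()
    return PglsResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_se=float(fit.bse[1]),
        p_value=float(fit.pvalues[1]),
        n=int(y.size),
        loglik=float(fit.llf),
    )


def pgls_residuals(y, x, tree: PhyloTree, taxa=None, method: str = "pgls") -> np.ndarray:
    """Residuals of ``y`` regressed on ``x`` (phylogenetic GLS by default,
    ordinary least squares with ``method='ols'``)."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    X = sm.add_constant(x)
    if method == "ols":
        fit = sm.OLS(y, X).fit()
    elif method == "pgls":
        taxa = list(tree.tip_labels) if taxa is None else list(taxa)
        C = _brownian_cov(tree, taxa)
        C = C / np.max(np.diag(C))
        fit = sm.GLS(y, X, sigma=C).fit()
    else:
        raise ValueError(f"unknown method {method!r}")
    return y - X @ fit.params


def pairwise_pgls_matrix(
    traits: pd.DataFrame, tree: PhyloTree, alpha: float = 0.05
) -> pd.DataFrame:
    """Pairwise PGLS between all trait columns with BH-FDR adjusted p-values.

    *traits* is indexed by species name; each unordered pair is fitted on its
    complete cases (second column regressed on first).  Returns a long-format
    frame with slope, raw and adjusted p, and a significance flag, shaped like
    a pairwise comparison table.
    """
    cols = list(traits.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 traits")
    rows = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            sub = traits[[cols[i], cols[j]]].dropna()
            sub = sub.loc[[s for s in sub.index if s in set(tree.tip_labels)]]
            if len(sub) < 4:
                rows.append((cols[i], cols[j], np.nan, np.nan, len(sub)))
                continue
            res = pgls(
                sub[cols[j]].to_numpy(),
                sub[cols[i]].to_numpy(),
                tree,
                taxa=list(sub.index),
            )
            rows.append((cols[i], cols[j], res.slope, res.p_value, res.n))
    out = pd.DataFrame(rows, columns=["trait_x", "trait_y", "beta", "p", "n"])
    mask = out["p"].notna()
    adj = np.full(len(out), np.nan)
    if mask.any():
        adj[mask.to_numpy()] = multipletests(
            out.loc[mask, "p"].to_numpy(), alpha=alpha, method="fdr_bh"
        )[1]
    out["p_fdr"] = adj
    out["flag"] = np.where(out["p_fdr"] < alpha, "*", "NS")
    out.loc[~mask, "flag"] = ""
    return out


# ---------------------------------------------------------------------------
# Gelman-Rubin
# ---------------------------------------------------------------------------


def gelman_rubin(chains) -> float:
    """Potential scale reduction factor from >= 2 equal-length chains.

    R-hat compares the between-chain variance of chain means with the pooled
    within-chain variance; values near 1 indicate the chains have mixed.
    Identical chains give exactly 1.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2:
        raise ValueError("chains must be a (n_chains, n_samples) array")
    m, n = chains.shape
    if m < 2:
        raise ValueError("need at least 2 chains")
    if n < 10:
        raise ValueError("chains too short (need length >= 10)")
    means = chains.mean(axis=1)
    W = float(np.mean(chains.var(axis=1, ddof=1)))
    B = float(n * np.var(means, ddof=1))
    if W == 0.0:
        if B == 0.0:
            return 1.0  # identical constant-free chains: converged by definition
        raise ValueError("zero within-chain variance in all chains")
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


# ---------------------------------------------------------------------------
# Polya-Gamma augmented phylogenetic logistic regression
# ---------------------------------------------------------------------------


_PG_TERMS = 100


def _sample_pg1(rng: np.random.Generator, c: np.ndarray) -> np.ndarray:
    """Draw PG(1, c) via the truncated infinite-sum-of-gammas representation,
    with a mean-matching correction for the dropped tail."""
    n = c.shape[0]
    k = np.arange(1, _PG_TERMS + 1)
    denom = (k - 0.5) ** 2 + (c[:, None] / (2 * np.pi)) ** 2  # (n, K)
    g = rng.standard_exponential(size=(n, _PG_TERMS))
    draws = (g / denom).sum(axis=1) / (2 * np.pi**2)
    # exact mean of PG(1,c) is tanh(c/2)/(2c); add the truncated tail's mean
    c_safe = np.where(np.abs(c) < 1e-8, 1e-8, c)
    full_mean = np.tanh(c_safe / 2) / (2 * c_safe)
    trunc_mean = (1.0 / denom).sum(axis=1) / (2 * np.pi**2)
    return draws + np.maximum(full_mean - trunc_mean, 0.0)


@dataclass
class PglmmSpec:
    """Settings for the phylogenetic logistic regression.

    ``prior`` is the (shape, scale) of the inverse-Gamma prior on the
    phylogenetic variance sigma^2 (default 0.001, 0.001, a conventionally
    vague choice that can behave degenerately near sigma^2 -> 0; a warning is
    raised when the posterior piles up at the boundary).
    """

    response: str
    predictors: list
    prior: tuple = (0.001, 0.001)
    n_iter: int = 4000
    burn_in: int = 1000
    thin: int = 2
    n_chains: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.n_iter <= self.burn_in or self.burn_in < 0:
            raise ValueError("need n_iter > burn_in >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 2:
            raise ValueError("need >= 2 chains for convergence diagnostics")


@dataclass
class RegressionResult:
    """Posterior coefficient summaries of the logistic PGLMM."""

    coefficients: pd.DataFrame  # mean, sd, CI, pMCMC, rhat, ess per beta
    sigma2_summary: dict
    n: int
    separation_warning: bool
    chains: np.ndarray = field(repr=False)  # (n_chains, n_samples, p+2)
    param_names: list = field(default_factory=list)


def _pglmm_chain(y, X, Cinv, prior, n_iter, burn_in, thin, rng):
    """One Gibbs chain.  Returns (n_kept, p + 2) draws: betas, sigma2, deviance."""
    n, p = X.shape
    a0, b0 = prior
    kappa = y - 0.5
    beta = np.zeros(p)
    u = np.zeros(n)
    e = np.zeros(n)
    sigma2 = 1.0
    B0_inv = np.eye(p) * 1e-8  # vague normal prior on fixed effects
    kept = []
    for it in range(n_iter):
        psi = X @ beta + u + e
        omega = _sample_pg1(rng, psi)
        z = kappa / omega
        # fixed effects
        prec = X.T @ (omega[:, None] * X) + B0_inv
        L = cho_factor(prec)
        mean = cho_solve(L, X.T @ (omega * (z - u - e)))
        # draw from N(mean, prec^-1) via Cholesky of the precision
        Lp = cholesky(prec, lower=True)
        beta = mean + np.linalg.solve(Lp.T, rng.standard_normal(p))
        # phylogenetic random effect
        prec_u = Cinv / sigma2 + np.diag(omega)
        Lu = cholesky(prec_u, lower=True)
        rhs = omega * (z - X @ beta - e)
        mean_u = np.linalg.solve(Lu.T, np.linalg.solve(Lu, rhs))
        u = mean_u + np.linalg.solve(Lu.T, rng.standard_normal(n))
        # iid latent residual, variance fixed at 1
        var_e = 1.0 / (1.0 + omega)
        mean_e = var_e * (omega * (z - X @ beta - u))
        e = mean_e + np.sqrt(var_e) * rng.standard_normal(n)
        # phylogenetic variance
        quad = float(u @ (Cinv @ u))
        sigma2 = 1.0 / rng.gamma(a0 + n / 2.0, 1.0 / (b0 + quad / 2.0))
        if it >= burn_in and (it - burn_in) % thin == 0:
            psi_now = X @ beta + u + e
            dev = -2.0 * float(
                np.sum(y * psi_now - np.logaddexp(0.0, psi_now))
            )
            kept.append(np.concatenate([beta, [sigma2, dev]]))
    return np.asarray(kept)


def pglmm_logistic(
    spec: PglmmSpec, table: pd.DataFrame, tree: PhyloTree
) -> RegressionResult:
    """Bayesian logistic regression with a phylogenetic random effect.

    *table* is indexed by species; the response must be binary.  Complete
    cases are used, the tree is pruned to them, and the phylogenetic
    covariance is scaled to unit height.  Significance is the two-sided
    posterior tail probability pMCMC = 2 * min(P(beta > 0), P(beta < 0)).
    """
    cols = [spec.response] + list(spec.predictors)
    missing_cols = [c for c in cols if c not in table.columns]
    if missing_cols:
        raise ValueError(f"columns not in table: {missing_cols}")
    sub = table[cols].dropna()
    sub = sub.loc[[s for s in sub.index if s in set(tree.tip_labels)]]
    y = sub[spec.response].to_numpy(dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("response must be binary 0/1")
    if np.unique(y).size < 2:
        raise ValueError("response has a single class among complete cases")
    n = len(sub)
    X = np.column_stack([np.ones(n)] + [sub[c].to_numpy(dtype=float) for c in spec.predictors])
    subtree = prune_to_taxa(tree, list(sub.index))
    C = vcv(subtree)
    order = [C.taxa.index(s) for s in sub.index]
    Cm = C.matrix[np.ix_(order, order)]
    Cm = Cm / np.max(np.diag(Cm))
    Cm[np.diag_indices_from(Cm)] += 1e-8  # guard zero-length cherries
    Cinv = np.linalg.inv(Cm)

    ss = np.random.SeedSequence(spec.seed)
    child = ss.spawn(spec.n_chains)
    chains = []
    for c_seed in child:
        rng = np.random.default_rng(c_seed)
        chains.append(
            _pglmm_chain(
                y, X, Cinv, spec.prior, spec.n_iter, spec.burn_in, spec.thin, rng
            )
        )
    chains = np.asarray(chains)  # (m, kept, p+2)
    p = X.shape[1]
    names = ["beta_0"] + [f"beta_{i + 1}" for i in range(p - 1)]
    pooled = chains.reshape(-1, chains.shape[-1])

    import arviz as az

    rows = []
    for i, name in enumerate(names):
        draws = pooled[:, i]
        per_chain = chains[:, :, i]
        gt = float(np.mean(draws > 0))
        pmcmc = 2 * min(gt, 1 - gt)
        pmcmc = max(pmcmc, 2.0 / len(draws))  # cannot resolve below MC resolution
        rhat = gelman_rubin(per_chain) if np.ptp(per_chain) > 0 else 1.0
        ess = float(np.asarray(az.ess(az.convert_to_dataset(per_chain)).x.values).ravel()[0])
        rows.append(
            {
                "parameter": name,
                "mean": float(draws.mean()),
                "sd": float(draws.std(ddof=1)),
                "q2.5": float(np.percentile(draws, 2.5)),
                "q97.5": float(np.percentile(draws, 97.5)),
                "pMCMC": float(pmcmc),
                "rhat": float(rhat),
                "ess": ess,
            }
        )
    coef = pd.DataFrame(rows).set_index("parameter")
    sig_draws = pooled[:, p]
    sigma2_summary = {
        "mean": float(sig_draws.mean()),
        "median": float(np.median(sig_draws)),
        "q2.5": float(np.percentile(sig_draws, 2.5)),
        "q97.5": float(np.percentile(sig_draws, 97.5)),
        "near_zero_mass": float(np.mean(sig_draws < 1e-4)),
    }
    # crude separation diagnostic: latent-scale coefficients drifting very large
    separation = bool(np.any(np.abs(coef["mean"].to_numpy()) > 50))
    return RegressionResult(
        coefficients=coef,
        sigma2_summary=sigma2_summary,
        n=n,
        separation_warning=separation,
        chains=chains,
        param_names=names + ["sigma2", "deviance"],
    )
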