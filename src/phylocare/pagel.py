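"""Correlated evolution of two binary traits (Pagel's discrete framework).

Two binary traits A and B are modelled jointly as a 4-state continuous-time
Markov chain on the paired state (A, B), with states numbered in the
conventional order

    1 = (0, 0),  2 = (0, 1),  3 = (1, 0),  4 = (1, 1)

Here trait A is an aposematism component (conspicuous coloration or skin
alkaloids) and trait B is phytotelm-breeding, so e.g. ``q24`` is the rate of
gaining the aposematic state while phytotelm-breeding is present, and ``q31``
its reversal when phytotelm-breeding is absent.  Simultaneous changes of both
traits (1<->4, 2<->3) are disallowed.

Three model classes are supported:

* ``independent`` — each trait evolves by its own 2-state chain (4 rates);
* ``dependent``  — all 8 single-change rates free;
* ``constrained`` — the dependent model with ``q34 = q43 = q12 = q21`` shared
  (all phytotelm-breeding gains/losses equal across backgrounds), 5 rates.

Model comparison uses log marginal likelihoods from a stepping-stone sampler
and the Bayes-factor convention logBF = 2 * (lnML_dependent - lnML_independent)
with the usual interpretation bands (<2 weak, 2-5 positive, 5-10 strong,
>10 very strong).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eig, expm, inv
from scipy.optimize import minimize
from scipy.special import logsumexp

from .mk import prune_loglik
from .trees import PhyloTree

__all__ = [
    "STATE_PAIRS",
    "RateMatrix4",
    "build_rate_matrix",
    "paired_loglik",
    "ml_fit",
    "ModelFitResult",
    "mcmc_sample",
    "PagelChain",
    "RatePrior",
    "UniformRatePrior",
    "ExponentialRatePrior",
    "stepping_stone_ml",
    "stepping_stone_evidence",
    "SteppingStoneResult",
    "log_bayes_factor",
    "BayesFactorReport",
    "transition_summary",
    "TransitionSummary",
]

# paired-state index (1-based, as printed in rate names) -> (traitA, traitB)
STATE_PAIRS = {1: (0, 0), 2: (0, 1), 3: (1, 0), 4: (1, 1)}

PARAM_NAMES = {
    "independent": ("qA01", "qA10", "qB01", "qB10"),
    "dependent": ("q12", "q13", "q21", "q24", "q31", "q34", "q42", "q43"),
    "constrained": ("shared", "q13", "q31", "q24", "q42"),
}

# (row, col) 0-based for each dependent-model rate name
_DEP_ENTRIES = {
    "q12": (0, 1),
    "q13": (0, 2),
    "q21": (1, 0),
    "q24": (1, 3),
    "q31": (2, 0),
    "q34": (2, 3),
    "q42": (3, 1),
    "q43": (3, 2),
}


@dataclass
class RateMatrix4:
    """A 4-state generator for two binary traits (no dual transitions)."""

    model_class: str
    rates: dict[str, float]
    Q: np.ndarray

    def dependent_rates(self) -> dict[str, float]:
        """All 8 single-change rates, whatever the model class."""
        return {name: float(self.Q[ij]) for name, ij in _DEP_ENTRIES.items()}


def _rates_dict(model_class, rates) -> dict[str, float]:
    names = PARAM_NAMES[model_class]
    if isinstance(rates, dict):
        missing = set(names) - set(rates)
        extra = set(rates) - set(names)
        if missing or extra:
            raise ValueError(
                f"{model_class} model needs rates {names}; "
                f"missing={sorted(missing)} unexpected={sorted(extra)}"
            )
        vals = {n: float(rates[n]) for n in names}
    else:
        rates = list(rates)
        if len(rates) != len(names):
            raise ValueError(
                f"{model_class} model needs {len(names)} rates, got {len(rates)}"
            )
        vals = dict(zip(names, map(float, rates)))
    for n, v in vals.items():
        if not np.isfinite(v) or v < 0:
            raise ValueError(f"rate {n} must be finite and non-negative, got {v}")
    return vals


def build_rate_matrix(model_class: str, rates) -> RateMatrix4:
    """Build the 4-state generator for a model class from named (or ordered) rates."""
    if model_class not in PARAM_NAMES:
        raise ValueError(f"unknown model class {model_class!r}")
    vals = _rates_dict(model_class, rates)
    if model_class == "independent":
        dep = {
            "q13": vals["qA01"],
            "q24": vals["qA01"],
            "q31": vals["qA10"],
            "q42": vals["qA10"],
            "q12": vals["qB01"],
            "q34": vals["qB01"],
            "q21": vals["qB10"],
            "q43": vals["qB10"],
        }
    elif model_class == "constrained":
        s = vals["shared"]
        dep = {
            "q12": s,
            "q21": s,
            "q34": s,
            "q43": s,
            "q13": vals["q13"],
            "q31": vals["q31"],
            "q24": vals["q24"],
            "q42": vals["q42"],
        }
    else:
        dep = vals
    Q = np.zeros((4, 4))
    for name, ij in _DEP_ENTRIES.items():
        Q[ij] = dep[name]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return RateMatrix4(model_class=model_class, rates=vals, Q=Q)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


def _transition_matrices(Q: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """P(t) = expm(Q t) for a batch of branch lengths.

    A single eigendecomposition of Q serves all branches; accuracy is verified
    against ``expm`` on the longest branch, with a per-branch ``expm`` fallback
    for defective or ill-conditioned generators.
    """
    t = np.asarray(lengths, dtype=float)
    try:
        w, V = eig(Q)
        Vinv = inv(V)
        # cheap accuracy check on the decomposition itself (expm fallback if bad)
        recon_err = np.max(np.abs((V * w) @ Vinv - Q).real)
        if not np.isfinite(recon_err) or recon_err > 1e-8 * max(1.0, np.max(np.abs(Q))):
            raise np.linalg.LinAlgError("eigendecomposition inaccurate")
        E = np.exp(t[:, None] * w[None, :])  # (n, k) complex
        P = np.ascontiguousarray(((V[None, :, :] * E[:, None, :]) @ Vinv).real)
    except np.linalg.LinAlgError:
        P = np.stack([expm(Q * ti) for ti in t])
    np.clip(P, 0.0, None, out=P)
    return P


def paired_tip_partials(traitA, traitB) -> np.ndarray:
    """(n_tips, 4) conditional likelihoods; a missing trait component is
    marginalised over its compatible paired states."""
    A = np.asarray(traitA, dtype=float)
    B = np.asarray(traitB, dtype=float)
    if A.shape != B.shape:
        raise ValueError("traitA and traitB must have equal length")
    for name, x in (("traitA", A), ("traitB", B)):
        obs = x[~np.isnan(x)]
        if not np.all(np.isin(obs, (0.0, 1.0))):
            raise ValueError(f"{name} must be binary (0/1) or missing")
    n = A.shape[0]
    part = np.ones((n, 4))
    # state order (A,B): 0=(0,0) 1=(0,1) 2=(1,0) 3=(1,1)
    a_of_state = np.array([0, 0, 1, 1], dtype=float)
    b_of_state = np.array([0, 1, 0, 1], dtype=float)
    for i in range(n):
        ok = np.ones(4, dtype=bool)
        if not np.isnan(A[i]):
            ok &= a_of_state == A[i]
        if not np.isnan(B[i]):
            ok &= b_of_state == B[i]
        part[i] = ok.astype(float)
    return part


UNIFORM_ROOT = np.full(4, 0.25)


def paired_loglik(
    tree: PhyloTree, traitA, traitB, Q: RateMatrix4 | np.ndarray, root_prior=None
) -> float:
    """Pruning log-likelihood of two binary tip traits under a 4-state chain."""
    if isinstance(Q, RateMatrix4):
        Qm = Q.Q
    else:
        Qm = np.asarray(Q, dtype=float)
        if Qm.shape != (4, 4) or not np.allclose(Qm.sum(axis=1), 0, atol=1e-8):
            raise ValueError("Q must be a 4x4 generator with zero row sums")
        off = Qm[~np.eye(4, dtype=bool)]
        if np.any(off < -1e-12):
            raise ValueError("off-diagonal rates must be non-negative")
    root_prior = UNIFORM_ROOT if root_prior is None else np.asarray(root_prior, float)
    tp = paired_tip_partials(traitA, traitB)
    if tp.shape[0] != tree.n_tips:
        raise ValueError("need one paired observation per tip")
    if not np.any(tp.sum(axis=1) < 4):
        raise ValueError("no tip has any observed trait")
    P = _transition_matrices(Qm, tree.lengths)
    return prune_loglik(tree, P, tp, root_prior)


class _PairedData:
    """Precomputed tip partials + data fingerprint for one (tree, A, B) triple."""

    def __init__(self, tree: PhyloTree, traitA, traitB):
        self.tree = tree
        self.A = np.asarray(traitA, dtype=float)
        self.B = np.asarray(traitB, dtype=float)
        self.partials = paired_tip_partials(self.A, self.B)
        h = hashlib.sha256()
        h.update(("|".join(tree.tip_labels)).encode())
        h.update(np.nan_to_num(self.A, nan=-9.0).tobytes())
        h.update(np.nan_to_num(self.B, nan=-9.0).tobytes())
        h.update(np.round(tree.lengths, 12).tobytes())
        self.fingerprint = h.hexdigest()[:16]

    def loglik(self, model_class, rate_values, root_prior=None) -> float:
        rm = build_rate_matrix(model_class, rate_values)
        P = _transition_matrices(rm.Q, self.tree.lengths)
        prior = UNIFORM_ROOT if root_prior is None else root_prior
        return prune_loglik(self.tree, P, self.partials, prior)


def data_fingerprint(tree: PhyloTree, traitA, traitB) -> str:
    return _PairedData(tree, traitA, traitB).fingerprint


# ---------------------------------------------------------------------------
# maximum likelihood
# ---------------------------------------------------------------------------

_RATE_LO, _RATE_HI = 1e-7, 1e3


@dataclass
class ModelFitResult:
    model_class: str
    rates: dict[str, float]
    loglik: float
    converged: list[bool]
    start_logliks: list[float]
    boundary: bool
    data_hash: str

    @property
    def rate_matrix(self) -> RateMatrix4:
        return build_rate_matrix(self.model_class, self.rates)


def _optimize(data: _PairedData, model_class, starts) -> tuple[np.ndarray, float, list, list]:
    names = PARAM_NAMES[model_class]
    lo, hi = np.log(_RATE_LO), np.log(_RATE_HI)

    def nll(theta):
        r = np.exp(np.clip(theta, lo, hi))
        ll = data.loglik(model_class, dict(zip(names, r)))
        return -ll if np.isfinite(ll) else 1e12

    best_theta, best_val = None, np.inf
    converged, values = [], []
    for x0 in starts:
        res = minimize(
            nll,
            np.clip(np.log(np.maximum(x0, _RATE_LO)), lo, hi),
            method="L-BFGS-B",
            bounds=[(lo, hi)] * len(names),
        )
        converged.append(bool(res.success))
        values.append(float(-res.fun))
        if res.fun < best_val:
            best_val, best_theta = float(res.fun), res.x
    if best_theta is None or not np.isfinite(best_val):
        raise RuntimeError("optimization failed for all starts")
    return np.exp(best_theta), -best_val, converged, values


def _embed_independent(rates: dict, model_class: str) -> np.ndarray:
    """Map an independent-model fit to a start for a richer model class."""
    a01, a10 = rates["qA01"], rates["qA10"]
    b01, b10 = rates["qB01"], rates["qB10"]
    if model_class == "dependent":
        return np.array([b01, a01, b10, a01, a10, b01, a10, b10])
    # constrained: shared B-rate approximated by the geometric mean of gain/loss
    s = float(np.sqrt(max(b01, _RATE_LO) * max(b10, _RATE_LO)))
    return np.array([s, a01, a10, a01, a10])


def ml_fit(
    tree: PhyloTree,
    traitA,
    traitB,
    model_class: str,
    n_starts: int = 5,
    seed: int = 0,
) -> ModelFitResult:
    """Maximum-likelihood rates for one model class (multi-start L-BFGS-B on
    log-rates; the independent fit seeds the dependent/constrained searches so
    the nesting chain of maximised likelihoods is respected numerically)."""
    if model_class not in PARAM_NAMES:
        raise ValueError(f"unknown model class {model_class!r}")
    data = _PairedData(tree, traitA, traitB)
    for name, x in (("traitA", data.A), ("traitB", data.B)):
        if np.sum(~np.isnan(x)) < 2:
            raise ValueError(f"{name} has fewer than 2 observed tips")
    rng = np.random.default_rng(seed)
    scale = 1.0 / max(tree.height(), 1e-12)
    names = PARAM_NAMES[model_class]

    base_starts = [np.full(len(names), scale), np.full(len(names), 10 * scale)]
    ind_rates = None
    if model_class != "independent":
        ind_fit = ml_fit(tree, traitA, traitB, "independent", n_starts=3, seed=seed)
        ind_rates = ind_fit.rates
        base_starts.insert(0, _embed_independent(ind_rates, model_class))
    while len(base_starts) < n_starts:
        jitter = np.exp(rng.normal(0.0, 1.0, size=len(names)))
        base_starts.append(base_starts[0] * jitter)
    rates, loglik, converged, values = _optimize(data, model_class, base_starts[:max(n_starts, len(base_starts))])
    rate_dict = dict(zip(names, map(float, rates)))
    boundary = bool(
        np.any(rates <= _RATE_LO * 10) or np.any(rates >= _RATE_HI / 10)
    )
    monoA = np.unique(data.A[~np.isnan(data.A)]).size < 2
    monoB = np.unique(data.B[~np.isnan(data.B)]).size < 2
    return ModelFitResult(
        model_class=model_class,
        rates=rate_dict,
        loglik=float(loglik),
        converged=converged,
        start_logliks=values,
        boundary=boundary or monoA or monoB,
        data_hash=data.fingerprint,
    )


# ---------------------------------------------------------------------------
# priors and MCMC
# ---------------------------------------------------------------------------


class RatePrior:
    """Independent prior on each transition rate."""

    def logpdf(self, rates: np.ndarray) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        raise NotImplementedError


@dataclass
class UniformRatePrior(RatePrior):
    """Uniform(0, hi) on each rate (the conventional default for this test)."""

    hi: float = 100.0

    def logpdf(self, rates):
        if np.any(rates <= 0) or np.any(rates >= self.hi):
            return -np.inf
        return -len(rates) * np.log(self.hi)

    def sample(self, rng, size):
        return rng.uniform(0.0, self.hi, size=size)


@dataclass
class ExponentialRatePrior(RatePrior):
    """Exponential with given mean on each rate."""

    mean: float = 10.0

    def logpdf(self, rates):
        if np.any(rates <= 0):
            return -np.inf
        return float(np.sum(-np.log(self.mean) - rates / self.mean))

    def sample(self, rng, size):
        return rng.exponential(self.mean, size=size)


@dataclass
class PagelChain:
    """Posterior (or power-posterior) samples of the transition rates."""

    model_class: str
    param_names: tuple
    samples: np.ndarray  # (n_samples, d) on the rate scale
    logliks: np.ndarray
    acceptance_rate: float
    seed: int
    data_hash: str
    likelihood_power: float = 1.0

    def summary(self):
        import pandas as pd

        qs = np.percentile(self.samples, [2.5, 50, 97.5], axis=0)
        return pd.DataFrame(
            {
                "mean": self.samples.mean(axis=0),
                "sd": self.samples.std(axis=0, ddof=1),
                "q2.5": qs[0],
                "median": qs[1],
                "q97.5": qs[2],
            },
            index=list(self.param_names),
        )


def _mh_run(
    logpost,
    theta0: np.ndarray,
    n_iter: int,
    burn_in: int,
    rng: np.random.Generator,
    step0: float = 0.6,
    adapt_target: float = 0.25,
    L_prop0: np.ndarray | None = None,
):
    """Adaptive random-walk Metropolis on an unconstrained vector.

    ``logpost(theta)`` returns ``(log target density, log-likelihood)`` so the
    sampler can report per-sample log-likelihoods without re-evaluating.
    Adaptation happens during burn-in only (keeping the post-burn-in kernel
    fixed and the chain valid): the first half of burn-in tunes an isotropic
    scale by Robbins-Monro, the second half switches to proposals shaped by
    the empirical covariance of the burn-in samples (adaptive Metropolis).
    """
    d = theta0.size
    theta = theta0.copy()
    lp, ll = logpost(theta)
    if not np.isfinite(lp):
        raise ValueError("initial state has zero posterior density")
    step = step0
    externally_shaped = L_prop0 is not None
    L_prop = np.eye(d) if L_prop0 is None else L_prop0
    kept = np.empty((n_iter, d))
    kept_ll = np.empty(n_iter)
    history = np.empty((burn_in, d)) if burn_in else None
    n_acc = 0
    total = burn_in + n_iter
    half = burn_in // 2
    for it in range(total):
        prop = theta + step * (L_prop @ rng.standard_normal(d))
        lp_prop, ll_prop = logpost(prop)
        if np.log(rng.uniform()) < lp_prop - lp:
            theta, lp, ll = prop, lp_prop, ll_prop
            acc = 1.0
        else:
            acc = 0.0
        if it < burn_in:
            history[it] = theta
            step = float(np.exp(np.log(step) + (acc - adapt_target) / (1 + it) ** 0.6))
            step = min(max(step, 1e-3), 10.0)
            if not externally_shaped and it == half and half >= max(20, 5 * d):
                cov = np.cov(history[half // 2 : half].T) + 1e-6 * np.eye(d)
                try:
                    L_prop = np.linalg.cholesky((2.38**2 / d) * cov)
                    step = 1.0
                except np.linalg.LinAlgError:
                    L_prop = np.eye(d)
        else:
            j = it - burn_in
            kept[j] = theta
            kept_ll[j] = ll
            n_acc += acc
    acc_rate = n_acc / n_iter if n_iter else 0.0
    return kept, kept_ll, acc_rate, step


def mcmc_sample(
    tree: PhyloTree,
    traitA,
    traitB,
    model_class: str,
    prior: RatePrior | None = None,
    n_iter: int = 5000,
    seed: int = 0,
    burn_in: int | None = None,
    likelihood_power: float = 1.0,
    init: np.ndarray | None = None,
    root_prior=None,
) -> PagelChain:
    """Metropolis-Hastings sampling of transition rates on the log scale.

    ``likelihood_power=0`` samples the prior through the same kernel, which is
    the basis of the prior-recovery check and of the stepping-stone ladder.
    """
    if model_class not in PARAM_NAMES:
        raise ValueError(f"unknown model class {model_class!r}")
    prior = prior or UniformRatePrior()
    data = _PairedData(tree, traitA, traitB)
    names = PARAM_NAMES[model_class]
    d = len(names)
    burn_in = n_iter // 5 if burn_in is None else burn_in
    rng = np.random.default_rng(seed)

    def logpost(theta):
        rates = np.exp(theta)
        lp = prior.logpdf(rates) + float(theta.sum())  # log-scale Jacobian
        if not np.isfinite(lp):
            return -np.inf, np.nan
        ll = np.nan
        if likelihood_power != 0.0:
            ll = data.loglik(model_class, dict(zip(names, rates)), root_prior)
            if not np.isfinite(ll):
                return -np.inf, np.nan
            lp += likelihood_power * ll
        return lp, ll

    if init is None:
        start_rates = np.full(d, 1.0 / max(tree.height(), 1e-12))
        if likelihood_power == 0.0:
            start_rates = np.maximum(prior.sample(rng, d), 1e-6)
    else:
        start_rates = np.asarray(init, dtype=float)
    kept, lls, acc, _ = _mh_run(logpost, np.log(start_rates), n_iter, burn_in, rng)
    if acc == 0.0:
        raise RuntimeError("MCMC accepted no proposals after adaptation")
    samples = np.exp(kept)
    return PagelChain(
        model_class=model_class,
        param_names=names,
        samples=samples,
        logliks=lls,
        acceptance_rate=float(acc),
        seed=seed,
        data_hash=data.fingerprint,
        likelihood_power=likelihood_power,
    )


# ---------------------------------------------------------------------------
# stepping-stone marginal likelihood
# ---------------------------------------------------------------------------


@dataclass
class SteppingStoneResult:
    log_ml: float
    betas: np.ndarray
    stone_mean_loglik: np.ndarray
    stone_contrib: np.ndarray
    n_stones: int
    iters_per_stone: int
    seed: int
    model_class: str = ""
    data_hash: str = ""


def stepping_stone_evidence(
    loglik_fn,
    log_prior_fn,
    sample_prior_fn,
    dim: int,
    seed: int,
    n_stones: int = 10,
    iters_per_stone: int = 2000,
    alpha: float = 0.4,
    burn_frac: float = 0.2,
    step0: float = 0.6,
    init_theta=None,
) -> SteppingStoneResult:
    """Generic stepping-stone estimator of the log evidence.

    Works on an unconstrained parameterisation: ``loglik_fn(theta)`` and
    ``log_prior_fn(theta)`` take the transformed vector (any Jacobian belongs
    in ``log_prior_fn``), and ``sample_prior_fn(rng, n)`` draws iid transformed
    prior samples.  The power ladder is ``beta_k = (k/K)**(1/alpha)`` (the
    quantiles of a Beta(alpha, 1), concentrating stones near the prior); stone
    ``k`` averages ``exp((beta_{k+1}-beta_k) * loglik)`` under the power
    posterior at ``beta_k``.  Stones are sampled in descending power order,
    warm-starting each Metropolis chain from the previous (more concentrated)
    stone — starting at the posterior end, ideally from ``init_theta`` (e.g. a
    maximum-likelihood point), avoids chains having to find the posterior
    mode from diffuse prior-side states.  The beta=0 stone uses iid prior
    draws.
    """
    K = int(n_stones)
    if K < 2:
        raise ValueError("stepping-stone schedule needs at least 2 stones "
                         "(it must include the beta=0 prior endpoint)")
    if iters_per_stone < 10:
        raise ValueError("iters_per_stone too small")
    betas = (np.arange(K + 1) / K) ** (1.0 / alpha)
    rng = np.random.default_rng(seed)
    burn = max(10, int(burn_frac * iters_per_stone))

    contribs = np.empty(K)
    mean_ll = np.empty(K)
    if init_theta is None:
        theta = sample_prior_fn(rng, 1)[0]
    else:
        theta = np.asarray(init_theta, dtype=float)
    L_prev = None  # proposal shape borrowed from the adjacent stone's samples
    for k in range(K - 1, -1, -1):
        beta = betas[k]
        if beta == 0.0:
            draws = sample_prior_fn(rng, iters_per_stone)
            lls = np.array([loglik_fn(t) for t in draws])
        else:
            def logpost(t, _b=beta):
                lp = log_prior_fn(t)
                if not np.isfinite(lp):
                    return -np.inf, np.nan
                ll = loglik_fn(t)
                if not np.isfinite(ll):
                    return -np.inf, np.nan
                return lp + _b * ll, ll
            kept, lls, _, _ = _mh_run(
                logpost, theta, iters_per_stone, burn, rng,
                step0=step0 if L_prev is None else 1.0,
                L_prop0=L_prev,
            )
            theta = kept[-1]
            try:
                cov = np.cov(kept.T) + 1e-8 * np.eye(dim)
                L_prev = np.linalg.cholesky((2.38**2 / dim) * cov)
            except np.linalg.LinAlgError:
                L_prev = None
        db = betas[k + 1] - betas[k]
        contribs[k] = logsumexp(db * lls) - np.log(len(lls))
        mean_ll[k] = float(np.mean(lls))
        if not np.isfinite(contribs[k]):
            raise RuntimeError(f"non-finite stepping-stone contribution at stone {k}")
    return SteppingStoneResult(
        log_ml=float(contribs.sum()),
        betas=betas,
        stone_mean_loglik=mean_ll,
        stone_contrib=contribs,
        n_stones=K,
        iters_per_stone=int(iters_per_stone),
        seed=seed,
    )


def stepping_stone_ml(
    tree: PhyloTree,
    traitA,
    traitB,
    model_class: str,
    prior: RatePrior | None = None,
    n_stones: int = 10,
    iters_per_stone: int = 2000,
    seed: int = 0,
    root_prior=None,
) -> SteppingStoneResult:
    """Stepping-stone log marginal likelihood for one Pagel model class."""
    if model_class not in PARAM_NAMES:
        raise ValueError(f"unknown model class {model_class!r}")
    prior = prior or UniformRatePrior()
    data = _PairedData(tree, traitA, traitB)
    names = PARAM_NAMES[model_class]
    d = len(names)

    def loglik_fn(theta):
        return data.loglik(model_class, dict(zip(names, np.exp(theta))), root_prior)

    def log_prior_fn(theta):
        rates = np.exp(theta)
        return prior.logpdf(rates) + float(theta.sum())

    def sample_prior_fn(rng, n):
        return np.log(np.maximum(prior.sample(rng, (n, d)), 1e-300))

    # ML point (clipped into the prior's support) seeds the posterior-end stone
    ml = ml_fit(tree, traitA, traitB, model_class, n_starts=2, seed=seed)
    init_rates = np.array([ml.rates[n] for n in names])
    init_rates = np.clip(init_rates, 1e-5, None)
    if isinstance(prior, UniformRatePrior):
        init_rates = np.minimum(init_rates, 0.99 * prior.hi)

    res = stepping_stone_evidence(
        loglik_fn,
        log_prior_fn,
        sample_prior_fn,
        dim=d,
        seed=seed,
        n_stones=n_stones,
        iters_per_stone=iters_per_stone,
        init_theta=np.log(init_rates),
    )
    res.model_class = model_class
    res.data_hash = data.fingerprint
    return res


# ---------------------------------------------------------------------------
# Bayes factors and posterior summaries
# ---------------------------------------------------------------------------


@dataclass
class BayesFactorReport:
    """logBF = 2 * (lnML_alt - lnML_null) with interpretation band.

    ``raw_log_bf`` (the plain lnML difference) is reported alongside because
    both conventions appear in the literature.
    """

    log_bf: float
    raw_log_bf: float
    band: str
    model_alt: str
    model_null: str
    ln_ml_alt: float
    ln_ml_null: float


def bf_band(log_bf: float) -> str:
    if log_bf < 2:
        return "weak"
    if log_bf < 5:
        return "positive"
    if log_bf <= 10:
        return "strong"
    return "very strong"


def log_bayes_factor(
    ml_dependent: SteppingStoneResult, ml_independent: SteppingStoneResult
) -> BayesFactorReport:
    """Compare two stepping-stone evidences computed on the same data."""
    for r in (ml_dependent, ml_independent):
        if not np.isfinite(r.log_ml):
            raise ValueError("non-finite marginal likelihood estimate")
    if (
        ml_dependent.data_hash
        and ml_independent.data_hash
        and ml_dependent.data_hash != ml_independent.data_hash
    ):
        raise ValueError("marginal likelihoods were computed on different data")
    delta = ml_dependent.log_ml - ml_independent.log_ml
    log_bf = 2.0 * delta
    return BayesFactorReport(
        log_bf=float(log_bf),
        raw_log_bf=float(delta),
        band=bf_band(log_bf),
        model_alt=ml_dependent.model_class or "dependent",
        model_null=ml_independent.model_class or "independent",
        ln_ml_alt=float(ml_dependent.log_ml),
        ln_ml_null=float(ml_independent.log_ml),
    )


@dataclass
class TransitionSummary:
    table: "object"  # pandas DataFrame: one row per q parameter
    ratios: dict[str, float]


def transition_summary(chain: PagelChain, model_class: str | None = None) -> TransitionSummary:
    """Posterior summaries of the eight single-change rates plus the
    aposematism-gain vs reversal contrasts (q24:q42, q24:q31, ...)."""
    import pandas as pd

    model_class = model_class or chain.model_class
    names = PARAM_NAMES[model_class]
    if tuple(chain.param_names) != names:
        raise ValueError("chain parameter names do not match the model class")
    # expand each draw into the 8 dependent-model rates
    dep_names = PARAM_NAMES["dependent"]
    dep_draws = np.empty((chain.samples.shape[0], 8))
    for i, s in enumerate(chain.samples):
        rm = build_rate_matrix(model_class, dict(zip(names, s)))
        dep = rm.dependent_rates()
        dep_draws[i] = [dep[n] for n in dep_names]
    qs = np.percentile(dep_draws, [2.5, 50, 97.5], axis=0)
    table = pd.DataFrame(
        {
            "mean": dep_draws.mean(axis=0),
            "sd": dep_draws.std(axis=0, ddof=1),
            "q2.5": qs[0],
            "median": qs[1],
            "q97.5": qs[2],
        },
        index=list(dep_names),
    )
    mean = dict(zip(dep_names, dep_draws.mean(axis=0)))

    def _ratio(a, b):
        return float(mean[a] / mean[b]) if mean[b] > 0 else float("inf")

    ratios = {
        "q24/q42": _ratio("q24", "q42"),
        "q24/q31": _ratio("q24", "q31"),
        "q13/q31": _ratio("q13", "q31"),
        "q24/q13": _ratio("q24", "q13"),
    }
    return TransitionSummary(table=table, ratios=ratios)
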