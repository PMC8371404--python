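"""Hierarchical Bayesian models for slider-elicited prior and posterior
beliefs about partial states.

Prior-probe model (one slider per state).  Participant j's beliefs about
target-set *sizes* at domain size k are a simplex ``p_jk`` of length k+1,
drawn from a population Dirichlet with mean vector ``mu_k`` and
concentration ``w``; states sharing a size are interchangeable, so the
state-level belief is ``Q_i = p_{j,m_i} / C(k, m_i)``.  A normalized slider
response P for state i follows a logit-normal channel around a
kappa-scaled logit of Q:

    logit(P) ~ Normal(kappa * logit(Q), sigma),

where kappa captures endpoint aversion/affinity (kappa = 1 means slider
values map linearly to beliefs on the logit scale).  Hyperpriors:
kappa ~ Gamma(5,5), w ~ Gamma(2, 0.1), sigma^2 ~ inv-Gamma(1,1),
mu_k ~ Dirichlet(1,...,1) (all Gammas in shape-rate convention).

Posterior-probe model (sliders over the states compatible with a focus
utterance).  Participant beliefs are first conditioned on the utterance
and then updated by a soft-max rational speaker with a per-participant
rationality alpha_j:

    Q_post(i) ∝ S1(foc | i; alpha_j) * Q_prior(i),

with alpha_j ~ Gamma(mu_alpha^2/sigma2_alpha, mu_alpha/sigma2_alpha) so the
population mean and variance of alpha are mu_alpha and sigma2_alpha;
mu_alpha ~ Gamma(5,5) (weakly informative, mean 1),
sigma2_alpha ~ inv-Gamma(1,1).  The population Dirichlet hyperparameters
(w, mu_k) are fixed at the posterior means of a prior-probe fit; kappa and
sigma^2 are refit.

Sampling is adaptive Metropolis-within-Gibbs (see :mod:`focusrsa.mcmc`):
there is no conditional conjugacy through the logit-normal channel and the
speaker bridge, but the per-participant blocks are conditionally
independent and are updated in one vectorized step per domain size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from math import comb

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import mcmc
from .states import compatible_states, expand_size_probs, state_sizes

__all__ = [
    "CLIP_EPS",
    "McmcConfig",
    "PriorHyperParams",
    "PosteriorHyperParams",
    "FitResult",
    "clip_unit",
    "slider_link",
    "alpha_gamma_params",
    "rsa_bridge",
    "prior_model_logdensity",
    "fit_prior_model",
    "fit_posterior_model",
    "posterior_predictive_hdi",
    "posterior_predictive_pvalues",
]

#: slider values are clipped to [CLIP_EPS, 1-CLIP_EPS] before the logit, so
#: responses of exactly 0 or 1 stay finite; the guard is far enough out that
#: it never distorts interior responses (a coarser clip visibly flattens the
#: extreme responses a sharp speaker produces and biases rationality
#: estimates downward)
CLIP_EPS = 1e-4

_ITEM_KEY = ["participant_id", "domain_size", "scenario", "prior_type"]


# --------------------------------------------------------------------------
# parameter containers


@dataclass
class McmcConfig:
    """Sampler settings: 4 chains, 50% warmup and thinning factor 5 follow
    the reference analysis; the default 2,000 iterations per chain is a
    desk-scale setting, ``paper_scale()`` selects 50,000."""

    chains: int = 4
    iterations: int = 2000
    warmup_frac: float = 0.5
    thin: int = 5
    seed: int = 0
    #: extra sweeps per iteration over the population-level blocks, which
    #: touch only O(J) Dirichlet/Gamma terms; cheap mixing insurance
    hyper_sweeps: int = 5

    @classmethod
    def paper_scale(cls, **kw) -> "McmcConfig":
        return cls(iterations=50_000, **kw)

    @property
    def warmup(self) -> int:
        return int(self.iterations * self.warmup_frac)

    @property
    def kept(self) -> int:
        return (self.iterations - self.warmup) // self.thin


@dataclass
class PriorHyperParams:
    """Population-level parameters of the prior-probe model.

    ``mu`` maps each domain size k to a length-(k+1) mean probability
    vector over target-set sizes 0..k.
    """

    kappa: float = 1.0
    w: float = 20.0
    sigma2: float = 0.25
    mu: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.kappa, self.w, self.sigma2) <= 0:
            raise ValueError("kappa, w and sigma2 must be positive")
        for k, v in self.mu.items():
            v = np.asarray(v, dtype=float)
            if v.shape != (k + 1,):
                raise ValueError(f"mu[{k}] must have length k+1={k + 1}")
            if abs(v.sum() - 1.0) > 1e-9 or (v < 0).any():
                raise ValueError(f"mu[{k}] must be a probability vector")
            self.mu[k] = v


@dataclass
class PosteriorHyperParams:
    """Population parameters of the posterior-probe model; ``w`` and ``mu``
    are carried over (fixed) from a prior-probe fit."""

    mu_alpha: float = 2.0
    sigma2_alpha: float = 1.0
    kappa: float = 1.0
    sigma2: float = 0.25
    w: float = 20.0
    mu: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.mu_alpha, self.sigma2_alpha, self.kappa, self.sigma2, self.w) <= 0:
            raise ValueError("all hyperparameters must be positive")


@dataclass
class FitResult:
    """Posterior draws and diagnostics of one MCMC fit.

    ``draws[name]`` has shape (chains, kept_draws, ...); ``rhat`` maps each
    free parameter to its worst split potential-scale-reduction factor.
    """

    model: str
    draws: dict
    rhat: dict
    converged: bool
    config: McmcConfig
    participants: tuple
    ks: tuple
    value_col: str

    def stacked(self, name: str) -> np.ndarray:
        """Draws pooled over chains: shape (chains*kept, ...)."""
        arr = np.asarray(self.draws[name])
        return arr.reshape((-1,) + arr.shape[2:])

    def mean(self, name: str) -> np.ndarray:
        return self.stacked(name).mean(axis=0)

    def hdi(self, name: str, prob: float = 0.95) -> np.ndarray:
        """HDI bounds; shape (..., 2) matching the parameter shape."""
        flat = self.stacked(name)
        if flat.ndim == 1:
            return np.array(mcmc.hdi_interval(flat, prob))
        out = np.empty(flat.shape[1:] + (2,))
        for idx in np.ndindex(flat.shape[1:]):
            out[idx] = mcmc.hdi_interval(flat[(slice(None),) + idx], prob)
        return out

    def hyper_means(self) -> PriorHyperParams:
        """Posterior-mean hyperparameters (for fixing in a posterior fit)."""
        if self.model != "prior":
            raise ValueError("hyper_means is defined for prior-probe fits")
        return PriorHyperParams(
            kappa=float(self.mean("kappa")),
            w=float(self.mean("w")),
            sigma2=float(self.mean("sigma2")),
            mu={k: self.mean(f"mu_{k}") for k in self.ks},
        )

    def draws_frame(self) -> pd.DataFrame:
        """Long-format table of the population-level draws (CSV-friendly)."""
        rows = []
        for name, arr in self.draws.items():
            arr = np.asarray(arr)
            if arr.ndim > 3:  # skip participant-level blocks
                continue
            C, D = arr.shape[:2]
            comps = [""] if arr.ndim == 2 else [f"[{i}]" for i in range(arr.shape[2])]
            for ci in range(C):
                for di in range(D):
                    vals = np.atleast_1d(arr[ci, di])
                    for comp, v in zip(comps, vals):
                        rows.append((name + comp, ci, di, float(v)))
        return pd.DataFrame(rows, columns=["parameter", "chain", "draw", "value"])

    def diagnostics(self) -> dict:
        return {
            "model": self.model,
            "converged": self.converged,
            "rhat": self.rhat,
            "chains": self.config.chains,
            "iterations": self.config.iterations,
            "warmup_frac": self.config.warmup_frac,
            "thin": self.config.thin,
            "seed": self.config.seed,
            "n_participants": len(self.participants),
        }


# --------------------------------------------------------------------------
# elementary pieces


def clip_unit(x, eps: float = CLIP_EPS) -> np.ndarray:
    """Clip slider values into [eps, 1-eps] so the logit is finite."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("slider values must lie in [0, 1]")
    return np.clip(x, eps, 1.0 - eps)


def slider_link(q, kappa: float):
    """Logit-scale response mean: kappa * logit(q).

    kappa=1 is the identity in logit space; kappa < 1 compresses responses
    toward the scale midpoint (endpoint aversion), kappa > 1 stretches them
    toward the endpoints.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0) or np.any(q >= 1):
        raise ValueError("q must be strictly inside (0, 1); clip first")
    return kappa * logit(q)


def alpha_gamma_params(mu_alpha: float, sigma2_alpha: float) -> tuple[float, float]:
    """Shape and rate of the population Gamma for alpha_j, parameterized so
    the mean is mu_alpha and the variance sigma2_alpha."""
    if mu_alpha <= 0 or sigma2_alpha <= 0:
        raise ValueError("mu_alpha and sigma2_alpha must be positive")
    return mu_alpha**2 / sigma2_alpha, mu_alpha / sigma2_alpha


@lru_cache(maxsize=None)
def _bridge_operator(k: int, include_null: bool = True):
    """Denotation matrix of the focus lexicon on the compatible subspace.

    States are the 2**(k-1) bitmask states containing the mentioned
    individual (canonically bit 0); expressions are one focus expression
    per nonempty subset plus (optionally) the null message.  Returns
    (T, foc_idx) where T is (n_expressions, n_states) boolean and foc_idx
    indexes the focus expression naming exactly the mentioned individual.
    """
    compat = compatible_states(k)
    masks = list(range(1, 1 << k))
    T = np.array([[(s & m) == m for s in compat] for m in masks])
    if include_null:
        T = np.vstack([T, np.ones((1, compat.size), dtype=bool)])
    return T, masks.index(1)


def rsa_bridge(
    q_prior: np.ndarray,
    alpha_j,
    k: int | None = None,
    include_null: bool = True,
) -> np.ndarray:
    """Map conditioned prior beliefs to posterior beliefs through the
    soft-max rational speaker.

    ``q_prior`` is a normalized vector over the 2**(k-1) compatible states
    (leading axes broadcast; ``alpha_j`` broadcasts against them).  The
    literal listener and speaker are computed on the compatible subspace
    with the focus lexicon; the posterior multiplies the prior by
    S1(foc | i; alpha_j) and renormalizes.  At k=2 this reproduces the
    full-space model exactly.
    """
    q = np.asarray(q_prior, dtype=float)
    S = q.shape[-1]
    if k is None:
        k = int(np.log2(S)) + 1
    if S != 1 << (k - 1):
        raise ValueError(f"expected 2**(k-1)={1 << (k - 1)} compatible states, got {S}")
    alpha = np.asarray(alpha_j, dtype=float)
    if np.any(alpha < 0):
        raise ValueError("alpha_j must be >= 0")
    T, foc_idx = _bridge_operator(k, include_null)
    post = _bridge_apply(q, alpha, T, foc_idx)
    if np.any(post.sum(axis=-1) == 0):
        raise ValueError("speaker assigns zero probability to every compatible state")
    return post


def _bridge_apply(q, alpha, T, foc_idx):
    """Vectorized core of the bridge; q (..., S), alpha broadcastable."""
    le = q @ T.T.astype(float)  # (..., E): listener mass of each expression
    # an expression is usable in a state iff it is true there, the state has
    # prior mass, and the expression has listener support
    valid = T & (q > 0)[..., None, :] & (le > 0)[..., :, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        logL0 = np.where(
            valid, np.log(q)[..., None, :] - np.log(le)[..., :, None], 0.0
        )
    a = np.asarray(alpha, dtype=float)[..., None, None]
    logw = np.where(valid, a * logL0, -np.inf)
    # normalize the speaker over expressions, per state
    top = np.where(valid.any(axis=-2), logw.max(axis=-2), 0.0)
    w = np.exp(logw - top[..., None, :], where=np.isfinite(logw), out=np.zeros_like(logw))
    denom = w.sum(axis=-2)
    s1_foc = np.where(denom > 0, w[..., foc_idx, :] / np.where(denom == 0, 1.0, denom), 0.0)
    post = s1_foc * q
    total = post.sum(axis=-1, keepdims=True)
    return post / np.where(total == 0, 1.0, total)


# --------------------------------------------------------------------------
# joint log density (prior model) -- also serves as the reference for the
# sampler's conditionals, which are derived from the same terms


def prior_model_logdensity(
    data: pd.DataFrame,
    hyper: PriorHyperParams,
    beliefs: dict,
    value_col: str = "raw_value",
) -> float:
    """Joint log density of the prior-probe model.

    ``beliefs`` maps (participant_id, domain_size) to the length-(k+1)
    size-probability vector p_jk.  Empty data returns the hyperprior (and
    Dirichlet) terms only.
    """
    lp = float(
        mcmc.gamma_logpdf(hyper.kappa, 5.0, 5.0)
        + mcmc.gamma_logpdf(hyper.w, 2.0, 0.1)
        + mcmc.invgamma_logpdf(hyper.sigma2, 1.0, 1.0)
    )
    from scipy.special import gammaln

    for k in hyper.mu:
        # flat Dirichlet([1]*(k+1)) hyperprior: constant density Gamma(k+1)
        lp += float(gammaln(k + 1))
    for (pid, k), p_jk in beliefs.items():
        p_jk = np.asarray(p_jk, dtype=float)
        lp += float(mcmc.dirichlet_logpdf(p_jk, hyper.w * hyper.mu[k]))
    if len(data) == 0:
        return lp
    vals = np.asarray(data[value_col], dtype=float)
    if np.any(vals < 0) or np.any(vals > 1):
        raise ValueError("responses must lie in [0, 1]")
    for (pid, k), sub in data.groupby(["participant_id", "domain_size"]):
        p_jk = np.asarray(beliefs[(pid, int(k))], dtype=float)
        m = state_sizes(int(k))
        denom = np.array([comb(int(k), int(mm)) for mm in m])
        Q = p_jk[m] / denom
        idx = sub["state_index"].to_numpy(dtype=int)
        y = logit(clip_unit(sub[value_col].to_numpy(dtype=float)))
        mu_resp = hyper.kappa * logit(clip_unit(Q[idx]))
        lp += float(mcmc.normal_logpdf_sum(y, mu_resp, hyper.sigma2))
    return lp


# --------------------------------------------------------------------------
# data preparation for the samplers


def _prepare_matrix(data: pd.DataFrame, probe: str, value_col: str):
    """Rectangularize slider records into per-domain-size observation
    matrices of logits.

    Returns (pids, ks, Y, cols) where Y[k] is (J, n_items*S) and cols[k]
    gives, per column, the position of its state within the modelled state
    list (all states for prior probes, compatible states for posterior).
    """
    df = data[data["probe"] == probe]
    if df.empty:
        raise ValueError(f"no records with probe={probe!r}")
    pids = tuple(sorted(df["participant_id"].unique()))
    ks = tuple(sorted(int(k) for k in df["domain_size"].unique()))
    Y, cols = {}, {}
    for k in ks:
        sub = df[df["domain_size"] == k]
        if probe == "prior":
            expected = np.arange(1 << k)
        else:
            expected = compatible_states(k)
        pos = {int(s): i for i, s in enumerate(expected)}
        mats, n_items_ref = [], None
        for pid in pids:
            pp = sub[sub["participant_id"] == pid]
            if pp.empty:
                raise ValueError(f"participant {pid!r} has no items at k={k}")
            items = []
            for _, item in pp.groupby(["scenario", "prior_type"], observed=True):
                got = np.sort(item["state_index"].to_numpy(dtype=int))
                if not np.array_equal(got, np.sort(expected)):
                    raise ValueError(
                        f"participant {pid!r}, k={k}: expected sliders for states "
                        f"{list(expected)}, got {list(got)}"
                    )
                item = item.sort_values("state_index")
                items.append(item[value_col].to_numpy(dtype=float))
            if n_items_ref is None:
                n_items_ref = len(items)
            elif len(items) != n_items_ref:
                raise ValueError(f"unbalanced item counts at k={k}")
            mats.append(np.concatenate(items))
        Y[k] = logit(clip_unit(np.array(mats)))
        cols[k] = np.tile(np.arange(expected.size), n_items_ref)
    return pids, ks, Y, cols


# --------------------------------------------------------------------------
# samplers


def _init_simplex(rng, base, C, J=None, jitter=0.15):
    """Jittered ALR coordinates around a base simplex vector."""
    z0 = mcmc.alr_forward(np.asarray(base, dtype=float).clip(1e-4))
    shape = (C, z0.size) if J is None else (C, J, z0.size)
    return z0 + jitter * rng.standard_normal(shape)


def fit_prior_model(
    data: pd.DataFrame,
    cfg: McmcConfig | None = None,
    value_col: str = "raw_value",
) -> FitResult:
    """Sample the joint posterior of the prior-probe model.

    Requires prior-probe records with a full set of 2**k sliders per item
    and a balanced design (same item count for every participant at each
    domain size); apply exclusions first.  Same seed, same data => draws
    are bitwise reproducible.
    """
    cfg = cfg or McmcConfig()
    pids, ks, Y, cols = _prepare_matrix(data, "prior", value_col)
    J, C = len(pids), cfg.chains
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))

    m_of = {k: state_sizes(k) for k in ks}
    # per-column size class and C(k,m) denominators
    colm, coldenom = {}, {}
    for k in ks:
        states = np.arange(1 << k)
        m = m_of[k][states]
        ncopies = cols[k].size // states.size
        colm[k] = np.tile(m, ncopies)
        coldenom[k] = np.array([comb(k, int(mm)) for mm in colm[k]], dtype=float)

    # initialization: moment estimates from the observed sliders
    obs_p = {}
    for k in ks:
        vals = expit(Y[k])  # (J, ncol) clipped responses
        sums = np.zeros((J, k + 1))
        for m_level in range(k + 1):
            sums[:, m_level] = vals[:, colm[k] == m_level].sum(axis=1)
        sums /= sums.sum(axis=1, keepdims=True)
        obs_p[k] = sums.clip(1e-3)
        obs_p[k] /= obs_p[k].sum(axis=1, keepdims=True)

    state = {
        "lkappa": 0.0 + 0.1 * rng.standard_normal(C),
        "lw": np.log(10.0) + 0.3 * rng.standard_normal(C),
        "lsig2": np.log(0.3) + 0.2 * rng.standard_normal(C),
        "zmu": {k: _init_simplex(rng, obs_p[k].mean(axis=0), C) for k in ks},
        # participant blocks start at their per-participant moment estimates
        "zp": {
            k: np.broadcast_to(mcmc.alr_forward(obs_p[k]), (C, J, k)).copy()
            + 0.05 * rng.standard_normal((C, J, k))
            for k in ks
        },
    }

    def loglik_k(k, kappa, sig2, p):
        """(C, J) response log likelihood at domain size k."""
        q = np.clip(p[..., colm[k]] / coldenom[k], CLIP_EPS, 1 - CLIP_EPS)
        mu = kappa[:, None, None] * logit(q)
        return mcmc.normal_logpdf_sum(Y[k][None], mu, sig2[:, None])

    def dir_k(k, w, mu_k, p):
        """(C, J) Dirichlet population term."""
        return mcmc.dirichlet_logpdf(p, (w[:, None] * mu_k)[:, None, :])

    # current values and caches
    kappa, w, sig2 = (np.exp(state[n]) for n in ("lkappa", "lw", "lsig2"))
    mu = {k: mcmc.alr_inverse(state["zmu"][k]) for k in ks}
    p = {k: mcmc.alr_inverse(state["zp"][k]) for k in ks}
    ll = {k: loglik_k(k, kappa, sig2, p[k]) for k in ks}
    dirs = {k: dir_k(k, w, mu[k], p[k]) for k in ks}

    ad_glob = mcmc.ScaleAdapter(C, 0.1)
    ad_w = mcmc.ScaleAdapter(C, 0.2)
    ad_mu = {k: mcmc.ScaleAdapter(C, 0.1) for k in ks}
    ad_p = {k: mcmc.ScaleAdapter((C, J), 0.3) for k in ks}

    kept = cfg.kept
    out = {
        "kappa": np.empty((C, kept)),
        "w": np.empty((C, kept)),
        "sigma2": np.empty((C, kept)),
        **{f"mu_{k}": np.empty((C, kept, k + 1)) for k in ks},
        **{f"p_{k}": np.empty((C, kept, J, k + 1)) for k in ks},
    }
    d = 0
    for it in range(cfg.iterations):
        warm = it < cfg.warmup

        # --- block 1: kappa, sigma2 (likelihood-only, shared scale)
        step = ad_glob.scale[:, None] * rng.standard_normal((C, 2))
        lk_n, ls2_n = state["lkappa"] + step[:, 0], state["lsig2"] + step[:, 1]
        kappa_n, sig2_n = np.exp(lk_n), np.exp(ls2_n)
        ll_n = {k: loglik_k(k, kappa_n, sig2_n, p[k]) for k in ks}
        delta = (
            mcmc.gamma_logpdf(kappa_n, 5.0, 5.0) + lk_n
            - mcmc.gamma_logpdf(kappa, 5.0, 5.0) - state["lkappa"]
            + mcmc.invgamma_logpdf(sig2_n, 1.0, 1.0) + ls2_n
            - mcmc.invgamma_logpdf(sig2, 1.0, 1.0) - state["lsig2"]
            + sum(ll_n[k].sum(axis=1) - ll[k].sum(axis=1) for k in ks)
        )
        acc = rng.random(C) < np.exp(np.minimum(delta, 0.0))
        state["lkappa"][acc], state["lsig2"][acc] = lk_n[acc], ls2_n[acc]
        kappa, sig2 = np.exp(state["lkappa"]), np.exp(state["lsig2"])
        for k in ks:
            ll[k][acc] = ll_n[k][acc]
        if warm:
            ad_glob.update(np.exp(np.minimum(delta, 0.0)))

        # --- blocks 2+3: w and mu_k (Dirichlet terms only, so several
        # sweeps per iteration are nearly free and help mixing)
        for _ in range(cfg.hyper_sweeps):
            lw_n = state["lw"] + ad_w.scale * rng.standard_normal(C)
            w_n = np.exp(lw_n)
            dirs_n = {k: dir_k(k, w_n, mu[k], p[k]) for k in ks}
            delta = (
                mcmc.gamma_logpdf(w_n, 2.0, 0.1) + lw_n
                - mcmc.gamma_logpdf(w, 2.0, 0.1) - state["lw"]
                + sum(dirs_n[k].sum(axis=1) - dirs[k].sum(axis=1) for k in ks)
            )
            acc = rng.random(C) < np.exp(np.minimum(delta, 0.0))
            state["lw"][acc] = lw_n[acc]
            w = np.exp(state["lw"])
            for k in ks:
                dirs[k][acc] = dirs_n[k][acc]
            if warm:
                ad_w.update(np.exp(np.minimum(delta, 0.0)))

            for k in ks:
                z_n = state["zmu"][k] + ad_mu[k].scale[:, None] * rng.standard_normal((C, k))
                mu_n = mcmc.alr_inverse(z_n)
                dirs_n_k = dir_k(k, w, mu_n, p[k])
                delta = (
                    mcmc.log_simplex_jacobian(mu_n)
                    - mcmc.log_simplex_jacobian(mu[k])
                    + dirs_n_k.sum(axis=1)
                    - dirs[k].sum(axis=1)
                )
                acc = rng.random(C) < np.exp(np.minimum(delta, 0.0))
                state["zmu"][k][acc] = z_n[acc]
                mu[k] = mcmc.alr_inverse(state["zmu"][k])
                dirs[k][acc] = dirs_n_k[acc]
                if warm:
                    ad_mu[k].update(np.exp(np.minimum(delta, 0.0)))

        # --- block 4: participant simplices, vectorized over (chain, j)
        for k in ks:
            z_n = state["zp"][k] + ad_p[k].scale[:, :, None] * rng.standard_normal((C, J, k))
            p_n = mcmc.alr_inverse(z_n)
            ll_n_k = loglik_k(k, kappa, sig2, p_n)
            dirs_n_k = dir_k(k, w, mu[k], p_n)
            delta = (
                mcmc.log_simplex_jacobian(p_n)
                - mcmc.log_simplex_jacobian(p[k])
                + dirs_n_k - dirs[k] + ll_n_k - ll[k]
            )
            acc = rng.random((C, J)) < np.exp(np.minimum(delta, 0.0))
            state["zp"][k][acc] = z_n[acc]
            p[k] = mcmc.alr_inverse(state["zp"][k])
            ll[k][acc] = ll_n_k[acc]
            dirs[k][acc] = dirs_n_k[acc]
            if warm:
                ad_p[k].update(np.exp(np.minimum(delta, 0.0)))

        if not warm and (it - cfg.warmup) % cfg.thin == 0 and d < kept:
            out["kappa"][:, d] = kappa
            out["w"][:, d] = w
            out["sigma2"][:, d] = sig2
            for k in ks:
                out[f"mu_{k}"][:, d] = mu[k]
                out[f"p_{k}"][:, d] = p[k]
            d += 1

    for key in out:
        out[key] = out[key][:, :d]
    rhat = mcmc.rhat_dict({n: out[n] for n in out if not n.startswith("p_")})
    converged = all(r < 1.05 for r in rhat.values())
    if not converged:
        warnings.warn(f"prior-probe fit did not converge: max R-hat "
                      f"{max(rhat.values()):.3f}", stacklevel=2)
    return FitResult("prior", out, rhat, converged, cfg, pids, ks, value_col)


def fit_posterior_model(
    data: pd.DataFrame,
    fixed: PriorHyperParams,
    cfg: McmcConfig | None = None,
    value_col: str = "raw_value",
    include_null: bool = True,
) -> FitResult:
    """Sample the posterior-probe model with (w, mu_k) fixed at the
    prior-fit posterior means (``fixed``); kappa and sigma^2 are refit and
    each participant gets one rationality alpha_j shared across items."""
    cfg = cfg or McmcConfig()
    pids, ks, Y, cols = _prepare_matrix(data, "posterior", value_col)
    for k in ks:
        if k not in fixed.mu:
            raise ValueError(f"fixed hyperparameters lack mu for k={k}")
    J, C = len(pids), cfg.chains
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))

    compat = {k: compatible_states(k) for k in ks}
    m_all = {k: state_sizes(k) for k in ks}
    denom_all = {k: np.array([comb(k, int(m)) for m in m_all[k]], dtype=float) for k in ks}
    ops = {k: _bridge_operator(k, include_null) for k in ks}

    def qpost_k(k, p, alpha):
        """(C, J, S) bridged beliefs over compatible states."""
        Qfull = p[..., m_all[k]] / denom_all[k]
        qc = Qfull[..., compat[k]]
        qc = qc / qc.sum(axis=-1, keepdims=True)
        T, foc = ops[k]
        return _bridge_apply(qc, alpha, T, foc)

    def loglik_k(k, kappa, sig2, qp):
        # the channel saturates at the response resolution on both sides
        mu_resp = kappa[:, None, None] * logit(
            np.clip(qp[..., cols[k]], CLIP_EPS, 1 - CLIP_EPS)
        )
        return mcmc.normal_logpdf_sum(Y[k][None], mu_resp, sig2[:, None])

    # moment initialization of each participant's rationality: invert the
    # two-state bridge at the smallest domain size, where the posterior of
    # the exhaustive state is 1/(1 + s (1-q)/q) with s = p^alpha/(1+p^alpha)
    k0 = ks[0]
    q0 = expand_size_probs(np.asarray(fixed.mu[k0], dtype=float), k0)
    q0 = q0[compat[k0]] / q0[compat[k0]].sum()
    exh_share = q0[0]
    vals0 = expit(Y[k0])
    r = np.clip(
        vals0[:, cols[k0] == 0].mean(axis=1)
        / np.maximum(
            sum(vals0[:, cols[k0] == c].mean(axis=1) for c in range(compat[k0].size)),
            1e-9,
        ),
        0.05,
        0.98,
    )
    s_hat = np.clip((1.0 / r - 1.0) * exh_share / (1.0 - exh_share), 1e-3, 0.98)
    with np.errstate(divide="ignore"):
        alpha_hat = np.log(s_hat / (1.0 - s_hat)) / np.log(1.0 - exh_share)
    alpha_hat = np.clip(alpha_hat, 0.3, 15.0)

    state = {
        "lkappa": 0.0 + 0.1 * rng.standard_normal(C),
        "lsig2": np.log(0.3) + 0.2 * rng.standard_normal(C),
        "lmua": np.log(np.clip(alpha_hat.mean(), 0.3, 10.0)) + 0.2 * rng.standard_normal(C),
        "ls2a": 0.0 + 0.3 * rng.standard_normal(C),
        "lalpha": np.log(alpha_hat)[None, :] + 0.2 * rng.standard_normal((C, J)),
        "zp": {
            k: np.broadcast_to(
                mcmc.alr_forward(np.clip(fixed.mu[k], 1e-4, None)), (C, J, k)
            ).copy()
            + 0.05 * rng.standard_normal((C, J, k))
            for k in ks
        },
    }

    kappa, sig2 = np.exp(state["lkappa"]), np.exp(state["lsig2"])
    mua, s2a = np.exp(state["lmua"]), np.exp(state["ls2a"])
    alpha = np.exp(state["lalpha"])
    p = {k: mcmc.alr_inverse(state["zp"][k]) for k in ks}
    qp = {k: qpost_k(k, p[k], alpha) for k in ks}
    ll = {k: loglik_k(k, kappa, sig2, qp[k]) for k in ks}
    dirs = {
        k: mcmc.dirichlet_logpdf(p[k], fixed.w * np.asarray(fixed.mu[k])) for k in ks
    }

    def alpha_prior(alpha, mua, s2a):
        a, b = mua**2 / s2a, mua / s2a
        return mcmc.gamma_logpdf(alpha, a[:, None], b[:, None])

    apri = alpha_prior(alpha, mua, s2a)

    ad_glob = mcmc.ScaleAdapter(C, 0.1)
    ad_hyp = mcmc.ScaleAdapter(C, 0.2)
    ad_a = mcmc.ScaleAdapter((C, J), 0.3)
    ad_ridge = mcmc.ScaleAdapter(C, 0.05, target=0.25)
    ad_p = {k: mcmc.ScaleAdapter((C, J), 0.3) for k in ks}

    kept = cfg.kept
    out = {
        "kappa": np.empty((C, kept)),
        "sigma2": np.empty((C, kept)),
        "mu_alpha": np.empty((C, kept)),
        "sigma2_alpha": np.empty((C, kept)),
        "alpha": np.empty((C, kept, J)),
        **{f"p_{k}": np.empty((C, kept, J, k + 1)) for k in ks},
    }
    d = 0
    for it in range(cfg.iterations):
        warm = it < cfg.warmup

        # --- kappa, sigma2 (responses enter through cached bridged beliefs,
        # so extra sweeps are cheap)
        for _ in range(cfg.hyper_sweeps):
            step = ad_glob.scale[:, None] * rng.standard_normal((C, 2))
            lk_n, ls2_n = state["lkappa"] + step[:, 0], state["lsig2"] + step[:, 1]
            kappa_n, sig2_n = np.exp(lk_n), np.exp(ls2_n)
            ll_n = {k: loglik_k(k, kappa_n, sig2_n, qp[k]) for k in ks}
            delta = (
                mcmc.gamma_logpdf(kappa_n, 5.0, 5.0) + lk_n
                - mcmc.gamma_logpdf(kappa, 5.0, 5.0) - state["lkappa"]
                + mcmc.invgamma_logpdf(sig2_n, 1.0, 1.0) + ls2_n
                - mcmc.invgamma_logpdf(sig2, 1.0, 1.0) - state["lsig2"]
                + sum(ll_n[k].sum(axis=1) - ll[k].sum(axis=1) for k in ks)
            )
            acc = rng.random(C) < np.exp(np.minimum(delta, 0.0))
            state["lkappa"][acc], state["lsig2"][acc] = lk_n[acc], ls2_n[acc]
            kappa, sig2 = np.exp(state["lkappa"]), np.exp(state["lsig2"])
            for k in ks:
                ll[k][acc] = ll_n[k][acc]
            if warm:
                ad_glob.update(np.exp(np.minimum(delta, 0.0)))

        # --- mu_alpha, sigma2_alpha (population of alpha_j only; cheap, so
        # swept several times per iteration)
        for _ in range(cfg.hyper_sweeps):
            step = ad_hyp.scale[:, None] * rng.standard_normal((C, 2))
            lmua_n, ls2a_n = state["lmua"] + step[:, 0], state["ls2a"] + step[:, 1]
            mua_n, s2a_n = np.exp(lmua_n), np.exp(ls2a_n)
            apri_n = alpha_prior(alpha, mua_n, s2a_n)
            delta = (
                mcmc.gamma_logpdf(mua_n, 5.0, 5.0) + lmua_n
                - mcmc.gamma_logpdf(mua, 5.0, 5.0) - state["lmua"]
                + mcmc.invgamma_logpdf(s2a_n, 1.0, 1.0) + ls2a_n
                - mcmc.invgamma_logpdf(s2a, 1.0, 1.0) - state["ls2a"]
                + apri_n.sum(axis=1) - apri.sum(axis=1)
            )
            acc = rng.random(C) < np.exp(np.minimum(delta, 0.0))
            state["lmua"][acc], state["ls2a"][acc] = lmua_n[acc], ls2a_n[acc]
            mua, s2a = np.exp(state["lmua"]), np.exp(state["ls2a"])
            apri[acc] = apri_n[acc]
            if warm:
                ad_hyp.update(np.exp(np.minimum(delta, 0.0)))

        # --- alpha_j, vectorized over (chain, j); two sweeps, since the
        # per-participant rationality is the slowest-mixing block
        for _ in range(2):
            la_n = state["lalpha"] + ad_a.scale * rng.standard_normal((C, J))
            alpha_n = np.exp(la_n)
            qp_n = {k: qpost_k(k, p[k], alpha_n) for k in ks}
            ll_n = {k: loglik_k(k, kappa, sig2, qp_n[k]) for k in ks}
            apri_n = alpha_prior(alpha_n, mua, s2a)
            delta = (
                apri_n - apri + la_n - state["lalpha"]
                + sum(ll_n[k] - ll[k] for k in ks)
            )
            acc = rng.random((C, J)) < np.exp(np.minimum(delta, 0.0))
            state["lalpha"][acc] = la_n[acc]
            alpha = np.exp(state["lalpha"])
            apri[acc] = apri_n[acc]
            for k in ks:
                qp[k][acc] = qp_n[k][acc]
                ll[k][acc] = ll_n[k][acc]
            if warm:
                ad_a.update(np.exp(np.minimum(delta, 0.0)))

        # --- joint ridge move: sharper speakers (all alpha_j up) trade off
        # against a steeper response link (kappa down), a direction that
        # single-block walks traverse slowly
        eps = ad_ridge.scale * rng.standard_normal(C)
        la_n = state["lalpha"] + eps[:, None]
        lk_n = state["lkappa"] - eps
        alpha_n, kappa_n = np.exp(la_n), np.exp(lk_n)
        qp_n = {k: qpost_k(k, p[k], alpha_n) for k in ks}
        ll_n = {k: loglik_k(k, kappa_n, sig2, qp_n[k]) for k in ks}
        apri_n = alpha_prior(alpha_n, mua, s2a)
        delta = (
            mcmc.gamma_logpdf(kappa_n, 5.0, 5.0) + lk_n
            - mcmc.gamma_logpdf(kappa, 5.0, 5.0) - state["lkappa"]
            + (apri_n - apri).sum(axis=1)
            + (J - 1) * eps  # log-scale Jacobian of the joint alpha/kappa shift
            + sum(ll_n[k].sum(axis=1) - ll[k].sum(axis=1) for k in ks)
        )
        acc = rng.random(C) < np.exp(np.minimum(delta, 0.0))
        state["lalpha"][acc] = la_n[acc]
        state["lkappa"][acc] = lk_n[acc]
        alpha, kappa = np.exp(state["lalpha"]), np.exp(state["lkappa"])
        apri[acc] = apri_n[acc]
        for k in ks:
            qp[k][acc] = qp_n[k][acc]
            ll[k][acc] = ll_n[k][acc]
        if warm:
            ad_ridge.update(np.exp(np.minimum(delta, 0.0)))

        # --- participant simplices
        for k in ks:
            z_n = state["zp"][k] + ad_p[k].scale[:, :, None] * rng.standard_normal((C, J, k))
            p_n = mcmc.alr_inverse(z_n)
            qp_n_k = qpost_k(k, p_n, alpha)
            ll_n_k = loglik_k(k, kappa, sig2, qp_n_k)
            dirs_n_k = mcmc.dirichlet_logpdf(p_n, fixed.w * np.asarray(fixed.mu[k]))
            delta = (
                mcmc.log_simplex_jacobian(p_n)
                - mcmc.log_simplex_jacobian(p[k])
                + dirs_n_k - dirs[k] + ll_n_k - ll[k]
            )
            acc = rng.random((C, J)) < np.exp(np.minimum(delta, 0.0))
            state["zp"][k][acc] = z_n[acc]
            p[k] = mcmc.alr_inverse(state["zp"][k])
            qp[k][acc] = qp_n_k[acc]
            ll[k][acc] = ll_n_k[acc]
            dirs[k][acc] = dirs_n_k[acc]
            if warm:
                ad_p[k].update(np.exp(np.minimum(delta, 0.0)))

        if not warm and (it - cfg.warmup) % cfg.thin == 0 and d < kept:
            out["kappa"][:, d] = kappa
            out["sigma2"][:, d] = sig2
            out["mu_alpha"][:, d] = mua
            out["sigma2_alpha"][:, d] = s2a
            out["alpha"][:, d] = alpha
            for k in ks:
                out[f"p_{k}"][:, d] = p[k]
            d += 1

    for key in out:
        out[key] = out[key][:, :d]
    rhat = mcmc.rhat_dict(
        {n: out[n] for n in ("kappa", "sigma2", "mu_alpha", "sigma2_alpha")}
    )
    converged = all(r < 1.05 for r in rhat.values())
    if not converged:
        warnings.warn(f"posterior-probe fit did not converge: max R-hat "
                      f"{max(rhat.values()):.3f}", stacklevel=2)
    res = FitResult("posterior", out, rhat, converged, cfg, pids, ks, value_col)
    res.fixed = fixed  # carried for posterior predictive simulation
    return res


# --------------------------------------------------------------------------
# posterior predictive checks


def _simulate_item(rng, Q, kappa, sigma2):
    """Raw logit-normal responses for one item's slider probabilities."""
    mu = kappa * logit(np.clip(Q, CLIP_EPS, 1 - CLIP_EPS))
    return expit(mu + np.sqrt(sigma2) * rng.standard_normal(np.shape(Q)))


def posterior_predictive_hdi(
    fit: FitResult,
    n_draws: int = 20_000,
    prob: float = 0.95,
    seed: int = 0,
    n_participants: int | None = None,
) -> pd.DataFrame:
    """95% HDIs of the population-average normalized slider value per state.

    Each predictive draw simulates a fresh cohort from one retained
    posterior draw of the hyperparameters, pushes beliefs through the
    response channel, renormalizes per item, and averages across the
    cohort.  Returns a table with columns (domain_size, state_index,
    lower, upper, mean).
    """
    if n_draws < 100:
        raise ValueError("n_draws must be at least 100")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x4D1]))
    J = n_participants or len(fit.participants)
    kappa = fit.stacked("kappa")
    sig2 = fit.stacked("sigma2")
    N = kappa.size
    pick = rng.integers(0, N, size=n_draws)
    rows = []
    posterior = fit.model == "posterior"
    if posterior:
        fixed = fit.fixed
        mua = fit.stacked("mu_alpha")
        s2a = fit.stacked("sigma2_alpha")
    else:
        w = fit.stacked("w")
    for k in fit.ks:
        states = compatible_states(k) if posterior else np.arange(1 << k)
        m = state_sizes(k)[states]
        denom = np.array([comb(k, int(mm)) for mm in m])
        if posterior:
            mu_k = np.broadcast_to(np.asarray(fixed.mu[k]), (n_draws, k + 1))
            conc = fixed.w * mu_k
        else:
            mu_k = fit.stacked(f"mu_{k}")[pick]
            conc = w[pick][:, None] * mu_k
        # cohort beliefs: (n_draws, J, k+1)
        g = rng.standard_gamma(np.repeat(conc[:, None, :], J, axis=1))
        pj = g / g.sum(axis=-1, keepdims=True)
        Q = pj[..., m] / denom  # (n_draws, J, S) state-level beliefs
        if posterior:
            Q = Q / Q.sum(axis=-1, keepdims=True)
            a, b = mua[pick] ** 2 / s2a[pick], mua[pick] / s2a[pick]
            alpha = rng.standard_gamma(np.repeat(a[:, None], J, axis=1)) / b[:, None]
            T, foc = _bridge_operator(k)
            Q = _bridge_apply(Q, alpha, T, foc)
        raw = _simulate_item(rng, Q, kappa[pick][:, None, None], sig2[pick][:, None, None])
        norm = raw / raw.sum(axis=-1, keepdims=True)
        pop_avg = norm.mean(axis=1)  # (n_draws, S)
        for si, s in enumerate(states):
            lo, hi = mcmc.hdi_interval(pop_avg[:, si], prob)
            rows.append((k, int(s), lo, hi, float(pop_avg[:, si].mean())))
    return pd.DataFrame(
        rows, columns=["domain_size", "state_index", "lower", "upper", "mean"]
    )


@dataclass
class PPPReport:
    """Posterior predictive p-values per participant-item, with the pooled
    fraction of responses flagged at the 0.05 level."""

    table: pd.DataFrame
    fraction_below_05: float


def posterior_predictive_pvalues(
    fit: FitResult, data: pd.DataFrame, seed: int = 0
) -> PPPReport:
    """Two-sided posterior predictive p-value of every participant-item's
    exhaustive-state response (normalized), using each participant's own
    posterior draws; the two tails are doubled and capped at 1."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9A9]))
    df = data[data["probe"] == ("posterior" if fit.model == "posterior" else "prior")]
    pid_index = {pid: i for i, pid in enumerate(fit.participants)}
    kappa = fit.stacked("kappa")
    sig2 = fit.stacked("sigma2")
    alpha = fit.stacked("alpha") if fit.model == "posterior" else None
    rows = []
    for key, item in df.groupby(_ITEM_KEY, observed=True):
        pid, k = key[0], int(key[1])
        if pid not in pid_index or k not in fit.ks:
            continue
        j = pid_index[pid]
        item = item.sort_values("state_index")
        states = item["state_index"].to_numpy(dtype=int)
        exh_pos = np.flatnonzero(states == 1)
        if exh_pos.size == 0:
            warnings.warn(f"item {key} lacks an exhaustive-state response; skipped")
            continue
        raw = item[fit.value_col].to_numpy(dtype=float)
        obs = raw[exh_pos[0]] / raw.sum()
        pj = fit.stacked(f"p_{k}")[:, j]  # (N, k+1)
        m = state_sizes(k)[states]
        denom = np.array([comb(k, int(mm)) for mm in m])
        Q = pj[:, m] / denom
        Q = Q / Q.sum(axis=-1, keepdims=True) if fit.model == "posterior" else Q
        if fit.model == "posterior":
            T, foc = _bridge_operator(k)
            Q = _bridge_apply(Q, alpha[:, j], T, foc)
        rep_raw = _simulate_item(rng, Q, kappa[:, None], sig2[:, None])
        rep = rep_raw[:, exh_pos[0]] / rep_raw.sum(axis=1)
        lo_tail = float(np.mean(rep <= obs))
        hi_tail = float(np.mean(rep >= obs))
        pval = min(1.0, 2.0 * min(lo_tail, hi_tail))
        rows.append(key + (obs, pval))
    table = pd.DataFrame(rows, columns=_ITEM_KEY + ["observed_exh", "p_value"])
    frac = float((table["p_value"] < 0.05).mean()) if len(table) else float("nan")
    return PPPReport(table, frac)
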