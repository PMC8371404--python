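"""Simulation-based calibration utilities.

The central check is hyperparameter recovery: generate slider data at the
two experimental arms' sample sizes from known population parameters, fit
both hierarchical models, and ask whether the generating values fall inside
their 95% highest-density intervals.  Pooled over seeds and hyperparameter
components, a calibrated sampler should cover at roughly the nominal rate.
"""

from __future__ import annotations

import warnings
from math import comb

import numpy as np
import pandas as pd

from . import hier, simulate

__all__ = ["binomial_size_probs", "recovery_study", "RECOVERY_TRUTH"]


def binomial_size_probs(k: int, p: float) -> np.ndarray:
    """Binomial(k, p) distribution over target-set sizes 0..k."""
    v = np.array([comb(k, m) * p**m * (1 - p) ** (k - m) for m in range(k + 1)])
    return v / v.sum()


#: generating values for the recovery study; mu_k is binomial(k, 0.4)
RECOVERY_TRUTH = {
    "kappa": 1.0,
    "w": 20.0,
    "sigma2": 0.25,
    "mu_alpha": 3.0,
    "sigma2_alpha": 1.0,
    "mu_p": 0.4,
}


def _truth_hyperparams(ks=(2, 3, 4)):
    mu = {k: binomial_size_probs(k, RECOVERY_TRUTH["mu_p"]) for k in ks}
    prior = hier.PriorHyperParams(
        kappa=RECOVERY_TRUTH["kappa"],
        w=RECOVERY_TRUTH["w"],
        sigma2=RECOVERY_TRUTH["sigma2"],
        mu=mu,
    )
    post = hier.PosteriorHyperParams(
        mu_alpha=RECOVERY_TRUTH["mu_alpha"],
        sigma2_alpha=RECOVERY_TRUTH["sigma2_alpha"],
        kappa=RECOVERY_TRUTH["kappa"],
        sigma2=RECOVERY_TRUTH["sigma2"],
        w=RECOVERY_TRUTH["w"],
        mu=mu,
    )
    return prior, post


def recovery_study(
    n_seeds: int = 10,
    base_seed: int = 1,
    cfg: hier.McmcConfig | None = None,
    track=("kappa", "w", "mu", "mu_alpha"),
) -> pd.DataFrame:
    """Fit both models on fresh synthetic cohorts for ``n_seeds`` seeds.

    Each seed simulates a 30-participant prior arm and a 66-participant
    posterior arm at domain sizes {2, 3, 4}, fits the prior-probe model,
    fixes (w, mu_k) at its posterior means, fits the posterior-probe model,
    and records whether each tracked generating hyperparameter lies inside
    its 95% HDI.  Returns one row per (seed, parameter component).
    """
    gen_prior, gen_post = _truth_hyperparams()
    behavior = simulate.ResponseBehavior(fast_fraction=0.0, allzero_fraction=0.0)
    d_prior = simulate.experiment1_design("prior")
    d_post = simulate.experiment1_design("posterior")
    rows = []
    for i in range(n_seeds):
        seed = int((base_seed * 100_003 + 7919 * i) % 2**31)
        mc = cfg or hier.McmcConfig()
        mc_prior = hier.McmcConfig(**{**mc.__dict__, "seed": seed})
        mc_post = hier.McmcConfig(**{**mc.__dict__, "seed": seed + 1})
        data_prior = simulate.generate_dataset(d_prior, gen_prior, behavior, seed=seed)
        data_post = simulate.generate_dataset(d_post, gen_post, behavior, seed=seed + 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit_p = hier.fit_prior_model(data_prior, mc_prior)
            fit_q = hier.fit_posterior_model(data_post, fit_p.hyper_means(), mc_post)

        def record(fit, name, true, label):
            lo, hi = fit.hdi(name)
            rows.append(
                {
                    "seed": seed,
                    "parameter": label,
                    "true": float(true),
                    "posterior_mean": float(fit.mean(name)),
                    "hdi_lower": lo,
                    "hdi_upper": hi,
                    "inside": bool(lo <= true <= hi),
                    "converged": fit.converged,
                }
            )

        if "kappa" in track:
            record(fit_p, "kappa", gen_prior.kappa, "kappa")
        if "w" in track:
            record(fit_p, "w", gen_prior.w, "w")
        if "sigma2" in track:
            record(fit_p, "sigma2", gen_prior.sigma2, "sigma2")
        if "mu" in track:
            for k in fit_p.ks:
                bounds = fit_p.hdi(f"mu_{k}")
                means = fit_p.mean(f"mu_{k}")
                for c in range(k + 1):
                    rows.append(
                        {
                            "seed": seed,
                            "parameter": f"mu_{k}[{c}]",
                            "true": float(gen_prior.mu[k][c]),
                            "posterior_mean": float(means[c]),
                            "hdi_lower": float(bounds[c, 0]),
                            "hdi_upper": float(bounds[c, 1]),
                            "inside": bool(bounds[c, 0] <= gen_prior.mu[k][c] <= bounds[c, 1]),
                            "converged": fit_p.converged,
                        }
                    )
        if "mu_alpha" in track:
            record(fit_q, "mu_alpha", gen_post.mu_alpha, "mu_alpha")
    return pd.DataFrame(rows)
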