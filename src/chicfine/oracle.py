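"""Exact posterior by exhaustive enumeration for small windows.

For fixed sigma_beta the model is conditionally linear-Gaussian: beta can
be integrated out analytically for each of the 2^F inclusion
configurations, so the configuration posterior, per-fragment inclusion
probabilities and P(beta_q > 0 | Y) are available in closed form.  This is
the test bed against which the RJMCMC sampler is validated.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .model import (
    BaitWindow,
    DecayKernel,
    build_design,
    conditional_log_marginal,
    log_model_prior,
)

MAX_ENUMERATION_F = 20


@dataclass
class ExactPosterior:
    """Enumeration result at fixed sigma_beta."""

    configs: np.ndarray            # (2^F, F) binary
    log_weights: np.ndarray        # unnormalized log posterior per config
    probs: np.ndarray              # normalized posterior per config
    inclusion: np.ndarray          # (F,) P(gamma_q = 1 | Y)
    prob_positive: np.ndarray      # (F,) P(beta_q > 0 | Y)  (the exact MPPC)
    sigma_beta: float


def enumerate_posterior(
    window: BaitWindow, sigma_beta: float = 1.0, kernel: DecayKernel | None = None
) -> ExactPosterior:
    """Enumerate all 2^F configurations of a small window.

    P(beta_q > 0 | Y, gamma) is the Gaussian orthant probability of the
    conditional posterior of beta (mean A^{-1} X'Y, covariance A^{-1} with
    A = X'X + I/sigma^2), which for a single coordinate is a univariate
    normal tail; it is averaged over the configuration posterior.
    """
    F = window.F
    if F > MAX_ENUMERATION_F:
        raise ValueError(
            f"F={F} > {MAX_ENUMERATION_F}: enumeration infeasible, use the sampler"
        )
    X = build_design(window, kernel)
    configs = np.array(list(product((0, 1), repeat=F)), dtype=np.int8)
    log_w = np.empty(len(configs))
    pos_given_cfg = np.zeros((len(configs), F))
    for i, g in enumerate(configs):
        log_w[i] = (
            conditional_log_marginal(window, g, sigma_beta, X)
            + log_model_prior(int(g.sum()), F)
        )
        idx = np.flatnonzero(g)
        if len(idx):
            Xg = X[:, idx]
            A = Xg.T @ Xg + np.eye(len(idx)) / sigma_beta**2
            cov = np.linalg.inv(A)
            mean = cov @ (Xg.T @ window.Y)
            sd = np.sqrt(np.diag(cov))
            pos_given_cfg[i, idx] = stats.norm.sf(-mean / sd)  # P(beta_q > 0)
    probs = np.exp(log_w - logsumexp(log_w))
    probs /= probs.sum()
    inclusion = probs @ configs
    prob_positive = probs @ pos_given_cfg
    return ExactPosterior(configs, log_w, probs, inclusion, prob_positive, sigma_beta)
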