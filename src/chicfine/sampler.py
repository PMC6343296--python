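"""Reversible-jump MCMC over (gamma, beta, sigma_beta) for one bait window.

Two parallel chains are run per bait with no burn-in, retaining one sample
per ``thin`` iterations.  Convergence is declared when the Pearson
correlation between the chains' per-fragment MPPC exceeds 0.75; otherwise
both chains are extended by another block of retained samples until an
iteration cap.  Inference uses the union of samples from both chains.

``propose`` and ``mh_ratio`` implement one transition explicitly on
ModelState objects; ``run_chain`` drives the compiled kernel for long runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from ._kernels import run_chain_kernel
from .model import (
    SIGMA_BETA_BOUNDS,
    BaitWindow,
    DecayKernel,
    ModelState,
    build_design,
    log_beta_prior,
    log_likelihood,
    log_model_prior,
)

logger = logging.getLogger(__name__)

MOVE_NAMES = ("add", "delete", "update_beta", "update_sigma")
DEFAULT_MOVE_WEIGHTS = (0.3, 0.3, 0.3, 0.1)


@dataclass(frozen=True)
class ChainConfig:
    """Sampling protocol for one bait.

    Defaults follow the production protocol: 5000 retained samples per
    chain at a density of one per 1000 iterations, no burn-in, two chains
    extended in 5000-sample blocks while the inter-chain MPPC correlation
    is at most ``convergence_rho``, capped at 2e7 iterations per chain.
    A short adaptation phase (discarded, frozen before retained sampling)
    tunes the beta random-walk scale.
    """

    n_retained: int = 5000
    thin: int = 1000
    burn_in: int = 0  # the protocol retains from the first sample on
    max_total_iterations: int = 20_000_000
    seed: int = 0
    convergence_rho: float = 0.75
    omega: float = DecayKernel().omega
    move_weights: tuple[float, float, float, float] = DEFAULT_MOVE_WEIGHTS
    beta_scale: float = 0.5
    sigma_scale: float = 0.25
    adapt_iters: int = 10_000
    sigma_fixed: float | None = None  # clamp sigma_beta (oracle comparisons)
    sigma_beta_bounds: tuple[float, float] = SIGMA_BETA_BOUNDS

    def __post_init__(self):
        if self.burn_in != 0:
            raise ValueError("protocol uses no burn-in")
        if self.n_retained * self.thin > self.max_total_iterations:
            raise ValueError("n_retained * thin exceeds the iteration cap")


@dataclass
class Chain:
    """Retained samples of one chain plus acceptance accounting."""

    betas: np.ndarray  # (n_retained, F); zeros where excluded
    sigmas: np.ndarray
    accept_counts: np.ndarray
    propose_counts: np.ndarray
    iterations: int
    final_state: ModelState
    beta_scale: float

    @property
    def n_samples(self) -> int:
        return len(self.betas)

    @property
    def mppc(self) -> np.ndarray:
        return (self.betas > 0).mean(axis=0)

    @property
    def acceptance_rate(self) -> float:
        tot = self.propose_counts.sum()
        return float(self.accept_counts.sum() / tot) if tot else 0.0


def derive_seed(base_seed: int, bait_id: int, chain_index: int = 0, segment: int = 0) -> int:
    """Deterministic per-bait, per-chain, per-segment seed below 2^31."""
    ss = np.random.SeedSequence(
        entropy=int(base_seed), spawn_key=(int(bait_id), int(chain_index), int(segment))
    )
    return int(ss.generate_state(1)[0] % (2**31 - 1))


# ---------------------------------------------------------------------------
# Single-transition operations (explicit, used for validation and testing)

def _available_moves(state: ModelState, F: int, cfg: ChainConfig) -> np.ndarray:
    w = np.array(cfg.move_weights, dtype=float)
    k = state.k
    if k >= F:
        w[0] = 0.0
    if k == 0:
        w[1] = w[2] = 0.0
    if cfg.sigma_fixed is not None:
        w[3] = 0.0
    return w / w.sum()


def propose(
    state: ModelState, window: BaitWindow, rng: np.random.Generator,
    cfg: ChainConfig | None = None,
) -> tuple[ModelState, float, str]:
    """Draw one proposal; return (proposed state, log g(old|new) - log g(new|old), move).

    The returned log proposal ratio includes the beta proposal densities,
    so `mh_ratio` can apply the full prior terms without cancellation
    book-keeping (the cancellation then happens numerically).
    """
    if cfg is None:
        cfg = ChainConfig()
    F = window.F
    probs = _available_moves(state, F, cfg)
    move = MOVE_NAMES[rng.choice(4, p=probs)]
    new = state.copy()
    if move == "add":
        excluded = np.flatnonzero(state.gamma == 0)
        q = rng.choice(excluded)
        b = rng.normal(0.0, state.sigma_beta)
        new.gamma[q] = 1
        new.beta[q] = b
        probs_new = _available_moves(new, F, cfg)
        log_fwd = np.log(probs[0] / len(excluded)) + stats.norm.logpdf(
            b, 0, state.sigma_beta
        )
        log_rev = np.log(probs_new[1] / new.k)
    elif move == "delete":
        included = np.flatnonzero(state.gamma == 1)
        q = rng.choice(included)
        b = state.beta[q]
        new.gamma[q] = 0
        new.beta[q] = 0.0
        probs_new = _available_moves(new, F, cfg)
        log_fwd = np.log(probs[1] / len(included))
        log_rev = np.log(probs_new[0] / (F - new.k)) + stats.norm.logpdf(
            b, 0, state.sigma_beta
        )
    elif move == "update_beta":
        included = np.flatnonzero(state.gamma == 1)
        q = rng.choice(included)
        new.beta[q] = state.beta[q] + rng.normal(0.0, cfg.beta_scale)
        log_fwd = log_rev = 0.0  # symmetric walk, same move prob both ways
    else:
        lo, hi = cfg.sigma_beta_bounds
        s = state.sigma_beta + rng.normal(0.0, cfg.sigma_scale)
        while s < lo or s > hi:
            s = 2 * lo - s if s < lo else 2 * hi - s
        new.sigma_beta = s
        log_fwd = log_rev = 0.0  # reflection keeps the walk symmetric
    return new, log_rev - log_fwd, move


def mh_ratio(
    window: BaitWindow,
    current: ModelState,
    proposed: ModelState,
    log_proposal_ratio: float,
    X: np.ndarray | None = None,
) -> float:
    """Reversible-jump Metropolis-Hastings ratio (likelihood x priors x g-ratio).

    Acceptance probability is min(1, MHR); a non-finite ratio maps to 0 so
    the proposal is rejected.
    """
    if X is None:
        X = build_design(window)
    log_mhr = (
        log_likelihood(window, proposed, X)
        - log_likelihood(window, current, X)
        + log_beta_prior(proposed)
        - log_beta_prior(current)
        + log_model_prior(proposed.k, window.F)
        - log_model_prior(current.k, window.F)
        + log_proposal_ratio
    )
    if not np.isfinite(log_mhr):
        logger.warning("non-finite MH ratio; proposal rejected")
        return 0.0
    return float(np.exp(min(log_mhr, 0.0)))


def step(
    state: ModelState, window: BaitWindow, rng: np.random.Generator,
    cfg: ChainConfig, X: np.ndarray | None = None,
) -> ModelState:
    """One explicit MH transition (reference path; the kernel is the fast path)."""
    proposed, lpr, _ = propose(state, window, rng, cfg)
    if rng.uniform() < mh_ratio(window, state, proposed, lpr, X):
        return proposed
    return state


# ---------------------------------------------------------------------------
# Long-run driver

def _log_prior_by_size(F: int) -> np.ndarray:
    return np.array([log_model_prior(k, F) for k in range(F + 1)])


def run_chain(
    window: BaitWindow,
    config: ChainConfig,
    initial: ModelState | None = None,
    adapt: bool = True,
) -> Chain:
    """Run (or extend) one chain, returning retained samples.

    Starts from the empty model with sigma_beta = 1 (the hyper-prior
    median) unless ``initial`` is given.  Identical seeds give bit-identical
    chains.
    """
    if window.F < 1:
        raise ValueError("window must contain at least one prey")
    X = build_design(window, DecayKernel(config.omega))
    F = window.F
    state = initial.copy() if initial is not None else ModelState(
        np.zeros(F, np.int8), np.zeros(F),
        1.0 if config.sigma_fixed is None else config.sigma_fixed,
    )
    sigma_arr = np.array([state.sigma_beta])
    beta_scale_arr = np.array([config.beta_scale])
    out_beta = np.zeros((config.n_retained, F))
    out_sigma = np.zeros(config.n_retained)
    accept = np.zeros(4, np.int64)
    proposed = np.zeros(4, np.int64)
    lo, hi = config.sigma_beta_bounds
    adapt_iters = config.adapt_iters if adapt else 0
    run_chain_kernel(
        X, window.Y, state.beta, state.gamma, sigma_arr,
        _log_prior_by_size(F),
        config.n_retained, config.thin, adapt_iters,
        np.array(config.move_weights, float),
        beta_scale_arr, config.sigma_scale, lo, hi,
        config.sigma_fixed is not None,
        int(config.seed),
        out_beta, out_sigma, accept, proposed,
    )
    state.sigma_beta = float(sigma_arr[0])
    iters = adapt_iters + config.n_retained * config.thin
    chain = Chain(out_beta, out_sigma, accept, proposed, iters, state,
                  float(beta_scale_arr[0]))
    rate = chain.acceptance_rate
    if not 0.05 < rate < 0.95:
        logger.info("overall acceptance rate %.3f outside (0.05, 0.95)", rate)
    return chain


def _extend(chain: Chain, window: BaitWindow, config: ChainConfig) -> Chain:
    cfg = replace(config, beta_scale=chain.beta_scale)
    more = run_chain(window, cfg, initial=chain.final_state, adapt=False)
    return Chain(
        np.vstack([chain.betas, more.betas]),
        np.concatenate([chain.sigmas, more.sigmas]),
        chain.accept_counts + more.accept_counts,
        chain.propose_counts + more.propose_counts,
        chain.iterations + more.iterations,
        more.final_state,
        more.beta_scale,
    )


@dataclass
class ConvergenceRecord:
    bait_id: int
    rho: float
    iterations: int
    converged: bool
    n_samples: int


def run_until_converged(
    window: BaitWindow, config: ChainConfig
) -> tuple[Chain, Chain, float, bool]:
    """Two-chain protocol with extension until the MPPC correlation passes.

    Chains use distinct deterministic seeds derived from ``config.seed``.
    Never raises on non-convergence at the iteration cap; the flag reports
    it.  For a single-prey window the correlation is undefined and the
    criterion falls back to |delta MPPC| < 0.05.
    """
    seeds = [derive_seed(config.seed, window.bait_id, c, 0) for c in (0, 1)]
    chains = [run_chain(window, replace(config, seed=s)) for s in seeds]
    segment = 1
    while True:
        rho, ok = _chain_agreement(chains[0], chains[1], config.convergence_rho)
        if ok:
            return chains[0], chains[1], rho, True
        per_chain_next = chains[0].iterations + config.n_retained * config.thin
        if per_chain_next > config.max_total_iterations:
            logger.info("bait %s: iteration cap reached (rho=%.3f)", window.bait_id, rho)
            return chains[0], chains[1], rho, False
        new_seeds = [derive_seed(config.seed, window.bait_id, c, segment) for c in (0, 1)]
        chains = [
            _extend(ch, window, replace(config, seed=s))
            for ch, s in zip(chains, new_seeds)
        ]
        segment += 1


def _chain_agreement(a: Chain, b: Chain, rho_threshold: float) -> tuple[float, bool]:
    ma, mb = a.mppc, b.mppc
    if len(ma) == 1:
        diff = abs(float(ma[0] - mb[0]))
        return 1.0 - diff, diff < 0.05
    sa, sb = ma.std(), mb.std()
    if sa == 0 or sb == 0:
        # no variation in at least one MPPC vector (e.g. all-zero: both
        # chains agree the window is empty) — treat exact match as converged
        same = bool(np.allclose(ma, mb, atol=0.05))
        return (1.0 if same else 0.0), same
    rho = float(np.corrcoef(ma, mb)[0, 1])
    return rho, rho > rho_threshold
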