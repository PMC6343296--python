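"""Joint spatial model for NB residuals around a bait.

The residual Y_bp at prey p is N(mu_bp, 1), where mu_bp sums exponentially
decaying contributions beta_bq * exp(-omega * d(p, q)) from the sparse set
of fragments q in direct contact with the bait (inclusion indicators
gamma).  Priors: beta | gamma=1 ~ N(0, sigma_beta^2) with
sigma_beta ~ Uniform(0.01, 2); theta_b ~ Beta(1, F_b) with gamma i.i.d.
Bernoulli(theta_b), which marginalizes to a Beta-Bernoulli model prior with
P(empty model) = 1/2 for every window size — an intrinsic multiplicity
correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betaln

DEFAULT_OMEGA = 10.0 ** -4.7  # per-bp decay rate of a contact's spillover
DEFAULT_WINDOW_BP = 5_000_000  # preys considered up to 5 Mb either side
SIGMA_BETA_BOUNDS = (0.01, 2.0)

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class DecayKernel:
    """Exponential spillover kernel exp(-omega * d)."""

    omega: float = DEFAULT_OMEGA

    def __post_init__(self):
        if self.omega <= 0:
            raise ValueError("omega must be > 0")

    def __call__(self, d):
        return decay(d, self)


def decay(d, kernel: DecayKernel | None = None) -> np.ndarray | float:
    """Unit-strength contribution at midpoint distance d (bp): exp(-omega*d)."""
    if kernel is None:
        kernel = DecayKernel()
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    out = np.exp(-kernel.omega * d)
    return float(out) if out.ndim == 0 else out


@dataclass
class BaitWindow:
    """One bait's prey fragments (with observed counts) inside the window.

    Preys are ordered by genomic position; Y holds their NB residuals and
    midpoints their coordinates.  Only recorded (nonzero-count) pairs have
    residuals, so F_b is the number of observed preys, not of all fragments.
    """

    bait_id: int
    prey_ids: np.ndarray
    Y: np.ndarray
    midpoints: np.ndarray
    bait_midpoint: int = 0
    counts: np.ndarray | None = None

    def __post_init__(self):
        order = np.argsort(self.midpoints, kind="stable")
        self.prey_ids = np.asarray(self.prey_ids)[order]
        self.Y = np.asarray(self.Y, dtype=float)[order]
        self.midpoints = np.asarray(self.midpoints, dtype=float)[order]
        if self.counts is not None:
            self.counts = np.asarray(self.counts)[order]
        if not np.all(np.isfinite(self.Y)):
            raise ValueError("residuals must be finite")

    @property
    def F(self) -> int:
        return len(self.Y)


@dataclass
class ModelState:
    """One RJMCMC sample: inclusions gamma, strengths beta, hyper sigma_beta."""

    gamma: np.ndarray
    beta: np.ndarray
    sigma_beta: float = 1.0

    def __post_init__(self):
        self.gamma = np.asarray(self.gamma, dtype=np.int8)
        self.beta = np.asarray(self.beta, dtype=float)
        if np.any((self.gamma == 0) & (self.beta != 0)):
            raise ValueError("beta must be 0 where gamma is 0")

    @property
    def k(self) -> int:
        return int(self.gamma.sum())

    def copy(self) -> "ModelState":
        return ModelState(self.gamma.copy(), self.beta.copy(), self.sigma_beta)


def build_design(window: BaitWindow, kernel: DecayKernel | None = None) -> np.ndarray:
    """F x F decay design: X[p, q] = exp(-omega |m_p - m_q|).

    Symmetric with unit diagonal; mu = X @ (gamma * beta).  Duplicate
    midpoints make columns identical (flagged by the caller via
    ``has_duplicate_midpoints``).
    """
    if kernel is None:
        kernel = DecayKernel()
    m = window.midpoints
    return np.exp(-kernel.omega * np.abs(m[:, None] - m[None, :]))


def has_duplicate_midpoints(window: BaitWindow) -> bool:
    return len(np.unique(window.midpoints)) < window.F


def expected_residuals(X: np.ndarray, state: ModelState) -> np.ndarray:
    return X @ (state.gamma * state.beta)


def log_likelihood(window: BaitWindow, state: ModelState,
                   X: np.ndarray | None = None) -> float:
    """Gaussian log-likelihood sum_p log phi(Y_p - mu_p) with unit variance."""
    if X is None:
        X = build_design(window)
    r = window.Y - expected_residuals(X, state)
    return float(-0.5 * len(r) * _LOG_2PI - 0.5 * np.dot(r, r))


def log_model_prior(gamma: np.ndarray | int, F: int | None = None) -> float:
    """Log prior of one configuration under the Beta(1, F)-Bernoulli model.

    Marginalizing theta ~ Beta(1, F) over i.i.d. Bernoulli(theta) inclusions
    gives P(gamma) = B(1 + k, 2F - k) / B(1, F), depending on gamma only
    through k = sum(gamma).  k = 0 yields exactly 1/2 for every F.
    """
    if F is None:
        gamma = np.asarray(gamma)
        k, F = int(gamma.sum()), len(gamma)
    else:
        k = int(gamma)
    if not 0 <= k <= F:
        raise ValueError("k must lie in [0, F]")
    return float(betaln(1 + k, 2 * F - k) - betaln(1, F))


def log_beta_prior(state: ModelState) -> float:
    """Log density of included strengths under N(0, sigma_beta^2)."""
    b = state.beta[state.gamma == 1]
    s = state.sigma_beta
    return float(-0.5 * len(b) * (_LOG_2PI + 2 * np.log(s)) - 0.5 * np.dot(b, b) / s**2)


def conditional_log_marginal(
    window: BaitWindow,
    gamma: np.ndarray,
    sigma_beta: float,
    X: np.ndarray | None = None,
) -> float:
    """Closed-form evidence log P(Y | gamma, sigma_beta), beta integrated out.

    With beta_gamma ~ N(0, sigma^2 I) and Y ~ N(X_gamma beta_gamma, I), Y is
    marginally N(0, I + sigma^2 X_gamma X_gamma^T); the determinant and the
    quadratic form are evaluated through the k x k information matrix
    (Woodbury), so the cost is O(F k^2).
    """
    if X is None:
        X = build_design(window)
    gamma = np.asarray(gamma).astype(bool)
    Y = window.Y
    F = len(Y)
    k = int(gamma.sum())
    if k == 0:
        return float(-0.5 * F * _LOG_2PI - 0.5 * np.dot(Y, Y))
    Xg = X[:, gamma]
    A = Xg.T @ Xg + np.eye(k) / sigma_beta**2  # posterior precision of beta
    sign, logdet_A = np.linalg.slogdet(A)
    if sign <= 0:
        raise np.linalg.LinAlgError("singular information matrix (duplicate midpoints?)")
    XtY = Xg.T @ Y
    m = np.linalg.solve(A, XtY)
    quad = np.dot(Y, Y) - np.dot(XtY, m)
    logdet_Sigma = logdet_A + 2 * k * np.log(sigma_beta)
    return float(-0.5 * F * _LOG_2PI - 0.5 * logdet_Sigma - 0.5 * quad)


def sample_model_prior(F: int, rng: np.random.Generator) -> np.ndarray:
    """Ancestral draw of gamma: theta ~ Beta(1, F), gamma_q ~ Bernoulli(theta)."""
    theta = rng.beta(1, F)
    return (rng.uniform(size=F) < theta).astype(np.int8)


@dataclass(frozen=True)
class SpatialPrior:
    """Bundle of prior hyper-parameters for one window."""

    F: int
    sigma_beta_bounds: tuple[float, float] = SIGMA_BETA_BOUNDS

    @property
    def marginal_inclusion_probability(self) -> float:
        # E[theta] under Beta(1, F): prior odds of inclusion are 1/F
        return 1.0 / (self.F + 1)


def build_windows(
    residuals: "pd.DataFrame",
    fragment_map: "pd.DataFrame",
    window_bp: int = DEFAULT_WINDOW_BP,
) -> list[BaitWindow]:
    """Group a residual table into per-bait windows (cis, within window_bp)."""
    import pandas as pd  # noqa: F401  (annotation convenience)

    windows = []
    cis = residuals[~residuals.get("trans", False)] if "trans" in residuals else residuals
    for bait_id, sub in cis.groupby("bait_id", sort=True):
        bait_mid = int(fragment_map.loc[bait_id, "midpoint"])
        prey_mid = fragment_map.loc[sub["prey_id"], "midpoint"].to_numpy()
        same = fragment_map.loc[sub["prey_id"], "chrom"].to_numpy() == fragment_map.loc[
            bait_id, "chrom"
        ]
        keep = same & (np.abs(prey_mid - bait_mid) <= window_bp)
        if not keep.any():
            continue
        windows.append(
            BaitWindow(
                bait_id=int(bait_id),
                prey_ids=sub["prey_id"].to_numpy()[keep],
                Y=sub["residual"].to_numpy(float)[keep],
                midpoints=prey_mid[keep],
                bait_midpoint=bait_mid,
                counts=sub["N"].to_numpy()[keep] if "N" in sub else None,
            )
        )
    return windows
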