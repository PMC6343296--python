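"""Posterior summaries: MPPC, stretch analysis and reproducibility ROC.

The MPPC of a prey is the proportion of retained samples (union of both
chains) in which its contact strength beta is strictly positive — not the
usual inclusion probability, because contacts are expected to raise, not
lower, counts.  beta_post is the posterior mean of beta with zeros from
excluded samples included.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .model import BaitWindow
from .sampler import Chain

logger = logging.getLogger(__name__)


@dataclass
class PosteriorSummary:
    """Per-prey MPPC/posterior-beta plus per-bait diagnostics."""

    bait_id: int
    prey_ids: np.ndarray
    mppc: np.ndarray
    beta_post: np.ndarray
    expected_contacts: float  # sum of MPPC = E[# preys with beta > 0]
    rho: float | None = None
    converged: bool | None = None
    n_samples: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bait": self.bait_id,
                "prey": self.prey_ids,
                "mppc": self.mppc,
                "beta.post": self.beta_post,
            }
        )


def summarize(
    chains: Chain | list[Chain],
    window: BaitWindow,
    rho: float | None = None,
    converged: bool | None = None,
) -> PosteriorSummary:
    """Pool retained samples across chains and summarize per prey."""
    if isinstance(chains, Chain):
        chains = [chains]
    if not chains or any(c.n_samples == 0 for c in chains):
        raise ValueError("no retained samples to summarize")
    betas = np.vstack([c.betas for c in chains])
    mppc = (betas > 0).mean(axis=0)
    beta_post = betas.mean(axis=0)
    return PosteriorSummary(
        bait_id=window.bait_id,
        prey_ids=window.prey_ids,
        mppc=mppc,
        beta_post=beta_post,
        expected_contacts=float(mppc.sum()),
        rho=rho,
        converged=converged,
        n_samples=len(betas),
    )


@dataclass
class Stretch:
    """A maximal run of adjacent fragments whose score exceeds a threshold."""

    bait_id: int
    start_index: int
    indices: np.ndarray
    length: int
    summed_mppc: float = np.nan


def find_stretches(
    scores: np.ndarray,
    threshold: float = 5.0,
    mppc: np.ndarray | None = None,
    bait_id: int = -1,
) -> list[Stretch]:
    """Maximal runs of consecutive fragments with score strictly above threshold.

    ``scores`` must be in genomic order; adjacency means consecutive
    entries of the window.  Any per-fragment score works (the canonical
    use is CHiCAGO scores with threshold 5).
    """
    scores = np.asarray(scores, float)
    above = scores > threshold
    stretches: list[Stretch] = []
    i = 0
    n = len(scores)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            idx = np.arange(i, j + 1)
            s = Stretch(bait_id, i, idx, j - i + 1)
            if mppc is not None:
                s.summed_mppc = float(np.asarray(mppc)[idx].sum())
            stretches.append(s)
            i = j + 1
        else:
            i += 1
    return stretches


def posterior_concentration(
    stretch: Stretch, mppc: np.ndarray
) -> tuple[np.ndarray, np.ndarray] | None:
    """Cumulative MPPC share captured by the top-k fragments of a stretch.

    Fragments are ranked by decreasing MPPC; returns (fraction of
    fragments, fraction of the stretch's summed MPPC) at k = 1..n.  The
    curve is nondecreasing and concave.  Returns None (with a log entry)
    when the stretch carries no posterior mass.
    """
    m = np.asarray(mppc, float)[stretch.indices]
    total = m.sum()
    if total <= 0:
        logger.info("stretch at %d has zero summed MPPC; skipped", stretch.start_index)
        return None
    ranked = np.sort(m)[::-1]
    frac_frag = np.arange(1, len(m) + 1) / len(m)
    frac_mppc = np.cumsum(ranked) / total
    return frac_frag, frac_mppc


def reproducibility_roc(
    reference_mppc: pd.Series,
    test_mppc: pd.Series,
    alpha: float = 0.01,
    negative_cutoff: float = 0.01,
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC of test MPPC against calls labelled from a reference dataset.

    Reference pairs with MPPC <= ``negative_cutoff`` are negatives and
    MPPC > ``alpha`` positives; pairs in between belong to neither class
    and are excluded.  Both series must be indexed by matching bait-prey
    keys.  Returns (fpr, tpr, auc) from a threshold sweep with trapezoid
    AUC.
    """
    common = reference_mppc.index.intersection(test_mppc.index)
    ref = reference_mppc.loc[common]
    test = test_mppc.loc[common]
    labels = pd.Series(np.nan, index=common)
    labels[ref <= negative_cutoff] = 0
    labels[ref > alpha] = 1
    keep = labels.notna()
    y = labels[keep].to_numpy(int)
    s = test[keep].to_numpy(float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("reference labelling yields no positives or no negatives")
    fpr, tpr, _ = _roc_curve(y, s)
    return fpr, tpr, float(_trapezoid_auc(fpr, tpr))
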