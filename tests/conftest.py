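import logging
import warnings

import numpy as np
import pandas as pd
import pytest

from chicfine.adjust import NegativeBinomialAdjuster
from chicfine.fine_map import ContactFineMapper
from chicfine.io import annotate_counts
from chicfine.model import BaitWindow, DecayKernel
from chicfine.synthetic import SimConfig, simulate_counts, simulate_fragment_map

# statsmodels truncated fits on small bins emit benign optimizer chatter
warnings.filterwarnings("ignore", module="statsmodels")
logging.getLogger("chicfine").setLevel(logging.ERROR)


@pytest.fixture
def tiny_fragment_map():
    """Six fragments on two chromosomes, fixed coordinates."""
    df = pd.DataFrame(
        {
            "fragment_id": [1, 2, 3, 4, 5, 6],
            "chrom": ["chr1", "chr1", "chr1", "chr1", "chr2", "chr2"],
            "start": [0, 4000, 8200, 12200, 0, 3800],
            "end": [4000, 8200, 12200, 16600, 3800, 9000],
        }
    )
    df["midpoint"] = (df["start"] + df["end"]) // 2
    return df.set_index("fragment_id")


def random_window(F: int, rng: np.random.Generator, planted: int = 0,
                  beta_range=(1.0, 4.0), span: int = 500_000) -> BaitWindow:
    """Synthetic residual window drawn from the joint model itself."""
    mids = np.sort(rng.choice(span, F, replace=False))
    X = np.exp(-DecayKernel().omega * np.abs(mids[:, None] - mids[None, :]))
    beta = np.zeros(F)
    if planted:
        beta[rng.choice(F, planted, replace=False)] = rng.uniform(*beta_range, planted)
    Y = X @ beta + rng.standard_normal(F)
    return BaitWindow(0, np.arange(F), Y, mids)


@pytest.fixture(scope="session")
def study_dataset():
    """The 50-bait study conditions: simulate, adjust, fine-map once.

    Shared across recovery/convergence checks; ~1.5 min of compute.
    """
    cfg = SimConfig(seed=11)
    fragments = simulate_fragment_map(cfg)
    counts, truth = simulate_counts(cfg, fragments)
    annotated = annotate_counts(counts, fragments)
    residuals = NegativeBinomialAdjuster(random_state=11).fit_transform(annotated)
    mapper = ContactFineMapper(n_retained=2500, thin=400, random_state=11)
    mapper.fit(residuals, fragment_map=fragments)
    results = mapper.results_.merge(
        truth.rename(columns={"bait_id": "bait", "prey_id": "prey"}),
        on=["bait", "prey"], how="left",
    )
    return {
        "config": cfg,
        "fragments": fragments,
        "truth": truth,
        "residuals": residuals,
        "mapper": mapper,
        "results": results,
    }
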