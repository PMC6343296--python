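"""Reading and writing fragment maps, sparse count tables and result tables.

The on-disk formats are plain CSV/TSV (separator sniffed from the header
line).  Coordinates are 0-based half-open internally; exports that demand
1-based coordinates convert at the boundary.
"""

from __future__ import annotations

import logging
import os

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FRAGMENT_COLUMNS = ["fragment_id", "chrom", "start", "end"]
COUNT_COLUMNS = ["bait_id", "prey_id", "N"]
RESULT_COLUMNS = ["bait", "prey", "N", "residual", "mppc", "beta.post"]


class FormatError(ValueError):
    """Input file does not have the expected columns or separator."""


class IntegrityError(ValueError):
    """Input violates a structural invariant (overlap, duplicate, range)."""


def _sniff_sep(path: str | os.PathLike) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def read_fragment_map(path: str | os.PathLike) -> pd.DataFrame:
    """Read a restriction-fragment coordinate table.

    Expects columns (fragment_id, chrom, start, end); order and extra
    columns are tolerated.  Returns a DataFrame indexed by ``fragment_id``
    with an added ``midpoint`` column, ``floor((start + end) / 2)``.

    Raises
    ------
    FormatError
        if a required column is missing.
    IntegrityError
        for duplicate IDs, zero/negative-length fragments, or overlapping
        fragments on one chromosome.
    """
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep)
    if df.empty:
        logger.warning("fragment map %s is empty", path)
        df = pd.DataFrame(columns=FRAGMENT_COLUMNS)
    missing = [c for c in FRAGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"fragment map missing columns: {missing}")
    df = df[FRAGMENT_COLUMNS].copy()
    if df["fragment_id"].duplicated().any():
        dupes = df.loc[df["fragment_id"].duplicated(), "fragment_id"].tolist()
        raise IntegrityError(f"duplicate fragment IDs: {dupes[:5]}")
    if (df["end"] <= df["start"]).any():
        bad = df.loc[df["end"] <= df["start"], "fragment_id"].tolist()
        raise IntegrityError(f"zero/negative-length fragments: {bad[:5]}")
    for chrom, sub in df.groupby("chrom", sort=False):
        s = sub.sort_values("start")
        if (s["start"].values[1:] < s["end"].values[:-1]).any():
            raise IntegrityError(f"overlapping fragments on {chrom}")
    df["midpoint"] = (df["start"] + df["end"]) // 2
    return df.set_index("fragment_id")


def write_fragment_map(fragments: pd.DataFrame, path: str | os.PathLike) -> None:
    out = fragments.reset_index()[FRAGMENT_COLUMNS]
    out.to_csv(path, index=False)


def read_counts(path: str | os.PathLike, fragment_map: pd.DataFrame) -> pd.DataFrame:
    """Read a sparse bait-prey count table and annotate it with coordinates.

    Only observed pairs are stored, so every count must be >= 1.  Each
    record gains bait/prey chromosome, midpoint and length columns, a
    ``trans`` flag, and the midpoint distance ``d`` (NaN for
    transchromosomal pairs, which are retained — they feed the bait-activity
    covariate).
    """
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"count table missing columns: {missing}")
    df = df[COUNT_COLUMNS].copy()
    if (df["N"] <= 0).any():
        raise ValueError("count table contains N <= 0; only observed pairs are stored")
    return annotate_counts(df, fragment_map)


def annotate_counts(counts: pd.DataFrame, fragment_map: pd.DataFrame) -> pd.DataFrame:
    """Attach distance and fragment covariates to raw (bait, prey, N) triples."""
    for role in ("bait", "prey"):
        ids = counts[f"{role}_id"]
        unknown = ids[~ids.isin(fragment_map.index)]
        if len(unknown):
            raise KeyError(f"unknown {role} fragment ID(s): {sorted(set(unknown))[:5]}")
    df = counts.copy()
    for role in ("bait", "prey"):
        frag = fragment_map.loc[df[f"{role}_id"]]
        df[f"{role}_chrom"] = frag["chrom"].values
        df[f"{role}_mid"] = frag["midpoint"].values
        df[f"{role}_len"] = (frag["end"] - frag["start"]).values
    df["trans"] = df["bait_chrom"] != df["prey_chrom"]
    d = np.abs(df["bait_mid"] - df["prey_mid"]).astype(float)
    d[df["trans"]] = np.nan
    df["d"] = d
    return df


def write_counts(counts: pd.DataFrame, path: str | os.PathLike) -> None:
    counts[COUNT_COLUMNS].to_csv(path, index=False)


def read_results(path: str | os.PathLike) -> pd.DataFrame:
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"result table missing columns: {missing}")
    return df[RESULT_COLUMNS]


def write_results(results: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write per-pair results (bait, prey, N, residual, mppc, beta.post).

    Raises IntegrityError if any MPPC falls outside [0, 1].
    """
    missing = [c for c in RESULT_COLUMNS if c not in results.columns]
    if missing:
        raise FormatError(f"result table missing columns: {missing}")
    mppc = results["mppc"].to_numpy(float)
    if ((mppc < 0) | (mppc > 1)).any():
        raise IntegrityError("mppc outside [0, 1]")
    results[RESULT_COLUMNS].to_csv(path, index=False)


def export_bedpe(
    results: pd.DataFrame,
    fragment_map: pd.DataFrame,
    path: str | os.PathLike,
    mppc_cutoff: float = 0.5,
) -> int:
    """Export contacts with MPPC above a cutoff as BEDPE (0-based half-open).

    Columns: chrom1 start1 end1 chrom2 start2 end2 name score, with the
    bait as the first interval and MPPC as the score.  Returns the number
    of lines written.
    """
    sel = results[results["mppc"] > mppc_cutoff]
    with open(path, "w") as fh:
        for row in sel.itertuples(index=False):
            b = fragment_map.loc[row.bait]
            p = fragment_map.loc[row.prey]
            name = f"{row.bait}_{row.prey}"
            score = getattr(row, "mppc")
            fh.write(
                f"{b['chrom']}\t{b['start']}\t{b['end']}\t"
                f"{p['chrom']}\t{p['start']}\t{p['end']}\t{name}\t{score:.6g}\n"
            )
    return len(sel)
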