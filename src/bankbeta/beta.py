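"""Pairwise Sorensen dissimilarity and its turnover/nestedness partition.

For two assemblages with a shared species, b species unique to the first and
c unique to the second:

    beta_sor = (b + c) / (2a + b + c)                 total dissimilarity
    beta_sim = min(b, c) / (a + min(b, c))            turnover (replacement)
    beta_sne = beta_sor - beta_sim                    nestedness-resultant

beta_sim is insensitive to richness difference; beta_sne captures the part of
beta_sor caused by one assemblage being a (partial) subset of the other.
The partition identity beta_sor = beta_sim + beta_sne holds exactly.

Degenerate pairs: both assemblages empty -> all three undefined (NaN, flagged
``undefined``); exactly one empty -> beta_sor = 1 with a ``degenerate`` flag
so such pairs can be excluded by configuration, mirroring how near-empty
banks are usually handled by manual exclusion rather than a hard rule.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .community import CommunityMatrix

PAIR_KEY = ["catchment", "site_code", "position", "visit"]


class SorensenResult(NamedTuple):
    a: int
    b: int
    c: int
    beta_sor: float  # NaN when both sets are empty


def sorensen_pair(x: Iterable, y: Iterable) -> SorensenResult:
    """Shared/unique species counts and Sorensen dissimilarity of two sets."""
    x, y = set(x), set(y)
    a = len(x & y)
    b = len(x - y)
    c = len(y - x)
    denom = 2 * a + b + c
    beta = (b + c) / denom if denom else float("nan")
    return SorensenResult(a, b, c, beta)


def baselga_partition(a: int, b: int, c: int) -> tuple[float, float]:
    """Split Sorensen dissimilarity into (beta_sim, beta_sne).

    Undefined (NaN, NaN) when a = b = c = 0.
    """
    if min(a, b, c) < 0:
        raise ValueError("a, b, c must be non-negative")
    if a + b + c == 0:
        return float("nan"), float("nan")
    m = min(b, c)
    beta_sim = m / (a + m) if (a + m) else 0.0
    beta_sor = (b + c) / (2 * a + b + c)
    return beta_sim, beta_sor - beta_sim


def beta_components(
    a: np.ndarray, b: np.ndarray, c: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized (beta_sor, beta_sim, beta_sne) from integer count arrays.

    Entries where a + b + c = 0 are NaN in all three outputs. Used on the
    hot path of the null model, where the same pair geometry is evaluated
    for hundreds of randomized matrices.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    m = np.minimum(b, c)
    with np.errstate(divide="ignore", invalid="ignore"):
        sor = np.where(2 * a + b + c > 0, (b + c) / (2 * a + b + c), np.nan)
        sim = np.where(a + m > 0, m / (a + m), 0.0)
    sim = np.where(np.isnan(sor), np.nan, sim)
    # one-empty pairs: all dissimilarity is treated as total, none as turnover
    sne = sor - sim
    return sor, sim, sne


def pair_indices(matrix: CommunityMatrix) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Row indices of the left and right bank sample of every complete pair.

    Returns ``(left_idx, right_idx, keys)`` where ``keys`` carries one row of
    PAIR_KEY columns per complete pair plus the sample ids. Site-visits with
    a missing partner are reported via ``keys.attrs['missing']`` (and logged),
    never silently dropped; duplicate bank samples are an error.
    """
    meta = matrix.metadata.reset_index()
    rows: list[dict] = []
    missing: list[tuple] = []
    pos = {sid: i for i, sid in enumerate(matrix.samples)}
    for key, grp in meta.groupby(PAIR_KEY, sort=True):
        banks = grp.groupby("bank")["sample_id"].agg(list).to_dict()
        for bank, ids in banks.items():
            if len(ids) > 1:
                raise ValueError(f"duplicate {bank}-bank sample for {key}: {ids}")
        if set(banks) != {"left", "right"}:
            missing.append(key)
            continue
        rows.append(
            dict(zip(PAIR_KEY, key))
            | {"left_id": banks["left"][0], "right_id": banks["right"][0]}
        )
    keys = pd.DataFrame(rows, columns=PAIR_KEY + ["left_id", "right_id"])
    keys.attrs["missing"] = missing
    left = np.array([pos[s] for s in keys["left_id"]], dtype=np.intp)
    right = np.array([pos[s] for s in keys["right_id"]], dtype=np.intp)
    return left, right, keys


def pair_counts(
    occ: np.ndarray, left_idx: np.ndarray, right_idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(a, b, c) arrays for the given pair geometry on a boolean matrix."""
    L = occ[left_idx]
    R = occ[right_idx]
    a = (L & R).sum(axis=1)
    b = L.sum(axis=1) - a
    c = R.sum(axis=1) - a
    return a, b, c


def cross_channel_extract(matrix: CommunityMatrix) -> pd.DataFrame:
    """One BetaPair record per site-visit with both bank samples present.

    Columns: pair key, dataset, a, b, c, beta_sor, beta_sim, beta_sne, and the
    flags ``degenerate`` (exactly one empty assemblage, beta_sor forced to 1)
    and ``undefined`` (both empty, beta NaN).
    """
    left, right, keys = pair_indices(matrix)
    a, b, c = pair_counts(matrix.values(), left, right)
    sor, sim, sne = beta_components(a, b, c)
    out = keys.copy()
    out["dataset"] = matrix.dataset_label
    out["a"], out["b"], out["c"] = a.astype(int), b.astype(int), c.astype(int)
    out["beta_sor"], out["beta_sim"], out["beta_sne"] = sor, sim, sne
    out["undefined"] = (a + b + c) == 0
    out["degenerate"] = ((a + b == 0) | (a + c == 0)) & ~out["undefined"]
    return out


def summarize_beta(pairs: pd.DataFrame) -> pd.DataFrame:
    """Per-dataset (n, min, mean, sd, max) of defined beta_sor values.

    SD uses the n-1 denominator. Raises if a dataset has no defined pairs.
    """
    defined = pairs[~pairs["beta_sor"].isna()]
    if defined.empty:
        raise ValueError("no defined beta values to summarize")
    out = (
        defined.groupby("dataset")["beta_sor"]
        .agg(n="count", min="min", mean="mean", sd=lambda v: v.std(ddof=1), max="max")
        .reset_index()
    )
    return out
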