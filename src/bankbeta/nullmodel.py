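"""Fixed-marginal null model and standardized effect sizes (z-scores).

The question the null model answers: is the dissimilarity between the two
bank assemblages of a site-visit smaller (or larger) than expected if species
occupied samples at random, given how rich each sample is and how frequent
each species is? Randomized matrices therefore preserve every row sum
(sample richness) and column sum (species occurrence frequency) of the
observed matrix — the "fixed-fixed" null family.

Each retained matrix is the end state of an independent chain started from
the observed matrix (burn-in of ``10 x number of presences`` effective moves
by default), which sidesteps autocorrelation between successive samples of a
single chain. For every randomized matrix the cross-channel extraction is
repeated, giving each pair x component a null distribution of draws, and

    z = (observed beta - null mean) / null SD

with the sample (n-1) SD of the draws. Negative z: the two banks share more
species than chance expects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import beta as _beta
from ._kernels import curveball_kernel, sequential_swap_kernel
from .community import CommunityMatrix

logger = logging.getLogger(__name__)

COMPONENTS = ("total", "turnover", "nestedness")
_COMPONENT_COLUMN = {"total": "beta_sor", "turnover": "beta_sim", "nestedness": "beta_sne"}
ALGORITHMS = ("curveball", "sequential_swap")


@dataclass(frozen=True)
class NullModelConfig:
    """Settings for one null ensemble.

    ``burn_in`` is the number of effective moves per chain. ``None`` picks a
    per-algorithm default: 10 x the number of presences for the sequential
    (checkerboard) swap, whose accepted moves each touch only four cells, and
    20 x the number of rows for curveball, whose every trade re-deals all
    non-shared species of a row pair (stationarity is typically reached by
    ~5 x rows; the factor 20 is a safety margin).
    """

    n_matrices: int = 999
    algorithm: str = "curveball"
    burn_in: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        if self.n_matrices < 1:
            raise ValueError("n_matrices must be >= 1")


@dataclass
class NullEnsemble:
    """Per-pair null draws plus provenance for one dataset's randomization."""

    pairs: pd.DataFrame            # observed BetaPair records (cross_channel_extract)
    draws: dict[str, np.ndarray]   # component -> (n_pairs, n_matrices) array
    provenance: dict = field(default_factory=dict)

    @property
    def n_matrices(self) -> int:
        return next(iter(self.draws.values())).shape[1]


def child_seeds(seed: int, n: int) -> np.ndarray:
    """Derive n independent sub-2^31 seeds from one master seed."""
    return (np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32) >> 1).astype(
        np.int64
    )


def randomize(
    matrix: np.ndarray, algorithm: str, n_moves: int, seed: int
) -> np.ndarray:
    """Return one marginal-preserving randomization of a binary matrix."""
    work = np.ascontiguousarray(matrix, dtype=np.uint8).copy()
    if algorithm == "curveball":
        curveball_kernel(work, n_moves, seed)
    elif algorithm == "sequential_swap":
        sequential_swap_kernel(work, n_moves, 200 * n_moves + 1000, seed)
    else:
        raise ValueError(f"unknown algorithm: {algorithm}")
    return work


def sequential_swap(matrix: np.ndarray, n_swaps: int, seed: int) -> np.ndarray:
    """Checkerboard-swap randomization (n_swaps effective swaps)."""
    return randomize(matrix, "sequential_swap", n_swaps, seed)


def curveball(matrix: np.ndarray, n_trades: int, seed: int) -> np.ndarray:
    """Curveball-trade randomization (n_trades trades)."""
    return randomize(matrix, "curveball", n_trades, seed)


def build_ensemble(matrix: CommunityMatrix, config: NullModelConfig) -> NullEnsemble:
    """Randomize a dataset's full matrix and collect per-pair null β draws.

    The whole analyzed matrix is randomized at once (all samples of the
    dataset, after exclusions); the left-right extraction is then repeated on
    every randomized matrix. Marginal conservation is asserted for every
    retained matrix.
    """
    if matrix.shape[1] == 0:
        raise ValueError(
            f"dataset {matrix.dataset_label!r} has no species columns; cannot randomize"
        )
    obs = np.ascontiguousarray(matrix.values(), dtype=np.uint8)
    row_sums = obs.sum(axis=1)
    col_sums = obs.sum(axis=0)
    fill = int(obs.sum())
    if config.burn_in is not None:
        burn_in = config.burn_in
    elif config.algorithm == "curveball":
        burn_in = 20 * obs.shape[0]
    else:
        burn_in = 10 * fill

    left, right, _keys = _beta.pair_indices(matrix)
    pairs = _beta.cross_channel_extract(matrix)
    n_pairs = len(pairs)
    draws = {comp: np.empty((n_pairs, config.n_matrices)) for comp in COMPONENTS}

    seeds = child_seeds(config.seed, config.n_matrices)
    for i in range(config.n_matrices):
        rnd = randomize(obs, config.algorithm, burn_in, int(seeds[i]))
        if not (
            np.array_equal(rnd.sum(axis=1), row_sums)
            and np.array_equal(rnd.sum(axis=0), col_sums)
        ):  # pragma: no cover - would indicate a kernel bug
            raise AssertionError("randomized matrix does not conserve marginals")
        a, b, c = _beta.pair_counts(rnd.astype(bool), left, right)
        sor, sim, sne = _beta.beta_components(a, b, c)
        draws["total"][:, i] = sor
        draws["turnover"][:, i] = sim
        draws["nestedness"][:, i] = sne

    provenance = {
        "algorithm": config.algorithm,
        "n_matrices": config.n_matrices,
        "burn_in": burn_in,
        "seed": config.seed,
        "dataset": matrix.dataset_label,
        "shape": list(matrix.shape),
        "fill": fill,
    }
    return NullEnsemble(pairs=pairs, draws=draws, provenance=provenance)


def ses_zscore(
    observed: np.ndarray, null_draws: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(null_mean, null_sd, z) per pair from a (n_pairs, n_draws) array.

    z is NaN wherever the null SD is zero (constant draws) or the observed
    value is undefined; both cases are logged.
    """
    null_draws = np.atleast_2d(np.asarray(null_draws, dtype=float))
    observed = np.asarray(observed, dtype=float)
    counts = (~np.isnan(null_draws)).sum(axis=1)
    null_mean = np.full(null_draws.shape[0], np.nan)
    null_sd = np.full(null_draws.shape[0], np.nan)
    ok = counts > 1
    null_mean[counts > 0] = np.nanmean(null_draws[counts > 0], axis=1)
    null_sd[ok] = np.nanstd(null_draws[ok], axis=1, ddof=1)
    # draws are ratios of small integers: an SD at rounding-noise level
    # (constant draws) is degenerate, not a real null spread
    null_sd = np.where(null_sd <= 1e-12, 0.0, null_sd)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (observed - null_mean) / null_sd
    z = np.where(null_sd > 0, z, np.nan)
    n_bad = int(np.isnan(z).sum())
    if n_bad:
        logger.warning("%d pair(s) have undefined z (zero null SD or undefined beta)", n_bad)
    return null_mean, null_sd, z


def ses_table(ensemble: NullEnsemble) -> pd.DataFrame:
    """Long SES table: one row per pair x component.

    Columns: pair key, dataset, component, observed, null_mean, null_sd, z.
    """
    records = []
    base = ensemble.pairs[_beta.PAIR_KEY + ["dataset", "degenerate", "undefined"]]
    for comp in COMPONENTS:
        observed = ensemble.pairs[_COMPONENT_COLUMN[comp]].to_numpy()
        null_mean, null_sd, z = ses_zscore(observed, ensemble.draws[comp])
        part = base.copy()
        part["component"] = comp
        part["observed"] = observed
        part["null_mean"] = null_mean
        part["null_sd"] = null_sd
        part["z"] = z
        records.append(part)
    return pd.concat(records, ignore_index=True)
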