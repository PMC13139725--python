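"""Replicated simulation experiments that validate the whole pipeline.

These are the package's standard self-checks — each builds synthetic worlds
with :mod:`bankbeta.synthetic`, pushes them through community construction,
the null model and the trend models, and measures a calibration or recovery
statistic:

* :func:`design_counts` — the design arithmetic of the default survey
  (traps, pooled samples, samples after the two whole-pair exclusions,
  cross-channel pairs);
* :func:`ses_calibration` — under the null scenario (independent banks) the
  pair-level z-scores should be approximately standard normal;
* :func:`convergence_power` — with temporal convergence injected
  (delta > 0) the limited-flight visit slope should be negative;
* :func:`type1_error` — under the null scenario the position and visit
  slopes should reject at roughly the nominal rate.

Seeding: a world's simulation seed is ``base_seed + replicate`` and its null
ensemble seed is ``10_000 + simulation seed``, so every experiment is fully
reproducible from ``base_seed`` alone.
"""

from __future__ import annotations

import numpy as np

from . import beta as _beta
from . import community as _community
from . import nullmodel as _nullmodel
from . import synthetic as _synthetic
from . import trends as _trends
from .pipeline import STUDY_EXCLUSIONS

DEFAULT_N_NULL = 999


def build_matrix(
    sim: _synthetic.SimulationResult,
    dataset: str = "all_species",
    exclusions: list | None = None,
) -> _community.CommunityMatrix:
    """Pool, harmonize, binarize, (optionally) exclude and split one world."""
    pooled = _community.pool_all_traps(sim.traps)
    matrix = _community.binarize(_community.harmonize_taxa(pooled, {}), sim.metadata)
    if exclusions:
        matrix = _community.apply_exclusions(matrix, exclusions)
    return _community.split_by_flight(matrix, sim.traits)[dataset]


def world_ses(
    scenario_name: str,
    seed: int,
    dataset: str,
    n_null: int = DEFAULT_N_NULL,
    exclusions: list | None = None,
    algorithm: str = "curveball",
    **scenario_overrides,
):
    """Simulate one world and return its long SES table for one dataset."""
    sim = _synthetic.simulate(
        _synthetic.scenario(scenario_name, seed=seed, **scenario_overrides)
    )
    matrix = build_matrix(sim, dataset, exclusions)
    ensemble = _nullmodel.build_ensemble(
        matrix,
        _nullmodel.NullModelConfig(
            n_matrices=n_null, algorithm=algorithm, seed=10_000 + seed
        ),
    )
    return _nullmodel.ses_table(ensemble)


def design_counts(seed: int = 0) -> dict:
    """Design arithmetic of the default synthetic survey."""
    sim = _synthetic.simulate(_synthetic.SimulationConfig(seed=seed))
    pooled = _community.pool_all_traps(sim.traps)
    full = _community.binarize(_community.harmonize_taxa(pooled, {}), sim.metadata)
    first = _community.apply_exclusions(full, [STUDY_EXCLUSIONS[0]])
    both = _community.apply_exclusions(first, [STUDY_EXCLUSIONS[1]])
    pairs = _beta.cross_channel_extract(both)
    return {
        "n_trap_records": sim.n_traps,
        "n_pooled_samples": full.shape[0],
        "n_samples_after_first_exclusion": first.shape[0],
        "n_samples_analyzed": both.shape[0],
        "n_cross_channel_pairs": len(pairs),
    }


def ses_calibration(
    n_worlds: int = 20, n_null: int = DEFAULT_N_NULL, base_seed: int = 0
) -> dict:
    """Pooled mean and SD of pair-level z under the null scenario."""
    zs = []
    for rep in range(n_worlds):
        ses = world_ses("null", base_seed + rep, "all_species", n_null)
        zs.append(ses.loc[ses["component"] == "total", "z"].to_numpy())
    z = np.concatenate(zs)
    return {
        "z_mean": float(np.nanmean(z)),
        "z_sd": float(np.nanstd(z, ddof=1)),
        "n_pairs": int(np.sum(~np.isnan(z))),
        "n_worlds": n_worlds,
    }


def convergence_power(
    n_worlds: int = 20,
    delta: float = 0.25,
    n_null: int = DEFAULT_N_NULL,
    base_seed: int = 100,
) -> dict:
    """Fraction of convergence worlds with a negative limited-flight visit slope."""
    slopes = []
    for rep in range(n_worlds):
        ses = world_ses(
            "convergence", base_seed + rep, "limited_flight", n_null, delta=delta
        )
        fit = _trends.fit_lmm(
            ses[ses["component"] == "total"], dataset="limited_flight"
        )
        slopes.append(fit.estimates["visit"])
    slopes = np.asarray(slopes)
    return {
        "negative_visit_slope_rate": float(np.mean(slopes < 0)),
        "mean_visit_slope": float(slopes.mean()),
        "n_worlds": n_worlds,
    }


def type1_error(
    n_worlds: int = 20,
    n_null: int = DEFAULT_N_NULL,
    base_seed: int = 200,
    alpha: float = 0.05,
) -> dict:
    """Rejection rate of both slopes pooled across null-scenario worlds."""
    rejections = 0
    estimates = {"position": [], "visit": []}
    for rep in range(n_worlds):
        ses = world_ses("null", base_seed + rep, "all_species", n_null)
        fit = _trends.fit_lmm(ses[ses["component"] == "total"], dataset="all_species")
        for term in ("position", "visit"):
            rejections += fit.pvalues[term] < alpha
            estimates[term].append(fit.estimates[term])
    n_tests = 2 * n_worlds
    return {
        "type1_error_rate": rejections / n_tests,
        "n_tests": n_tests,
        "mean_position_slope": float(np.mean(estimates["position"])),
        "mean_visit_slope": float(np.mean(estimates["visit"])),
    }
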