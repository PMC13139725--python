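"""End-to-end orchestration: (load | simulate) -> harmonize -> binarize ->
exclude -> split -> beta -> null model -> SES -> trend models -> report.

Every stage boundary is persisted as CSV when an output directory is given,
so downstream stages can be re-run from intermediates, and a manifest records
the config, seeds and record counts for full provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import beta as _beta
from . import community as _community
from . import nullmodel as _nullmodel
from . import synthetic as _synthetic
from . import trends as _trends

logger = logging.getLogger(__name__)

#: the two whole-pair exclusions of the motivating survey: B6 V4 (livestock
#: disturbance) and B3 V4 (single-species bank inflating dissimilarity)
STUDY_EXCLUSIONS = [
    {"site": "B6", "visit": 4, "reason": "livestock"},
    {"site": "B3", "visit": 4, "reason": "singleton-inflation"},
]

DATASETS = ("all_species", "flight_capable", "limited_flight")


@dataclass
class RunConfig:
    """One pipeline run: either a simulation scenario or input file paths."""

    scenario: str | None = None
    scenario_overrides: dict = field(default_factory=dict)
    occurrences: str | None = None
    metadata: str | None = None
    traits: str | None = None
    harmonize_rules: dict = field(default_factory=dict)
    exclusions: list = field(default_factory=lambda: [dict(e) for e in STUDY_EXCLUSIONS])
    n_null: int = 999
    null_algorithm: str = "curveball"
    burn_in: int | None = None
    seed: int = 0
    drop_degenerate: bool = False
    outdir: str | None = None

    def __post_init__(self) -> None:
        has_files = self.occurrences is not None
        if has_files == (self.scenario is not None):
            raise ValueError("set exactly one of scenario or input file paths")
        if has_files and (self.metadata is None or self.traits is None):
            raise ValueError("file input needs occurrences, metadata and traits paths")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunResult:
    matrices: dict[str, _community.CommunityMatrix]
    pairs: pd.DataFrame
    beta_summary: pd.DataFrame
    ses: pd.DataFrame
    fits: list[_trends.TrendFit]
    trend_table: pd.DataFrame
    manifest: dict


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


@_stage("load")
def _load_inputs(config: RunConfig):
    if config.scenario is not None:
        sim_cfg = _synthetic.scenario(
            config.scenario, **(config.scenario_overrides | {"seed": config.seed})
        )
        sim = _synthetic.simulate(sim_cfg)
        pooled = _community.pool_all_traps(sim.traps)
        return pooled, sim.metadata, sim.traits, sim
    occ = _community.read_occurrences(config.occurrences)
    meta = _community.read_metadata(config.metadata)
    traits = _community.read_traits(config.traits)
    return occ, meta, traits, None


def run(config: RunConfig) -> RunResult:
    """Execute the full analysis and (optionally) persist every stage."""
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    pooled, metadata, traits, sim = _load_inputs(config)
    harmonized = _stage("harmonize")(_community.harmonize_taxa)(
        pooled, config.harmonize_rules
    )
    full = _stage("binarize")(_community.binarize)(harmonized, metadata)
    analyzed = _stage("exclusions")(_community.apply_exclusions)(full, config.exclusions)
    splits = _stage("split")(_community.split_by_flight)(analyzed, traits)

    all_pairs, all_ses = [], []
    fits: list[_trends.TrendFit] = []
    null_seeds = _nullmodel.child_seeds(config.seed, len(DATASETS))
    provenance = {}
    for i, label in enumerate(DATASETS):
        matrix = splits[label]
        pairs = _stage("beta")(_beta.cross_channel_extract)(matrix)
        all_pairs.append(pairs)
        null_cfg = _nullmodel.NullModelConfig(
            n_matrices=config.n_null,
            algorithm=config.null_algorithm,
            burn_in=config.burn_in,
            seed=int(null_seeds[i]),
        )
        ensemble = _stage("null")(_nullmodel.build_ensemble)(matrix, null_cfg)
        provenance[label] = ensemble.provenance
        ses = _nullmodel.ses_table(ensemble)
        all_ses.append(ses)
    pairs = pd.concat(all_pairs, ignore_index=True)
    ses = pd.concat(all_ses, ignore_index=True)
    beta_summary = _stage("summary")(_beta.summarize_beta)(pairs)
    fits = _stage("fit")(_trends.component_trends)(ses, config.drop_degenerate)
    trend_table = _trends.trend_table(fits)

    manifest = {
        "bankbeta_version": __version__,
        "config": dataclasses.asdict(config),
        "config_digest": config.digest(),
        "seed": config.seed,
        "null_provenance": provenance,
        "n_samples_full": full.shape[0],
        "n_samples_analyzed": analyzed.shape[0],
        "n_pairs_per_dataset": int(len(pairs) / len(DATASETS)),
        "exclusion_log": analyzed.exclusion_log,
    }

    if outdir:
        if sim is not None:
            sim.traps.to_csv(outdir / "trap_counts.csv", index=False)
            metadata.to_csv(outdir / "sample_metadata.csv", index=False)
            traits.rename("wing_morphology").rename_axis("taxon").reset_index().to_csv(
                outdir / "traits.csv", index=False
            )
            with open(outdir / "truth.json", "w") as fh:
                json.dump(sim.truth, fh, indent=1)
        analyzed.occurrence.to_csv(outdir / "community_matrix.csv")
        pairs.to_csv(outdir / "beta_pairs.csv", index=False)
        beta_summary.to_csv(outdir / "beta_summary.csv", index=False)
        ses.to_csv(outdir / "ses.csv", index=False)
        trend_table.to_csv(outdir / "trend_fits.csv", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)

    return RunResult(
        matrices=splits,
        pairs=pairs,
        beta_summary=beta_summary,
        ses=ses,
        fits=fits,
        trend_table=trend_table,
        manifest=manifest,
    )
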