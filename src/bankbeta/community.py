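"""Occurrence data handling: pooling, harmonization, binarization, splits.

The analysis consumes binary sample x species matrices built from pitfall-trap
counts. Counts are kept through pooling and taxonomic harmonization (so those
steps are testable and the synthetic generator has realistic outputs) and are
binarized only once, because trap catches measure activity density rather than
abundance and all downstream statistics are occurrence-based.

Conventions used throughout the package:

* rows = samples, columns = species — so the null model's "row sums" are
  sample richness and "column sums" are species occurrence frequencies;
* species columns are ordered lexicographically for deterministic output;
* a *sample* is the pooled catch of the six traps on one bank of one site on
  one visit, identified by ``(catchment, site_code, bank, visit)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RANKS = ("species", "species_aggregate", "genus", "family")
BANKS = ("left", "right")
MORPHOLOGIES = ("macropterous", "brachypterous", "polymorphic")

#: columns of a long-format occurrence table
OCC_COLUMNS = ["sample_id", "taxon", "rank", "count"]
#: columns of a sample-metadata table
META_COLUMNS = ["sample_id", "catchment", "site_code", "position", "bank", "visit"]


class CommunityDataError(ValueError):
    """Raised for structural problems in occurrence/metadata/trait inputs."""


# ---------------------------------------------------------------------------
# validation helpers


def validate_occurrences(table: pd.DataFrame) -> pd.DataFrame:
    """Check a long occurrence table and return it with canonical dtypes."""
    missing = [c for c in OCC_COLUMNS if c not in table.columns]
    if missing:
        raise CommunityDataError(f"occurrence table missing columns: {missing}")
    table = table.copy()
    table["count"] = pd.to_numeric(table["count"])
    if (table["count"] < 0).any():
        bad = table.loc[table["count"] < 0, "taxon"].unique().tolist()
        raise CommunityDataError(f"negative counts for taxa: {bad}")
    unknown = set(table["rank"]) - set(RANKS)
    if unknown:
        raise CommunityDataError(f"unknown taxon ranks: {sorted(unknown)}")
    return table


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Check a sample-metadata table (one row per pooled bank sample)."""
    missing = [c for c in META_COLUMNS if c not in metadata.columns]
    if missing:
        raise CommunityDataError(f"metadata missing columns: {missing}")
    metadata = metadata.copy()
    if metadata["sample_id"].duplicated().any():
        dups = metadata.loc[metadata["sample_id"].duplicated(), "sample_id"].tolist()
        raise CommunityDataError(f"duplicate sample_id in metadata: {dups}")
    bad_bank = set(metadata["bank"]) - set(BANKS)
    if bad_bank:
        raise CommunityDataError(f"bank must be one of {BANKS}, got {sorted(bad_bank)}")
    key = metadata[["catchment", "site_code", "bank", "visit"]]
    if key.duplicated().any():
        raise CommunityDataError("(catchment, site_code, bank, visit) must be unique")
    return metadata


def validate_traits(traits: pd.Series | dict) -> pd.Series:
    """Check a taxon -> wing morphology mapping."""
    traits = pd.Series(traits)
    unknown = set(traits) - set(MORPHOLOGIES)
    if unknown:
        raise CommunityDataError(
            f"wing morphology must be one of {MORPHOLOGIES}, got {sorted(unknown)}"
        )
    return traits


# ---------------------------------------------------------------------------
# core container


@dataclass
class CommunityMatrix:
    """Binary sample x species matrix with aligned metadata.

    Attributes
    ----------
    occurrence
        DataFrame indexed by ``sample_id`` with one lexicographically ordered
        column per species; entries are 0/1 (int8).
    metadata
        DataFrame indexed by ``sample_id`` in the same row order, carrying
        catchment, site_code, position, bank and visit.
    dataset_label
        One of ``all_species``, ``flight_capable``, ``limited_flight`` (or a
        user label).
    exclusion_log
        Records of site-visit pairs removed by :func:`apply_exclusions`.
    """

    occurrence: pd.DataFrame
    metadata: pd.DataFrame
    dataset_label: str = "all_species"
    exclusion_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.occurrence.index.equals(self.metadata.index):
            raise CommunityDataError("occurrence and metadata row order differ")
        vals = self.occurrence.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise CommunityDataError("occurrence entries must be 0/1")

    @property
    def samples(self) -> list[str]:
        return list(self.occurrence.index)

    @property
    def species(self) -> list[str]:
        return list(self.occurrence.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.occurrence.shape

    def values(self) -> np.ndarray:
        """Occurrence matrix as a boolean ndarray (rows = samples)."""
        return self.occurrence.to_numpy(dtype=bool)

    def row_species(self, sample_id: str) -> frozenset[str]:
        row = self.occurrence.loc[sample_id]
        return frozenset(row.index[row.astype(bool)])


# ---------------------------------------------------------------------------
# operations


def pool_traps(trap_counts: pd.DataFrame) -> pd.DataFrame:
    """Pool per-trap counts for ONE bank of one site-visit into one sample.

    Parameters
    ----------
    trap_counts
        Long table with columns ``catchment, site_code, bank, visit, trap,
        taxon, rank, count``; every row must belong to the same
        (catchment, site_code, bank, visit).

    Returns
    -------
    DataFrame with columns ``sample_id, taxon, rank, count`` (counts summed
    over traps). An all-empty trap set yields a zero-row table.
    """
    required = ["catchment", "site_code", "bank", "visit", "trap", "taxon", "rank", "count"]
    missing = [c for c in required if c not in trap_counts.columns]
    if missing:
        raise CommunityDataError(f"trap table missing columns: {missing}")
    keys = trap_counts[["catchment", "site_code", "bank", "visit"]].drop_duplicates()
    if len(keys) > 1:
        offending = trap_counts.loc[
            ~(trap_counts[keys.columns] == keys.iloc[0]).all(axis=1), "trap"
        ].unique()
        raise CommunityDataError(
            f"traps from mixed bank/site/visit cannot be pooled; offending traps: "
            f"{sorted(map(str, offending))}"
        )
    if (trap_counts["count"] < 0).any():
        raise CommunityDataError("negative trap counts")
    if trap_counts.empty:
        return pd.DataFrame(columns=OCC_COLUMNS)
    k = keys.iloc[0]
    sample_id = make_sample_id(k["site_code"], k["bank"], k["visit"])
    pooled = (
        trap_counts.groupby(["taxon", "rank"], as_index=False)["count"].sum()
    )
    pooled = pooled[pooled["count"] > 0]
    pooled.insert(0, "sample_id", sample_id)
    return pooled.reset_index(drop=True)[OCC_COLUMNS]


def pool_all_traps(trap_counts: pd.DataFrame) -> pd.DataFrame:
    """Pool every (catchment, site, bank, visit) group of a trap-level table."""
    if trap_counts.empty:
        return pd.DataFrame(columns=OCC_COLUMNS)
    parts = [
        pool_traps(group)
        for _, group in trap_counts.groupby(
            ["catchment", "site_code", "bank", "visit"], sort=True
        )
    ]
    parts = [p for p in parts if not p.empty]
    if not parts:
        return pd.DataFrame(columns=OCC_COLUMNS)
    return pd.concat(parts, ignore_index=True)


def make_sample_id(site_code: str, bank: str, visit: int) -> str:
    """Canonical sample identifier, e.g. ``B6-L-V4``."""
    return f"{site_code}-{str(bank)[0].upper()}-V{int(visit)}"


def harmonize_taxa(
    table: pd.DataFrame,
    rules: dict[str, str] | None = None,
    drop_family: bool = True,
) -> pd.DataFrame:
    """Merge genus-level records into a designated species per genus.

    Records identified only to genus inflate cross-channel dissimilarity when
    the same population appears as e.g. *Pterostichus* in one sample and
    *Pterostichus madidus* in the other, so each genus-level taxon is
    reassigned to a single most-likely species and its counts are added to
    that species' counts.

    Parameters
    ----------
    table
        Long occurrence table (``sample_id, taxon, rank, count``).
    rules
        Mapping genus-level taxon name -> species-level taxon name. Every
        genus appearing in the table must have a rule; an unmapped genus is an
        error, never a silent drop.
    drop_family
        Family-level records (a fraction of a percent of individuals in the
        motivating survey) are dropped with a logged warning; no reassignment
        rule for families is supported.
    """
    table = validate_occurrences(table)
    rules = dict(rules or {})

    fam = table["rank"] == "family"
    if fam.any():
        if not drop_family:
            raise CommunityDataError(
                f"family-level records present: {sorted(table.loc[fam, 'taxon'].unique())}"
            )
        logger.warning(
            "dropping %d family-level records (%g individuals)",
            int(fam.sum()),
            float(table.loc[fam, "count"].sum()),
        )
        table = table[~fam]

    genus = table["rank"] == "genus"
    unresolved = sorted(set(table.loc[genus, "taxon"]) - set(rules))
    if unresolved:
        raise CommunityDataError(
            f"genus-level taxa with no reassignment rule: {unresolved}"
        )
    if genus.any():
        table = table.copy()
        table.loc[genus, "taxon"] = table.loc[genus, "taxon"].map(rules)
        table.loc[genus, "rank"] = "species"

    out = (
        table.groupby(["sample_id", "taxon"], as_index=False)
        .agg(rank=("rank", "first"), count=("count", "sum"))
    )
    return out[OCC_COLUMNS].reset_index(drop=True)


def binarize(table: pd.DataFrame, metadata: pd.DataFrame) -> CommunityMatrix:
    """Build a binary CommunityMatrix from a harmonized occurrence table.

    Every sample listed in ``metadata`` becomes a row (samples that caught
    nothing are all-zero rows); species never observed are dropped; species
    columns are sorted lexicographically. Occurrence is 1 wherever the pooled
    count is positive — the analysis is deliberately abundance-invariant.
    """
    table = validate_occurrences(table)
    metadata = validate_metadata(metadata)
    known = set(metadata["sample_id"])
    orphans = sorted(set(table["sample_id"]) - known)
    if orphans:
        raise CommunityDataError(f"samples absent from metadata: {orphans}")

    meta = metadata.sort_values(["catchment", "position", "visit", "bank"])
    meta = meta.set_index("sample_id")
    present = table[table["count"] > 0]
    wide = (
        present.assign(occ=1)
        .pivot_table(index="sample_id", columns="taxon", values="occ", fill_value=0)
        .reindex(index=meta.index, fill_value=0)
    )
    wide = wide[sorted(wide.columns)].astype(np.int8)
    wide = wide.loc[:, wide.sum(axis=0) > 0]
    wide.columns.name = None
    return CommunityMatrix(occurrence=wide, metadata=meta, dataset_label="all_species")


def apply_exclusions(
    matrix: CommunityMatrix,
    exclusions: list[tuple[str, int, str]] | list[dict],
) -> CommunityMatrix:
    """Remove both bank samples of listed site-visit pairs.

    Exclusions always operate on whole cross-channel pairs (the motivating
    survey removed B6 V4 for livestock disturbance and B3 V4 for a
    single-species bank that inflated dissimilarity), so row counts decrease
    by even numbers. Species columns left with no occurrences are dropped.
    """
    meta = matrix.metadata
    keep = pd.Series(True, index=meta.index)
    log = list(matrix.exclusion_log)
    for item in exclusions:
        if isinstance(item, dict):
            site, visit = item["site"], int(item["visit"])
            reason = item.get("reason", "")
        else:
            site, visit, reason = item[0], int(item[1]), item[2] if len(item) > 2 else ""
        hit = (meta["site_code"] == site) & (meta["visit"] == visit)
        if not hit.any():
            raise CommunityDataError(f"exclusion references unknown site-visit: {site} V{visit}")
        keep &= ~hit
        log.append({"site": site, "visit": visit, "reason": reason,
                    "n_removed": int(hit.sum())})
        logger.info("excluded %s V%d (%s): %d samples", site, visit, reason, int(hit.sum()))
    occ = matrix.occurrence.loc[keep]
    occ = occ.loc[:, occ.sum(axis=0) > 0]
    return CommunityMatrix(
        occurrence=occ,
        metadata=meta.loc[keep],
        dataset_label=matrix.dataset_label,
        exclusion_log=log,
    )


def split_by_flight(
    matrix: CommunityMatrix, traits: pd.Series | dict
) -> dict[str, CommunityMatrix]:
    """Split columns into the three wing-morphology datasets.

    Returns ``{"all_species": ..., "flight_capable": ..., "limited_flight": ...}``
    where flight_capable holds macropterous species only and limited_flight
    holds brachypterous plus polymorphic species. The splits partition the
    all-species columns. Rows that lose every species in a subset are kept as
    all-zero rows; their β pairs are handled downstream by the
    empty-assemblage rule.
    """
    traits = validate_traits(traits)
    missing = sorted(set(matrix.species) - set(traits.index))
    if missing:
        raise CommunityDataError(f"species with no wing-morphology assignment: {missing}")
    morph = traits.reindex(matrix.species)
    fc_cols = [s for s in matrix.species if morph[s] == "macropterous"]
    lf_cols = [s for s in matrix.species if morph[s] in ("brachypterous", "polymorphic")]

    def _subset(cols: list[str], label: str) -> CommunityMatrix:
        return CommunityMatrix(
            occurrence=matrix.occurrence[cols],
            metadata=matrix.metadata,
            dataset_label=label,
            exclusion_log=list(matrix.exclusion_log),
        )

    return {
        "all_species": _subset(list(matrix.species), "all_species"),
        "flight_capable": _subset(fc_cols, "flight_capable"),
        "limited_flight": _subset(lf_cols, "limited_flight"),
    }


# ---------------------------------------------------------------------------
# file I/O


def _read_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return pd.read_csv(path, sep=sep)


def read_occurrences(path) -> pd.DataFrame:
    """Read a long (sample_id, taxon, rank, count) or wide (samples x taxa)
    occurrence CSV/TSV; wide tables are melted and assigned rank 'species'."""
    df = _read_table(path)
    if set(OCC_COLUMNS) <= set(df.columns):
        return validate_occurrences(df[OCC_COLUMNS])
    if "sample_id" not in df.columns:
        raise CommunityDataError("occurrence table needs a sample_id column")
    long = df.melt(id_vars="sample_id", var_name="taxon", value_name="count")
    long = long[long["count"] > 0]
    long["rank"] = "species"
    return validate_occurrences(long[OCC_COLUMNS].reset_index(drop=True))


def read_metadata(path) -> pd.DataFrame:
    return validate_metadata(_read_table(path))


def read_traits(path) -> pd.Series:
    df = _read_table(path)
    need = {"taxon", "wing_morphology"}
    if not need <= set(df.columns):
        raise CommunityDataError(f"trait table needs columns {sorted(need)}")
    return validate_traits(pd.Series(df["wing_morphology"].values, index=df["taxon"]))
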