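import logging

import numpy as np
import pandas as pd
import pytest

from bankbeta import community as com
from bankbeta import synthetic as syn

logging.getLogger("bankbeta").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_sim():
    """One default-design synthetic survey shared across tests."""
    return syn.simulate(syn.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def full_matrix(default_sim):
    """All 96 samples, binarized, before exclusions."""
    pooled = com.pool_all_traps(default_sim.traps)
    return com.binarize(com.harmonize_taxa(pooled, {}), default_sim.metadata)


@pytest.fixture(scope="session")
def analyzed_matrix(full_matrix):
    """The 92-sample matrix after both whole-pair exclusions."""
    return com.apply_exclusions(
        full_matrix, [("B6", 4, "livestock"), ("B3", 4, "singleton-inflation")]
    )


def make_metadata(n_sites=2, n_visits=2, catchments=("B",)):
    rows = []
    for c in catchments:
        for pos in range(1, n_sites + 1):
            for v in range(1, n_visits + 1):
                for bank in ("left", "right"):
                    rows.append(
                        {
                            "sample_id": com.make_sample_id(f"{c}{pos}", bank, v),
                            "catchment": c,
                            "site_code": f"{c}{pos}",
                            "position": pos,
                            "bank": bank,
                            "visit": v,
                        }
                    )
    return pd.DataFrame(rows)


def matrix_from_sets(assemblages: dict[str, set], metadata: pd.DataFrame):
    """Hand-build a CommunityMatrix from sample_id -> species-set."""
    records = [
        {"sample_id": sid, "taxon": sp, "rank": "species", "count": 1}
        for sid, spp in assemblages.items()
        for sp in spp
    ]
    table = pd.DataFrame(records, columns=com.OCC_COLUMNS)
    return com.binarize(table, metadata)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
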