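import logging

import numpy as np
import pandas as pd
import pytest

from consensusdeg import deg, synthgen
from consensusdeg.consensus import build_consensus_table

logging.getLogger("consensusdeg").setLevel(logging.ERROR)

# fixed seed for all seeded fixtures; the study-condition defaults of
# SimConfig are never altered here
FIXED_SEED = 11


@pytest.fixture(scope="session")
def study_config():
    """The default study conditions: 5 cohorts, 2,000 genes, 200+200 planted
    at effect 1.5 log2 units, noise sd 1, 40+40 samples, 10% dropout."""
    return synthgen.SimConfig(seed=FIXED_SEED)


@pytest.fixture(scope="session")
def study_sim(study_config):
    cohorts, truth = synthgen.simulate_multicohort(study_config)
    return cohorts, truth


@pytest.fixture(scope="session")
def study_de(study_config, study_sim):
    cohorts, _ = study_sim
    discovery = cohorts[: study_config.n_cohorts]
    return [deg.moderated_ttest(c, "tumor", "normal", alpha=0.05) for c in discovery]


@pytest.fixture(scope="session")
def study_consensus(study_de):
    return build_consensus_table(study_de, m=4, tier2=3)


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down planted cohorts for fast structural tests."""
    return synthgen.SimConfig(
        genes_total=300,
        n_true_up=60,
        n_true_down=60,
        n_inconsistent=20,
        n_tumor=12,
        n_normal=12,
        n_essential=20,
        n_common_essential=10,
        n_prognostic=5,
        n_subtype_genes=15,
        n_proliferation_genes=8,
        seed=FIXED_SEED,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    return synthgen.simulate_multicohort(small_config)


def make_de_result(name, directions=None, log2fc=None, p_raw=None, p_adj=None,
                   alpha=0.05):
    """Hand-build a CohortDEResult table for rule-level tests."""
    genes = sorted(
        set()
        | set((directions or {}).keys())
        | set((log2fc or {}).keys())
        | set((p_raw or {}).keys())
    )
    rows = {}
    for g in genes:
        fc = (log2fc or {}).get(g, 0.0)
        p = (p_raw or {}).get(g, 1.0)
        pa = (p_adj or {}).get(g, (p_raw or {}).get(g, 1.0))
        d = (directions or {}).get(g)
        if d is None:
            d = "up" if (pa < alpha and fc > 0) else ("down" if (pa < alpha and fc < 0) else "ns")
        rows[g] = {"log2fc": fc, "t": 0.0, "p_raw": p, "p_adj": pa, "direction": d}
    columns = ["log2fc", "t", "p_raw", "p_adj", "direction"]
    if rows:
        table = pd.DataFrame.from_dict(rows, orient="index")[columns]
    else:
        table = pd.DataFrame(columns=columns)
    table.index.name = "gene"
    return deg.CohortDEResult(cohort=name, table=table, alpha=alpha)


@pytest.fixture
def rng():
    return np.random.default_rng(FIXED_SEED)
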