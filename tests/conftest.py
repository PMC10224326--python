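import numpy as np
import pandas as pd
import pytest

from ccikit import SimulationConfig, SurveyDesign, draw_sample, \
    generate_population


def make_srs_design(n, weights=None):
    """Equal-weight element-sampling design: one stratum, each record a PSU."""
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    return SurveyDesign(np.zeros(n, dtype=int), np.arange(n), w)


def full_record(**overrides):
    rec = {c: 0 for c in ("FPS", "SBA", "ANCS", "DTC3", "MSL", "BCG",
                          "ORT", "CPNM")}
    rec.update(overrides)
    return rec


@pytest.fixture(scope="session")
def small_population():
    """Compact finite population reused across tests (~7,700 records)."""
    cfg = SimulationConfig(clusters_per_stratum=8, households_per_cluster=60,
                           seed=20180527)
    pop, truth = generate_population(cfg)
    return cfg, pop, truth


@pytest.fixture(scope="session")
def clustered_sample(small_population):
    """A two-stage sample from the small population, with its design."""
    _, pop, _ = small_population
    sample, _ = draw_sample(pop, clusters_per_stratum=5,
                            households_per_cluster=25, seed=99)
    sample = sample.reset_index(drop=True)
    design = SurveyDesign(sample["stratum_id"], sample["cluster_id"],
                          sample["weight"])
    return sample, design
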