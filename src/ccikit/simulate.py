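"""Synthetic DHS-like microdata with known ground truth.

Emulates the design of a national demographic and health survey: a finite
population of household clusters in region x urban/rural strata, a latent
wealth gradient confounded with region and residence, sociodemographic and
obstetric covariates, and the eight care-continuum component indicators
drawn from logistic models with known coefficients.  Sampling is two-stage:
systematic PPS cluster selection within strata, then systematic household
selection within clusters, yielding inverse-inclusion-probability weights
(self-weighting within stratum, variable across strata).

Everything is deterministic given (config, seed): the same configuration
always reproduces the same population, truth and samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cci import COMPONENTS, score_records, OPTIMAL
from .errors import ConfigurationError, SamplingError

GUINEA_REGIONS = ("Boké", "Conakry", "Faranah", "Kankan",
                  "Kindia", "Labé", "Mamou", "N'Zérékoré")

#: Linear-predictor features for the component logistic models, in order.
COMPONENT_FEATURES = ("intercept", "wealth_c", "anc4", "urban",
                      "edu_any", "planned", "radio")

#: Default per-component log-odds coefficients on COMPONENT_FEATURES.
#: Wealth and antenatal-care frequency carry the strongest effects, echoing
#: the equity gradient the index is designed to expose.
DEFAULT_COMPONENT_COEFFICIENTS = {
    "FPS":  (-2.4, 0.45, 0.30, 0.30, 0.30, 0.00, 0.20),
    "SBA":  (-0.7, 0.80, 0.70, 0.80, 0.40, 0.10, 0.10),
    "ANCS": (0.6, 0.50, 1.00, 0.40, 0.30, 0.20, 0.10),
    "DTC3": (-0.2, 0.50, 0.50, 0.20, 0.20, 0.10, 0.20),
    "MSL":  (0.6, 0.40, 0.40, 0.20, 0.20, 0.10, 0.10),
    "BCG":  (1.5, 0.50, 0.50, 0.30, 0.20, 0.10, 0.10),
    "ORT":  (0.5, 0.30, 0.30, 0.20, 0.20, 0.10, 0.10),
    "CPNM": (0.6, 0.30, 0.30, 0.20, 0.20, 0.10, 0.10),
}

#: Regional shift of the latent wealth index (Conakry, the capital, well
#: above; the mountainous north below), scaled by wealth_region_sd.
DEFAULT_REGION_WEALTH = {
    "Boké": 0.1, "Conakry": 1.4, "Faranah": -0.5, "Kankan": -0.3,
    "Kindia": 0.2, "Labé": -0.8, "Mamou": -0.6, "N'Zérékoré": -0.2,
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic survey population."""

    regions: tuple = GUINEA_REGIONS
    clusters_per_stratum: int = 25
    households_per_cluster: int = 125     # mean; sizes vary 0.6-1.4x
    urban_fraction: float = 0.32
    wealth_region_sd: float = 0.5         # strength of region->wealth confounding
    wealth_urban_shift: float = 0.9
    applicability_rates: dict = field(
        default_factory=lambda: {"diarrhoea": 0.25, "cough": 0.30})
    component_coefficients: dict = field(
        default_factory=lambda: dict(DEFAULT_COMPONENT_COEFFICIENTS))
    seed: int = 20180527

    def validate(self):
        if self.clusters_per_stratum <= 0:
            raise ConfigurationError("clusters_per_stratum must be > 0")
        if self.households_per_cluster <= 0:
            raise ConfigurationError("households_per_cluster must be > 0")
        if not 0.0 <= self.urban_fraction <= 1.0:
            raise ConfigurationError("urban_fraction must lie in [0, 1]")
        for k, v in self.applicability_rates.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(
                    f"applicability_rates[{k!r}] must lie in [0, 1]")
        if set(self.applicability_rates) != {"diarrhoea", "cough"}:
            raise ConfigurationError(
                "applicability_rates must define diarrhoea and cough")
        if set(self.component_coefficients) != set(COMPONENTS):
            raise ConfigurationError(
                "component_coefficients must give exactly one vector per "
                f"CCI component {sorted(COMPONENTS)}")
        for comp, beta in self.component_coefficients.items():
            if len(beta) != len(COMPONENT_FEATURES):
                raise ConfigurationError(
                    f"component_coefficients[{comp!r}] must have "
                    f"{len(COMPONENT_FEATURES)} entries ({COMPONENT_FEATURES})")
        if len(set(self.regions)) != len(self.regions):
            raise ConfigurationError("regions must be unique")

    def to_dict(self):
        d = asdict(self)
        d["regions"] = list(self.regions)
        d["component_coefficients"] = {
            k: list(v) for k, v in self.component_coefficients.items()}
        return d


@dataclass
class PopulationTruth:
    """Ground truth of the generated finite population."""

    component_coefficients: dict
    region_optimal_proportion: dict
    marginal_optimal_proportion: float
    population_size: int
    seed: int

    def to_dict(self):
        return {
            "component_coefficients": {
                k: list(v) for k, v in self.component_coefficients.items()},
            "region_optimal_proportion": dict(self.region_optimal_proportion),
            "marginal_optimal_proportion": self.marginal_optimal_proportion,
            "population_size": self.population_size,
            "seed": self.seed,
        }


def _invlogit(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_population(config: SimulationConfig):
    """Generate the finite population and its ground truth.

    Returns (DataFrame, PopulationTruth).  One row per eligible woman-child
    pair (one per household).  ORT is non-missing iff the child had a
    diarrhoea episode; CPNM iff a cough episode.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    frames = []
    cluster_id = 0
    for region in config.regions:
        for urban in (1, 0):
            stratum = f"{region}|{'urban' if urban else 'rural'}"
            n_clusters = config.clusters_per_stratum
            sizes = rng.integers(
                int(np.ceil(0.6 * config.households_per_cluster)),
                int(np.floor(1.4 * config.households_per_cluster)) + 1,
                size=n_clusters)
            for size in sizes:
                frames.append((region, urban, stratum, cluster_id, int(size)))
                cluster_id += 1
    rows_region, rows_urban, rows_stratum, rows_cluster, rows_hh = [], [], [], [], []
    for region, urban, stratum, cid, size in frames:
        rows_region.extend([region] * size)
        rows_urban.extend([urban] * size)
        rows_stratum.extend([stratum] * size)
        rows_cluster.extend([cid] * size)
        rows_hh.extend(range(size))
    n = len(rows_region)
    df = pd.DataFrame({
        "region": rows_region,
        "urban": np.array(rows_urban, dtype=int),
        "stratum_id": rows_stratum,
        "cluster_id": np.array(rows_cluster, dtype=int),
        "household_id": np.array(rows_hh, dtype=int),
    })

    region_shift = np.array([DEFAULT_REGION_WEALTH.get(r, 0.0)
                             for r in df["region"]])
    latent = (config.wealth_region_sd * region_shift
              + config.wealth_urban_shift * df["urban"].to_numpy()
              + rng.normal(size=n))
    # population quintiles of the latent index -> 1..5
    q = np.quantile(latent, [0.2, 0.4, 0.6, 0.8])
    df["wealth_quintile"] = (np.searchsorted(q, latent, side="right") + 1)
    wq_c = df["wealth_quintile"].to_numpy() - 3.0

    urban_arr = df["urban"].to_numpy(dtype=float)
    edu_lin = -1.2 + 0.55 * wq_c + 0.7 * urban_arr + rng.normal(size=n)
    df["mother_edu"] = pd.cut(
        edu_lin, [-np.inf, 0.45, 1.0, 2.1, np.inf],
        labels=["none", "primary", "secondary", "higher"]).astype(str)
    pedu_lin = -0.9 + 0.5 * wq_c + 0.6 * urban_arr + rng.normal(size=n)
    df["partner_edu"] = pd.cut(
        pedu_lin, [-np.inf, 0.35, 0.85, 1.7, np.inf],
        labels=["none", "primary", "secondary", "higher"]).astype(str)
    df["newspaper"] = rng.binomial(
        1, _invlogit(-3.3 + 0.5 * wq_c + 0.6 * urban_arr))
    df["radio"] = rng.binomial(1, _invlogit(0.55 + 0.30 * wq_c))
    df["tv"] = rng.binomial(1, _invlogit(-0.9 + 0.8 * wq_c + 1.0 * urban_arr))
    df["working"] = rng.binomial(1, 0.77, size=n)
    df["married"] = rng.binomial(1, 0.93, size=n)
    df["planned_pregnancy"] = rng.binomial(1, 0.74, size=n)
    df["anc4"] = rng.binomial(
        1, _invlogit(-0.3 + 0.35 * wq_c + 0.45 * urban_arr))
    df["child_sex"] = np.where(rng.random(n) < 0.51, "male", "female")
    df["child_age"] = rng.integers(1, 5, size=n)
    df["diarrhoea"] = rng.binomial(
        1, config.applicability_rates["diarrhoea"], size=n)
    df["cough"] = rng.binomial(1, config.applicability_rates["cough"], size=n)

    feats = np.column_stack([
        np.ones(n), wq_c, df["anc4"].to_numpy(dtype=float), urban_arr,
        (df["mother_edu"] != "none").astype(float),
        df["planned_pregnancy"].to_numpy(dtype=float),
        df["radio"].to_numpy(dtype=float),
    ])
    for comp in COMPONENTS:
        beta = np.asarray(config.component_coefficients[comp], dtype=float)
        p = _invlogit(feats @ beta)
        x = rng.binomial(1, p).astype(float)
        if comp == "ORT":
            x = np.where(df["diarrhoea"].to_numpy() == 1, x, np.nan)
        elif comp == "CPNM":
            x = np.where(df["cough"].to_numpy() == 1, x, np.nan)
        df[comp] = x

    scored = score_records(df, na_policy="renormalise")
    optimal = (scored["cci_label"] == OPTIMAL)
    truth = PopulationTruth(
        component_coefficients={k: tuple(v) for k, v in
                                config.component_coefficients.items()},
        region_optimal_proportion={
            r: float(optimal[df["region"] == r].mean())
            for r in config.regions},
        marginal_optimal_proportion=float(optimal.mean()),
        population_size=n,
        seed=config.seed)
    return df, truth


def draw_sample(population: pd.DataFrame, clusters_per_stratum: int,
                households_per_cluster: int, seed: int):
    """Two-stage sample: systematic PPS clusters, systematic households.

    Returns (sample DataFrame with a ``weight`` column, warnings list).
    Weights are un-normalised inverse inclusion probabilities; the census
    case (all clusters, all households) yields weights of exactly 1.
    """
    if clusters_per_stratum <= 0 or households_per_cluster <= 0:
        raise SamplingError("sample sizes must be > 0")
    rng = np.random.default_rng(seed)
    warn = []
    # positional row indices per (stratum, cluster), computed once
    strat_of_cluster = {}
    cluster_rows = {}
    grp = population.groupby(["stratum_id", "cluster_id"], sort=True).indices
    for (stratum, c), idx in grp.items():
        strat_of_cluster.setdefault(stratum, []).append(c)
        cluster_rows[(stratum, c)] = np.asarray(idx)
    take_rows, take_weights = [], []
    for stratum in sorted(strat_of_cluster):
        clusters = np.array(sorted(strat_of_cluster[stratum]))
        sizes = np.array([len(cluster_rows[(stratum, c)]) for c in clusters])
        m = clusters_per_stratum
        if m > len(clusters):
            raise SamplingError(
                f"stratum {stratum!r} has {len(clusters)} clusters, "
                f"{m} requested")
        if m == len(clusters):      # take-all first stage
            chosen = clusters
            pi1 = {c: 1.0 for c in clusters}
        else:
            order = rng.permutation(len(clusters))
            sz, cl = sizes[order], clusters[order]
            total = sz.sum()
            step = total / m
            start = rng.random() * step
            points = start + step * np.arange(m)
            cum = np.cumsum(sz)
            pick_idx = np.unique(np.searchsorted(cum, points, side="right"))
            chosen = cl[pick_idx]
            size_of = dict(zip(clusters, sizes))
            pi1 = {c: min(1.0, m * size_of[c] / total) for c in chosen}
        for c in chosen:
            rows = cluster_rows[(stratum, c)]
            size = len(rows)
            h = households_per_cluster
            if h >= size:
                sel = rows
                pi2 = 1.0
            else:
                step = size / h
                start = rng.random() * step
                pos = (start + step * np.arange(h)).astype(int)
                perm = rng.permutation(size)
                sel = rows[perm[pos]]
                pi2 = h / size
            take_rows.append(sel)
            take_weights.append(np.full(len(sel), 1.0 / (pi1[c] * pi2)))
    if clusters_per_stratum == 1:
        warn.append("single PSU per stratum: design-based variance is not "
                    "estimable without a single-PSU rule")
        warnings.warn(warn[-1], stacklevel=2)
    sample = population.iloc[np.concatenate(take_rows)].copy()
    sample["weight"] = np.concatenate(take_weights)
    sample.reset_index(drop=True, inplace=True)
    return sample, warn


def guinea_adjacency() -> dict:
    """First-order adjacency of Guinea's 8 administrative regions.

    Encoded once from the regional map (Conakry is the peninsula enclave
    within Kindia; the highlands chain Labé-Mamou-Faranah links west to
    east; the forest region borders Kankan and Faranah).
    """
    adj = {
        "Boké": ["Kindia", "Labé"],
        "Conakry": ["Kindia"],
        "Faranah": ["Mamou", "Labé", "Kankan", "N'Zérékoré"],
        "Kankan": ["Faranah", "N'Zérékoré"],
        "Kindia": ["Conakry", "Boké", "Mamou", "Labé"],
        "Labé": ["Boké", "Kindia", "Mamou", "Faranah"],
        "Mamou": ["Kindia", "Labé", "Faranah"],
        "N'Zérékoré": ["Faranah", "Kankan"],
    }
    return adj
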