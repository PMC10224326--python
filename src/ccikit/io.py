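"""Microdata I/O, configuration, and the end-to-end analysis pipeline.

The microdata interchange format is a plain CSV: comma-separated, UTF-8,
"." decimal, empty field = missing/not-applicable, one row per woman-child
pair, with the canonical columns of :data:`MICRODATA_COLUMNS`.  The region
adjacency travels as a JSON object {region: [neighbours]}.

``run_pipeline`` chains the full analysis: CCI scoring, coverage and
component tables, design-based bivariate tests, backward-AIC survey
logistic regression with a Hosmer-Lemeshow check and an OR table, global
and local Moran spatial statistics over regional coverage, and a
classification tree on the selected covariates.  A JSON manifest records
every option and seed so a rerun reproduces the bundle exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cci as cci_mod
from .cci import COMPONENTS, CONDITIONAL, score_records, coverage_table, component_table
from .design import SurveyDesign, rao_scott_test, svy_ranksum
from .errors import ConfigurationError, DataError
from .logit import (ModelSpec, Term, backward_stepwise_aic, hosmer_lemeshow,
                    or_table)
from .simulate import SimulationConfig, generate_population, draw_sample, \
    guinea_adjacency
from .spatial import build_weights, regional_cci_surface
from .tree import TreeParams, grow_tree, export_tree

log = logging.getLogger("ccikit")

#: Canonical microdata columns (the data dictionary).
MICRODATA_COLUMNS = [
    "survey_year", "region", "stratum_id", "cluster_id", "household_id",
    "weight", "urban", "wealth_quintile", "mother_edu", "partner_edu",
    "newspaper", "radio", "tv", "working", "married", "planned_pregnancy",
    "anc4", "child_sex", "child_age", "diarrhoea", "cough",
] + list(COMPONENTS)

MANDATORY_COLUMNS = ["region", "stratum_id", "cluster_id", "weight"] + \
    [c for c in COMPONENTS if c not in CONDITIONAL]

#: Default covariates offered to the stepwise selection, with types.
DEFAULT_PREDICTORS = [
    ("wealth_quintile", "categorical", 5),     # reference: richest
    ("mother_edu", "categorical", "higher"),
    ("partner_edu", "categorical", "higher"),
    ("newspaper", "categorical", 1),
    ("radio", "categorical", 1),
    ("tv", "categorical", 1),
    ("working", "categorical", 0),
    ("married", "categorical", 1),
    ("planned_pregnancy", "categorical", 0),
    ("anc4", "categorical", 0),
    ("child_sex", "categorical", "female"),
    ("urban", "categorical", 1),
]


@dataclass
class ValidationReport:
    n_rows: int
    missing_by_column: dict
    problems: list    # [(row_number, message)]

    def to_dict(self):
        return {"n_rows": self.n_rows,
                "missing_by_column": self.missing_by_column,
                "problems": [list(p) for p in self.problems]}


def read_microdata(path, regions=None):
    """Read and validate a microdata CSV.

    Returns (DataFrame, ValidationReport).  Raises on schema errors
    (missing mandatory column, empty file); record-level invariant
    violations are listed in the report with their row numbers.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise DataError(f"{path}: empty file") from exc
    if len(df) == 0:
        raise DataError(f"{path}: no records")
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise DataError(f"{path}: missing mandatory column {col!r}")
    problems = []
    if (df["weight"] <= 0).any():
        for i in df.index[df["weight"] <= 0]:
            problems.append((int(i) + 2, "weight must be > 0"))
    if regions is not None:
        bad = ~df["region"].isin(regions)
        for i in df.index[bad]:
            problems.append((int(i) + 2,
                             f"unknown region {df.loc[i, 'region']!r}"))
    for comp in COMPONENTS:
        if comp not in df.columns:
            continue
        vals = df[comp].dropna()
        bad = ~vals.isin([0, 1])
        for i in vals.index[bad]:
            problems.append((int(i) + 2,
                             f"component {comp} must be 0/1, got "
                             f"{vals[i]!r}"))
        if comp not in CONDITIONAL:
            for i in df.index[df[comp].isna()]:
                problems.append((int(i) + 2, f"component {comp} missing"))
    missing = {c: int(df[c].isna().sum()) for c in df.columns}
    return df, ValidationReport(len(df), missing, problems)


def write_microdata(df: pd.DataFrame, path):
    """Write microdata CSV in the canonical dialect (empty = missing)."""
    cols = [c for c in MICRODATA_COLUMNS if c in df.columns] + \
        [c for c in df.columns if c not in MICRODATA_COLUMNS]
    df.to_csv(path, index=False, columns=cols)


def read_adjacency(path) -> dict:
    with open(path) as fh:
        adj = json.load(fh)
    if not isinstance(adj, dict):
        raise DataError(f"{path}: adjacency must be a JSON object")
    return adj


def write_adjacency(adj: dict, path):
    with open(path, "w") as fh:
        json.dump(adj, fh, ensure_ascii=False, indent=1)


@dataclass
class PipelineConfig:
    """Configuration of the end-to-end analysis."""

    microdata: str = None           # input CSV path ...
    adjacency: str = None           # ... and adjacency JSON, or:
    simulate: dict = None           # SimulationConfig fields
    sample: dict = field(default_factory=lambda: {
        "clusters_per_stratum": 8, "households_per_cluster": 30})
    na_policy: str = "renormalise"
    single_psu: str = "error"
    predictors: list = None         # [(name, kind, reference)]
    locked_terms: tuple = ()
    tree: dict = field(default_factory=lambda: {
        "max_depth": 4, "min_node_weight": 50.0, "min_improvement": 1e-3})
    spatial_style: str = "row-standardised"
    n_permutations: int = 999
    alpha: float = 0.05
    cci_class: str = "partial"
    decimals: int = 1
    seed: int = 20180527
    out_dir: str = "ccikit_out"

    def validate(self):
        has_input = self.microdata is not None
        has_sim = self.simulate is not None
        if has_input == has_sim:
            raise ConfigurationError(
                "exactly one of microdata/adjacency paths or a simulate "
                "block must be given")
        if has_input and self.adjacency is None:
            raise ConfigurationError("adjacency JSON required with microdata")

    @classmethod
    def from_file(cls, path):
        path = Path(path)
        with open(path) as fh:
            data = (json.load(fh) if path.suffix == ".json"
                    else yaml.safe_load(fh))
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write the report bundle.

    Returns the manifest dict.  Output files (CSV/JSON/text) land in
    ``config.out_dir``; any stage failure is recorded in the manifest
    before the exception propagates.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in config.__dict__.items()},
                "stages": [], "failure": None, "seeds": {"root": config.seed}}

    def stage(name):
        manifest["stages"].append(name)
        log.info("stage %s", name)

    try:
        stage("load")
        if config.simulate is not None:
            sim = SimulationConfig(**{**config.simulate,
                                      "seed": config.simulate.get(
                                          "seed", config.seed)})
            population, truth = generate_population(sim)
            manifest["seeds"]["population"] = sim.seed
            df, warns = draw_sample(population,
                                    config.sample["clusters_per_stratum"],
                                    config.sample["households_per_cluster"],
                                    seed=config.seed + 1)
            manifest["seeds"]["sample"] = config.seed + 1
            manifest["sampling_warnings"] = warns
            adjacency = guinea_adjacency()
            with open(out / "truth.json", "w") as fh:
                json.dump(truth.to_dict(), fh, indent=1, ensure_ascii=False,
                          default=_json_default)
            write_microdata(df, out / "microdata.csv")
        else:
            df, report = read_microdata(config.microdata)
            with open(out / "validation.json", "w") as fh:
                json.dump(report.to_dict(), fh, indent=1)
            if report.problems:
                raise DataError(
                    f"{len(report.problems)} invalid records; see "
                    f"{out / 'validation.json'}")
            adjacency = read_adjacency(config.adjacency)
        log.info("records in: %d", len(df))

        stage("cci")
        df = score_records(df, na_policy=config.na_policy)
        df.reset_index(drop=True, inplace=True)
        df.to_csv(out / "cci_scores.csv", index=False,
                  columns=["region", "stratum_id", "cluster_id", "weight",
                           "cci_score", "cci_label", "cci_renormalised"])
        design = SurveyDesign(df["stratum_id"], df["cluster_id"],
                              df["weight"], single_psu=config.single_psu)

        stage("tables")
        group = ["survey_year"] if "survey_year" in df.columns else []
        component_table(df, design=None, decimals=config.decimals,
                        group_by=group).to_csv(out / "table1_components.csv",
                                               index=False)
        coverage_table(df, design=design, group_by=group,
                       decimals=config.decimals).to_csv(
            out / "table2_cci.csv", index=False)

        stage("bivariate")
        predictors = config.predictors or DEFAULT_PREDICTORS
        biv_rows = []
        for name, kind, ref in predictors:
            if name not in df.columns:
                continue
            try:
                rs = rao_scott_test(design, df[name], df["cci_label"])
                biv_rows.append({"variable": name, "test": "rao_scott",
                                 "statistic": rs.statistic, "df": rs.df,
                                 "p": rs.p})
            except Exception as exc:   # constant variable etc.
                biv_rows.append({"variable": name, "test": "rao_scott",
                                 "statistic": np.nan, "df": np.nan,
                                 "p": np.nan, "note": str(exc)})
        # rank-sum for the quantitative covariates across the two CCI classes
        for qvar in ("child_age",):
            if qvar in df.columns:
                rk = svy_ranksum(design, df["cci_label"], df[qvar])
                biv_rows.append({"variable": qvar, "test": "svy_ranksum",
                                 "statistic": rk.statistic, "p": rk.p})
        pd.DataFrame(biv_rows).to_csv(out / "table3_bivariate.csv",
                                      index=False)

        stage("regression")
        df["cci_optimal"] = (df["cci_label"] == "optimal").astype(int)
        terms = tuple(Term(n, k, r) for n, k, r in predictors
                      if n in df.columns)
        full = ModelSpec("cci_optimal", terms)
        sel_spec, fit, trail = backward_stepwise_aic(df, design, full,
                                                     config.locked_terms)
        pd.DataFrame([{"dropped": s.dropped, "aic": s.aic}
                      for s in trail]).to_csv(out / "stepwise_trail.csv",
                                              index=False)
        or_table(fit, decimals=2).to_csv(out / "table4_or.csv", index=False)
        hl = hosmer_lemeshow(fit)
        with open(out / "hosmer_lemeshow.json", "w") as fh:
            json.dump(hl.to_dict(), fh, indent=1)

        stage("spatial")
        sw = build_weights(adjacency, style=config.spatial_style)
        table, moran, lisa = regional_cci_surface(
            df, design, sw, cci_class=config.cci_class,
            n_permutations=config.n_permutations, seed=config.seed + 2,
            alpha=config.alpha)
        manifest["seeds"]["spatial"] = config.seed + 2
        table.to_csv(out / "table5_lisa.csv", index=False)
        with open(out / "table5_moran.json", "w") as fh:
            json.dump(moran.to_dict(), fh, indent=1)

        stage("tree")
        tree_predictors = {t.name: t.kind for t in sel_spec.terms}
        if not tree_predictors:   # intercept-only selection: use full set
            tree_predictors = {t.name: t.kind for t in terms}
        tp = TreeParams(**config.tree)
        tree = grow_tree(df, df["weight"].to_numpy(), "cci_optimal",
                         tree_predictors, tp)
        with open(out / "tree.json", "w") as fh:
            json.dump(export_tree(tree, "json"), fh, indent=1)
        (out / "tree.txt").write_text(export_tree(tree, "text") + "\n")

        stage("manifest")
        manifest["n_records"] = int(len(df))
        manifest["selected_terms"] = [t.name for t in sel_spec.terms]
        manifest["final_aic"] = fit.aic
        manifest["moran_I"] = moran.I
        manifest["moran_p"] = moran.p_perm_two_sided
    except Exception as exc:
        manifest["failure"] = f"{type(exc).__name__}: {exc}"
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=_json_default)
        raise
    body = json.dumps(manifest, indent=1, sort_keys=True,
                      default=_json_default)
    manifest["manifest_sha256"] = hashlib.sha256(body.encode()).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=_json_default)
    return manifest
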