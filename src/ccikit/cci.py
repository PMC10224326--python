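"""Composite Coverage Index (CCI) scoring and coverage tables.

The CCI summarises eight preventive and curative interventions along the
maternal and child care continuum as a single weighted average in [0, 1]:

    CCI = 1/4 * ( FPS + (SBA + ANCS)/2 + (2*DTC3 + MSL + BCG)/4
                  + (ORT + CPNM)/2 )

i.e. component weights, in sixteenths: family planning satisfied (FPS) 4,
skilled birth attendance (SBA) 2, antenatal care by a qualified provider
(ANCS) 2, three pentavalent/DTC doses (DTC3) 2, measles (MSL) 1, BCG 1,
oral rehydration during diarrhoea (ORT) 2, care-seeking for cough/pneumonia
(CPNM) 2.  A record is classified *optimal* when CCI >= 0.50 and *partial*
otherwise.

ORT and CPNM are defined only for children who had a diarrhoea or cough
episode; the ``na_policy`` argument controls how not-applicable components
enter the score (the default renormalises the remaining weights).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, DomainError

#: The eight CCI components, in canonical order.
COMPONENTS = ("FPS", "SBA", "ANCS", "DTC3", "MSL", "BCG", "ORT", "CPNM")

#: Components that are defined for every record (never not-applicable).
ALWAYS_APPLICABLE = ("FPS", "SBA", "ANCS", "DTC3", "MSL", "BCG")

#: Components conditional on an illness episode.
CONDITIONAL = ("ORT", "CPNM")

#: Exact component weights (sixteenths), summing to 1.
CCI_WEIGHTS: Mapping[str, Fraction] = {
    "FPS": Fraction(4, 16),
    "SBA": Fraction(2, 16),
    "ANCS": Fraction(2, 16),
    "DTC3": Fraction(2, 16),
    "MSL": Fraction(1, 16),
    "BCG": Fraction(1, 16),
    "ORT": Fraction(2, 16),
    "CPNM": Fraction(2, 16),
}

NA_POLICIES = ("renormalise", "impute_zero", "impute_one", "drop_record")

PARTIAL = "partial"
OPTIMAL = "optimal"
OPTIMAL_THRESHOLD = 0.50


@dataclass
class CCIResult:
    """Per-record CCI score and dichotomised coverage label."""

    score: float
    label: str
    components_used: tuple
    renormalised: bool


def classify(score: float) -> str:
    """Dichotomise a CCI score: optimal iff score >= 0.50."""
    if not (0.0 <= score <= 1.0):
        raise DomainError(f"CCI score must lie in [0, 1], got {score!r}")
    return OPTIMAL if score >= OPTIMAL_THRESHOLD else PARTIAL


def compute_cci(record: Mapping, weights: Mapping = CCI_WEIGHTS,
                na_policy: str = "renormalise") -> CCIResult | None:
    """Score one woman-child record.

    ``record`` maps component names to 0/1, with ``None``/NaN allowed for the
    conditional components ORT and CPNM.  Returns ``None`` under
    ``na_policy='drop_record'`` when any component is not applicable.
    """
    if na_policy not in NA_POLICIES:
        raise ConfigurationError(
            f"unknown na_policy {na_policy!r}; expected one of {NA_POLICIES}")
    values = {}
    for comp in COMPONENTS:
        v = record.get(comp) if hasattr(record, "get") else record[comp]
        if v is None or (isinstance(v, float) and np.isnan(v)):
            if comp in ALWAYS_APPLICABLE:
                ident = record.get("record_id", "<record>") if hasattr(record, "get") else "<record>"
                raise DataError(
                    f"component {comp} missing for record {ident}; "
                    f"{comp} is always applicable")
            values[comp] = None
        else:
            v = int(v)
            if v not in (0, 1):
                raise DataError(f"component {comp} must be 0/1, got {v!r}")
            values[comp] = v

    missing = [c for c in COMPONENTS if values[c] is None]
    if not missing:
        score = float(sum(weights[c] * values[c] for c in COMPONENTS))
        return CCIResult(score, classify(score), COMPONENTS, False)

    if na_policy == "drop_record":
        return None
    if na_policy == "impute_zero":
        filled = {c: (0 if values[c] is None else values[c]) for c in COMPONENTS}
        score = float(sum(weights[c] * filled[c] for c in COMPONENTS))
        return CCIResult(score, classify(score), COMPONENTS, True)
    if na_policy == "impute_one":
        filled = {c: (1 if values[c] is None else values[c]) for c in COMPONENTS}
        score = float(sum(weights[c] * filled[c] for c in COMPONENTS))
        return CCIResult(score, classify(score), COMPONENTS, True)

    # renormalise: drop the missing components, rescale remaining weights to 1
    used = tuple(c for c in COMPONENTS if values[c] is not None)
    total = sum(weights[c] for c in used)
    score = float(sum(Fraction(weights[c], 1) * values[c] for c in used) / total)
    return CCIResult(score, classify(score), used, True)


def score_records(df: pd.DataFrame, na_policy: str = "renormalise",
                  weights: Mapping = CCI_WEIGHTS) -> pd.DataFrame:
    """Vectorised CCI over a microdata frame.

    Returns a copy of ``df`` with ``cci_score``, ``cci_label`` and
    ``cci_renormalised`` columns appended.  Under ``drop_record`` the rows
    with a not-applicable component are removed.
    """
    if na_policy not in NA_POLICIES:
        raise ConfigurationError(
            f"unknown na_policy {na_policy!r}; expected one of {NA_POLICIES}")
    for comp in ALWAYS_APPLICABLE:
        if comp not in df.columns:
            raise DataError(f"missing mandatory component column {comp}")
        bad = df[comp].isna()
        if bad.any():
            raise DataError(
                f"component {comp} missing for rows {list(df.index[bad][:5])}; "
                f"{comp} is always applicable")

    w = np.array([float(weights[c]) for c in COMPONENTS])
    X = df[list(COMPONENTS)].to_numpy(dtype=float)
    na_mask = np.isnan(X)

    if na_policy == "drop_record":
        keep = ~na_mask.any(axis=1)
        out = df.loc[keep].copy()
        scores = (X[keep] * w).sum(axis=1)
        out["cci_score"] = scores
        out["cci_label"] = np.where(scores >= OPTIMAL_THRESHOLD, OPTIMAL, PARTIAL)
        out["cci_renormalised"] = False
        return out

    out = df.copy()
    if na_policy == "impute_zero":
        filled = np.where(na_mask, 0.0, X)
        scores = (filled * w).sum(axis=1)
    elif na_policy == "impute_one":
        filled = np.where(na_mask, 1.0, X)
        scores = (filled * w).sum(axis=1)
    else:  # renormalise
        filled = np.where(na_mask, 0.0, X)
        avail = (~na_mask * w).sum(axis=1)
        scores = (filled * w).sum(axis=1) / avail
    out["cci_score"] = scores
    out["cci_label"] = np.where(scores >= OPTIMAL_THRESHOLD, OPTIMAL, PARTIAL)
    out["cci_renormalised"] = na_mask.any(axis=1)
    return out


def _weighted_pct(labels: np.ndarray, weights: np.ndarray, cls: str) -> float:
    tot = weights.sum()
    if tot <= 0:
        return float("nan")
    return float(weights[labels == cls].sum() / tot * 100.0)


def coverage_table(df: pd.DataFrame, design=None,
                   group_by: Iterable[str] = ("survey_year",),
                   decimals: int | None = None) -> pd.DataFrame:
    """Partial/optimal counts and proportions per group (printed-table shape).

    ``df`` must carry ``cci_label`` (see :func:`score_records`).  Reports, per
    group and class: unweighted n, unweighted %, weighted % and — when a
    survey ``design`` is given — a design-based standard error from Taylor
    linearisation.
    """
    if "cci_label" not in df.columns:
        raise DataError("records must be scored first (no cci_label column)")
    group_by = list(group_by)
    rows = []
    groups = df.groupby(group_by, observed=True, dropna=False) if group_by else [((), df)]
    for key, g in groups:
        if not isinstance(key, tuple):
            key = (key,)
        n = len(g)
        wts = g["weight"].to_numpy(dtype=float) if "weight" in g else np.ones(n)
        labels = g["cci_label"].to_numpy()
        for cls in (PARTIAL, OPTIMAL):
            n_cls = int((labels == cls).sum())
            unw = 100.0 * n_cls / n if n else float("nan")
            wpct = _weighted_pct(labels, wts, cls)
            row = dict(zip(group_by, key))
            row.update({
                "class": cls,
                "n_unweighted": n_cls,
                "n_group": n,
                "pct_unweighted": round(unw, decimals) if decimals is not None and n else unw,
                "pct_weighted": round(wpct, decimals) if decimals is not None and n else wpct,
            })
            if design is not None and n:
                from .design import design_proportion
                dom = df.index.isin(g.index).astype(float)
                ind = (df["cci_label"] == cls).astype(float).to_numpy()
                dp = design_proportion(design, ind, domain=dom)
                row["pct_weighted"] = round(dp.estimate * 100, decimals) if decimals is not None else dp.estimate * 100
                row["se_weighted_pct"] = dp.se * 100
            rows.append(row)
    return pd.DataFrame(rows)


def component_table(df: pd.DataFrame, design=None,
                    decimals: int | None = None,
                    group_by: Iterable[str] = ()) -> pd.DataFrame:
    """Per-component coverage (Yes proportion), conditional components over
    their applicable denominator only."""
    group_by = list(group_by)
    rows = []
    groups = df.groupby(group_by, observed=True, dropna=False) if group_by else [((), df)]
    for key, g in groups:
        if not isinstance(key, tuple):
            key = (key,)
        for comp in COMPONENTS:
            col = g[comp]
            applicable = col.notna()
            denom = int(applicable.sum())
            row = dict(zip(group_by, key))
            row.update({"component": comp, "n_applicable": denom})
            if denom == 0:
                row.update({"n_yes": 0, "pct_unweighted": float("nan"),
                            "pct_weighted": float("nan")})
            else:
                x = col[applicable].to_numpy(dtype=float)
                wts = (g.loc[applicable, "weight"].to_numpy(dtype=float)
                       if "weight" in g else np.ones(denom))
                n_yes = int(x.sum())
                unw = 100.0 * n_yes / denom
                wpct = float((x * wts).sum() / wts.sum() * 100.0)
                row.update({
                    "n_yes": n_yes,
                    "pct_unweighted": round(unw, decimals) if decimals is not None else unw,
                    "pct_weighted": round(wpct, decimals) if decimals is not None else wpct,
                })
                if design is not None:
                    from .design import design_proportion
                    dom = (df.index.isin(g.index) & df[comp].notna()).astype(float)
                    ind = df[comp].fillna(0).astype(float).to_numpy()
                    dp = design_proportion(design, ind, domain=dom.to_numpy()
                                           if hasattr(dom, "to_numpy") else dom)
                    row["se_weighted_pct"] = dp.se * 100
            rows.append(row)
    return pd.DataFrame(rows)
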