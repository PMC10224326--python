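"""Survey-weighted logistic regression with AIC stepwise selection.

Point estimation is pseudo-maximum-likelihood: beta maximises the weighted
log-likelihood  sum_i w_i [ y_i log p_i + (1-y_i) log(1-p_i) ]  by
iteratively reweighted least squares.  Inference is design-based: the
covariance is the sandwich  A^-1 B A^-1  with A the weighted observed
information and B the with-replacement between-PSU covariance of the score
totals within strata (delegated to :class:`ccikit.design.SurveyDesign`).

The AIC of a pseudo-likelihood is not uniquely defined; here the weights
are normalised to mean 1 inside the AIC so that AIC scales with n rather
than with the sum of the weights, making model comparison invariant to the
weight scale.  Backward elimination drops whole categorical blocks, one
term per step, choosing the removal with the lowest AIC until no removal
improves it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import SurveyDesign
from .errors import ConfigurationError, DataError, FitError

_SEP_BOUND = 15.0   # |beta| beyond this flags quasi-separation


@dataclass(frozen=True)
class Term:
    """One model term: a covariate with its declared type."""

    name: str
    kind: str = "categorical"        # categorical | ordinal | numeric
    reference: object = None         # reference level (categorical only)

    def __post_init__(self):
        if self.kind not in ("categorical", "ordinal", "numeric"):
            raise ConfigurationError(
                f"term {self.name!r}: unknown kind {self.kind!r}")


@dataclass(frozen=True)
class ModelSpec:
    """Response + main-effect terms (the models here use no interactions)."""

    response: str
    terms: tuple

    def __post_init__(self):
        names = [t.name for t in self.terms]
        if self.response in names:
            raise ConfigurationError("response cannot appear among predictors")
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate predictor names")

    def drop(self, term_name: str) -> "ModelSpec":
        return ModelSpec(self.response,
                         tuple(t for t in self.terms if t.name != term_name))


def build_design_matrix(df: pd.DataFrame, spec: ModelSpec):
    """Reference-level dummy coding.  Returns (X, y, column meta, row mask).

    Complete-case: rows with a missing response or predictor are dropped and
    counted in the returned mask.
    """
    cols = [spec.response] + [t.name for t in spec.terms]
    for c in cols:
        if c not in df.columns:
            raise DataError(f"column {c!r} not in data")
    mask = df[cols].notna().all(axis=1).to_numpy()
    sub = df.loc[mask]
    y = sub[spec.response].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise DataError(f"response {spec.response!r} must be binary 0/1")
    blocks = [("Intercept", None)]
    refs = {}
    X_cols = [np.ones(len(sub))]
    for t in spec.terms:
        v = sub[t.name]
        if t.kind in ("numeric", "ordinal"):
            if t.kind == "ordinal" and not np.issubdtype(v.dtype, np.number):
                v = pd.Categorical(v).codes.astype(float)
            X_cols.append(np.asarray(v, dtype=float))
            blocks.append((t.name, None))
        else:
            cat = pd.Categorical(v)
            levels = list(cat.categories)
            ref = t.reference if t.reference is not None else levels[0]
            if ref not in levels:
                raise ConfigurationError(
                    f"reference level {ref!r} absent from {t.name!r}")
            refs[t.name] = ref
            for lev in levels:
                if lev == ref:
                    continue
                X_cols.append((cat == lev).astype(float))
                blocks.append((t.name, lev))
    X = np.column_stack(X_cols)
    return X, y, blocks, mask, refs


@dataclass
class LogisticFit:
    """Pseudo-MLE coefficients with design-based (sandwich) inference."""

    params: pd.Series
    cov: pd.DataFrame
    aic: float
    loglike: float            # weighted log-pseudolikelihood, mean-1 weights
    n: int
    n_dropped: int
    converged: bool
    separation: bool
    spec: ModelSpec
    blocks: list
    references: dict
    fitted: np.ndarray
    design: SurveyDesign = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)
    fit_weights: np.ndarray = field(repr=False, default=None)

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.clip(np.diag(self.cov.to_numpy()), 0,
                                         None)),
                         index=self.params.index)

    def odds_ratios(self, ci_level: float = 0.95) -> pd.DataFrame:
        z = stats.norm.ppf(0.5 + ci_level / 2)
        se = self.se
        zstat = self.params / se
        return pd.DataFrame({
            "OR": np.exp(self.params),
            "ci_low": np.exp(self.params - z * se),
            "ci_high": np.exp(self.params + z * se),
            "p": 2 * stats.norm.sf(np.abs(zstat)),
        })


def _param_names(blocks):
    return [b[0] if b[1] is None else f"{b[0]}[{b[1]}]" for b in blocks]


def fit_svy_logistic(df: pd.DataFrame, design: SurveyDesign,
                     spec: ModelSpec, max_iter: int = 50,
                     tol: float = 1e-10) -> LogisticFit:
    """Fit the survey-weighted logistic regression defined by ``spec``."""
    X, y, blocks, mask, refs = build_design_matrix(df, spec)
    n_dropped = int((~mask).sum())
    w_full = design.weights
    if len(w_full) != len(df):
        raise DataError("design length does not match data")
    w = w_full[mask]
    n, k = X.shape
    if n == 0:
        raise FitError("no complete cases")
    if np.linalg.matrix_rank(X) < k:
        raise FitError("design matrix not full column rank after encoding")

    def loglike(b):
        eta = np.clip(X @ b, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        return float(np.sum(w * (y * np.log(p) + (1 - y) * np.log1p(-p)))), p

    beta = np.zeros(k)
    ll, p = loglike(beta)
    converged = False
    for _ in range(max_iter):
        Wd = w * p * (1 - p)
        score = X.T @ (w * (y - p))
        A = X.T @ (X * Wd[:, None])
        try:
            step = np.linalg.solve(A + 1e-12 * np.eye(k), score)
        except np.linalg.LinAlgError as exc:
            raise FitError(f"singular information matrix: {exc}",
                           last_params=beta) from exc
        # step halving keeps the weighted likelihood non-decreasing
        # (quasi-separation otherwise makes plain Newton oscillate)
        new_ll, new_p = loglike(beta + step)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 30:
            step *= 0.5
            halvings += 1
            new_ll, new_p = loglike(beta + step)
        beta = beta + step
        if np.max(np.abs(step)) < tol or abs(new_ll - ll) < 1e-10 * (abs(ll) + 1):
            ll, p = new_ll, new_p
            converged = True
            break
        ll, p = new_ll, new_p
    if not converged:
        raise FitError("IRLS did not converge", last_params=beta)
    separation = bool(np.max(np.abs(beta)) > _SEP_BOUND)
    if separation:
        import warnings
        warnings.warn("possible separation: |beta| exceeds bound",
                      stacklevel=2)

    eta = np.clip(X @ beta, -30, 30)
    p = 1.0 / (1.0 + np.exp(-eta))
    Wd = w * p * (1 - p)
    A = X.T @ (X * Wd[:, None])
    # sandwich B: between-PSU covariance of score totals over the full design
    # (zero contributions for dropped rows keep stratum/PSU structure intact)
    U = np.zeros((design.n, k))
    U[mask] = (w * (y - p))[:, None] * X
    B = design.linearized_cov(U)
    Ainv = np.linalg.inv(A)
    cov = Ainv @ B @ Ainv

    w1 = w / w.mean()
    with np.errstate(divide="ignore"):
        ll = float(np.sum(w1 * (y * np.log(p) + (1 - y) * np.log1p(-p))))
    aic = -2.0 * ll + 2.0 * k
    names = _param_names(blocks)
    return LogisticFit(
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        aic=aic, loglike=ll, n=n, n_dropped=n_dropped,
        converged=converged, separation=separation, spec=spec,
        blocks=blocks, references=refs, fitted=p, design=design, y=y,
        fit_weights=w)


@dataclass
class StepRecord:
    dropped: str
    aic: float


def backward_stepwise_aic(df: pd.DataFrame, design: SurveyDesign,
                          full_spec: ModelSpec, locked_terms=()):
    """Backward elimination by AIC.

    At each step the single term (whole categorical block) whose removal
    yields the lowest AIC is dropped; stops when no removal lowers the AIC.
    Ties within 1e-9 resolve to the term earliest in the spec order.
    Returns (selected spec, final fit, trail of StepRecord).
    """
    import warnings as _warnings
    locked = set(locked_terms)
    n_separation = 0
    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always")
        fit = fit_svy_logistic(df, design, full_spec)
        trail = [StepRecord("<full>", fit.aic)]
        spec = full_spec
        while True:
            candidates = [t.name for t in spec.terms if t.name not in locked]
            if not candidates:
                break
            best_name, best_fit = None, None
            for name in candidates:   # spec order => earliest wins ties
                try:
                    cand_fit = fit_svy_logistic(df, design, spec.drop(name))
                except FitError:
                    continue
                if best_fit is None or cand_fit.aic < best_fit.aic - 1e-9:
                    best_name, best_fit = name, cand_fit
            if best_fit is None or best_fit.aic >= fit.aic - 1e-9:
                break
            spec, fit = spec.drop(best_name), best_fit
            trail.append(StepRecord(best_name, fit.aic))
        n_separation = sum("separation" in str(w.message) for w in caught)
        for w in caught:
            if "separation" not in str(w.message):
                _warnings.warn_explicit(w.message, w.category, w.filename,
                                        w.lineno)
    if n_separation:
        import warnings
        warnings.warn(f"possible separation in {n_separation} candidate "
                      "fit(s) during stepwise search", stacklevel=2)
    return spec, fit, trail


@dataclass
class HosmerLemeshowResult:
    statistic: float
    df: int
    p: float
    table: pd.DataFrame   # per group: weighted n, observed, expected, p_mean

    def to_dict(self):
        return {"statistic": self.statistic, "df": self.df, "p": self.p,
                "method": "Hosmer-Lemeshow (weighted deciles of risk)",
                "options": {"groups": int(self.df + 2)}}


def hosmer_lemeshow(fit: LogisticFit, g: int = 10) -> HosmerLemeshowResult:
    """Grouped observed-vs-expected calibration chi-square, df = g - 2.

    Records are sorted by fitted probability and cut into g groups of
    near-equal weighted size; the statistic is
    sum_g (O_g - E_g)^2 / (W_g pbar_g (1 - pbar_g)).
    """
    if g < 3:
        raise ConfigurationError("g must be >= 3")
    p = fit.fitted
    y = fit.y
    w = fit.fit_weights
    n_distinct = len(np.unique(p))
    if n_distinct < g:
        import warnings
        warnings.warn(f"only {n_distinct} distinct fitted values; "
                      f"reducing groups to {n_distinct}", stacklevel=2)
        g = max(3, n_distinct)
    order = np.argsort(p, kind="mergesort")
    ps, ys, ws = p[order], y[order], w[order]
    cumw = np.cumsum(ws)
    W = cumw[-1]
    edges = np.searchsorted(cumw, W * np.arange(1, g) / g, side="left") + 1
    # never split a block of tied fitted probabilities across groups
    snapped = []
    for e in edges:
        while 0 < e < len(ps) and ps[e] == ps[e - 1]:
            e += 1
        if e < len(ps):
            snapped.append(e)
    edges = sorted(set(snapped))
    idx_groups = np.split(np.arange(len(ps)), edges)
    rows, stat = [], 0.0
    for gi, idx in enumerate(idx_groups):
        if len(idx) == 0:
            continue
        Wg = ws[idx].sum()
        O = float((ws[idx] * ys[idx]).sum())
        E = float((ws[idx] * ps[idx]).sum())
        pbar = E / Wg
        denom = Wg * pbar * (1 - pbar)
        if denom > 0:
            stat += (O - E) ** 2 / denom
        rows.append({"group": gi + 1, "weighted_n": Wg, "observed": O,
                     "expected": E, "mean_p": pbar})
    df_ = len(rows) - 2
    p_val = float(stats.chi2.sf(stat, df_)) if df_ >= 1 else float("nan")
    return HosmerLemeshowResult(float(stat), df_, p_val, pd.DataFrame(rows))


def or_table(fit: LogisticFit, decimals: int = 2,
             ci_level: float = 0.95) -> pd.DataFrame:
    """Publication-style adjusted-OR table with reference rows marked em-dash."""
    ors = fit.odds_ratios(ci_level)
    rows = []
    for t in fit.spec.terms:
        if t.kind in ("numeric", "ordinal"):
            r = ors.loc[t.name]
            rows.append({"term": t.name, "level": "",
                         "OR": round(r.OR, decimals),
                         "95% CI": f"{r.ci_low:.{decimals}f}, "
                                   f"{r.ci_high:.{decimals}f}",
                         "p": _fmt_p(r.p)})
            continue
        levels = [b[1] for b in fit.blocks if b[0] == t.name]
        ref = fit.references.get(t.name, "(reference)")
        rows.append({"term": t.name, "level": str(ref),
                     "OR": "—", "95% CI": "—", "p": "—"})
        for lev in levels:
            r = ors.loc[f"{t.name}[{lev}]"]
            rows.append({"term": t.name, "level": str(lev),
                         "OR": round(r.OR, decimals),
                         "95% CI": f"{r.ci_low:.{decimals}f}, "
                                   f"{r.ci_high:.{decimals}f}",
                         "p": _fmt_p(r.p)})
    return pd.DataFrame(rows)


def _fmt_p(p: float) -> str:
    return "< 0.001" if p < 0.001 else f"{p:.3g}"
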