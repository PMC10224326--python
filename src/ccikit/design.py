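"""Design-based estimation for two-stage stratified cluster samples.

Variance estimation throughout is first-order Taylor linearisation with the
with-replacement PSU approximation: the covariance of an estimator whose
influence contributions are u_i is built from the between-PSU variability of
the PSU totals of u within strata,

    V = sum_h  n_h/(n_h - 1) * sum_j (t_hj - tbar_h)(t_hj - tbar_h)'

with t_hj the total of u over PSU j of stratum h.  No finite-population
correction is applied and no replicate-weight methods are provided.

Implements the estimators and bivariate tests used in complex-survey
maternal and child health analyses: weighted proportions with logit-scale
confidence intervals and design effects, the Rao-Scott second-order
(Satterthwaite) corrected chi-square test of independence, and a
design-based Wilcoxon rank-sum (mean rank-score Wald) test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, EstimationError, TestError


class SurveyDesign:
    """Stratum / PSU / weight structure governing all variance estimation.

    Parameters
    ----------
    strata, psu : array-like
        Stratum and primary-sampling-unit identifier per record.  PSU ids
        are interpreted within stratum.
    weights : array-like
        Positive sampling weights (inverse inclusion probabilities, any
        scale; all estimators here are ratio-type and scale invariant).
    normalize : {"raw", "mean1"}
        "mean1" rescales weights to mean 1 at construction.
    single_psu : {"error", "center"}
        What to do with strata containing a single PSU: raise, or centre
        that PSU's total at the grand mean of PSU totals (contributing its
        squared deviation with factor 1).
    """

    def __init__(self, strata, psu, weights, *, normalize="raw",
                 single_psu="error"):
        strata = np.asarray(strata)
        psu = np.asarray(psu)
        weights = np.asarray(weights, dtype=float)
        if not (len(strata) == len(psu) == len(weights)):
            raise DataError("strata, psu and weights must have equal length")
        if len(weights) == 0:
            raise DataError("empty design")
        if not np.all(weights > 0):
            raise DataError("all weights must be > 0")
        if normalize not in ("raw", "mean1"):
            raise DataError(f"unknown weight normalisation {normalize!r}")
        if single_psu not in ("error", "center"):
            raise DataError(f"unknown single_psu rule {single_psu!r}")
        if normalize == "mean1":
            weights = weights / weights.mean()
        self.weights = weights
        self.single_psu = single_psu
        # integer codes for (stratum, psu-within-stratum)
        self._stratum_codes, self._strata_uniq = pd.factorize(strata)
        combo = pd.MultiIndex.from_arrays([strata, psu])
        self._psu_codes, psu_uniq = pd.factorize(combo)
        self._psu_stratum = pd.factorize(psu_uniq.get_level_values(0))[0]
        self.n = len(weights)
        self.n_strata = len(self._strata_uniq)
        self.n_psu = len(psu_uniq)
        counts = np.bincount(self._psu_stratum, minlength=self.n_strata)
        self.lonely_strata = [self._strata_uniq[h] for h in
                              np.nonzero(counts == 1)[0]]
        if self.lonely_strata:
            if single_psu == "error":
                raise DataError(
                    "strata with a single PSU (variance not estimable): "
                    f"{self.lonely_strata}; pass single_psu='center' to "
                    "centre them at the grand mean")
            warnings.warn(
                f"single-PSU strata {self.lonely_strata} centred at the "
                "grand mean of PSU totals", stacklevel=2)

    @property
    def design_df(self) -> int:
        """Design degrees of freedom: #PSUs - #strata."""
        return self.n_psu - self.n_strata

    def psu_totals(self, U: np.ndarray) -> np.ndarray:
        """Totals of the columns of U over PSUs (n_psu x q)."""
        U = np.atleast_2d(np.asarray(U, dtype=float).T).T
        out = np.zeros((self.n_psu, U.shape[1]))
        np.add.at(out, self._psu_codes, U)
        return out

    def linearized_cov(self, U: np.ndarray) -> np.ndarray:
        """With-replacement covariance of the vector of totals of U.

        U is an (n x q) matrix of per-record linearised contributions
        (already carrying the weights).
        """
        T = self.psu_totals(U)
        q = T.shape[1]
        V = np.zeros((q, q))
        grand_mean = T.mean(axis=0)
        for h in range(self.n_strata):
            sel = self._psu_stratum == h
            n_h = int(sel.sum())
            Th = T[sel]
            if n_h == 1:
                d = Th[0] - grand_mean
                V += np.outer(d, d)
                continue
            D = Th - Th.mean(axis=0)
            V += (n_h / (n_h - 1)) * D.T @ D
        return V


@dataclass
class DesignProportion:
    """Weighted proportion with linearised SE and logit-scale 95% CI."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    n_unweighted: int
    deff: float

    def to_dict(self):
        return {"estimate": self.estimate, "se": self.se,
                "ci_low": self.ci_low, "ci_high": self.ci_high,
                "n": self.n_unweighted, "deff": self.deff}


def design_proportion(design: SurveyDesign, indicator, domain=None,
                      ci_level: float = 0.95) -> DesignProportion:
    """Design-based estimate of P(indicator = 1), optionally over a domain.

    Domain estimation keeps the full design (zero contributions outside the
    domain) so the variance correctly reflects the random domain size.
    """
    x = np.asarray(indicator, dtype=float)
    if len(x) != design.n:
        raise DataError("indicator length does not match design")
    d = np.ones(design.n) if domain is None else np.asarray(domain, dtype=float)
    w = design.weights * d
    W = w.sum()
    n_dom = int((d > 0).sum())
    if W <= 0 or n_dom == 0:
        raise EstimationError("empty domain (no positive weight)")
    p = float((w * x).sum() / W)
    # influence of the ratio mean
    u = w * (x - p) / W
    var = float(design.linearized_cov(u[:, None])[0, 0])
    se = np.sqrt(max(var, 0.0))
    z = stats.norm.ppf(0.5 + ci_level / 2)
    if 0.0 < p < 1.0 and se > 0:
        lo = np.log(p / (1 - p)) - z * se / (p * (1 - p))
        hi = np.log(p / (1 - p)) + z * se / (p * (1 - p))
        ci = (1 / (1 + np.exp(-lo)), 1 / (1 + np.exp(-hi)))
    else:
        ci = (p, p)
    srs_var = p * (1 - p) / (n_dom - 1) if n_dom > 1 else np.nan
    deff = var / srs_var if srs_var and srs_var > 0 else np.nan
    return DesignProportion(p, float(se), float(ci[0]), float(ci[1]),
                            n_dom, float(deff))


@dataclass
class RaoScottResult:
    """Rao-Scott second-order corrected chi-square test of independence."""

    pearson_x2: float
    statistic: float          # Satterthwaite-corrected statistic
    df: float                 # Satterthwaite df
    p_chisq: float
    f_statistic: float
    f_df: tuple
    p_f: float
    deff_mean: float          # first-order mean generalised design effect
    p: float = field(init=False)   # printed p (F version)
    flags: list = field(default_factory=list)

    def __post_init__(self):
        self.p = self.p_f

    def to_dict(self):
        return {"statistic": self.statistic, "df": self.df, "p": self.p,
                "pearson_x2": self.pearson_x2, "p_chisq": self.p_chisq,
                "f_statistic": self.f_statistic, "f_df": list(self.f_df),
                "deff_mean": self.deff_mean,
                "method": "Rao-Scott second-order corrected chi-square",
                "options": {"printed_p": "F"}, "flags": self.flags}


def rao_scott_test(design: SurveyDesign, row_var, col_var) -> RaoScottResult:
    """Test of independence of two categorical variables under the design.

    The Pearson X2 is computed on the weighted cell proportions scaled to
    the unweighted n, then corrected by the Rao-Scott (1984) second-order
    procedure: eigenvalues of the generalised design-effect matrix over the
    interaction contrast space give a Satterthwaite-adjusted statistic and
    degrees of freedom.  The printed p uses the F reference with denominator
    df = (#PSUs - #strata) * df_Satterthwaite; the chi-square version is
    also reported.
    """
    r = pd.Categorical(np.asarray(row_var))
    c = pd.Categorical(np.asarray(col_var))
    r = r.remove_unused_categories()
    c = c.remove_unused_categories()
    R, C = len(r.categories), len(c.categories)
    if R < 2 or C < 2:
        raise TestError("both variables need >= 2 observed levels")
    if len(r) != design.n or len(c) != design.n:
        raise DataError("variable length does not match design")
    flags = []
    n = design.n
    w = design.weights
    T = R * C
    cell = (np.asarray(r.codes) * C + np.asarray(c.codes)).astype(int)
    # weighted cell proportions
    Wtot = w.sum()
    p_hat = np.bincount(cell, weights=w, minlength=T) / Wtot
    P = p_hat.reshape(R, C)
    prow = P.sum(axis=1)
    pcol = P.sum(axis=0)
    E = np.outer(prow, pcol)
    if np.any(E == 0):
        flags.append("zero expected cell; generalised inverse used")
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(E > 0, (P - E) ** 2 / E, 0.0)
    x2 = float(n * contrib.sum())

    # design covariance of the cell-proportion vector (ratio means)
    Z = np.zeros((n, T))
    Z[np.arange(n), cell] = 1.0
    U = (w[:, None] * (Z - p_hat)) / Wtot
    V = design.linearized_cov(U)

    # SRS reference covariance with the same with-replacement n/(n-1) factor,
    # so the generalised deff is exactly I under equal-weight element sampling
    Pm = (np.diag(p_hat) - np.outer(p_hat, p_hat)) * (n / (n - 1)) / n

    # Jacobian of the (R-1)(C-1) interaction functions h_ab = p_ab - p_a. p_.b
    d = (R - 1) * (C - 1)
    H = np.zeros((d, T))
    for a in range(R - 1):
        for b in range(C - 1):
            k = a * (C - 1) + b
            for i in range(R):
                for j in range(C):
                    t = i * C + j
                    val = 0.0
                    if i == a and j == b:
                        val += 1.0
                    if i == a:
                        val -= pcol[b]
                    if j == b:
                        val -= prow[a]
                    H[k, t] = val
    A = H @ Pm @ H.T
    B = H @ V @ H.T
    # generalised design effects on the subspace where the null (SRS)
    # covariance of the interaction contrasts is non-degenerate
    evals, Q = np.linalg.eigh(A)
    tol = max(A.shape[0], 1) * np.finfo(float).eps * max(evals.max(), 0.0)
    keep = evals > max(tol, 0.0)
    if not keep.any():
        # all interaction contrasts have zero null variance (e.g. empty
        # off-diagonal cells): no correction is estimable
        flags.append("degenerate null covariance; uncorrected Pearson "
                     "reference used")
        c1, nu, delta_sum = 1.0, float(d), float(d)
    else:
        if keep.sum() < d:
            flags.append("rank-deficient null covariance; corrected on "
                         f"{int(keep.sum())} of {d} contrasts")
        Qk = Q[:, keep] / np.sqrt(evals[keep])
        Delta = Qk.T @ B @ Qk
        delta_sum = float(np.trace(Delta))
        delta_sq = float(np.trace(Delta @ Delta))
        if delta_sum <= 0 or delta_sq <= 0:
            raise TestError("degenerate design-effect matrix")
        c1 = delta_sq / delta_sum             # Satterthwaite scale
        nu = delta_sum ** 2 / delta_sq        # Satterthwaite df
    stat = x2 / c1
    p_chisq = float(stats.chi2.sf(stat, nu))
    ddf = max(design.design_df, 1)
    fstat = stat / nu
    p_f = float(stats.f.sf(fstat, nu, nu * ddf))
    return RaoScottResult(
        pearson_x2=x2, statistic=float(stat), df=float(nu),
        p_chisq=p_chisq, f_statistic=float(fstat),
        f_df=(float(nu), float(nu * ddf)), p_f=p_f,
        deff_mean=delta_sum / d, flags=flags)


@dataclass
class RankSumResult:
    """Design-based Wilcoxon rank-sum (mean rank-score) test."""

    statistic: float      # z statistic, sign: first group minus second
    p: float
    mean_rank: dict
    groups: tuple

    def to_dict(self):
        return {"statistic": self.statistic, "p": self.p,
                "mean_rank": self.mean_rank, "groups": list(self.groups),
                "method": "design-based Wilcoxon rank-sum",
                "options": {"scores": "weighted mid-ranks scaled to (0,1]"}}


def weighted_midranks(y, w) -> np.ndarray:
    """Weighted mid-rank scores in (0, 1]: r_i = (W_below + W_tie/2) / W."""
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    order = np.argsort(y, kind="mergesort")
    ys, ws = y[order], w[order]
    W = ws.sum()
    ranks = np.empty_like(ws)
    i = 0
    below = 0.0
    while i < len(ys):
        j = i
        tie_w = 0.0
        while j < len(ys) and ys[j] == ys[i]:
            tie_w += ws[j]
            j += 1
        ranks[i:j] = (below + tie_w / 2.0) / W
        below += tie_w
        i = j
    out = np.empty_like(ranks)
    out[order] = ranks
    return out


def svy_ranksum(design: SurveyDesign, group, outcome) -> RankSumResult:
    """Design-based two-sample rank test.

    The outcome is replaced by pooled weighted mid-rank scores in (0, 1];
    the test is a Wald test that the design-weighted mean rank score differs
    between the two groups, with Taylor-linearised variance of the
    difference of the two domain ratio means and a t reference on the design
    degrees of freedom.
    """
    g = pd.Categorical(np.asarray(group)).remove_unused_categories()
    if len(g.categories) != 2:
        raise TestError(
            f"exactly two groups required, got {list(g.categories)}")
    y = np.asarray(outcome, dtype=float)
    if len(y) != design.n or len(g) != design.n:
        raise DataError("variable length does not match design")
    w = design.weights
    r = weighted_midranks(y, w)
    codes = np.asarray(g.codes)
    means, infl = [], []
    for k in (0, 1):
        d = (codes == k).astype(float)
        Wk = (w * d).sum()
        if Wk <= 0:
            raise TestError(f"group {g.categories[k]!r} is empty")
        mk = (w * d * r).sum() / Wk
        means.append(mk)
        infl.append(w * d * (r - mk) / Wk)
    diff = means[0] - means[1]
    u = infl[0] - infl[1]
    var = float(design.linearized_cov(u[:, None])[0, 0])
    se = np.sqrt(max(var, 0.0))
    if se == 0:
        raise TestError("zero variance of rank-score difference")
    z = diff / se
    ddf = max(design.design_df, 1)
    p = float(2 * stats.t.sf(abs(z), ddf))
    return RankSumResult(
        statistic=float(z), p=p,
        mean_rank={str(g.categories[0]): means[0],
                   str(g.categories[1]): means[1]},
        groups=(str(g.categories[0]), str(g.categories[1])))
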