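"""Global Moran's I and local Moran (LISA) over regional indicator values.

With few spatial units (8 administrative regions here) the analytic normal
approximation to Moran's I is unreliable, so permutation inference is
primary: the global test permutes the value vector across units, the local
tests use conditional permutation (unit i held fixed, the remaining values
permuted into its neighbours' positions).  The analytic z/p under the
randomisation moments is reported as approximate.

Quadrants (high-high, low-low, high-low, low-high) are assigned from the
signs of the mean-centred value and of its spatial lag, independent of
significance; a separate flag marks units whose conditional permutation p
falls below alpha.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, DomainError

QUADRANTS = ("high-high", "low-low", "high-low", "low-high")


@dataclass
class SpatialWeights:
    """Adjacency-based spatial weights over named units."""

    names: list
    binary: np.ndarray            # symmetric 0/1, zero diagonal
    row_standardised: np.ndarray  # rows sum to 1 (units with neighbours)
    style: str                    # default matrix used by the statistics

    @property
    def W(self) -> np.ndarray:
        return (self.row_standardised if self.style == "row-standardised"
                else self.binary)

    @property
    def s0(self) -> float:
        return float(self.W.sum())

    @property
    def n(self) -> int:
        return len(self.names)


def build_weights(adjacency: dict, style: str = "row-standardised",
                  allow_islands: bool = False) -> SpatialWeights:
    """Build spatial weights from an {unit: [neighbours]} adjacency mapping."""
    if style not in ("binary", "row-standardised"):
        raise DataError(f"unknown weights style {style!r}")
    names = list(adjacency)
    idx = {nm: i for i, nm in enumerate(names)}
    n = len(names)
    A = np.zeros((n, n))
    for u, neighbours in adjacency.items():
        for v in neighbours:
            if v not in idx:
                raise DataError(f"neighbour {v!r} of {u!r} is not a unit")
            if v == u:
                raise DataError(f"self-loop on {u!r}")
            A[idx[u], idx[v]] = 1.0
    asym = [(names[i], names[j]) for i in range(n) for j in range(i + 1, n)
            if A[i, j] != A[j, i]]
    if asym:
        raise DataError(f"asymmetric adjacency for pairs: {asym}")
    rowsum = A.sum(axis=1)
    islands = [names[i] for i in np.nonzero(rowsum == 0)[0]]
    if islands and not allow_islands:
        raise DataError(f"units with no neighbours: {islands}")
    Wr = np.divide(A, np.where(rowsum > 0, rowsum, 1.0)[:, None])
    return SpatialWeights(names, A, Wr, style)


@dataclass
class MoranResult:
    I: float
    expected: float           # -1/(n-1) under randomisation
    z_analytic: float
    p_analytic: float         # approximate (normal) two-sided
    p_perm_two_sided: float
    p_perm_one_sided: float
    n_permutations: int
    seed: object

    def to_dict(self):
        return {"I": self.I, "expected": self.expected,
                "z_analytic": self.z_analytic, "p_analytic": self.p_analytic,
                "p_perm_two_sided": self.p_perm_two_sided,
                "p_perm_one_sided": self.p_perm_one_sided,
                "n_permutations": self.n_permutations,
                "method": "Global Moran's I (permutation primary)"}


def _moran_stat(z: np.ndarray, W: np.ndarray, s0: float) -> float:
    return float(len(z) / s0 * (z @ W @ z) / (z @ z))


def global_moran(values, weights: SpatialWeights, n_permutations: int = 999,
                 seed=None, exact: bool = False) -> MoranResult:
    """Global Moran's I with permutation and analytic randomisation inference.

    ``exact=True`` enumerates all n! relabellings (only sensible for n <= 8)
    instead of Monte-Carlo sampling.
    """
    x = np.asarray(values, dtype=float)
    n = weights.n
    if len(x) != n:
        raise DataError("values length does not match weights")
    if n < 3:
        raise DomainError("Moran's I needs at least 3 units")
    z = x - x.mean()
    if np.allclose(z, 0):
        raise DomainError("Moran undefined for zero variance")
    W = weights.W
    s0 = weights.s0
    I_obs = _moran_stat(z, W, s0)
    EI = -1.0 / (n - 1)

    # randomisation moments (Cliff & Ord)
    s1 = 0.5 * ((W + W.T) ** 2).sum()
    s2 = ((W.sum(axis=1) + W.sum(axis=0)) ** 2).sum()
    m2 = (z ** 2).sum() / n
    m4 = (z ** 4).sum() / n
    b2 = m4 / m2 ** 2
    num = (n * ((n * n - 3 * n + 3) * s1 - n * s2 + 3 * s0 ** 2)
           - b2 * ((n * n - n) * s1 - 2 * n * s2 + 6 * s0 ** 2))
    den = (n - 1) * (n - 2) * (n - 3) * s0 ** 2
    VI = num / den - EI ** 2
    z_an = (I_obs - EI) / math.sqrt(VI) if VI > 0 else float("nan")
    from scipy import stats as _st
    p_an = float(2 * _st.norm.sf(abs(z_an))) if VI > 0 else float("nan")

    if exact:
        perms = np.array([_moran_stat(z[list(p)], W, s0)
                          for p in itertools.permutations(range(n))])
        M = len(perms)
        m_two = int((np.abs(perms) >= abs(I_obs) - 1e-12).sum())
        m_one = int(((perms >= I_obs - 1e-12) if I_obs >= EI
                     else (perms <= I_obs + 1e-12)).sum())
        # full enumeration includes the identity; (m+1)/(M+1) convention kept
        p_two = m_two / M
        p_one = m_one / M
    else:
        rng = np.random.default_rng(seed)
        M = int(n_permutations)
        perms = np.empty(M)
        for m in range(M):
            perms[m] = _moran_stat(rng.permutation(z), W, s0)
        m_two = int((np.abs(perms) >= abs(I_obs) - 1e-12).sum())
        m_one = int(((perms >= I_obs - 1e-12) if I_obs >= EI
                     else (perms <= I_obs + 1e-12)).sum())
        p_two = (m_two + 1) / (M + 1)
        p_one = (m_one + 1) / (M + 1)
    return MoranResult(I_obs, EI, float(z_an), p_an, float(p_two),
                       float(p_one), M, seed)


@dataclass
class LisaResult:
    table: pd.DataFrame       # unit, local_I, quadrant, p_perm, significant
    alpha: float
    n_permutations: int
    seed: object

    def to_dict(self):
        return {"alpha": self.alpha, "n_permutations": self.n_permutations,
                "units": self.table.to_dict(orient="records"),
                "method": "local Moran (LISA), conditional permutation"}


def local_moran(values, weights: SpatialWeights, n_permutations: int = 999,
                seed=None, alpha: float = 0.05) -> LisaResult:
    """Local Moran I_i with quadrants and conditional-permutation p-values."""
    x = np.asarray(values, dtype=float)
    n = weights.n
    if len(x) != n:
        raise DataError("values length does not match weights")
    if n < 3:
        raise DomainError("local Moran needs at least 3 units")
    z = x - x.mean()
    if np.allclose(z, 0):
        raise DomainError("Moran undefined for zero variance")
    W = weights.W
    m2 = (z ** 2).sum() / n
    lag = W @ z
    I_loc = z / m2 * lag

    rng = np.random.default_rng(seed)
    M = int(n_permutations)
    rows = []
    for i in range(n):
        quad = ("high-" if z[i] > 0 else "low-") + \
               ("high" if lag[i] > 0 else "low")
        wi = W[i].copy()
        wi_others = np.delete(wi, i)
        z_others = np.delete(z, i)
        k = int((wi_others > 0).sum())
        if k == 0:
            rows.append({"unit": weights.names[i], "local_I": float(I_loc[i]),
                         "quadrant": quad, "p_perm": float("nan"),
                         "significant": False})
            continue
        # conditional permutation: draw k neighbour values from the others
        nz_w = wi_others[wi_others > 0]
        sims = np.empty(M)
        for m in range(M):
            draw = rng.choice(z_others, size=k, replace=False)
            sims[m] = z[i] / m2 * float(nz_w @ draw)
        extreme = int(((sims >= I_loc[i] - 1e-12) if I_loc[i] >= 0
                       else (sims <= I_loc[i] + 1e-12)).sum())
        p_i = (extreme + 1) / (M + 1)
        rows.append({"unit": weights.names[i], "local_I": float(I_loc[i]),
                     "quadrant": quad, "p_perm": float(p_i),
                     "significant": bool(p_i < alpha)})
    return LisaResult(pd.DataFrame(rows), alpha, M, seed)


def regional_cci_surface(df: pd.DataFrame, design, weights: SpatialWeights,
                         cci_class: str = "partial",
                         n_permutations: int = 999, seed=None,
                         alpha: float = 0.05):
    """Region-level coverage proportions with global and local Moran tests.

    Returns (region table, MoranResult, LisaResult).  The region value is
    the design-weighted proportion of records in ``cci_class`` (partial by
    default).
    """
    from .design import design_proportion
    if "cci_label" not in df.columns:
        raise DataError("records must be scored first (no cci_label column)")
    missing = [r for r in weights.names if r not in set(df["region"])]
    if missing:
        raise DataError(f"regions with no records: {missing}")
    unknown = set(df["region"]) - set(weights.names)
    if unknown:
        raise DataError(f"records in regions absent from weights: {sorted(unknown)}")
    ind = (df["cci_label"] == cci_class).astype(float).to_numpy()
    vals, rows = [], []
    for region in weights.names:
        dom = (df["region"] == region).astype(float).to_numpy()
        dp = design_proportion(design, ind, domain=dom)
        vals.append(dp.estimate)
        rows.append({"region": region, f"{cci_class}_proportion": dp.estimate,
                     "se": dp.se, "n": dp.n_unweighted})
    vals = np.asarray(vals)
    moran = global_moran(vals, weights, n_permutations=n_permutations,
                         seed=seed)
    lisa = local_moran(vals, weights, n_permutations=n_permutations,
                       seed=seed, alpha=alpha)
    table = pd.DataFrame(rows)
    table = table.merge(lisa.table.rename(columns={"unit": "region"}),
                        on="region")
    return table, moran, lisa
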