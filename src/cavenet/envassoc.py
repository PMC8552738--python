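"""Environment-community association tests.

Mantel permutation tests between a community distance matrix (Bray-Curtis)
and an environmental distance matrix built per variable or over all
variables jointly, plus a pairwise variable-vs-variable correlation screen
with the conventional significance stars.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .tables import SampleMetadata, TableError

__all__ = [
    "env_distance",
    "MantelResult",
    "mantel",
    "mantel_table",
    "star_class",
    "CorrelationCell",
    "correlation_screen",
]


def env_distance(m: SampleMetadata, variables: list[str]) -> DistanceMatrix:
    """Euclidean distance between samples on z-standardized variables.

    Variables are standardized (mean 0, sd 1) before the distance because the
    raw units are incommensurable (pH vs mg/kg vs ppm).  For a single
    variable this reduces to |difference| after standardization.
    """
    num = m.numeric(variables)
    x = num.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    # constant variables carry no information: zero contribution (so fully
    # identical samples give an all-zero matrix rather than an error here;
    # a downstream Mantel test on such a matrix fails loudly instead)
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (x - x.mean(axis=0)) / safe_sd
    z[:, sd == 0] = 0.0
    return DistanceMatrix(squareform(pdist(z, metric="euclidean")), ids=m.sample_ids)


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    variable: str = ""

    def __post_init__(self) -> None:
        if not -1 <= self.r <= 1:
            raise ValueError(f"correlation out of range: {self.r}")


def _condensed(d: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(d.shape[0], k=1)
    return d[iu]


def mantel(
    dx: DistanceMatrix,
    dy: DistanceMatrix,
    n_perm: int = 9999,
    seed: int = 0,
    method: str = "spearman",
    variable: str = "",
) -> MantelResult:
    """Mantel permutation test between two distance matrices.

    r is the rank (Spearman, default) or Pearson correlation of the upper
    triangles.  Significance comes from ``n_perm`` simultaneous row/column
    permutations of ``dy``; the one-sided p-value is
    (#{permuted r >= observed} + 1) / (n_perm + 1).
    """
    if list(dx.ids) != list(dy.ids):
        dy = dy.filter(dx.ids)  # raises if sample sets differ
    if n_perm < 99:
        raise ValueError("need at least 99 permutations")
    n = dx.shape[0]
    x = _condensed(dx.data)
    ymat = dy.data

    if method == "spearman":
        x = scipy.stats.rankdata(x)

        def corr(yvec: np.ndarray) -> float:
            return float(np.corrcoef(x, scipy.stats.rankdata(yvec))[0, 1])

    elif method == "pearson":

        def corr(yvec: np.ndarray) -> float:
            return float(np.corrcoef(x, yvec)[0, 1])

    else:
        raise ValueError(f"unknown method {method!r}")

    y = _condensed(ymat)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant distance matrix: Mantel correlation undefined")

    r_obs = corr(y)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        idx = rng.permutation(n)
        perm = _condensed(ymat[np.ix_(idx, idx)])
        if corr(perm) >= r_obs:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return MantelResult(r=r_obs, p=p, n_perm=n_perm, variable=variable)


def mantel_table(
    community_d: DistanceMatrix,
    metadata: SampleMetadata,
    variables: list[str],
    n_perm: int = 9999,
    seed: int = 0,
    method: str = "spearman",
) -> pd.DataFrame:
    """Per-variable and all-variable Mantel tests, one row per variable."""
    rows = []
    specs = [("all", list(variables))] + [(v, [v]) for v in variables]
    for k, (label, vs) in enumerate(specs):
        dy = env_distance(metadata, vs)
        res = mantel(
            community_d, dy, n_perm=n_perm, seed=seed + k, method=method, variable=label
        )
        rows.append(
            {
                "variable": label,
                "r": res.r,
                "p": res.p,
                "n_perm": res.n_perm,
                "stars": star_class(res.p),
            }
        )
    return pd.DataFrame(rows).set_index("variable")


def star_class(p: float) -> str:
    """Significance stars: * 0.01<P<0.05, ** 0.001<P<0.01, *** P<0.001."""
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class CorrelationCell:
    variable: str
    taxon: str
    rho: float
    p: float
    stars: str
    defined: bool = True


def correlation_screen(
    x: pd.DataFrame,
    y: pd.DataFrame,
    method: str = "spearman",
) -> list[CorrelationCell]:
    """Score every (column of x, column of y) pair with rho, p, and stars.

    Rows are paired samples.  Zero-variance columns yield an explicitly
    undefined cell (NaN rho) rather than a fabricated value.
    """
    if len(x) != len(y):
        raise ValueError("x and y must have the same samples (rows)")
    if method == "spearman":
        func = scipy.stats.spearmanr
    elif method == "pearson":
        func = scipy.stats.pearsonr
    else:
        raise ValueError(f"unknown method {method!r}")
    cells = []
    for xv in x.columns:
        xs = x[xv].to_numpy(dtype=float)
        for yv in y.columns:
            ys = y[yv].to_numpy(dtype=float)
            if np.ptp(xs) == 0 or np.ptp(ys) == 0:
                cells.append(CorrelationCell(xv, yv, np.nan, np.nan, "", defined=False))
                continue
            rho, p = func(xs, ys)
            cells.append(CorrelationCell(xv, yv, float(rho), float(p), star_class(p)))
    return cells
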