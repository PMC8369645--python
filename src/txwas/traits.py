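"""Descriptive phenotype statistics, Pearson correlations, trait dendrogram.

Correlation confidence intervals use the Fisher z-transform:
CI = tanh(atanh(r) +/- z_{1-(1-conf)/2} / sqrt(n-3)); the two-sided p-value
comes from t = r*sqrt((n-2)/(1-r^2)) with n-2 degrees of freedom.
Correlations use pairwise-complete observations, since traits may be measured
on different subsets of samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.stats import norm, t as t_dist

__all__ = ["TraitSummary", "CorrelationResult", "summarize", "pearson_ci",
           "correlation_table", "trait_dendrogram", "linkage_to_newick"]


@dataclass
class TraitSummary:
    trait: str
    n: int
    mean: float
    sd: float
    cv_percent: float
    n_missing: int = 0


@dataclass
class CorrelationResult:
    trait_pair: tuple[str, str]
    n: int
    r: float
    ci_low: float
    ci_high: float
    p_value: float

    def __post_init__(self) -> None:
        if not self.ci_low <= self.r <= self.ci_high:
            raise ValueError("confidence interval must contain r")


def summarize(values, trait: str = "") -> TraitSummary:
    """Sample mean, SD (n-1), and CV% (2 decimals) with missing values dropped."""
    v = np.asarray(values, dtype=float)
    missing = int(np.isnan(v).sum())
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise ValueError("need at least 2 non-missing values")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    cv = round(100.0 * sd / mean, 2) if mean != 0 else float("nan")
    if sd == 0:
        cv = 0.0
    return TraitSummary(trait=trait, n=int(v.size), mean=mean, sd=sd,
                        cv_percent=cv, n_missing=missing)


def pearson_ci(x, y, conf: float = 0.95,
               names: tuple[str, str] = ("x", "y")) -> CorrelationResult:
    """Pearson r on pairwise-complete observations with Fisher-z CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 complete pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input has no defined correlation")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(min(r, 1.0), -1.0)
    zcrit = norm.ppf(1.0 - (1.0 - conf) / 2.0)
    if abs(r) >= 1.0:            # atanh diverges; CI degenerates to a point
        lo = hi = r
        p = 0.0
    else:
        z = np.arctanh(r)
        half = zcrit / np.sqrt(n - 3)
        lo, hi = float(np.tanh(z - half)), float(np.tanh(z + half))
        t_stat = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * t_dist.sf(abs(t_stat), df=n - 2))
    return CorrelationResult(trait_pair=names, n=n, r=r, ci_low=lo, ci_high=hi,
                             p_value=p)


def correlation_table(phenotypes: pd.DataFrame, conf: float = 0.95) -> pd.DataFrame:
    """Square table with r in the lower triangle and the CI as "[lo, hi]"
    strings in the upper triangle (pairwise-complete n per pair)."""
    cols = list(phenotypes.columns)
    out = pd.DataFrame("", index=cols, columns=cols, dtype=object)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if i <= j:
                continue
            res = pearson_ci(phenotypes[a], phenotypes[b], conf=conf, names=(a, b))
            out.loc[a, b] = round(res.r, 2)
            out.loc[b, a] = f"[{res.ci_low:.2f}, {res.ci_high:.2f}]"
    return out


def trait_dendrogram(phenotypes: pd.DataFrame) -> np.ndarray:
    """Complete-linkage agglomeration of standardized trait columns under
    Euclidean distance (the hclust/dist defaults); returns the linkage matrix."""
    if phenotypes.shape[1] < 2:
        raise ValueError("need at least 2 traits")
    Z = phenotypes.to_numpy(dtype=float)
    sd = Z.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant trait column")
    Z = (Z - Z.mean(axis=0)) / sd
    # observations are traits: cluster the columns
    return linkage(Z.T, method="complete", metric="euclidean")


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick string with branch
    lengths derived from merge heights."""
    tree = to_tree(Z)

    def walk(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.10g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    root = f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"
    return root


def summary_table(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Descriptive-statistics table: one row per trait."""
    rows = []
    for col in phenotypes.columns:
        s = summarize(phenotypes[col], trait=col)
        rows.append({"trait": s.trait, "n": s.n, "mean": s.mean, "sd": s.sd,
                     "cv_percent": s.cv_percent})
    return pd.DataFrame(rows).set_index("trait")
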