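"""Multivariate analysis of genotype genetic values: correlation tables,
PCA, Ward hierarchical clustering, and per-group summaries.

Works on a genotype x trait table of genetic values (BLUPs), the default trait
panel being c_volume, a_volume, STAR, I_PL, WDI, NDVI, MCARI2.  Traits are
standardized to zero mean / unit variance before PCA and clustering because
their units are incommensurable (m^3 next to dimensionless indices).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "DEFAULT_TRAITS",
    "PCAResult",
    "ClusterResult",
    "correlation_table",
    "pca",
    "hac_ward",
    "group_summary",
]

DEFAULT_TRAITS = ("c_volume", "a_volume", "STAR", "I_PL", "WDI", "NDVI", "MCARI2")

#: Significance thresholds and their star codes (loosest first).
_STARS = ((0.001, "****"), (0.01, "***"), (0.05, "**"), (0.08, "*"))


def _stars(p: float) -> str:
    for thr, code in _STARS:
        if p <= thr:
            return code
    return "ns"


def correlation_table(values: pd.DataFrame, level: str = "phenotypic") -> pd.DataFrame:
    """Pairwise Pearson correlations between trait columns, reported as squared
    correlation (R^2) with the sign carried separately and significance stars.

    ``level`` is a label only ("phenotypic" for per-tree values, "genotypic"
    for BLUPs); the computation is identical.  Pairs with fewer than 3 complete
    observations, or a constant column, yield a missing (NaN) cell.
    """
    traits = list(values.columns)
    rows = []
    for i, a in enumerate(traits):
        for b in traits[i + 1 :]:
            pair = values[[a, b]].dropna()
            if len(pair) < 3 or pair[a].nunique() < 2 or pair[b].nunique() < 2:
                rows.append(
                    {"trait_a": a, "trait_b": b, "level": level, "r2": np.nan,
                     "sign": "", "p": np.nan, "stars": "", "n": len(pair)}
                )
                continue
            r, p = stats.pearsonr(pair[a], pair[b])
            rows.append(
                {"trait_a": a, "trait_b": b, "level": level, "r2": r**2,
                 "sign": "+" if r >= 0 else "-", "p": p, "stars": _stars(p),
                 "n": len(pair)}
            )
    return pd.DataFrame(rows)


@dataclass
class PCAResult:
    """PCA of standardized traits (eigendecomposition of the correlation matrix)."""

    loadings: pd.DataFrame  # trait x axis
    scores: pd.DataFrame  # genotype x axis
    pct_variance: np.ndarray  # per axis, sums to 100
    n_axes: int


def _standardize(table: pd.DataFrame) -> pd.DataFrame:
    sd = table.std(ddof=1)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"constant trait column(s) cannot be standardized: {bad}")
    return (table - table.mean()) / sd


def pca(blups: pd.DataFrame, scale: bool = True) -> PCAResult:
    """Principal components of the genotype x trait table.

    With ``scale=True`` (default) the decomposition is of the correlation
    matrix, i.e. variables are standardized first.  Percent variance per axis
    sums to 100 and is non-increasing.  The sign of each axis is fixed so that
    its largest-magnitude loading is positive (determinism across linear
    algebra backends).  Rank deficiency reduces the axis count with a warning.
    """
    if blups.shape[1] < 2 or blups.shape[0] < 3:
        raise ValueError("PCA needs >= 2 traits and >= 3 genotypes")
    Z = _standardize(blups) if scale else blups - blups.mean()
    cov = np.cov(Z.to_numpy(), rowvar=False, ddof=1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(eigval.max(), 0) * 1e-10
    keep = eigval > tol
    if keep.sum() < len(eigval):
        warnings.warn(
            f"rank-deficient trait table: keeping {int(keep.sum())} of "
            f"{len(eigval)} axes",
            RuntimeWarning,
            stacklevel=2,
        )
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    # sign convention: largest-magnitude loading per axis is positive
    flips = np.sign(eigvec[np.argmax(np.abs(eigvec), axis=0), np.arange(eigvec.shape[1])])
    eigvec = eigvec * flips
    axes = [f"PC{i + 1}" for i in range(eigvec.shape[1])]
    loadings = pd.DataFrame(eigvec, index=blups.columns, columns=axes)
    scores = pd.DataFrame(Z.to_numpy() @ eigvec, index=blups.index, columns=axes)
    pct = 100.0 * eigval / eigval.sum()
    return PCAResult(loadings=loadings, scores=scores, pct_variance=pct, n_axes=len(axes))


@dataclass
class ClusterResult:
    """Genotype groups from Ward hierarchical clustering."""

    labels: pd.Series  # genotype -> group in 1..k
    k: int
    linkage_matrix: np.ndarray = field(repr=False, default=None)
    standardized: bool = True


def hac_ward(blups: pd.DataFrame, k: int = 6, scale: bool = True) -> ClusterResult:
    """Hierarchical ascendant classification with Ward linkage (squared
    Euclidean increase criterion) on standardized trait values, cut at ``k``
    groups (default 6)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(blups):
        raise ValueError(f"k={k} exceeds the number of genotypes ({len(blups)})")
    Z = _standardize(blups) if scale else blups
    link = linkage(Z.to_numpy(), method="ward")
    labels = fcluster(link, t=k, criterion="maxclust")
    labels = pd.Series(labels, index=blups.index, name="group")
    return ClusterResult(labels=labels, k=k, linkage_matrix=link, standardized=scale)


def group_summary(result: ClusterResult, blups: pd.DataFrame) -> pd.DataFrame:
    """Per-group trait means with a one-way ANOVA p-value per trait and a
    compact letter display from pairwise Tukey HSD comparisons at 0.05.

    Groups of size 1 are excluded from the Tukey comparison (with a warning)
    but still appear in the mean table.  Groups sharing no letter differ
    significantly for that trait.
    """
    labels = result.labels.reindex(blups.index)
    if labels.isna().any():
        raise ValueError("cluster labels do not cover all genotypes in the table")
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("group summary needs >= 2 groups")
    sizes = labels.value_counts()
    small = [g for g in groups if sizes[g] < 2]
    if small:
        warnings.warn(
            f"group(s) {small} have a single member and are excluded from Tukey HSD",
            RuntimeWarning,
            stacklevel=2,
        )
    rows = []
    for trait in blups.columns:
        x = blups[trait]
        samples = [x[labels == g].to_numpy() for g in groups]
        anova = stats.f_oneway(*[s for s in samples if len(s) > 0])
        anova_p = anova.pvalue
        if np.isnan(anova_p) and anova.statistic <= 0:
            anova_p = 1.0  # rounding can push a zero between-group SS negative
        big = [g for g in groups if sizes[g] >= 2]
        letters = {g: "" for g in groups}
        if len(big) >= 2:
            sel = labels.isin(big)
            tuk = pairwise_tukeyhsd(x[sel].to_numpy(), labels[sel].to_numpy(), alpha=0.05)
            letters.update(
                _compact_letter_display(big, tuk, means={g: x[labels == g].mean() for g in big})
            )
        row = {"trait": trait, "anova_p": float(anova_p)}
        for g in groups:
            row[f"mean_{g}"] = float(x[labels == g].mean())
            row[f"letters_{g}"] = letters[g]
        rows.append(row)
    return pd.DataFrame(rows)


def _compact_letter_display(groups, tukey, means: dict) -> dict:
    """Insert-and-absorb compact letter display from a Tukey HSD result.

    Groups connected by a non-significant comparison share at least one letter;
    letters are assigned in descending order of group mean.
    """
    differ = set()
    res = tukey.summary().data[1:]
    for row in res:
        a, b, reject = row[0], row[1], row[-1]
        if bool(reject):
            differ.add(frozenset((a, b)))
    order = sorted(groups, key=lambda g: -means[g])
    # Start with one letter set containing everything, then split on each
    # significant pair (insert-and-absorb).
    sets = [set(order)]
    for pair in differ:
        a, b = tuple(pair)
        new_sets = []
        for s in sets:
            if a in s and b in s:
                sa, sb = s - {b}, s - {a}
                for cand in (sa, sb):
                    if not any(cand <= t for t in sets + new_sets if t is not s):
                        new_sets.append(cand)
            else:
                new_sets.append(s)
        # absorb subsets
        sets = [s for s in new_sets if not any(s < t for t in new_sets)]
    # letter per set, ordered by the best mean it contains
    sets.sort(key=lambda s: -max(means[g] for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for i, s in enumerate(sets):
        for g in order:
            if g in s:
                letters[g] += alphabet[i % len(alphabet)]
    return letters
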