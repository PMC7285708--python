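"""Distance matrices, ordination, and permutation statistics.

Bray-Curtis dissimilarities for community tables, Euclidean distances on
z-scored geochemistry, PCA / classical PCoA, and the permutation tests that
back the depth-stratification analysis: ANOSIM (rank-based R), PERMANOVA
(Anderson's variance partition, pseudo-F and R^2), and the Mantel test.

Permutation p-values follow the vegan-style add-one convention,
p = (1 + #{permuted statistic >= observed}) / (1 + permutations), so p is
never 0. Each test also has an exhaustive mode that enumerates every distinct
relabelling (feasible at the n <= 11 scales this package targets), where
p = #{statistic >= observed} / #relabellings with the identity included.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations as iter_permutations
from math import factorial

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    d: np.ndarray               # square, symmetric, zero diagonal
    metric: str

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.sample_ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("non-zero diagonal")
        if (self.d < 0).any():
            raise ValueError("negative distances")

    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame   # samples x axes
    eigenvalues: np.ndarray     # all, ordered decreasing (PCoA keeps negatives)
    proportion_explained: np.ndarray
    method: str


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def bray_curtis(table: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples (rows) of an abundance table."""
    x = table.values.astype(float)
    if (x < 0).any():
        raise ValueError("negative abundances")
    zero = table.index[x.sum(axis=1) == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero)}")
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(list(table.index), d, "bray_curtis")


def standardize(table: pd.DataFrame) -> pd.DataFrame:
    """Per-column z-scores (mean 0, sample sd with n-1 denominator).

    Constant columns cannot be standardized and are dropped with a warning.
    """
    sd = table.std(ddof=1)
    constant = list(sd[sd == 0].index)
    if constant:
        warnings.warn(f"dropping constant parameter(s): {constant}")
        table = table.drop(columns=constant)
        sd = sd.drop(constant)
    return (table - table.mean()) / sd


def euclidean(table: pd.DataFrame, pre_standardize: bool = True) -> DistanceMatrix:
    """Euclidean distances between samples, on z-scored columns by default."""
    if pre_standardize:
        table = standardize(table)
    d = squareform(pdist(table.values.astype(float), metric="euclidean"))
    return DistanceMatrix(list(table.index), d, "euclidean")


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

def pca(table: pd.DataFrame, n_axes: int | None = None) -> OrdinationResult:
    n_axes = n_axes or min(table.shape) - 1 or 1
    model = PCA(n_components=n_axes)
    scores = model.fit_transform(table.values.astype(float))
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return OrdinationResult(
        pd.DataFrame(scores, index=table.index, columns=cols),
        model.explained_variance_, model.explained_variance_ratio_, "PCA")


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Classical scaling (Torgerson): double-center -d^2/2, eigendecompose.

    Negative eigenvalues are reported but excluded from the
    proportion-explained denominator; axes are returned for positive
    eigenvalues only, ordered by decreasing eigenvalue.
    """
    d2 = dm.d ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    prop = np.where(evals > 0, evals, 0.0) / evals[pos].sum() if pos.any() else evals * 0
    return OrdinationResult(
        pd.DataFrame(coords, index=dm.sample_ids, columns=cols),
        evals, prop, "PCoA")


# ---------------------------------------------------------------------------
# permutation machinery
# ---------------------------------------------------------------------------

def _distinct_label_orderings(labels: np.ndarray):
    """All distinct orderings of a label vector (the identity included)."""
    seen = set()
    for perm in iter_permutations(range(len(labels))):
        key = tuple(labels[list(perm)])
        if key not in seen:
            seen.add(key)
            yield np.array(perm)


def _perm_pvalue(stat_fn, labels: np.ndarray, observed: float,
                 permutations: int, seed, method: str) -> float:
    n = len(labels)
    if method == "auto":
        method = "exhaustive" if factorial(n) <= max(permutations, 5000) else "sampled"
    if method == "exhaustive":
        count = total = 0
        for perm in _distinct_label_orderings(labels):
            total += 1
            if stat_fn(labels[perm]) >= observed - 1e-12:
                count += 1
        return count / total
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        if stat_fn(rng.permutation(labels)) >= observed - 1e-12:
            hits += 1
    return (1 + hits) / (1 + permutations)


def _check_groups(dm: DistanceMatrix, groups: pd.Series) -> np.ndarray:
    labels = np.asarray([groups[s] for s in dm.sample_ids])
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    if not (counts >= 2).any():
        raise ValueError("at least one group must have >= 2 samples")
    return labels


# ---------------------------------------------------------------------------
# ANOSIM / PERMANOVA / Mantel / Pearson
# ---------------------------------------------------------------------------

def anosim(dm: DistanceMatrix, groups: pd.Series, permutations: int = 999,
           seed: int | None = 0, method: str = "sampled"
           ) -> tuple[float, float]:
    """ANOSIM R and permutation p for a grouping of the samples.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2 distances, ranked with mid-ranks.
    """
    labels = _check_groups(dm, groups)
    ranks = sps.rankdata(dm.condensed())
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    m = len(ranks)

    def r_stat(lab):
        within = lab[iu[0]] == lab[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / (m / 2.0)

    observed = r_stat(labels)
    p = _perm_pvalue(r_stat, labels, observed, permutations, seed, method)
    return float(observed), float(p)


def permanova(dm: DistanceMatrix, groups: pd.Series, permutations: int = 999,
              seed: int | None = 0, method: str = "sampled"
              ) -> tuple[float, float, float]:
    """PERMANOVA pseudo-F, R^2, and permutation p (Anderson's formulation).

    SS_total = sum of squared distances / n over all pairs; SS_within sums
    each group's squared within-distances over its size; R^2 = 1 -
    SS_within / SS_total; F = (SS_between/(g-1)) / (SS_within/(n-g)).
    """
    labels = _check_groups(dm, groups)
    d2 = dm.d ** 2
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    d2c = d2[iu]
    ss_total = d2c.sum() / n
    uniq = np.unique(labels)
    g = len(uniq)

    def f_stat(lab):
        ss_within = 0.0
        for u in uniq:
            mask = lab == u
            ng = int(mask.sum())
            if ng > 1:
                pair_mask = mask[iu[0]] & mask[iu[1]]
                ss_within += d2c[pair_mask].sum() / ng
        ss_between = ss_total - ss_within
        if ss_within == 0:
            return np.inf           # identical replicates within every group
        return (ss_between / (g - 1)) / (ss_within / (n - g))

    observed_f = f_stat(labels)
    # R^2 from the observed labelling
    ss_within = 0.0
    for u in uniq:
        mask = labels == u
        ng = int(mask.sum())
        if ng > 1:
            pair_mask = mask[iu[0]] & mask[iu[1]]
            ss_within += d2c[pair_mask].sum() / ng
    r2 = 1.0 - ss_within / ss_total
    p = _perm_pvalue(f_stat, labels, observed_f, permutations, seed, method)
    return float(observed_f), float(r2), float(p)


def mantel(d1: DistanceMatrix, d2: DistanceMatrix, permutations: int = 999,
           seed: int | None = 0, method: str = "sampled") -> tuple[float, float]:
    """Mantel r (Pearson over off-diagonal pairs) and permutation p.

    The p-value permutes rows and columns of the second matrix jointly.
    """
    if d1.sample_ids != d2.sample_ids:
        raise ValueError("distance matrices cover different sample sets/orders")
    n = len(d1.sample_ids)
    iu = np.triu_indices(n, k=1)
    v1 = d1.d[iu]
    observed = float(sps.pearsonr(v1, d2.d[iu]).statistic)

    def r_of_perm(perm):
        dp = d2.d[np.ix_(perm, perm)]
        return float(sps.pearsonr(v1, dp[iu]).statistic)

    if method == "auto":
        method = "exhaustive" if factorial(n) <= max(permutations, 5000) else "sampled"
    if method == "exhaustive":
        count = total = 0
        for perm in iter_permutations(range(n)):
            total += 1
            if r_of_perm(np.array(perm)) >= observed - 1e-12:
                count += 1
        p = count / total
    else:
        rng = np.random.default_rng(seed)
        hits = sum(r_of_perm(rng.permutation(n)) >= observed - 1e-12
                   for _ in range(permutations))
        p = (1 + hits) / (1 + permutations)
    return observed, float(p)


def pearson(x, y) -> tuple[float, float]:
    """Pearson r with the two-sided t-transform p (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def log_zscore_linkage(table: pd.DataFrame):
    """Average-linkage clustering of log-transformed, row-z-scored profiles.

    Plotting convenience for indicator-COG heatmaps; non-inferential.
    """
    from scipy.cluster import hierarchy
    x = np.log10(table.values.astype(float) + 1e-9)
    x = (x - x.mean(axis=1, keepdims=True)) / (x.std(axis=1, ddof=1, keepdims=True) + 1e-12)
    return hierarchy.linkage(x, method="average", metric="euclidean")
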