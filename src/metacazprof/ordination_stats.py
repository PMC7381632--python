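"""Ordination and group-difference statistics on CLR data.

PCA of sample columns, Aitchison distances (Euclidean on CLR), one-way
PERMANOVA with sampled or exhaustive permutation nulls, and the
Mann–Whitney U test for diet comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA as _SkPCA
from sympy.utilities.iterables import multiset_permutations

from .core_model import ValidationError, logger


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # features x components
    explained_variance_ratio: np.ndarray


def pca(clr_matrix: pd.DataFrame, n_components: int | None = None) -> PcaResult:
    """Feature-centered PCA of the sample columns of a CLR matrix.

    Component signs are fixed by making each component's largest-magnitude
    loading positive, so scores are fully deterministic.
    """
    if clr_matrix.shape[1] < 2 or clr_matrix.shape[0] < 2:
        raise ValidationError("PCA needs at least 2 samples and 2 features")
    X = clr_matrix.T.values  # samples x features
    if np.allclose(X, X[0]):
        raise ValidationError("constant matrix; PCA undefined")
    max_rank = min(X.shape[0] - 1, X.shape[1])
    if n_components is None:
        n_components = max_rank
    model = _SkPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_.T  # features x components
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comp_names = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PcaResult(
        scores=pd.DataFrame(scores, index=clr_matrix.columns, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=clr_matrix.index, columns=comp_names),
        explained_variance_ratio=model.explained_variance_ratio_,
    )


# ---------------------------------------------------------------------------
# Aitchison distance and PERMANOVA
# ---------------------------------------------------------------------------


def aitchison_distance(clr_matrix: pd.DataFrame) -> pd.DataFrame:
    """Euclidean distance between sample columns of a CLR matrix (the
    Aitchison distance of the underlying compositions)."""
    D = squareform(pdist(clr_matrix.T.values, metric="euclidean"))
    return pd.DataFrame(D, index=clr_matrix.columns, columns=clr_matrix.columns)


@dataclass
class PermanovaResult:
    f_statistic: float
    p_value: float
    n_permutations: int
    mode: str  # "sampled" | "exhaustive"
    ss_between: float
    ss_within: float
    ss_total: float


def _group_f(D2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float, float]:
    """Pseudo-F decomposition from squared distances and integer labels."""
    N = D2.shape[0]
    ss_total = D2[np.triu_indices(N, k=1)].sum() / N
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            sub = D2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    return ss_total, ss_within, ss_total - ss_within


def _f_from_ss(ss_between: float, ss_within: float, N: int, g: int) -> float:
    if ss_within <= 0:
        return math.inf
    return (ss_between / (g - 1)) / (ss_within / (N - g))


def _batch_f(D2: np.ndarray, perms: np.ndarray, n_groups: int, ss_total: float) -> np.ndarray:
    """Pseudo-F for a batch of label vectors (rows of ``perms``)."""
    N = D2.shape[0]
    g = n_groups
    ss_within = np.zeros(perms.shape[0])
    for grp in range(g):
        M = (perms == grp).astype(float)
        n_g = M.sum(axis=1)
        quad = np.einsum("pi,ij,pj->p", M, D2, M) / 2.0
        ss_within += np.divide(quad, n_g, out=np.zeros_like(quad), where=n_g > 0)
    ss_between = ss_total - ss_within
    with np.errstate(divide="ignore"):
        F = (ss_between / (g - 1)) / np.where(ss_within > 0, ss_within / (N - g), np.nan)
    F = np.where(ss_within > 0, F, np.inf)
    return F


def _n_distinct_labelings(counts: Sequence[int]) -> int:
    total = math.factorial(sum(counts))
    for c in counts:
        total //= math.factorial(c)
    return total


def permanova(
    distance: pd.DataFrame,
    labels: Mapping[str, str],
    n_permutations: int = 999,
    seed: int = 0,
    exhaustive: bool | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA on a sample distance matrix.

    SS_total = (1/N) sum_{i<j} d_ij^2; SS_within sums (1/n_g) sum over
    within-group pairs; F = (SS_between/(g-1)) / (SS_within/(N-g)).

    ``exhaustive=None`` auto-selects exhaustive enumeration when the
    number of distinct label vectors is at most 10,000; the exhaustive p
    is the fraction of label vectors (observed included) reaching the
    observed F, while the sampled p uses (1 + hits) / (1 + n_permutations).
    """
    samples = list(distance.index)
    lab = [labels[s] for s in samples]
    groups = sorted(set(lab))
    if len(groups) < 2:
        raise ValidationError("PERMANOVA needs at least 2 groups")
    codes = np.array([groups.index(v) for v in lab])
    counts = [int((codes == g).sum()) for g in range(len(groups))]
    if min(counts) < 1:
        raise ValidationError("every group must be non-empty")
    D2 = np.asarray(distance.values, dtype=float) ** 2
    N, g = len(samples), len(groups)
    ss_total, ss_within, ss_between = _group_f(D2, codes, g)
    f_obs = _f_from_ss(ss_between, ss_within, N, g)

    n_labelings = _n_distinct_labelings(counts)
    if exhaustive is None:
        exhaustive = n_labelings <= 10_000
    if exhaustive:
        perms = np.array(list(multiset_permutations(list(codes))))
        F = _batch_f(D2, perms, g, ss_total)
        hits = int((F >= f_obs - 1e-12).sum())
        total = perms.shape[0]
        p = hits / total
        mode, n_used = "exhaustive", total
    else:
        if n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        rng = np.random.default_rng(seed)
        perms = rng.permuted(np.tile(codes, (n_permutations, 1)), axis=1)
        F = _batch_f(D2, perms, g, ss_total)
        hits = int((F >= f_obs - 1e-12).sum())
        p = (1 + hits) / (1 + n_permutations)
        mode, n_used = "sampled", n_permutations
    if not math.isinf(f_obs) and f_obs < 0:
        raise AssertionError("negative pseudo-F")
    return PermanovaResult(
        f_statistic=f_obs,
        p_value=p,
        n_permutations=n_used,
        mode=mode,
        ss_between=ss_between,
        ss_within=ss_within,
        ss_total=ss_total,
    )


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


@dataclass
class MannWhitneyResult:
    u_statistic: float
    p_value: float
    method: str  # "exact" | "normal-approximation"


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> MannWhitneyResult:
    """Two-sided Mann–Whitney U test with U = min(U_x, U_y) and midrank
    ties.

    For small pooled samples (n1 + n2 <= 12) the p-value is computed
    exactly by enumerating all group assignments of the pooled values
    (valid with ties since the enumeration uses midranks); larger samples
    use the normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = st.rankdata(pooled)
    u_x = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    u_y = n1 * n2 - u_x
    u_obs = min(u_x, u_y)
    n = n1 + n2
    if n <= 12:
        hits = 0
        total = 0
        for idx in combinations(range(n), n1):
            r = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
            u = min(r, n1 * n2 - r)
            hits += u <= u_obs + 1e-12
            total += 1
        return MannWhitneyResult(u_obs, hits / total, "exact")
    mean = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return MannWhitneyResult(u_obs, 1.0, "normal-approximation")
    z = (u_obs - mean + 0.5) / math.sqrt(var)  # continuity correction toward the null
    p = min(1.0, 2.0 * st.norm.cdf(z))
    return MannWhitneyResult(u_obs, p, "normal-approximation")


def diet_comparison(
    diet_values: Mapping[str, Mapping[str, float]],
    group_a: Sequence[str],
    group_b: Sequence[str],
    columns: Sequence[str],
) -> pd.DataFrame:
    """Mann–Whitney comparison of diet columns between two donor groups.

    ``diet_values`` maps sample_id -> {column -> value}.  Returns a
    DataFrame indexed by column with medians, U and p.
    """
    rows = []
    for col in columns:
        a = [diet_values[s][col] for s in group_a]
        b = [diet_values[s][col] for s in group_b]
        res = mann_whitney(a, b)
        rows.append(
            {
                "component": col,
                "median_a": float(np.median(a)),
                "median_b": float(np.median(b)),
                "u_statistic": res.u_statistic,
                "p_value": res.p_value,
                "method": res.method,
            }
        )
    return pd.DataFrame(rows).set_index("component")
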