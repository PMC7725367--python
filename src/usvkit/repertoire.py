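"""Repertoire diversity and composition statistics.

A recording's vocal repertoire is summarised two ways: *diversity*, the
number of distinct syllable types emitted (0 to 15), and *composition*, the
per-type count profile.  Composition profiles are compared across groups
with the standard community-ecology toolbox on the Bray-Curtis
dissimilarity d(x, y) = sum|x_i - y_i| / sum(x_i + y_i):

- ANOSIM: rank-based R in [-1, 1], R = (mean between-group rank - mean
  within-group rank) / (M/2) with M = n(n-1)/2 pairs, tested by permuting
  group labels.
- PERMANOVA: pseudo-F from the partition of squared dissimilarities into
  between- and within-group sums (Gower identity: within-group sum of
  squares = sum of squared pairwise dissimilarities / group size), tested
  by permutation.
- nMDS: Kruskal stress-1 minimised by SMACOF iterations with isotonic
  (monotone) regression disparities, over several random starts.
- SIMPER: decomposition of the average between-group Bray-Curtis into
  per-type contributions |x_i - y_i| / sum_j(x_j + y_j), ranked with a
  cumulative-percentage cutoff.

All permutation p-values use the add-one convention
p = (1 + #{permuted statistic >= observed}) / (1 + n_permutations), so the
smallest attainable p with 999 permutations is 0.001.  Subjects that never
vocalized (all-zero profiles) leave Bray-Curtis undefined and are excluded
from composition analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "RepertoireCounts",
    "PermutationResult",
    "diversity",
    "bray_curtis",
    "dissimilarity_matrix",
    "anosim",
    "permanova",
    "nmds",
    "simper",
    "stress_interpretation",
]


@dataclass(frozen=True)
class RepertoireCounts:
    """Per-subject syllable-type counts over the ultrasonic vocabulary."""

    subject_id: str
    group: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c)


@dataclass(frozen=True)
class PermutationResult:
    statistic: float
    p_value: float
    n_permutations: int
    seed: int
    name: str = ""


def diversity(counts: np.ndarray | RepertoireCounts) -> int:
    """Number of syllable types with a non-zero count (0 = silent,
    15 = every type used)."""
    c = counts.counts if isinstance(counts, RepertoireCounts) else np.asarray(counts)
    return int((c > 0).sum())


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("count vectors differ in length")
    denom = (x + y).sum()
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero profiles")
    return float(np.abs(x - y).sum() / denom)


def dissimilarity_matrix(counts: np.ndarray, exclude_silent: bool = True):
    """Pairwise Bray-Curtis matrix for an n x types count table.

    Returns (matrix, kept_row_indices).  All-zero (silent) rows are dropped
    when ``exclude_silent``; otherwise they raise.
    """
    counts = np.asarray(counts, dtype=float)
    nonzero = counts.sum(axis=1) > 0
    if exclude_silent:
        kept = np.flatnonzero(nonzero)
        counts = counts[kept]
    else:
        if not nonzero.all():
            raise ValueError("all-zero profile present; Bray-Curtis undefined")
        kept = np.arange(counts.shape[0])
    n = counts.shape[0]
    d = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    vals = np.abs(counts[iu] - counts[ju]).sum(axis=1) / (
        counts[iu] + counts[ju]
    ).sum(axis=1)
    d[iu, ju] = vals
    d[ju, iu] = vals
    return d, kept


def _check_matrix_groups(d: np.ndarray, groups) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    groups = np.asarray(groups)
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T) or groups.size != n:
        raise ValueError("need a square symmetric matrix with one label per row")
    _, counts = np.unique(groups, return_counts=True)
    if counts.size < 2 or (counts < 2).any():
        raise ValueError("need >= 2 groups with >= 2 members each")
    return groups


def _permuted_labels(groups: np.ndarray, n_perm: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return np.array([rng.permutation(groups) for _ in range(n_perm)])


def anosim(
    d: np.ndarray, groups, n_perm: int = 999, seed: int = 0
) -> PermutationResult:
    """Analysis of similarities on a dissimilarity matrix.

    R = (mean rank of between-group dissimilarities - mean rank of
    within-group dissimilarities) / (M/2), with mid-ranks for ties.  R is 0
    under the null, near 1 when groups are well separated, negative when
    within-group dissimilarities exceed between-group ones.
    """
    groups = _check_matrix_groups(d, groups)
    n = len(groups)
    iu, ju = np.triu_indices(n, k=1)
    ranks = rankdata(np.asarray(d)[iu, ju])
    m = ranks.size
    denom = m / 2.0

    def stat(labels_rows: np.ndarray) -> np.ndarray:
        within = labels_rows[..., iu] == labels_rows[..., ju]
        r_w = (within * ranks).sum(axis=-1) / within.sum(axis=-1)
        between = ~within
        r_b = (between * ranks).sum(axis=-1) / between.sum(axis=-1)
        return (r_b - r_w) / denom

    observed = float(stat(groups[None, :])[0])
    # integer-encode for permutation comparisons
    codes = np.unique(groups, return_inverse=True)[1]
    perms = _permuted_labels(codes, n_perm, seed)
    perm_stats = stat(perms)
    p = (1 + int((perm_stats >= observed).sum())) / (1 + n_perm)
    return PermutationResult(observed, p, n_perm, seed, name="ANOSIM R")


def _permanova_f(d2_cond: np.ndarray, iu, ju, labels_rows: np.ndarray, n: int):
    """Pseudo-F for each row of labels; vectorised over permutations."""
    labels_rows = np.atleast_2d(labels_rows)
    levels = np.unique(labels_rows[0])
    g = levels.size
    ss_t = d2_cond.sum() / n
    ss_w = np.zeros(labels_rows.shape[0])
    for lev in levels:
        is_lev = labels_rows == lev
        n_lev = is_lev[0].sum()
        within = is_lev[..., iu] & is_lev[..., ju]
        ss_w += (within * d2_cond).sum(axis=-1) / n_lev
    ss_a = ss_t - ss_w
    with np.errstate(divide="ignore"):  # ss_w = 0: perfect separation, F = inf
        return (ss_a / (g - 1)) / (ss_w / (n - g))


def permanova(
    d: np.ndarray, groups, n_perm: int = 999, seed: int = 0
) -> PermutationResult:
    """Permutational multivariate ANOVA: pseudo-F over squared
    dissimilarities, significance by label permutation.  For 1-D Euclidean
    distances the pseudo-F equals the classical one-way ANOVA F."""
    groups = _check_matrix_groups(d, groups)
    n = len(groups)
    iu, ju = np.triu_indices(n, k=1)
    d2 = np.asarray(d, dtype=float)[iu, ju] ** 2
    observed = float(_permanova_f(d2, iu, ju, groups[None, :], n)[0])
    codes = np.unique(groups, return_inverse=True)[1]
    perms = _permuted_labels(codes, n_perm, seed)
    perm_stats = _permanova_f(d2, iu, ju, perms, n)
    p = (1 + int((perm_stats >= observed).sum())) / (1 + n_perm)
    return PermutationResult(observed, p, n_perm, seed, name="PERMANOVA pseudo-F")


def _nmds_single(
    d_cond: np.ndarray, n: int, k: int, rng, max_iter: int, tol: float
) -> tuple[np.ndarray, float]:
    iso = IsotonicRegression()
    x = rng.standard_normal((n, k))
    prev = np.inf
    stress = np.inf
    iu, ju = np.triu_indices(n, k=1)
    for _ in range(max_iter):
        dist = pdist(x)
        dist = np.maximum(dist, 1e-12)
        dhat = iso.fit(d_cond, dist).predict(d_cond)
        stress = float(np.sqrt(((dist - dhat) ** 2).sum() / (dist**2).sum()))
        if prev - stress < tol:
            break
        prev = stress
        # Guttman transform with unit weights
        ratio = dhat / dist
        b = np.zeros((n, n))
        b[iu, ju] = -ratio
        b[ju, iu] = -ratio
        np.fill_diagonal(b, -b.sum(axis=1))
        x = b @ x / n
    return x, stress


def nmds(
    d: np.ndarray,
    k: int = 2,
    n_starts: int = 21,
    max_iter: int = 300,
    seed: int = 0,
    tol: float = 1e-7,
):
    """Non-metric MDS minimising Kruskal stress-1.

    Runs ``n_starts`` random initialisations (21 by default) of SMACOF
    iterations with monotone-regression disparities and returns the best
    configuration, its stress, and the mean stress across starts.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if n < k + 2:
        raise ValueError(f"need at least k+2={k + 2} points for k={k} dimensions")
    iu, ju = np.triu_indices(n, k=1)
    d_cond = d[iu, ju]
    rng = np.random.default_rng(seed)
    stresses = []
    best_x, best_stress = None, np.inf
    for _ in range(n_starts):
        x, stress = _nmds_single(d_cond, n, k, rng, max_iter, tol)
        stresses.append(stress)
        if stress < best_stress:
            best_x, best_stress = x, stress
    return best_x, best_stress, float(np.mean(stresses))


def stress_interpretation(stress: float) -> str:
    """Conventional verbal reading of a Kruskal stress-1 value."""
    if stress < 0.05:
        return "excellent"
    if stress < 0.1:
        return "good"
    if stress < 0.2:
        return "fair"
    if stress < 0.3:
        return "poor"
    return "near-arbitrary"


def simper(
    counts: pd.DataFrame, groups, cumulative_cutoff: float = 0.70
) -> pd.DataFrame:
    """Similarity-percentages decomposition.

    For every group pair, the contribution of type t averaged over all
    cross-group subject pairs (x, y) is |x_t - y_t| / sum_j(x_j + y_j);
    contributions sum to the mean between-group Bray-Curtis.  Types are
    ranked by contribution; ``in_top`` marks those within the cumulative
    cutoff (70% by convention).
    """
    groups = np.asarray(groups)
    x = counts.to_numpy(dtype=float)
    if x.shape[0] != groups.size:
        raise ValueError("one group label per row required")
    levels = [lev for lev in pd.unique(groups)]
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    rows = []
    for a_i, a in enumerate(levels):
        for b in levels[a_i + 1 :]:
            xa = x[groups == a]
            xb = x[groups == b]
            contribs = np.zeros(x.shape[1])
            n_pairs = 0
            for va in xa:
                for vb in xb:
                    denom = (va + vb).sum()
                    if denom == 0:
                        raise ValueError(
                            "all-zero profile pair; exclude silent subjects first"
                        )
                    contribs += np.abs(va - vb) / denom
                    n_pairs += 1
            contribs /= n_pairs
            total = contribs.sum()
            order = np.argsort(-contribs, kind="stable")
            cum = 0.0
            for rank, t in enumerate(order, start=1):
                frac = contribs[t] / total if total > 0 else 0.0
                in_top = cum < cumulative_cutoff
                cum += frac
                rows.append(
                    {
                        "group_a": a,
                        "group_b": b,
                        "type": counts.columns[t],
                        "contribution": contribs[t],
                        "pct": 100.0 * frac,
                        "cumulative_pct": 100.0 * cum,
                        "rank": rank,
                        "in_top": in_top,
                        "mean_between_bc": total,
                    }
                )
    return pd.DataFrame(rows)
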