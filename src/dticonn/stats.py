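"""Edge-wise group statistics for stacked connectivity matrices.

Group differences are tested with a nonparametric permutation test on the
per-edge difference of group means.  Family-wise error across the edge
family is controlled with the single-step max-statistic construction: each
permutation reassigns subjects to the two groups (keeping the group sizes
fixed), all edge statistics are recomputed, and the corrected p-value of an
edge compares its observed |T| with the permutation distribution of the
maximum |T| over all tested edges.  The add-one estimator
p = (1 + #{perm >= obs}) / (n_perm + 1) keeps Monte-Carlo p-values valid
and strictly positive.  An exhaustive mode enumerates every group
assignment for small cohorts and reports exact proportions.

Clinical-score screening pools both groups per edge and computes Spearman's
rank correlation (rank both vectors with average ranks for ties, then
Pearson on the ranks) with a large-sample t approximation for the raw
p-value, followed by Holm-Bonferroni step-down correction over the tested
edge family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "CohortStack",
    "PermutationResult",
    "CorrelationResult",
    "permutation_group_test",
    "spearman_rho",
    "spearman_rho_pvalue",
    "holm_bonferroni",
    "correlate_edges_with_scores",
]

_EXHAUSTIVE_LIMIT = 500_000


@dataclass
class CohortStack:
    """Per-subject connectivity matrices with group labels and scores."""

    matrices: np.ndarray  # (n_subjects, R, R)
    group_labels: np.ndarray  # (n_subjects,) str
    scores: np.ndarray  # (n_subjects,) int
    subject_ids: list[str]
    groups: tuple[str, str]  # (group A, group B); statistic is mean(A) - mean(B)
    region_names: list[str] | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrices)
        if m.ndim != 3 or m.shape[1] != m.shape[2]:
            raise ValueError("matrices must be (n_subjects, R, R)")
        if not np.array_equal(m, np.transpose(m, (0, 2, 1))):
            raise ValueError("matrices must be symmetric")
        self.matrices = m
        self.group_labels = np.asarray(self.group_labels)
        self.scores = np.asarray(self.scores)
        if len(self.group_labels) != m.shape[0] or len(self.scores) != m.shape[0]:
            raise ValueError("labels/scores length must match subject count")
        ga, gb = self.groups
        na = int(np.sum(self.group_labels == ga))
        nb = int(np.sum(self.group_labels == gb))
        if na + nb != m.shape[0]:
            raise ValueError("every subject must belong to one of the two groups")
        if na < 2 or nb < 2:
            raise ValueError("each group needs at least 2 subjects")

    @property
    def n_regions(self) -> int:
        return self.matrices.shape[1]

    @property
    def n_subjects(self) -> int:
        return self.matrices.shape[0]

    def edge_vectors(self):
        """(subject x edge matrix, upper-triangle (i, j) index arrays)."""
        iu, ju = np.triu_indices(self.n_regions, k=1)
        return self.matrices[:, iu, ju].astype(float), iu, ju


@dataclass
class PermutationResult:
    """Edge-wise permutation test output.

    Arrays are aligned with ``edges`` (the tested upper-triangle pairs);
    edges that were all-zero in every subject are excluded as untestable.
    """

    edges: list[tuple[int, int]]
    observed_stat: np.ndarray
    p_uncorrected: np.ndarray
    p_corrected: np.ndarray
    n_permutations: int
    alpha: float
    seed: int | None
    method: str
    significant_edges: list[tuple[int, int]] = field(default_factory=list)
    group_means: np.ndarray | None = None  # (2, n_edges): group A, group B
    group_sds: np.ndarray | None = None


@dataclass
class CorrelationResult:
    """Spearman screening output over a tested edge family."""

    edges: list[tuple[int, int]]
    rho: np.ndarray
    p_raw: np.ndarray
    p_corrected: np.ndarray
    rejected: np.ndarray
    alpha: float
    excluded_edges: list[tuple[int, int]] = field(default_factory=list)

    @property
    def significant_edges(self) -> list[tuple[int, int]]:
        return [e for e, r in zip(self.edges, self.rejected) if r]


def _group_weight_rows(perm_rows: np.ndarray, n_a: int, n_subjects: int) -> np.ndarray:
    """Rows of +1/n_a, -1/n_b contrasts for a batch of permuted assignments."""
    n_b = n_subjects - n_a
    w = np.full(perm_rows.shape, -1.0 / n_b)
    np.put_along_axis(w, np.argsort(perm_rows, axis=1)[:, :n_a], 1.0 / n_a, axis=1)
    return w


def permutation_group_test(
    stack: CohortStack,
    n_permutations: int = 10_000,
    alpha: float = 0.05,
    seed: int | None = None,
    method: str = "montecarlo",
) -> PermutationResult:
    """Two-sided permutation test of mean(group A) - mean(group B) per edge.

    ``method="montecarlo"`` draws ``n_permutations`` random reassignments of
    the fixed group sizes (add-one p estimator); ``method="exhaustive"``
    enumerates all C(n, n_a) assignments and reports exact proportions.
    Corrected p-values use the single-step max-|T| distribution over the
    tested edges; ``significant_edges`` holds edges with corrected p < alpha.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if method not in ("montecarlo", "exhaustive"):
        raise ValueError("method must be 'montecarlo' or 'exhaustive'")

    X, iu, ju = stack.edge_vectors()
    tested = np.any(X != 0, axis=0)
    Xt = X[:, tested]
    edges = [(int(i), int(j)) for i, j in zip(iu[tested], ju[tested])]
    if not edges:  # every edge all-zero: nothing is testable
        empty = np.array([])
        return PermutationResult(
            edges=[], observed_stat=empty, p_uncorrected=empty, p_corrected=empty,
            n_permutations=0, alpha=alpha, seed=seed, method=method,
            group_means=empty.reshape(2, 0), group_sds=empty.reshape(2, 0),
        )

    ga, gb = stack.groups
    is_a = stack.group_labels == ga
    n = stack.n_subjects
    n_a = int(is_a.sum())
    t_obs = Xt[is_a].mean(axis=0) - Xt[~is_a].mean(axis=0)
    abs_obs = np.abs(t_obs)

    if method == "exhaustive":
        n_comb = math.comb(n, n_a)
        if n_comb > _EXHAUSTIVE_LIMIT:
            raise ValueError(
                f"exhaustive enumeration of C({n}, {n_a}) = {n_comb} assignments refused"
            )
        count_edge = np.zeros(Xt.shape[1], dtype=int)
        count_max = np.zeros(Xt.shape[1], dtype=int)
        n_b = n - n_a
        for combo in combinations(range(n), n_a):
            sel = np.zeros(n, dtype=bool)
            sel[list(combo)] = True
            t_perm = Xt[sel].mean(axis=0) - Xt[~sel].mean(axis=0)
            abs_perm = np.abs(t_perm)
            count_edge += abs_perm >= abs_obs - 1e-12
            count_max += abs_perm.max() >= abs_obs - 1e-12
        p_unc = count_edge / n_comb
        p_cor = count_max / n_comb
        n_used = n_comb
    else:
        rng = np.random.default_rng(seed)
        perm = rng.random((n_permutations, n))
        W = _group_weight_rows(perm, n_a, n)
        T = W @ Xt  # (n_perm, n_edges)
        abs_T = np.abs(T)
        max_T = abs_T.max(axis=1)
        p_unc = (1 + np.sum(abs_T >= abs_obs[None, :] - 1e-12, axis=0)) / (n_permutations + 1)
        p_cor = (1 + np.sum(max_T[:, None] >= abs_obs[None, :] - 1e-12, axis=0)) / (
            n_permutations + 1
        )
        n_used = n_permutations

    significant = [e for e, p in zip(edges, p_cor) if p < alpha]
    group_means = np.vstack([Xt[is_a].mean(axis=0), Xt[~is_a].mean(axis=0)])
    group_sds = np.vstack([Xt[is_a].std(axis=0, ddof=1), Xt[~is_a].std(axis=0, ddof=1)])
    return PermutationResult(
        edges=edges,
        observed_stat=t_obs,
        p_uncorrected=p_unc,
        p_corrected=p_cor,
        n_permutations=n_used,
        alpha=alpha,
        seed=seed,
        method=method,
        significant_edges=significant,
        group_means=group_means,
        group_sds=group_sds,
    )


def spearman_rho(x, y) -> float:
    """Spearman's rank correlation: average ranks, then Pearson on ranks.

    Raises ``ValueError`` on unequal lengths, n < 3, or a constant input
    (the coefficient is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("spearman_rho undefined for a constant input")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman_rho_pvalue(x, y) -> tuple[float, float]:
    """(rho, two-sided p) with the large-sample t approximation.

    t = rho * sqrt((n - 2) / (1 - rho^2)) on n - 2 degrees of freedom.
    """
    rho = spearman_rho(x, y)
    n = len(x)
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return rho, float(min(1.0, p))


def holm_bonferroni(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Holm's step-down procedure: (adjusted p-values, rejection flags).

    The k-th smallest p is rejected while p_(k) <= alpha / (m - k + 1),
    stopping at the first failure; the adjusted value is
    min(1, cummax((m - k + 1) * p_(k))), mapped back to input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D vector")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    factors = m - np.arange(m)
    adj_sorted = np.minimum(1.0, np.maximum.accumulate(factors * p[order]))
    reject_sorted = np.zeros(m, dtype=bool)
    for k in range(m):
        if p[order[k]] <= alpha / (m - k):
            reject_sorted[k] = True
        else:
            break
    adjusted = np.empty(m)
    rejected = np.empty(m, dtype=bool)
    adjusted[order] = adj_sorted
    rejected[order] = reject_sorted
    return adjusted, rejected


def correlate_edges_with_scores(
    stack: CohortStack,
    edges: list[tuple[int, int]],
    alpha: float = 0.001,
) -> CorrelationResult:
    """Spearman screening of edge weights against the clinical score.

    Subjects of both groups are pooled per edge.  Edges with a constant
    weight vector (undefined correlation) are excluded from the family and
    reported in ``excluded_edges``.  Holm-Bonferroni correction is applied
    over the tested family, with rejection at the stated alpha.
    """
    if not edges:
        raise ValueError("edges must be non-empty")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    scores = stack.scores.astype(float)
    kept: list[tuple[int, int]] = []
    excluded: list[tuple[int, int]] = []
    rhos: list[float] = []
    praw: list[float] = []
    for i, j in edges:
        w = stack.matrices[:, i, j].astype(float)
        try:
            rho, p = spearman_rho_pvalue(w, scores)
        except ValueError:
            excluded.append((int(i), int(j)))
            continue
        kept.append((int(i), int(j)))
        rhos.append(rho)
        praw.append(p)
    if not kept:
        return CorrelationResult(
            edges=[],
            rho=np.array([]),
            p_raw=np.array([]),
            p_corrected=np.array([]),
            rejected=np.array([], dtype=bool),
            alpha=alpha,
            excluded_edges=excluded,
        )
    adjusted, rejected = holm_bonferroni(np.array(praw), alpha=alpha)
    return CorrelationResult(
        edges=kept,
        rho=np.array(rhos),
        p_raw=np.array(praw),
        p_corrected=adjusted,
        rejected=rejected,
        alpha=alpha,
        excluded_edges=excluded,
    )
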