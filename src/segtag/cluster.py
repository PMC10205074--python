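"""Cluster-based permutation tests, nonparametric ROI tests, mixed ANOVA.

The cluster test thresholds node-wise t statistics at the cluster-alpha
level, groups suprathreshold nodes by adjacency (requiring a minimum
number of suprathreshold neighbors), and compares each observed cluster's
summed t against the Monte-Carlo distribution of the most extreme cluster
statistic under random condition exchange, two-sided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

from .corpus import mann_whitney

__all__ = ["AdjacencyGraph", "ClusterResult", "build_adjacency",
           "cluster_permutation", "roi_tests", "mixed_anova"]


@dataclass
class AdjacencyGraph:
    positions: np.ndarray
    neighbors: list[np.ndarray]     # per-node neighbor index arrays

    def __post_init__(self) -> None:
        for i, nb in enumerate(self.neighbors):
            if i in nb:
                raise ValueError("self-neighbors are not allowed")
        for i, nb in enumerate(self.neighbors):
            for j in nb:
                if i not in self.neighbors[j]:
                    raise ValueError("adjacency must be symmetric")

    @property
    def n_nodes(self) -> int:
        return len(self.neighbors)

    def matrix(self) -> sparse.csr_matrix:
        rows = [i for i, nb in enumerate(self.neighbors) for _ in nb]
        cols = [j for nb in self.neighbors for j in nb]
        data = np.ones(len(rows), bool)
        return sparse.csr_matrix((data, (rows, cols)),
                                 shape=(self.n_nodes, self.n_nodes))


def build_adjacency(positions: np.ndarray, max_dist: float) -> AdjacencyGraph:
    """Neighbors are nodes strictly within ``max_dist`` (inclusive), excluding self."""
    positions = np.asarray(positions, float)
    d = np.linalg.norm(positions[:, None] - positions[None], axis=2)
    neighbors = []
    for i in range(positions.shape[0]):
        nb = np.flatnonzero((d[i] <= max_dist + 1e-12) & (np.arange(len(d)) != i))
        neighbors.append(nb)
    return AdjacencyGraph(positions, neighbors)


@dataclass
class ClusterResult:
    clusters: list[tuple[np.ndarray, float, int]]   # (node set, summed t, sign)
    p_values: np.ndarray
    n_permutations: int
    cluster_alpha: float
    t_values: np.ndarray
    perm_distribution: np.ndarray

    def significant(self, alpha: float = 0.05) -> list[int]:
        return [i for i, p in enumerate(self.p_values) if p <= alpha]


def _paired_t(diff: np.ndarray) -> np.ndarray:
    n = diff.shape[0]
    m = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    sd[sd == 0] = np.inf
    return m / (sd / np.sqrt(n))


def _independent_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    n1, n2 = a.shape[0], b.shape[0]
    v1 = a.var(axis=0, ddof=1)
    v2 = b.var(axis=0, ddof=1)
    sp = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    denom = np.sqrt(sp * (1 / n1 + 1 / n2))
    denom[denom == 0] = np.inf
    return (a.mean(axis=0) - b.mean(axis=0)) / denom


def _find_clusters(t: np.ndarray, t_crit: float, graph: AdjacencyGraph,
                   adj: sparse.csr_matrix, min_neighbors: int
                   ) -> list[tuple[np.ndarray, float, int]]:
    clusters = []
    for sign in (1, -1):
        mask = (sign * t) > t_crit
        if min_neighbors > 0:
            # keep only nodes supported by enough suprathreshold neighbors
            support = adj.dot(mask.astype(int))
            mask = mask & (support >= min_neighbors)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        sub = adj[idx][:, idx]
        n_comp, labels = connected_components(sub, directed=False)
        for c in range(n_comp):
            nodes = idx[labels == c]
            clusters.append((nodes, float(t[nodes].sum()), sign))
    return clusters


def _max_cluster_stat(t: np.ndarray, t_crit: float, graph: AdjacencyGraph,
                      adj: sparse.csr_matrix, min_neighbors: int) -> float:
    cl = _find_clusters(t, t_crit, graph, adj, min_neighbors)
    if not cl:
        return 0.0
    sums = np.array([c[1] for c in cl])
    return float(sums[np.argmax(np.abs(sums))])


def cluster_permutation(valuesA: np.ndarray, valuesB: np.ndarray, design: str,
                        graph: AdjacencyGraph, n_perm: int = 1000,
                        cluster_alpha: float = 0.05, min_neighbors: int = 2,
                        seed: int = 0) -> ClusterResult:
    """Monte-Carlo cluster permutation test between two condition maps.

    ``valuesA``/``valuesB`` are (subjects, nodes); for the paired design
    condition labels are exchanged within subject (sign flips of the
    difference), for the unpaired design group labels are permuted.  Each
    permutation records the most extreme summed cluster t; the two-sided
    Monte-Carlo p of each observed cluster is (b + 1) / (n_perm + 1).
    """
    A = np.asarray(valuesA, float)
    B = np.asarray(valuesB, float)
    if design not in ("paired", "unpaired"):
        raise ValueError("design must be 'paired' or 'unpaired'")
    if design == "paired" and A.shape != B.shape:
        raise ValueError("paired design requires matched subject counts")
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations gives a coarse p value")
    rng = np.random.default_rng(seed)
    adj = graph.matrix()

    if design == "paired":
        diff = A - B
        n = diff.shape[0]
        df = n - 1
        t_obs = _paired_t(diff)
    else:
        n1 = A.shape[0]
        df = n1 + B.shape[0] - 2
        t_obs = _independent_t(A, B)
    t_crit = stats.t.ppf(1 - cluster_alpha / 2, df)

    observed = _find_clusters(t_obs, t_crit, graph, adj, min_neighbors)
    if not observed:
        return ClusterResult([], np.array([]), n_perm, cluster_alpha, t_obs,
                             np.array([]))

    perm_stats = np.empty(n_perm)
    if design == "paired":
        for p in range(n_perm):
            signs = rng.choice([-1.0, 1.0], size=diff.shape[0])[:, None]
            perm_stats[p] = _max_cluster_stat(_paired_t(signs * diff), t_crit,
                                              graph, adj, min_neighbors)
    else:
        pooled = np.vstack([A, B])
        n1 = A.shape[0]
        for p in range(n_perm):
            idx = rng.permutation(pooled.shape[0])
            pa, pb = pooled[idx[:n1]], pooled[idx[n1:]]
            perm_stats[p] = _max_cluster_stat(_independent_t(pa, pb), t_crit,
                                              graph, adj, min_neighbors)

    p_values = np.array([
        (np.sum(np.abs(perm_stats) >= abs(s)) + 1) / (n_perm + 1)
        for _, s, _ in observed])
    return ClusterResult(observed, p_values, n_perm, cluster_alpha, t_obs,
                         perm_stats)


def roi_tests(valuesA: np.ndarray, valuesB: np.ndarray,
              rois: dict[str, np.ndarray], design: str, alpha: float = 0.05,
              n_tests: int | None = None) -> dict[str, dict]:
    """Nonparametric per-ROI condition tests with Bonferroni correction.

    ROI values are node means per subject; paired data use the Wilcoxon
    signed-rank test (exact null for small samples), unpaired data the
    Mann-Whitney test.  The corrected alpha is ``alpha / n_tests`` with
    ``n_tests`` defaulting to the number of ROIs.
    """
    A = np.asarray(valuesA, float)
    B = np.asarray(valuesB, float)
    if n_tests is None:
        n_tests = len(rois)
    corrected_alpha = alpha / n_tests
    out: dict[str, dict] = {}
    for name, idx in rois.items():
        a = A[:, idx].mean(axis=1)
        b = B[:, idx].mean(axis=1)
        if design == "paired":
            d = a - b
            if np.all(d == 0):
                p = 1.0
            else:
                method = "exact" if (a.size <= 25 and not np.any(d == 0)
                                     and np.unique(np.abs(d)).size == d.size) \
                    else "approx"
                p = float(stats.wilcoxon(a, b, alternative="two-sided",
                                         method=method).pvalue)
        elif design == "unpaired":
            _, p = mann_whitney(a, b)
        else:
            raise ValueError("design must be 'paired' or 'unpaired'")
        out[name] = {"p": p, "significant": p < corrected_alpha,
                     "corrected_alpha": corrected_alpha}
    return out


def mixed_anova(data, dv: str = "value", subject: str = "participant",
                between: str = "experiment",
                within: tuple[str, str] = ("condition", "hemisphere")) -> dict:
    """Split-plot ANOVA: one between-subject and two within-subject factors.

    Expects a long-format DataFrame with complete within-subject cells
    (every subject measured in every within-factor combination).  Returns
    F, degrees of freedom, p, and partial eta squared for every main
    effect and interaction; within-subject effects use their
    factor-by-subject interaction error terms.
    """
    import pandas as pd

    df = pd.DataFrame(data)
    b_levels = np.sort(df[between].unique())
    w1_levels = np.sort(df[within[0]].unique())
    w2_levels = np.sort(df[within[1]].unique())
    a, b, c = len(b_levels), len(w1_levels), len(w2_levels)

    cell = df.groupby([between, subject, within[0], within[1]])[dv]
    per_subject = df.groupby([between, subject]).size()
    if (cell.count() != 1).any() or (per_subject != b * c).any():
        raise ValueError("design must have exactly one observation per cell")

    # y[g][s, j, k] per group
    groups = []
    for g in b_levels:
        sub = df[df[between] == g]
        subs = np.sort(sub[subject].unique())
        y = np.empty((len(subs), b, c))
        piv = sub.set_index([subject, within[0], within[1]])[dv]
        for si, s in enumerate(subs):
            for j, w1 in enumerate(w1_levels):
                for k, w2 in enumerate(w2_levels):
                    y[si, j, k] = piv.loc[(s, w1, w2)]
        groups.append(y)
    ns = np.array([g.shape[0] for g in groups])
    N = ns.sum()
    ally = np.concatenate(groups, axis=0)
    M = ally.mean()

    Mg = np.array([g.mean() for g in groups])
    Mgs = [g.mean(axis=(1, 2)) for g in groups]                 # per subject
    Mj = ally.mean(axis=(0, 2))
    Mk = ally.mean(axis=(0, 1))
    Mjk = ally.mean(axis=0)
    Mgj = np.array([g.mean(axis=(0, 2)) for g in groups])       # (a, b)
    Mgk = np.array([g.mean(axis=(0, 1)) for g in groups])       # (a, c)
    Mgjk = np.array([g.mean(axis=0) for g in groups])           # (a, b, c)
    Mgsj = [g.mean(axis=2) for g in groups]                     # (n_g, b)
    Mgsk = [g.mean(axis=1) for g in groups]                     # (n_g, c)

    ss = {}
    ss["between"] = b * c * float(np.sum(ns * (Mg - M) ** 2))
    ss["subj"] = b * c * float(sum(((Mgs[g] - Mg[g]) ** 2).sum()
                                   for g in range(a)))
    ss["w1"] = N * c * float(np.sum((Mj - M) ** 2))
    ss["bw1"] = c * float(sum(ns[g] * ((Mgj[g] - Mg[g] - Mj + M) ** 2).sum()
                              for g in range(a)))
    ss["w1_err"] = c * float(sum(((Mgsj[g] - Mgs[g][:, None] - Mgj[g][None]
                                   + Mg[g]) ** 2).sum() for g in range(a)))
    ss["w2"] = N * b * float(np.sum((Mk - M) ** 2))
    ss["bw2"] = b * float(sum(ns[g] * ((Mgk[g] - Mg[g] - Mk + M) ** 2).sum()
                              for g in range(a)))
    ss["w2_err"] = b * float(sum(((Mgsk[g] - Mgs[g][:, None] - Mgk[g][None]
                                   + Mg[g]) ** 2).sum() for g in range(a)))
    ss["w1w2"] = N * float(np.sum((Mjk - Mj[:, None] - Mk[None] + M) ** 2))
    ss["bw1w2"] = float(sum(
        ns[g] * ((Mgjk[g] - Mgj[g][:, None] - Mgk[g][None] - Mjk
                  + Mg[g] + Mj[:, None] + Mk[None] - M) ** 2).sum()
        for g in range(a)))
    ss["w1w2_err"] = float(sum(
        ((groups[g] - Mgsj[g][:, :, None] - Mgsk[g][:, None, :]
          - Mgjk[g][None] + Mgs[g][:, None, None] + Mgj[g][None, :, None]
          + Mgk[g][None, None, :] - Mg[g]) ** 2).sum() for g in range(a)))

    dfs = {
        "between": (a - 1, int(N - a), "subj"),
        "w1": (b - 1, int((N - a) * (b - 1)), "w1_err"),
        "bw1": ((a - 1) * (b - 1), int((N - a) * (b - 1)), "w1_err"),
        "w2": (c - 1, int((N - a) * (c - 1)), "w2_err"),
        "bw2": ((a - 1) * (c - 1), int((N - a) * (c - 1)), "w2_err"),
        "w1w2": ((b - 1) * (c - 1), int((N - a) * (b - 1) * (c - 1)), "w1w2_err"),
        "bw1w2": ((a - 1) * (b - 1) * (c - 1),
                  int((N - a) * (b - 1) * (c - 1)), "w1w2_err"),
    }
    names = {"between": between, "w1": within[0], "w2": within[1],
             "bw1": f"{between}*{within[0]}", "bw2": f"{between}*{within[1]}",
             "w1w2": f"{within[0]}*{within[1]}",
             "bw1w2": f"{between}*{within[0]}*{within[1]}"}
    out = {}
    for key, (df1, df2, err) in dfs.items():
        ms = ss[key] / df1 if df1 else np.nan
        mse = ss[err] / df2 if df2 else np.nan
        if mse == 0:
            F = 0.0 if ss[key] == 0 else np.inf
            p = 1.0 if ss[key] == 0 else 0.0
        else:
            F = ms / mse
            p = float(stats.f.sf(F, df1, df2))
        denom = ss[key] + ss[err]
        out[names[key]] = {
            "F": float(F), "df": (df1, df2), "p": p,
            "partial_eta_sq": float(ss[key] / denom) if denom else 0.0,
            "ss": ss[key], "ss_error": ss[err],
        }
    return out
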