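"""Independent brute-force oracles used by the test suite.

Everything here is written as literal, loop-based re-implementations of the
definitions (direct sums, exhaustive enumerations), deliberately sharing no
code path with the package.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def normal_cdf(v: float) -> float:
    return 0.5 * (1.0 + math.erf(v / math.sqrt(2.0)))


def kernel_statistic_oracle(x: np.ndarray, bw_factor: float = 4.0) -> np.ndarray:
    """Direct double-sum Gaussian-kernel CDF statistic, gene by gene."""
    g, n = x.shape
    z = np.zeros((g, n))
    for i in range(g):
        s = float(np.std(x[i], ddof=1))
        h = s / bw_factor
        for j in range(n):
            z[i, j] = sum(normal_cdf((x[i, j] - x[i, k]) / h) for k in range(n))
    return z


def walk_scores_oracle(x: np.ndarray, genes: list[str], sig: set[str],
                       tau: float = 1.0, bw_factor: float = 4.0) -> np.ndarray:
    """Step-by-step random-walk enrichment score, one sample at a time."""
    z = kernel_statistic_oracle(x, bw_factor)
    g, n = x.shape
    out = np.zeros(n)
    for j in range(n):
        zj = z[:, j]
        # average ranks, rank 1 = largest z
        ranks = np.empty(g)
        for i in range(g):
            greater = sum(1 for k in range(g) if zj[k] > zj[i])
            equal = sum(1 for k in range(g) if zj[k] == zj[i])
            ranks[i] = greater + (equal + 1) / 2.0
        d = np.abs(g / 2.0 - ranks) ** tau
        order = sorted(range(g), key=lambda i: (-zj[i], genes[i]))
        m = sum(1 for i in range(g) if genes[i] in sig)
        denom_hit = sum(d[i] for i in order if genes[i] in sig)
        nu_max, nu_min = -np.inf, np.inf
        hit_sum, miss_count = 0.0, 0
        for i in order:
            if genes[i] in sig:
                hit_sum += d[i]
            else:
                miss_count += 1
            nu = hit_sum / denom_hit - miss_count / (g - m)
            nu_max = max(nu_max, nu)
            nu_min = min(nu_min, nu)
        out[j] = max(0.0, nu_max) + min(0.0, nu_min)
    return out


def morans_i_double_sum(x: np.ndarray, y: np.ndarray, w_dense: np.ndarray) -> float:
    """I = sum_i sum_j w_ij zx_i zy_j / sum_i zx_i^2, fully written out."""
    zx = (x - x.mean()) / x.std()
    zy = (y - y.mean()) / y.std()
    n = len(x)
    num = 0.0
    for i in range(n):
        for j in range(n):
            num += w_dense[i, j] * zx[i] * zy[j]
    return num / sum(zx[i] ** 2 for i in range(n))


def mannwhitney_exact_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided p by enumerating every assignment of the pooled values
    (tie-free inputs only)."""
    pooled = np.concatenate([a, b])
    n1 = len(a)

    def u_stat(group_idx: tuple[int, ...]) -> float:
        ga = pooled[list(group_idx)]
        gb = pooled[[i for i in range(len(pooled)) if i not in group_idx]]
        return float(sum(1.0 for x in ga for y in gb if x > y)
                     + 0.5 * sum(1.0 for x in ga for y in gb if x == y))

    observed = u_stat(tuple(range(n1)))
    n1n2 = n1 * (len(pooled) - n1)
    us = [u_stat(c) for c in combinations(range(len(pooled)), n1)]
    # two-sided: fold around the null mean n1 n2 / 2
    dev = abs(observed - n1n2 / 2.0)
    extreme = sum(1 for u in us if abs(u - n1n2 / 2.0) >= dev - 1e-12)
    return extreme / len(us)


def welch_t_closed_form(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch two-sample t and two-sided p from the textbook formulas."""
    from scipy.stats import t as tdist
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t_stat = (ma - mb) / math.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * tdist.sf(abs(t_stat), df)
    return t_stat, p


def qc_filter_literal(qc) -> set:
    """Apply the five removal rules exactly as stated, cell by cell."""
    umi = qc["umi_count"].to_numpy(dtype=float)
    feat = qc["feature_count"].to_numpy(dtype=float)
    mito = qc["mito_fraction"].to_numpy(dtype=float)
    dbl = qc["doublet_score"].to_numpy(dtype=float)
    u5, u95 = np.percentile(umi, 5), np.percentile(umi, 95)
    f5, f95 = np.percentile(feat, 5), np.percentile(feat, 95)
    d90 = np.percentile(dbl, 90)
    kept = set()
    for i, cell in enumerate(qc.index):
        if umi[i] < u5 or umi[i] > u95:
            continue
        if feat[i] < f5 or feat[i] > f95:
            continue
        if mito[i] > 0.05:
            continue
        if dbl[i] > d90:
            continue
        kept.add(cell)
    return kept


def betweenness_brute(adj: np.ndarray) -> np.ndarray:
    """Normalized betweenness by explicit enumeration of all shortest paths."""
    n = adj.shape[0]

    def all_shortest_paths(s: int, t: int) -> list[list[int]]:
        # BFS distances from s
        dist = [math.inf] * n
        dist[s] = 0
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for v in range(n):
                    if adj[u, v] and dist[v] == math.inf:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        if dist[t] == math.inf:
            return []
        paths = []

        def extend(path):
            u = path[-1]
            if u == t:
                paths.append(list(path))
                return
            for v in range(n):
                if adj[u, v] and dist[v] == dist[u] + 1:
                    extend(path + [v])

        extend([s])
        return paths

    cent = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = all_shortest_paths(s, t)
            if not paths:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p)
                cent[v] += through / len(paths)
    norm = (n - 1) * (n - 2) / 2.0
    return cent / norm if norm > 0 else cent


def edge_f1(pred: set, truth: set) -> float:
    tp = len(pred & truth)
    if tp == 0:
        return 0.0
    precision = tp / len(pred)
    recall = tp / len(truth)
    return 2 * precision * recall / (precision + recall)
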