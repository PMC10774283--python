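"""Joint (group) graphical lasso over per-section metabolite matrices.

Estimates one sparse precision matrix per tumor section while encouraging a
shared edge support across sections: the objective is

    sum_k [ tr(S_k Theta_k) - log det Theta_k ]
        + lambda1 * sum_k sum_{i!=j} |Theta_k,ij|
        + lambda2 * sum_{i!=j} sqrt( sum_k Theta_k,ij^2 )

solved by ADMM with a closed-form spectral Theta-step (always SPD), an
elementwise soft-threshold plus groupwise shrinkage Z-step, and scaled dual
updates. Model selection sweeps a (lambda1, lambda2) grid and picks the
minimum extended BIC; networks, betweenness centralities and cross-group
edge-presence summaries are derived from the selected solution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class GGLConfig:
    lambda1_grid: tuple[float, ...] = (0.05, 0.1, 0.15, 0.2, 0.25)
    lambda2_grid: tuple[float, ...] = (0.01, 0.02, 0.03, 0.04, 0.05)
    gamma: float = 20.0          # eBIC sparsity weight; far beyond the usual [0, 1]
    rho: float = 1.0             # ADMM penalty, fixed (no adaptive scaling)
    tol: float = 1e-5
    max_iter: int = 1000
    zero_tol: float = 1e-5

    def __post_init__(self) -> None:
        if any(l <= 0 for l in (*self.lambda1_grid, *self.lambda2_grid)):
            raise ValueError("lambda grids must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.gamma > 1:
            logger.warning("eBIC gamma=%g is outside the usual [0, 1] range; "
                           "this strongly favors sparse networks", self.gamma)


@dataclass
class GGLSolution:
    precisions: list[np.ndarray]         # Theta_k, SPD
    sparse_precisions: list[np.ndarray]  # Z_k, exact zeros define the support
    covariances: list[np.ndarray]        # S_k
    n_obs: list[int]
    lambda1: float
    lambda2: float
    iterations: int
    converged: bool
    zero_tol: float = 1e-5

    def supports(self) -> list[np.ndarray]:
        out = []
        for z in self.sparse_precisions:
            s = np.abs(z) > self.zero_tol
            np.fill_diagonal(s, False)
            out.append(s)
        return out


def section_covariances(sections: list[pd.DataFrame],
                        ) -> tuple[list[np.ndarray], list[int]]:
    """Per-section standardized covariance (= correlation) matrices.

    Each section is spots x metabolites; metabolites are z-scored within the
    section with population normalization (1/n_k), so diag(S_k) = 1.
    """
    covs, ns = [], []
    for idx, sec in enumerate(sections):
        x = sec.to_numpy(dtype=float)
        n = x.shape[0]
        if n < 10:
            raise ValueError(f"section {idx} has fewer than 10 spots")
        sd = x.std(axis=0)
        if (sd == 0).any():
            bad = sec.columns[sd == 0].tolist()
            raise ValueError(f"zero-variance metabolites in section {idx}: {bad}")
        z = (x - x.mean(axis=0)) / sd
        covs.append(z.T @ z / n)
        ns.append(n)
    return covs, ns


def _theta_step(s: np.ndarray, z: np.ndarray, u: np.ndarray, rho: float) -> np.ndarray:
    """argmin tr(S T) - logdet T + rho/2 ||T - Z + U||^2; spectral closed form."""
    a = rho * (z - u) - s
    lam, q = np.linalg.eigh(a)
    theta_eig = (lam + np.sqrt(lam**2 + 4 * rho)) / (2 * rho)
    return (q * theta_eig) @ q.T


def _z_step(a_stack: np.ndarray, lambda1: float, lambda2: float, rho: float,
            ) -> np.ndarray:
    """Elementwise soft threshold then groupwise L2 shrinkage, off-diagonal only."""
    k, p, _ = a_stack.shape
    soft = np.sign(a_stack) * np.maximum(np.abs(a_stack) - lambda1 / rho, 0.0)
    norms = np.sqrt((soft**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = np.maximum(0.0, 1.0 - (lambda2 / rho) / norms)
    factor = np.where(norms > 0, factor, 0.0)
    z = soft * factor[None, :, :]
    diag = np.arange(p)
    z[:, diag, diag] = a_stack[:, diag, diag]  # diagonal unpenalized
    return z


def group_graphical_lasso(covs: list[np.ndarray], n_obs: list[int],
                          lambda1: float, lambda2: float,
                          config: GGLConfig | None = None) -> GGLSolution:
    """ADMM solver for the group graphical lasso at one (lambda1, lambda2)."""
    config = config or GGLConfig()
    p = covs[0].shape[0]
    for s in covs:
        if s.shape != (p, p):
            raise ValueError("covariance matrices disagree in dimension")
    k = len(covs)
    rho = config.rho
    s_stack = np.stack(covs)
    z = np.stack([np.eye(p) for _ in range(k)])
    u = np.zeros_like(z)
    theta = z.copy()

    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        for j in range(k):
            theta[j] = _theta_step(s_stack[j], z[j], u[j], rho)
        z_old = z
        z = _z_step(theta + u, lambda1, lambda2, rho)
        u = u + theta - z
        primal = np.abs(theta - z).max()
        dual = rho * np.abs(z - z_old).max()
        if max(primal, dual) < config.tol:
            converged = True
            break
    if not converged:
        logger.warning("GGL did not converge in %d iterations "
                       "(primal %.2e, dual %.2e)", it, primal, dual)
    # symmetrize against floating-point drift
    theta_sym = [(t + t.T) / 2 for t in theta]
    z_sym = [(zz + zz.T) / 2 for zz in z]
    return GGLSolution(precisions=theta_sym, sparse_precisions=z_sym,
                       covariances=[np.asarray(s) for s in covs], n_obs=list(n_obs),
                       lambda1=lambda1, lambda2=lambda2, iterations=it,
                       converged=converged, zero_tol=config.zero_tol)


def ebic(solution: GGLSolution, gamma: float = 20.0, pooled_n: bool = False,
         ) -> float:
    """Extended BIC of a converged solution.

        sum_k [ n_k (tr(S_k Theta_k) - logdet Theta_k)
                + E_k log n_k + 4 gamma E_k log p ]

    with E_k the nonzero off-diagonal upper-triangle count at zero_tol.
    ``pooled_n`` swaps every n_k for the pooled sample size (exported for
    comparison).
    """
    total = 0.0
    n_pool = sum(solution.n_obs)
    p = solution.precisions[0].shape[0]
    for s, theta, sup, n_k in zip(solution.covariances, solution.precisions,
                                  solution.supports(), solution.n_obs):
        sign, logdet = np.linalg.slogdet(theta)
        if sign <= 0:
            raise ValueError("singular or non-PD precision in eBIC")
        n_eff = n_pool if pooled_n else n_k
        e_k = int(np.triu(sup, 1).sum())
        total += (n_eff * (np.trace(s @ theta) - logdet)
                  + e_k * np.log(n_eff) + 4 * gamma * e_k * np.log(p))
    return float(total)


def sweep_and_select(covs: list[np.ndarray], n_obs: list[int],
                     config: GGLConfig | None = None,
                     ) -> tuple[GGLSolution, pd.DataFrame]:
    """Fit every (lambda1, lambda2) grid pair and return the minimum-eBIC
    solution plus the full score table. Ties break toward larger lambda1
    then larger lambda2 (the sparser, more-shared model)."""
    config = config or GGLConfig()
    rows = []
    best: GGLSolution | None = None
    best_score = np.inf
    for l1 in config.lambda1_grid:
        for l2 in config.lambda2_grid:
            sol = group_graphical_lasso(covs, n_obs, l1, l2, config)
            score = ebic(sol, config.gamma) if sol.converged else np.inf
            rows.append({"lambda1": l1, "lambda2": l2, "ebic": score,
                         "ebic_pooled": ebic(sol, config.gamma, pooled_n=True)
                         if sol.converged else np.inf,
                         "converged": sol.converged, "iterations": sol.iterations})
            better = score < best_score
            tie = (score == best_score and best is not None
                   and (l1, l2) > (best.lambda1, best.lambda2))
            if better or tie:
                best, best_score = sol, score
    if best is None or not np.isfinite(best_score):
        raise RuntimeError("no grid point converged")
    return best, pd.DataFrame(rows)


def networks_and_centrality(solution: GGLSolution, names: list[str],
                            ) -> tuple[list[nx.Graph], pd.DataFrame]:
    """Unweighted undirected graphs from the off-diagonal support and
    normalized betweenness centrality per section."""
    graphs = []
    cent_rows = []
    for sup in solution.supports():
        g = nx.Graph()
        g.add_nodes_from(names)
        for i, j in zip(*np.where(np.triu(sup, 1))):
            g.add_edge(names[i], names[j])
        graphs.append(g)
        cent_rows.append(nx.betweenness_centrality(g, normalized=True))
    centrality = pd.DataFrame(cent_rows).T.fillna(0.0)
    centrality.index.name = "metabolite"
    return graphs, centrality


def edge_presence_summary(graphs: list[nx.Graph], group_labels: list[str],
                          threshold: float = 0.5) -> pd.DataFrame:
    """Classify every observed edge as group-specific, shared, or neither.

    An edge is present in a group when its presence fraction over that
    group's networks is >= threshold.
    """
    labels = sorted(set(group_labels))
    if len(labels) != 2:
        raise ValueError(f"exactly 2 groups required, got {labels}")
    g1, g2 = labels
    all_edges = sorted({tuple(sorted(e)) for g in graphs for e in g.edges})
    rows = []
    for edge in all_edges:
        frac = {}
        for lab in labels:
            members = [g for g, gl in zip(graphs, group_labels) if gl == lab]
            frac[lab] = np.mean([g.has_edge(*edge) for g in members])
        in1, in2 = frac[g1] >= threshold, frac[g2] >= threshold
        if in1 and in2:
            cls = "shared"
        elif in1:
            cls = f"{g1}-specific"
        elif in2:
            cls = f"{g2}-specific"
        else:
            cls = "neither"
        rows.append({"node1": edge[0], "node2": edge[1],
                     f"fraction_{g1}": frac[g1], f"fraction_{g2}": frac[g2],
                     "classification": cls})
    return pd.DataFrame(rows)


def centrality_difference(centrality: pd.DataFrame, group_labels: list[str],
                          ) -> pd.DataFrame:
    """Per-node mean betweenness per group and their difference, ranked
    descending. A node absent from a network counts as centrality 0 there."""
    labels = sorted(set(group_labels))
    if len(labels) != 2:
        raise ValueError(f"exactly 2 groups required, got {labels}")
    g1, g2 = labels
    gl = np.asarray(group_labels)
    mean1 = centrality.loc[:, gl == g1].mean(axis=1)
    mean2 = centrality.loc[:, gl == g2].mean(axis=1)
    out = pd.DataFrame({f"mean_{g1}": mean1, f"mean_{g2}": mean2,
                        "difference": mean1 - mean2})
    return out.sort_values("difference", ascending=False)
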