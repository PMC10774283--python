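"""Resampled k-means consensus co-clustering of signature score matrices.

Signatures are the clustered items; tumors (the columns of the score matrix)
are the features that get subsampled each trial. The consensus matrix M_ab
is the fraction of trials in which signatures a and b land in the same
k-means cluster; because items are never subsampled the denominator is the
trial count, making every entry an exact rational count / n_trials.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cut_tree, leaves_list
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)


@dataclass
class ConsensusConfig:
    n_trials: int = 1000
    feature_subsample_fraction: float = 0.5
    k_range: tuple[int, ...] = tuple(range(2, 11))
    kmeans_restarts: int = 10
    seed: int = 0
    elbow_threshold: float = 0.1
    ambiguity_limit: float = 0.3

    def __post_init__(self) -> None:
        if not (0 < self.feature_subsample_fraction <= 1):
            raise ValueError("feature_subsample_fraction must be in (0, 1]")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass
class ConsensusResult:
    per_k: dict[int, pd.DataFrame]            # k -> signatures x signatures matrix
    chosen_k: int | None = None
    delta_area: pd.DataFrame | None = None
    no_structure: bool = False
    labels: pd.Series | None = None
    order: list[str] | None = None

    def matrix(self, k: int | None = None) -> pd.DataFrame:
        return self.per_k[k if k is not None else self.chosen_k]


def consensus_cluster(scores: pd.DataFrame, config: ConsensusConfig | None = None,
                      ) -> ConsensusResult:
    """Run the subsampled k-means co-clustering for every k in the range.

    ``scores`` is signatures x samples. Per trial, ceil(fraction * n_samples)
    sample columns are drawn without replacement (seeded per trial), k-means
    with Euclidean distance and ``kmeans_restarts`` random initializations is
    run on the signature rows, and co-membership is recorded.
    """
    config = config or ConsensusConfig()
    n_sig, n_samples = scores.shape
    if n_sig < 3:
        raise ValueError("need at least 3 signatures")
    n_sub = int(np.ceil(config.feature_subsample_fraction * n_samples))
    if n_sub < 2:
        raise ValueError("subsample would retain fewer than 2 samples")
    for k in config.k_range:
        if k > n_sig:
            raise ValueError(f"k={k} exceeds the number of signatures ({n_sig})")

    x = scores.to_numpy(dtype=float)
    master = np.random.default_rng(config.seed)
    trial_seeds = master.integers(0, 2**31 - 1, size=config.n_trials)

    counts = {k: np.zeros((n_sig, n_sig)) for k in config.k_range}
    for trial in range(config.n_trials):
        rng = np.random.default_rng(trial_seeds[trial])
        cols = rng.choice(n_samples, size=n_sub, replace=False)
        sub = x[:, cols]
        for k in config.k_range:
            km = KMeans(n_clusters=k, n_init=config.kmeans_restarts,
                        random_state=int(rng.integers(0, 2**31 - 1)))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                lab = km.fit_predict(sub)
            co = (lab[:, None] == lab[None, :])
            counts[k] += co

    per_k = {}
    for k in config.k_range:
        m = counts[k] / config.n_trials
        np.fill_diagonal(m, 1.0)
        per_k[k] = pd.DataFrame(m, index=scores.index, columns=scores.index)
    return ConsensusResult(per_k=per_k)


def _area_under_cdf(m: pd.DataFrame) -> float:
    """Area under the empirical CDF of the upper-triangle consensus values."""
    vals = np.sort(squareform(m.to_numpy(), checks=False))
    n = len(vals)
    if n == 0:
        return 0.0
    # stepwise CDF integrated over [0, 1]
    grid = np.concatenate([vals, [1.0]])
    cdf = np.arange(1, n + 1) / n
    return float(np.sum(cdf * np.diff(grid)))


def choose_k(result: ConsensusResult, threshold: float = 0.1,
             ambiguity_limit: float = 0.3,
             force_k: int | None = None) -> ConsensusResult:
    """Automated elbow over the consensus-CDF area curve.

    The relative change in area under the consensus CDF (delta-area) is
    computed per k; the chosen k is the largest one whose delta-area still
    reaches ``threshold`` — the point after which further splits add no
    material consensus gain. When the consensus matrix at that k remains
    ambiguous (more than ``ambiguity_limit`` of its off-diagonal entries
    strictly between 0.1 and 0.9), no stable grouping exists: the result is
    flagged no-structure and falls back to the smallest k.

    All diagnostics are stored for manual inspection; ``force_k`` bypasses
    the automation entirely.
    """
    ks = sorted(result.per_k)
    if len(ks) < 2:
        raise ValueError("need at least 2 values of k")
    areas = {k: _area_under_cdf(result.per_k[k]) for k in ks}
    delta = {}
    for i, k in enumerate(ks):
        if i == 0:
            delta[k] = areas[k]
        else:
            prev = areas[ks[i - 1]]
            delta[k] = (areas[k] - prev) / prev if prev > 0 else 0.0
    result.delta_area = pd.DataFrame(
        {"k": ks, "area": [areas[k] for k in ks], "delta_area": [delta[k] for k in ks]})

    if force_k is not None:
        result.chosen_k = force_k
        return result

    chosen = ks[0]
    for i in range(1, len(ks)):
        if delta[ks[i]] >= threshold:
            chosen = ks[i]
    vals = squareform(result.per_k[chosen].to_numpy(), checks=False)
    ambiguous = float(np.mean((vals > 0.1) & (vals < 0.9)))
    if ambiguous > ambiguity_limit:
        result.no_structure = True
        chosen = ks[0]
        logger.warning("choose_k: %.0f%% of consensus entries ambiguous; "
                       "no consensus structure detected", 100 * ambiguous)
    result.chosen_k = chosen
    return result


def order_for_display(result: ConsensusResult, k: int | None = None) -> ConsensusResult:
    """Average-linkage hierarchical clustering of consensus rows with
    correlation distance (1 - Pearson r); returns the leaf order and the
    flat group labels from cutting the dendrogram at the chosen k."""
    m = result.matrix(k)
    k_cut = k if k is not None else result.chosen_k
    if k_cut is None:
        raise ValueError("no k chosen; run choose_k or pass k explicitly")
    x = m.to_numpy(dtype=float)
    n = x.shape[0]
    sd = x.std(axis=1)
    dist = np.ones((n, n))
    ok = sd > 0
    if ok.any():
        c = np.corrcoef(x[ok])
        dist[np.ix_(ok, ok)] = 1.0 - c
    if (~ok).any():
        logger.info("order_for_display: %d constant rows assigned distance 1", int((~ok).sum()))
    np.fill_diagonal(dist, 0.0)
    z = average(squareform(dist, checks=False))
    order = leaves_list(z)
    labels = cut_tree(z, n_clusters=min(k_cut, n)).ravel()
    result.order = m.index[order].tolist()
    result.labels = pd.Series(labels, index=m.index, name="group")
    return result
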