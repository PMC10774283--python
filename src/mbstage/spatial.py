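"""Spatial metabolomics statistics on MALDI spot lattices.

Total-ion-count normalization, ppm-window assignment of observed m/z peaks
to reference metabolites, the raw-intensity quality filter, k-nearest-spot
row-standardized weights, bivariate Moran's I (cross-correlation of one
metabolite with the spatial lag of another), and across-section group
differential means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

DEFAULT_PPM_WINDOW = 2.0
DEFAULT_MIN_INTENSITY = 100_000.0
DEFAULT_MIN_FRACTION = 0.5
DEFAULT_K_NEIGHBORS = 24  # two levels out on the spot grid


@dataclass
class SpatialWeightMatrix:
    """Sparse row-standardized k-nearest-neighbor weights; zero diagonal,
    exactly k nonzeros of 1/k per row."""

    weights: sparse.csr_matrix
    k: int
    spot_ids: list = field(default_factory=list)


def tic_normalize(intensities: pd.DataFrame) -> pd.DataFrame:
    """Divide each spot's intensity vector by its own sum (rows = spots)."""
    totals = intensities.sum(axis=1)
    zero = totals[totals <= 0]
    if len(zero) > 0:
        raise ValueError(f"spots with zero total intensity: {zero.index.tolist()[:10]}")
    return intensities.div(totals, axis=0)


def assign_peaks(intensities: pd.DataFrame, refs: pd.DataFrame,
                 ppm_window: float = DEFAULT_PPM_WINDOW,
                 ) -> tuple[pd.DataFrame, list[str]]:
    """Assign observed peaks to reference metabolites within a ppm window.

    ``intensities`` is spots x peaks with numeric m/z column labels; ``refs``
    has columns ``name`` and ``mz``. For each reference mass M the candidate
    peaks satisfy |peak - M| / M * 1e6 <= ppm_window (boundary included);
    the assigned per-spot value is the maximum intensity among candidates.
    References without any candidate get all-zero columns and are returned
    in the unmatched list.
    """
    if ppm_window <= 0:
        raise ValueError("ppm_window must be positive")
    peak_mz = np.asarray([float(c) for c in intensities.columns])
    x = intensities.to_numpy(dtype=float)
    out = np.zeros((x.shape[0], len(refs)))
    unmatched: list[str] = []
    for j, (name, m) in enumerate(zip(refs["name"], refs["mz"])):
        within = np.abs(peak_mz - m) / m * 1e6 <= ppm_window
        if not within.any():
            unmatched.append(str(name))
            continue
        out[:, j] = x[:, within].max(axis=1)
    if unmatched:
        logger.info("assign_peaks: %d unmatched metabolites: %s",
                    len(unmatched), unmatched[:10])
    return (pd.DataFrame(out, index=intensities.index, columns=list(refs["name"])),
            unmatched)


def filter_metabolites(assigned_raw: pd.DataFrame,
                       min_intensity: float = DEFAULT_MIN_INTENSITY,
                       min_fraction: float = DEFAULT_MIN_FRACTION) -> list[str]:
    """Metabolites kept by the raw-intensity prevalence filter.

    Keep a metabolite iff the fraction of spots with raw (pre-TIC) intensity
    strictly greater than ``min_intensity`` is strictly greater than
    ``min_fraction``.
    """
    frac = (assigned_raw > min_intensity).mean(axis=0)
    return assigned_raw.columns[frac > min_fraction].tolist()


def knn_weights(coords: pd.DataFrame, k: int = DEFAULT_K_NEIGHBORS,
                ) -> SpatialWeightMatrix:
    """Row-standardized Euclidean k-nearest-neighbor weights.

    Self is excluded; ties in distance are broken by ascending spot position
    in the input table so the neighbor set is deterministic on regular grids.
    """
    xy = coords[["x", "y"]].to_numpy(dtype=float)
    n = xy.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of spots ({n})")
    if len(np.unique(xy, axis=0)) != n:
        raise ValueError("duplicate spot coordinates")
    d = cdist(xy, xy)
    np.fill_diagonal(d, np.inf)
    # lexsort: distance primary, index secondary for deterministic ties
    idx_matrix = np.broadcast_to(np.arange(n), (n, n))
    order = np.lexsort((idx_matrix, d), axis=1)
    neighbors = order[:, :k]
    rows = np.repeat(np.arange(n), k)
    w = sparse.csr_matrix((np.full(n * k, 1.0 / k), (rows, neighbors.ravel())),
                          shape=(n, n))
    return SpatialWeightMatrix(weights=w, k=k, spot_ids=list(coords.index))


def bivariate_morans_i(x: np.ndarray | pd.Series, y: np.ndarray | pd.Series,
                       w: SpatialWeightMatrix) -> float:
    """Bivariate Moran's I: cross-product of z-scored x with the spatial lag
    of z-scored y, normalized by the sum of squares of x.

        I = sum_i zx_i (W zy)_i / sum_i zx_i^2

    Z-scoring uses the population SD across spots.
    """
    zx = np.asarray(x, dtype=float)
    zy = np.asarray(y, dtype=float)
    for name, v in (("x", zx), ("y", zy)):
        if v.std() == 0:
            raise ValueError(f"variable {name} has zero variance")
    zx = (zx - zx.mean()) / zx.std()
    zy = (zy - zy.mean()) / zy.std()
    lag = w.weights @ zy
    return float(zx @ lag / (zx @ zx))


def morans_i_permutation_p(x, y, w: SpatialWeightMatrix, n_perm: int = 999,
                           seed: int = 0) -> tuple[float, float]:
    """Optional permutation null: spots of y are shuffled; two-sided pseudo-p."""
    rng = np.random.default_rng(seed)
    observed = bivariate_morans_i(x, y, w)
    y = np.asarray(y, dtype=float)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = bivariate_morans_i(x, rng.permutation(y), w)
    extreme = np.sum(np.abs(null - null.mean()) >= abs(observed - null.mean()))
    return observed, float((extreme + 1) / (n_perm + 1))


def differential_means(sections: list[pd.DataFrame], groups: list[str],
                       ) -> pd.DataFrame:
    """Across-section differential metabolite means between two groups.

    Each section is a spots x metabolites TIC-normalized matrix; the section
    mean is the mean over spots, the group summary is the mean of section
    means, fold change is log2 of the ratio (with a 1e-12 floor inside the
    log), and the p-value is a two-sided Mann-Whitney across sections. A
    group with fewer than 2 sections gets its p omitted (NaN) but keeps the
    fold change.
    """
    if len(sections) != len(groups):
        raise ValueError("one group label per section required")
    names = sections[0].columns
    for s in sections[1:]:
        if not s.columns.equals(names):
            raise ValueError("sections disagree on metabolite columns")
    section_means = pd.DataFrame([s.mean(axis=0) for s in sections])
    section_means["group"] = groups
    labels = sorted(set(groups))
    if len(labels) != 2:
        raise ValueError(f"exactly 2 groups required, got {labels}")
    g1, g2 = labels
    a = section_means[section_means["group"] == g1][names]
    b = section_means[section_means["group"] == g2][names]
    floor = 1e-12
    lfc = np.log2(np.maximum(a.mean(axis=0), floor) / np.maximum(b.mean(axis=0), floor))
    can_test = len(a) >= 2 and len(b) >= 2
    pvals = []
    for met in names:
        if not can_test:
            pvals.append(np.nan)
        elif np.ptp(np.concatenate([a[met], b[met]])) == 0:
            pvals.append(1.0)
        else:
            pvals.append(float(stats.mannwhitneyu(
                a[met], b[met], alternative="two-sided").pvalue))
    out = pd.DataFrame({
        f"mean_{g1}": a.mean(axis=0), f"mean_{g2}": b.mean(axis=0),
        "log2_fold_change": lfc, "p_value": pvals,
    })
    return out.sort_values("log2_fold_change", key=np.abs, ascending=False)
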