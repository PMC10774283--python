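"""Per-sample activation scoring of gene signatures (the GSVA-style stage).

Converts a genes x samples expression matrix into a signatures x samples
score matrix. Each gene is first turned into a sample-wise statistic by a
Gaussian-kernel CDF estimate; per sample, genes are ranked by that statistic
and a weighted Kolmogorov-Smirnov random walk over the ranked list yields an
enrichment score in the open interval (-1, 1) per signature. Positive scores
mean the signature's genes concentrate at the top of the sample's ranking.

Per-cell activation display scores (mean z-scored expression over signature
genes, optionally floored at zero) live here too.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

_KERNEL_CHUNK = 256  # genes per block in the pairwise kernel sum


@dataclass
class GsvaConfig:
    """Pinned defaults of the scoring engine.

    tau
        Exponent on the symmetric rank statistic in the random walk. 1 keeps
        the classic linear weighting.
    kernel_bandwidth_factor
        Per-gene kernel bandwidth is sample SD divided by this factor.
    es_mode
        Fixed: the enrichment score is the signed sum of the largest positive
        and largest negative deviation of the walk.
    drop_zero_variance
        Drop genes whose sample SD is zero (with a warning) rather than fail.
    """

    tau: float = 1.0
    kernel_bandwidth_factor: float = 4.0
    es_mode: str = field(default="signed-sum of extreme deviations")
    drop_zero_variance: bool = True

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.kernel_bandwidth_factor <= 0:
            raise ValueError("kernel_bandwidth_factor must be positive")


def gene_statistic(expression: pd.DataFrame,
                   config: GsvaConfig | None = None) -> pd.DataFrame:
    """Gaussian-kernel CDF statistic per gene and sample.

    For gene i with values ``x_i.`` and sample SD ``s_i`` the bandwidth is
    ``h_i = s_i / kernel_bandwidth_factor`` and

        z_ij = sum_k Phi((x_ij - x_ik) / h_i)

    with Phi the standard normal CDF. z is strictly increasing in ``x_ij``,
    so it is a smooth rank-generating statistic.
    """
    config = config or GsvaConfig()
    if expression.shape[1] < 2:
        raise ValueError("gene_statistic requires at least 2 samples")
    x = expression.to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = expression.index[~keep].tolist()
        if not config.drop_zero_variance:
            raise ValueError(f"zero-variance genes present: {dropped[:5]}")
        logger.warning("dropping %d zero-variance genes (e.g. %s)",
                       len(dropped), dropped[:5])
        x = x[keep]
        sd = sd[keep]
    h = sd / config.kernel_bandwidth_factor
    n_genes = x.shape[0]
    z = np.empty_like(x)
    for start in range(0, n_genes, _KERNEL_CHUNK):
        sl = slice(start, min(start + _KERNEL_CHUNK, n_genes))
        diff = (x[sl, :, None] - x[sl, None, :]) / h[sl, None, None]
        z[sl] = ndtr(diff).sum(axis=2)
    return pd.DataFrame(z, index=expression.index[keep], columns=expression.columns)


def _walk_scores(d_pow: np.ndarray, order: np.ndarray, hit: np.ndarray) -> np.ndarray:
    """Random-walk enrichment scores for one signature, all samples at once.

    d_pow: (genes, samples) weight |p/2 - r|^tau; order: (genes, samples)
    walk sequence per sample; hit: boolean per gene.
    """
    p, n = d_pow.shape
    hits_sorted = hit[order]                                   # (p, n)
    d_sorted = np.take_along_axis(d_pow, order, axis=0)
    dw = np.where(hits_sorted, d_sorted, 0.0)
    num = np.cumsum(dw, axis=0)
    denom = num[-1]                                            # sum over hits
    m = int(hit.sum())
    miss = np.cumsum(~hits_sorted, axis=0) / (p - m)
    nu = num / denom - miss
    return np.maximum(nu.max(axis=0), 0.0) + np.minimum(nu.min(axis=0), 0.0)


def enrichment_scores(expression: pd.DataFrame,
                      signatures: dict[str, list[str]],
                      config: GsvaConfig | None = None) -> pd.DataFrame:
    """Signatures x samples enrichment-score matrix.

    Per sample, genes are ranked by the kernel statistic descending (rank 1 =
    largest; ties get average ranks, and the walk sequence breaks ties by
    gene name ascending for determinism). With p genes, the symmetric rank
    statistic is d_ij = |p/2 - r_ij|; the walk accumulates d^tau over
    signature genes against a uniform penalty over the rest, and the score is
    the signed sum of the extreme positive and negative deviations.
    """
    config = config or GsvaConfig()
    z = gene_statistic(expression, config)
    zv = z.to_numpy()
    p, n = zv.shape

    universe = z.index
    gene_pos = {g: i for i, g in enumerate(universe)}
    hits: dict[str, np.ndarray] = {}
    for name, genes in signatures.items():
        idx = [gene_pos[g] for g in dict.fromkeys(genes) if g in gene_pos]
        if len(idx) == 0:
            raise ValueError(f"signature {name!r} has no genes in the expression matrix")
        if len(idx) < 2:
            raise ValueError(f"signature {name!r} retains < 2 genes after intersection")
        logger.info("signature %s: %d of %d genes present", name, len(idx), len(genes))
        mask = np.zeros(p, dtype=bool)
        mask[idx] = True
        hits[name] = mask

    ranks = rankdata(-zv, axis=0, method="average")            # rank 1 = largest z
    d_pow = np.abs(p / 2.0 - ranks) ** config.tau
    # deterministic walk sequence: z descending, then gene name ascending
    name_order = np.argsort(np.argsort(universe.to_numpy()))
    order = np.lexsort((np.broadcast_to(name_order[:, None], (p, n)), -zv), axis=0)

    out = np.empty((len(hits), n))
    for row, (name, mask) in enumerate(hits.items()):
        if mask.sum() >= p:
            raise ValueError(f"signature {name!r} covers the whole gene universe")
        out[row] = _walk_scores(d_pow, order, mask)
    return pd.DataFrame(out, index=list(hits), columns=expression.columns)


def score_cells(cell_matrix: pd.DataFrame, signature: list[str],
                floor_at_zero: bool = False) -> pd.Series:
    """Per-cell activation: mean of gene-wise z-scored expression.

    ``cell_matrix`` is cells x genes. Gene-wise z-scoring is across cells;
    the score averages over the signature genes present in the matrix. With
    ``floor_at_zero`` values below 0 are replaced by 0 (display export).
    """
    if cell_matrix.shape[0] < 10:
        raise ValueError("score_cells requires at least 10 cells")
    present = [g for g in dict.fromkeys(signature) if g in cell_matrix.columns]
    if not present:
        raise ValueError("no signature genes present in the cell matrix")
    x = cell_matrix[present].to_numpy(dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0  # constant genes contribute 0 to every cell
    scores = ((x - mu) / sd).mean(axis=1)
    if floor_at_zero:
        scores = np.maximum(scores, 0.0)
    return pd.Series(scores, index=cell_matrix.index, name="activation")
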