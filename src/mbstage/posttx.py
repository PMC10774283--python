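"""Protein-RNA rank differences as a proxy for post-transcriptional control.

Within each sample, protein and RNA abundances are separately rank-normalized
onto [-0.5, 0.5]; the per-gene rank difference (protein rank - RNA rank) is
positive when a gene's protein sits higher in its sample's protein ranking
than its transcript does in the RNA ranking. Genes are stratified into four
categories by synaptic-gene and FMRP-target membership and the focal
category's rank differences are contrasted against the others.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CATEGORIES = ("Non-SYN", "Non-SYN FMRP", "SYN", "SYN FMRP")


@dataclass
class PairedOmicsMatrix:
    """Protein and RNA layers over one shared genes x samples index."""

    protein: pd.DataFrame
    rna: pd.DataFrame
    group: pd.Series        # per-sample label

    def __post_init__(self) -> None:
        if not self.protein.index.equals(self.rna.index):
            raise ValueError("protein and rna gene indices differ")
        if not self.protein.columns.equals(self.rna.columns):
            raise ValueError("protein and rna sample columns differ")
        if self.protein.isna().any().any() or self.rna.isna().any().any():
            raise ValueError("missing values are not allowed")
        self.group = self.group.loc[self.protein.columns]


def rank_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-sample average-tie ranks mapped linearly onto [-0.5, 0.5].

    With G genes and average-tie rank r in [1, G], the normalized value is
    (r - 1)/(G - 1) - 0.5; a sample's unique minimum and maximum attain the
    endpoints, and an all-tied sample maps to 0 everywhere.
    """
    g = matrix.shape[0]
    if g < 2:
        raise ValueError("rank_normalize requires at least 2 genes")
    r = stats.rankdata(matrix.to_numpy(dtype=float), axis=0, method="average")
    return pd.DataFrame((r - 1.0) / (g - 1.0) - 0.5,
                        index=matrix.index, columns=matrix.columns)


def rank_differences(paired: PairedOmicsMatrix) -> pd.DataFrame:
    """Per-gene mean rank difference per group.

    Delta_gj = proteinRank_gj - rnaRank_gj; the summary is the mean of Delta
    over each group's samples, one column per group.
    """
    delta = rank_normalize(paired.protein) - rank_normalize(paired.rna)
    out = {}
    for group in sorted(paired.group.unique()):
        cols = paired.group.index[paired.group == group]
        if len(cols) == 0:
            raise ValueError(f"empty group {group!r}")
        out[group] = delta[cols].mean(axis=1)
    return pd.DataFrame(out)


def per_sample_rank_differences(paired: PairedOmicsMatrix) -> pd.DataFrame:
    """The full genes x samples rank-difference matrix."""
    return rank_normalize(paired.protein) - rank_normalize(paired.rna)


def categorize_genes(genes: list[str], syn_set: set[str] | list[str],
                     fmrp_set: set[str] | list[str]) -> pd.Series:
    """Four categories from the synaptic / FMRP-target membership flags."""
    syn = set(syn_set)
    fmrp = set(fmrp_set)
    cats = []
    for g in genes:
        if g in syn:
            cats.append("SYN FMRP" if g in fmrp else "SYN")
        else:
            cats.append("Non-SYN FMRP" if g in fmrp else "Non-SYN")
    ser = pd.Series(pd.Categorical(cats, categories=list(CATEGORIES)),
                    index=pd.Index(genes, name="gene"), name="category")
    logger.info("categorize_genes: %s", ser.value_counts().to_dict())
    return ser


def compare_categories(summary: pd.DataFrame, annotation: pd.Series, group: str,
                       focal: str = "SYN FMRP", min_size: int = 3) -> pd.DataFrame:
    """Contrast the focal category's mean rank differences against the rest.

    For the chosen group's per-gene mean Delta: a two-sided Mann-Whitney U of
    the focal category vs each other category, and a one-sample t-test of
    each category's Delta against 0. A zero-variance category's t-test is
    reported as missing (NaN), not 0 and not an error; comparisons against a
    category smaller than ``min_size`` are skipped with a warning.
    """
    if group not in summary.columns:
        raise ValueError(f"group {group!r} not in summary")
    delta = summary[group]
    annotation = annotation.loc[delta.index]

    by_cat = {c: delta[annotation == c].to_numpy(dtype=float)
              for c in annotation.cat.categories}

    rows = []
    for cat, vals in by_cat.items():
        if len(vals) == 0:
            continue
        if len(vals) >= 2 and vals.std(ddof=1) > 0:
            t_res = stats.ttest_1samp(vals, 0.0)
            t_stat, t_p = float(t_res.statistic), float(t_res.pvalue)
        else:
            t_stat, t_p = np.nan, np.nan
        mwu_p = np.nan
        mwu_u = np.nan
        if cat != focal:
            focal_vals = by_cat.get(focal, np.empty(0))
            if len(vals) < min_size or len(focal_vals) < min_size:
                logger.warning("compare_categories: %s vs %s skipped (too few genes)",
                               focal, cat)
            else:
                if np.ptp(np.concatenate([focal_vals, vals])) == 0:
                    mwu_u, mwu_p = np.nan, 1.0  # all values tied
                else:
                    method = ("exact" if len(vals) + len(focal_vals) <= 20
                              and len(np.unique(np.concatenate([focal_vals, vals])))
                              == len(vals) + len(focal_vals) else "asymptotic")
                    res = stats.mannwhitneyu(focal_vals, vals,
                                             alternative="two-sided", method=method)
                    mwu_u, mwu_p = float(res.statistic), float(res.pvalue)
        rows.append({"category": cat, "n_genes": len(vals),
                     "mean_delta": float(vals.mean()),
                     "t_stat_vs_zero": t_stat, "t_p_vs_zero": t_p,
                     "mwu_U_vs_focal": mwu_u, "mwu_p_vs_focal": mwu_p})
    return pd.DataFrame(rows)
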