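"""Composite developmental scores and the arm-level CNV association screen.

Composites are linear combinations of signature activation scores
(proliferation = cycling GCP - GCP; progenitor = cycling GCP + GCP;
late-stage GN = migrating GN + postmigratory GN). The CNV screen runs, for
every (chromosome arm, score) pair, up to two two-sided Mann-Whitney U tests
(loss vs rest, gain vs rest), skips empty groups, counts only performed
tests, and flags results at the Bonferroni-corrected alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

EXACT_MAX_TOTAL_N = 20  # exact Mann-Whitney enumeration at or below this combined n


@dataclass(frozen=True)
class CompositeDefinition:
    name: str
    plus_terms: tuple[str, ...]
    minus_terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (self.plus_terms or self.minus_terms):
            raise ValueError(f"composite {self.name!r} has no terms")


#: The shipped composites over the granule-neuron stage signatures.
DEFAULT_COMPOSITES = (
    CompositeDefinition("proliferation", ("cyclingGCP",), ("GCP",)),
    CompositeDefinition("progenitor", ("cyclingGCP", "GCP")),
    CompositeDefinition("late_stage_GN", ("migratingGN", "postmigratoryGN")),
)


def composite_scores(scores: pd.DataFrame,
                     defs: tuple[CompositeDefinition, ...] = DEFAULT_COMPOSITES,
                     ) -> pd.DataFrame:
    """Append composite rows (sum of plus terms minus sum of minus terms) to
    a signatures x samples score matrix."""
    out = scores.copy()
    for d in defs:
        for term in (*d.plus_terms, *d.minus_terms):
            if term not in scores.index:
                raise ValueError(f"composite {d.name!r} references missing signature {term!r}")
        vals = np.zeros(scores.shape[1])
        for term in d.plus_terms:
            vals = vals + scores.loc[term].to_numpy()
        for term in d.minus_terms:
            vals = vals - scores.loc[term].to_numpy()
        out.loc[d.name] = vals
    return out


def group_means(scores: pd.DataFrame, group_labels: pd.Series) -> pd.DataFrame:
    """Per (score, group): mean within the group and mean over all other
    samples. A group holding every sample reports the complement mean as
    missing (NaN), never 0."""
    group_labels = group_labels.loc[scores.columns]
    rows = []
    for group in sorted(group_labels.unique()):
        in_g = (group_labels == group).to_numpy()
        if in_g.sum() == 0:
            raise ValueError(f"unknown or empty group {group!r}")
        for score_name in scores.index:
            vals = scores.loc[score_name].to_numpy(dtype=float)
            mean_in = float(vals[in_g].mean())
            mean_out = float(vals[~in_g].mean()) if (~in_g).any() else np.nan
            rows.append({"score": score_name, "group": group,
                         "mean_in_group": mean_in, "mean_others": mean_out})
    return pd.DataFrame(rows)


def correlate_scores(scores: pd.DataFrame, score_a: str, score_b: str,
                     ) -> tuple[float, float]:
    """Pearson r between two score rows with the two-sided t-transform p."""
    a = scores.loc[score_a].to_numpy(dtype=float)
    b = scores.loc[score_b].to_numpy(dtype=float)
    if len(a) < 3:
        raise ValueError("need at least 3 samples")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant score input")
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


def _mwu(group: np.ndarray, rest: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact enumeration for small combined n,
    normal approximation with tie correction otherwise."""
    method = "exact" if len(group) + len(rest) <= EXACT_MAX_TOTAL_N else "asymptotic"
    if method == "exact" and (len(np.unique(np.concatenate([group, rest])))
                              < len(group) + len(rest)):
        method = "asymptotic"  # scipy's exact method does not correct ties
    res = stats.mannwhitneyu(group, rest, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def cnv_association(scores: pd.DataFrame, arms: pd.DataFrame,
                    famwise_alpha: float = 0.01) -> pd.DataFrame:
    """Arm-level CNV association screen with Bonferroni control.

    For every (arm, score): loss samples vs the rest, then gain samples vs
    the rest; a test whose group is empty is skipped; samples with missing
    arm status are excluded from both sides for that arm. The per-test alpha
    is famwise_alpha divided by the number of tests actually performed.
    """
    common = scores.columns.intersection(arms.index)
    if len(common) == 0:
        raise ValueError("score matrix and arm table share no sample ids")
    scores = scores[common]
    arms = arms.loc[common]

    tests = []
    for arm in arms.columns:
        status = arms[arm]
        known = status.notna().to_numpy()
        for direction in ("loss", "gain"):
            in_g = (status == direction).to_numpy() & known
            rest = known & ~in_g
            if in_g.sum() == 0 or rest.sum() == 0:
                continue
            for score_name in scores.index:
                vals = scores.loc[score_name].to_numpy(dtype=float)
                u, p = _mwu(vals[in_g], vals[rest])
                tests.append({"arm": arm, "score": score_name, "direction": direction,
                              "n_group": int(in_g.sum()), "n_rest": int(rest.sum()),
                              "U": u, "p_value": p})
    if not tests:
        logger.warning("cnv_association: no loss/gain groups anywhere; empty result")
        return pd.DataFrame(columns=["arm", "score", "direction", "n_group", "n_rest",
                                     "U", "p_value", "alpha", "comparisons", "significant"])
    table = pd.DataFrame(tests)
    comparisons = len(table)
    alpha = famwise_alpha / comparisons
    table["alpha"] = alpha
    table["comparisons"] = comparisons
    table["significant"] = table["p_value"] < alpha
    return table


def bonferroni_alpha(famwise_alpha: float, comparisons: int) -> float:
    """Per-test alpha under Bonferroni control."""
    if comparisons < 1:
        raise ValueError("comparisons must be >= 1")
    return famwise_alpha / comparisons
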