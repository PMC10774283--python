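"""Marker-gene signature derivation from cluster-labeled cells and bulk data.

Covers the per-cell QC filter (percentile rules on UMI/feature counts,
mitochondrial fraction, doublet score), one-vs-rest Wilcoxon marker tests
with optional per-cluster downsampling, rank-normalized Welch-t bulk subtype
markers, top-n signature assembly, and mouse-to-human ortholog mapping with
the capitalization fallback and next-ranked-marker replacement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SignatureSource:
    study: str
    species: str          # human | mouse
    data_type: str        # scRNA | snRNA | bulk
    material: str         # tumor | cerebellum

    def encode(self) -> str:
        return f"study={self.study};species={self.species};type={self.data_type};material={self.material}"

    @classmethod
    def decode(cls, text: str) -> "SignatureSource":
        kv = dict(item.split("=", 1) for item in text.split(";"))
        return cls(kv["study"], kv["species"], kv["type"], kv["material"])


@dataclass
class GeneSignature:
    """Named, ordered marker-gene list with provenance metadata."""

    name: str
    genes: list[str]
    source: SignatureSource = field(
        default_factory=lambda: SignatureSource("unspecified", "human", "bulk", "tumor"))

    def __post_init__(self) -> None:
        if len(self.genes) < 1:
            raise ValueError(f"signature {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} has duplicate genes")


def qc_filter(qc: pd.DataFrame) -> set:
    """Cell ids passing all QC rules.

    A cell is removed when ANY holds: UMI or feature count strictly below its
    column's 5th percentile or strictly above its 95th percentile;
    mitochondrial fraction > 0.05; doublet score strictly above its 90th
    percentile. Percentiles use linear interpolation over the input table.
    Removal reasons are logged per cell.
    """
    required = {"umi_count", "feature_count", "mito_fraction", "doublet_score"}
    missing = required - set(qc.columns)
    if missing:
        raise ValueError(f"qc table missing columns: {sorted(missing)}")
    if len(qc) == 0:
        raise ValueError("qc table is empty")

    umi = qc["umi_count"].to_numpy(dtype=float)
    feat = qc["feature_count"].to_numpy(dtype=float)
    mito = qc["mito_fraction"].to_numpy(dtype=float)
    dbl = qc["doublet_score"].to_numpy(dtype=float)

    umi_lo, umi_hi = np.percentile(umi, [5, 95])
    feat_lo, feat_hi = np.percentile(feat, [5, 95])
    dbl_hi = np.percentile(dbl, 90)

    reasons = {
        "umi_low": umi < umi_lo,
        "umi_high": umi > umi_hi,
        "feature_low": feat < feat_lo,
        "feature_high": feat > feat_hi,
        "mito": mito > 0.05,
        "doublet": dbl > dbl_hi,
    }
    removed = np.zeros(len(qc), dtype=bool)
    for why, mask in reasons.items():
        for cell in qc.index[mask & ~removed]:
            logger.info("qc_filter: removing %s (%s)", cell, why)
        removed |= mask
    return set(qc.index[~removed])


def _downsample(labels: pd.Series, seed: int, cap: int | None = None) -> pd.Index:
    """Subsample every cluster without replacement to the minimum cluster size
    (optionally further capped)."""
    rng = np.random.default_rng(seed)
    n_min = labels.value_counts().min()
    if cap is not None:
        n_min = min(n_min, cap)
    keep: list = []
    for cluster in sorted(labels.unique()):
        cells = labels.index[labels == cluster].to_numpy()
        keep.extend(rng.choice(cells, size=n_min, replace=False))
    return pd.Index(keep)


def find_markers(matrix: pd.DataFrame, labels: pd.Series, downsample: bool = True,
                 n_per_cluster_cap: int | None = None, seed: int = 0) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum markers per cluster.

    ``matrix`` is cells x genes; ``labels`` assigns each cell a cluster. With
    ``downsample``, every cluster is first subsampled without replacement to
    the minimum cluster size (seeded) so clusters are equally represented.
    P-values are Bonferroni-adjusted over genes within each cluster; only
    positively enriched genes (log2 fold change of means, pseudocount 1,
    > 0) are kept. Rows are ordered by adjusted p ascending, then log2FC
    descending, then gene name ascending.
    """
    labels = labels.loc[matrix.index]
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ValueError("find_markers requires at least 2 clusters")
    if downsample:
        kept = _downsample(labels, seed, n_per_cluster_cap)
        matrix = matrix.loc[kept]
        labels = labels.loc[kept]
    counts = labels.value_counts()
    for cluster in clusters:
        if counts.get(cluster, 0) < 3:
            raise ValueError(f"cluster {cluster!r} has fewer than 3 cells")

    x = matrix.to_numpy(dtype=float)
    genes = matrix.columns.to_numpy()
    n_genes = len(genes)
    rows = []
    for cluster in clusters:
        in_c = (labels == cluster).to_numpy()
        a, b = x[in_c], x[~in_c]
        stat, p = stats.mannwhitneyu(a, b, axis=0, alternative="two-sided",
                                     method="auto")
        adj = np.minimum(p * n_genes, 1.0)
        lfc = np.log2((a.mean(axis=0) + 1.0) / (b.mean(axis=0) + 1.0))
        tab = pd.DataFrame({
            "cluster": cluster, "gene": genes, "statistic": stat,
            "p_value": p, "adjusted_p": adj, "log2_fold_change": lfc,
        })
        tab = tab[tab["log2_fold_change"] > 0]
        tab = tab.sort_values(
            ["adjusted_p", "log2_fold_change", "gene"],
            ascending=[True, False, True], kind="mergesort")
        rows.append(tab)
    return pd.concat(rows, ignore_index=True)


def bulk_subtype_markers(expression: pd.DataFrame, subtype_labels: pd.Series,
                         ) -> pd.DataFrame:
    """Subtype markers from bulk data by rank normalization and Welch t-tests.

    Expression (genes x samples) is rank-normalized per sample (average ties,
    linear map onto [0, 1]); each subtype is tested against all other samples
    per gene with a two-sided Welch t-test. Markers are the positive-t genes,
    ordered by p ascending then t descending. A gene with zero variance in
    both groups gets p = 1 (logged), never an exception.
    """
    subtype_labels = subtype_labels.loc[expression.columns]
    counts = subtype_labels.value_counts()
    if (counts < 3).any():
        small = counts[counts < 3].index.tolist()
        raise ValueError(f"subtypes with fewer than 3 samples: {small}")

    r = stats.rankdata(expression.to_numpy(dtype=float), axis=0, method="average")
    g = r.shape[0]
    ranked = (r - 1.0) / (g - 1.0) if g > 1 else np.zeros_like(r)
    genes = expression.index.to_numpy()

    rows = []
    for subtype in sorted(counts.index):
        in_s = (subtype_labels == subtype).to_numpy()
        a, b = ranked[:, in_s], ranked[:, ~in_s]
        with np.errstate(divide="ignore", invalid="ignore"):
            t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
        degenerate = ~np.isfinite(p)
        if degenerate.any():
            logger.info("bulk_subtype_markers: %d degenerate genes in %s set to p=1",
                        int(degenerate.sum()), subtype)
            p = np.where(degenerate, 1.0, p)
            t = np.where(np.isfinite(t), t, 0.0)
        tab = pd.DataFrame({
            "cluster": subtype, "gene": genes, "statistic": t,
            "p_value": p, "adjusted_p": np.minimum(p * len(genes), 1.0),
            "log2_fold_change": np.log2((a.mean(axis=1) + 1.0) / (b.mean(axis=1) + 1.0)),
        })
        tab = tab[tab["statistic"] > 0]
        tab = tab.sort_values(["p_value", "statistic", "gene"],
                              ascending=[True, False, True], kind="mergesort")
        rows.append(tab)
    return pd.concat(rows, ignore_index=True)


def build_signature(markers: pd.DataFrame, cluster, n: int = 100,
                    source: SignatureSource | None = None,
                    name: str | None = None) -> GeneSignature:
    """Top-n genes of a cluster in marker-table order; fewer markers than n
    means all of them are used."""
    if n < 1:
        raise ValueError("n must be >= 1")
    sub = markers[markers["cluster"] == cluster]
    if len(sub) == 0:
        raise ValueError(f"no markers for cluster {cluster!r}")
    genes = sub["gene"].tolist()[:n]
    return GeneSignature(name or str(cluster), genes,
                         source or SignatureSource("unspecified", "human", "scRNA", "tumor"))


def map_orthologs(signature: GeneSignature, table: dict[str, str],
                  target_universe: set[str] | list[str],
                  markers: pd.DataFrame, n: int = 100) -> GeneSignature:
    """Map a mouse signature onto human symbols.

    Per gene: use the ortholog table entry when present; otherwise include
    the upper-cased mouse symbol if it exists in the target gene universe;
    otherwise drop the gene and promote the next-ranked marker from the
    cluster's marker table. Output length is at most n.
    """
    if signature.source.species != "mouse":
        raise ValueError("map_orthologs expects a mouse signature")
    universe = set(target_universe)
    ranked = markers[markers["cluster"] == signature.name]["gene"].tolist()
    candidates = list(signature.genes)
    for g in ranked:
        if g not in candidates:
            candidates.append(g)

    mapped: list[str] = []
    for mouse_gene in candidates:
        if len(mapped) >= n:
            break
        if mouse_gene in table:
            human = table[mouse_gene]
        elif mouse_gene.upper() in universe:
            human = mouse_gene.upper()
        else:
            logger.info("map_orthologs: dropping unmappable %s", mouse_gene)
            continue
        if human not in mapped:
            mapped.append(human)
    if len(mapped) < min(n, len(signature.genes)):
        logger.warning("map_orthologs: marker list exhausted, signature %s has %d genes",
                       signature.name, len(mapped))
    new_source = SignatureSource(signature.source.study, "human",
                                 signature.source.data_type, signature.source.material)
    return GeneSignature(signature.name, mapped, new_source)
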