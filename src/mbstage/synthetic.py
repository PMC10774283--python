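"""Synthetic inputs with planted, recoverable structure for every stage.

Four generators emulate the pipeline's real inputs: cluster-labeled cell
matrices with known stage markers along the granule-neuron trajectory; a
bulk tumor cohort whose subtypes and chromosome-arm statuses carry additive
signature activations; paired protein/RNA matrices with a protein-specific
shift planted on a target gene subset in one group; and spatial spot
lattices whose metabolite vectors come from group-specific sparse precision
matrices, with one planted spatially anticorrelated metabolite pair.

Every generator is a pure function of its arguments including the seed.
Expression noise is additive Gaussian on a log-like scale, matching the
variance structure the scoring stage assumes; nonnegativity is enforced by
shifting by the global minimum (never clipping) so planted mean differences
and covariance structure survive exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Ordered granule-neuron developmental stages used as default cluster ids.
STAGES = ("cyclingGCP", "GCP", "premigratoryGN", "migratingGN", "postmigratoryGN")

#: QC metric distributions (fixed defaults, recorded in output metadata).
QC_DEFAULTS = {
    "umi_lognormal_mean": 8.5, "umi_lognormal_sigma": 0.6,
    "features_lognormal_mean": 7.0, "features_lognormal_sigma": 0.5,
    "mito_beta_a": 2.0, "mito_beta_b": 38.0,
    "doublet_uniform_low": 0.0, "doublet_uniform_high": 1.0,
}


# ---------------------------------------------------------------- cell data

@dataclass
class SyntheticCellData:
    matrix: pd.DataFrame                  # cells x genes, log-like scale, >= 0
    labels: pd.Series                     # per-cell cluster id
    truth_markers: dict[str, set[str]]    # cluster -> planted marker genes
    qc: pd.DataFrame                      # umi_count, feature_count, mito_fraction, doublet_score
    qc_params: dict = field(default_factory=dict)
    seed: int = 0


def generate_cell_data(n_cells_per_cluster: int = 50, n_genes: int = 200,
                       n_markers_per_cluster: int = 10, effect: float = 3.0,
                       noise_sd: float = 0.5, seed: int = 0,
                       clusters: tuple[str, ...] = STAGES) -> SyntheticCellData:
    """Staged cell matrix with disjoint planted markers per cluster.

    Each planted marker gene has mean expression higher by ``effect`` in its
    own cluster than elsewhere; the rest is gene-independent Gaussian noise
    around a common baseline, shifted to be nonnegative.
    """
    if n_cells_per_cluster < 2 or n_genes < 1 or n_markers_per_cluster < 0:
        raise ValueError("non-positive dimensions")
    if effect < 0 or noise_sd < 0:
        raise ValueError("effect and noise_sd must be nonnegative")
    if n_markers_per_cluster * len(clusters) > n_genes:
        raise ValueError("marker genes would exceed the gene universe")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    cells, labels = [], []
    for c in clusters:
        for i in range(n_cells_per_cluster):
            cells.append(f"{c}_cell{i:03d}")
            labels.append(c)
    n_cells = len(cells)
    x = rng.normal(1.0, noise_sd, size=(n_cells, n_genes))
    truth: dict[str, set[str]] = {}
    for ci, c in enumerate(clusters):
        marker_idx = range(ci * n_markers_per_cluster, (ci + 1) * n_markers_per_cluster)
        truth[c] = {genes[g] for g in marker_idx}
        rows = [i for i, lab in enumerate(labels) if lab == c]
        for g in marker_idx:
            x[rows, g] += effect
    if x.min() < 0:
        x = x - x.min()
    qc = pd.DataFrame({
        "umi_count": rng.lognormal(QC_DEFAULTS["umi_lognormal_mean"],
                                   QC_DEFAULTS["umi_lognormal_sigma"], n_cells).astype(int),
        "feature_count": rng.lognormal(QC_DEFAULTS["features_lognormal_mean"],
                                       QC_DEFAULTS["features_lognormal_sigma"], n_cells).astype(int),
        "mito_fraction": rng.beta(QC_DEFAULTS["mito_beta_a"], QC_DEFAULTS["mito_beta_b"], n_cells),
        "doublet_score": rng.uniform(QC_DEFAULTS["doublet_uniform_low"],
                                     QC_DEFAULTS["doublet_uniform_high"], n_cells),
    }, index=cells)
    return SyntheticCellData(
        matrix=pd.DataFrame(x, index=cells, columns=genes),
        labels=pd.Series(labels, index=cells, name="cluster"),
        truth_markers=truth, qc=qc, qc_params=dict(QC_DEFAULTS), seed=seed)


# ------------------------------------------------------------------- cohort

@dataclass
class SyntheticCohort:
    expression: pd.DataFrame              # genes x samples
    subtype: pd.Series                    # per-sample label
    arm_status: pd.DataFrame              # samples x arms, loss/neutral/gain
    effects: dict
    arm_effects: dict
    seed: int = 0


DEFAULT_ARMS = ("1p", "1q", "2p", "2q", "3p", "3q", "9p", "9q", "10p", "10q", "17p", "17q")


def generate_cohort(n_samples: int = 200,
                    subtype_props: dict[str, float] | None = None,
                    signatures: dict[str, list[str]] | None = None,
                    effects: dict[tuple[str, str], float] | None = None,
                    arm_effects: dict[tuple[str, str, str], float] | None = None,
                    noise_sd: float = 1.0, seed: int = 0,
                    arms: tuple[str, ...] = DEFAULT_ARMS,
                    loss_rate: float = 0.2, gain_rate: float = 0.2,
                    n_background_genes: int = 100,
                    gene_universe: list[str] | None = None) -> SyntheticCohort:
    """Bulk cohort with planted subtype and chromosome-arm activations.

    Samples of a subtype get an additive mean shift on the genes of that
    subtype's activated signatures; arm statuses are drawn per-arm Bernoulli
    (loss_rate, gain_rate), and configured (arm, status, signature) effects
    add the stated shift to the signature's genes in the matching samples.
    """
    subtype_props = subtype_props or {"S1": 0.5, "S2": 0.5}
    signatures = signatures or {}
    effects = effects or {}
    arm_effects = arm_effects or {}
    if abs(sum(subtype_props.values()) - 1.0) > 1e-9:
        raise ValueError("subtype_props must sum to 1")

    sig_genes: list[str] = []
    for gs in signatures.values():
        for g in gs:
            if g not in sig_genes:
                sig_genes.append(g)
    if gene_universe is None:
        universe = sig_genes + [f"BG{i:04d}" for i in range(n_background_genes)]
    else:
        universe = list(gene_universe)
        for name, gs in signatures.items():
            for g in gs:
                if g not in set(universe):
                    raise ValueError(f"signature {name!r} gene {g!r} not in gene universe")
    gene_pos = {g: i for i, g in enumerate(universe)}

    # largest-remainder apportionment of samples to subtypes
    names = sorted(subtype_props)
    raw = {s: subtype_props[s] * n_samples for s in names}
    counts = {s: int(np.floor(raw[s])) for s in names}
    short = n_samples - sum(counts.values())
    for s in sorted(names, key=lambda s: raw[s] - counts[s], reverse=True)[:short]:
        counts[s] += 1
    for s, c in counts.items():
        if c < 3:
            raise ValueError(f"subtype {s!r} would have {c} < 3 samples")
    subtype = pd.Series(
        [s for s in names for _ in range(counts[s])],
        index=[f"T{i:03d}" for i in range(n_samples)], name="subtype")

    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, noise_sd, size=(len(universe), n_samples))

    for (sub, signame), e in effects.items():
        if signame not in signatures:
            raise ValueError(f"effect references unknown signature {signame!r}")
        rows = [gene_pos[g] for g in signatures[signame]]
        cols = np.where(subtype.to_numpy() == sub)[0]
        x[np.ix_(rows, cols)] += e

    status = rng.choice(["loss", "gain", "neutral"], size=(n_samples, len(arms)),
                        p=[loss_rate, gain_rate, 1 - loss_rate - gain_rate])
    arm_status = pd.DataFrame(status, index=subtype.index, columns=list(arms))

    for (arm, st, signame), e in arm_effects.items():
        if arm not in arm_status.columns:
            raise ValueError(f"unknown arm {arm!r}")
        if signame not in signatures:
            raise ValueError(f"arm effect references unknown signature {signame!r}")
        rows = [gene_pos[g] for g in signatures[signame]]
        cols = np.where((arm_status[arm] == st).to_numpy())[0]
        x[np.ix_(rows, cols)] += e

    expression = pd.DataFrame(x, index=universe, columns=subtype.index)
    return SyntheticCohort(expression=expression, subtype=subtype,
                           arm_status=arm_status, effects=dict(effects),
                           arm_effects=dict(arm_effects), seed=seed)


# ------------------------------------------------------------- paired omics

@dataclass
class SyntheticPairedOmics:
    protein: pd.DataFrame
    rna: pd.DataFrame
    group: pd.Series
    target_genes: set[str]
    delta: float
    seed: int = 0


def generate_paired_omics(n_genes: int = 2000, n_samples_per_group: int = 10,
                          n_targets: int = 100, delta: float = 0.0,
                          noise_sd: float = 0.5, seed: int = 0) -> SyntheticPairedOmics:
    """Paired protein/RNA matrices with a protein-specific planted shift.

    protein = rna + independent noise everywhere, plus ``delta`` added to the
    protein values of the target genes in group B samples only.
    """
    if n_targets > n_genes:
        raise ValueError("n_targets exceeds n_genes")
    if delta < 0 or noise_sd < 0:
        raise ValueError("delta and noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    samples = ([f"A{i:02d}" for i in range(n_samples_per_group)]
               + [f"B{i:02d}" for i in range(n_samples_per_group)])
    group = pd.Series(["A"] * n_samples_per_group + ["B"] * n_samples_per_group,
                      index=samples, name="group")
    rna = rng.normal(0.0, 1.0, size=(n_genes, len(samples)))
    protein = rna + rng.normal(0.0, noise_sd, size=rna.shape)
    target_idx = rng.choice(n_genes, size=n_targets, replace=False)
    b_cols = np.arange(n_samples_per_group, 2 * n_samples_per_group)
    protein[np.ix_(target_idx, b_cols)] += delta
    return SyntheticPairedOmics(
        protein=pd.DataFrame(protein, index=genes, columns=samples),
        rna=pd.DataFrame(rna, index=genes, columns=samples),
        group=group, target_genes={genes[i] for i in target_idx},
        delta=delta, seed=seed)


# ----------------------------------------------------------------- sections

@dataclass
class SyntheticSection:
    coords: pd.DataFrame                  # spot x, y on a regular lattice
    intensities: pd.DataFrame             # spots x metabolites, >= 0
    group: str
    truth_precision: np.ndarray
    anticorr_pair: tuple[str, str] | None
    seed: int = 0


def make_sparse_precision(p: int, n_edges: int, value: float = 0.4,
                          seed: int = 0, hub: int | None = None,
                          margin: float = 1.0, disjoint: bool = False,
                          ) -> np.ndarray:
    """Random sparse SPD precision matrix via strict diagonal dominance.

    Each edge (i, j) gets off-diagonal +-``value``; diagonals are the
    absolute row sums plus ``margin``, so the partial correlation of an edge
    between two degree-1 nodes is value / (value + margin) — small margins
    give strong, easily recoverable conditional dependencies.

    ``disjoint`` draws the edges as a random matching (no shared nodes;
    requires n_edges <= p // 2), which keeps every planted partial
    correlation at that degree-1 strength. ``hub`` instead wires one node to
    many others so the generating graph has a known high-centrality
    metabolite.
    """
    rng = np.random.default_rng(seed)
    a = np.zeros((p, p))
    if disjoint:
        if n_edges > p // 2:
            raise ValueError("a matching needs n_edges <= p // 2")
        nodes = rng.permutation(p)
        chosen = [(min(nodes[2 * e], nodes[2 * e + 1]),
                   max(nodes[2 * e], nodes[2 * e + 1])) for e in range(n_edges)]
    elif hub is not None:
        hub_pairs = [(min(hub, j), max(hub, j)) for j in range(p) if j != hub]
        chosen = hub_pairs[: min(len(hub_pairs), n_edges)]
        pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
        remaining = [pr for pr in pairs if pr not in set(chosen)]
        extra = n_edges - len(chosen)
        if extra > 0:
            idx = rng.choice(len(remaining), size=extra, replace=False)
            chosen = chosen + [remaining[i] for i in idx]
    else:
        pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
        idx = rng.choice(len(pairs), size=n_edges, replace=False)
        chosen = [pairs[i] for i in idx]
    for i, j in chosen:
        v = value * rng.choice([-1.0, 1.0])
        a[i, j] = a[j, i] = v
    np.fill_diagonal(a, np.abs(a).sum(axis=1) + margin)
    return a


def _smooth_field(nx_: int, ny_: int) -> np.ndarray:
    """Low-frequency unit-SD field over the lattice (linear diagonal gradient)."""
    xs, ys = np.meshgrid(np.arange(nx_), np.arange(ny_), indexing="ij")
    f = (xs / max(nx_ - 1, 1) - 0.5) + (ys / max(ny_ - 1, 1) - 0.5)
    f = f.ravel()
    return (f - f.mean()) / f.std()


def generate_sections(n_sections_per_group: dict[str, int],
                      grid_shape: tuple[int, int],
                      truth_precisions: dict[str, np.ndarray],
                      anticorr_pair: tuple[str, str] | None = None,
                      field_scale: float = 0.0, seed: int = 0,
                      metabolite_names: list[str] | None = None,
                      ) -> list[SyntheticSection]:
    """Spot lattices with metabolite vectors from group-specific precisions.

    Per spot the metabolite vector is multivariate normal with covariance
    inverse(truth_precision of the section's group), shifted by the global
    minimum to be nonnegative. In LSGN sections the anticorrelated pair gets
    +f(x, y) and -f(x, y) from a smooth low-frequency field of amplitude
    ``field_scale``.
    """
    if grid_shape[0] < 10 or grid_shape[1] < 10:
        raise ValueError("grid_shape must be at least (10, 10)")
    if set(n_sections_per_group) != set(truth_precisions):
        raise ValueError("need one truth precision per group")
    p = next(iter(truth_precisions.values())).shape[0]
    names = metabolite_names or [f"met{i:02d}" for i in range(p)]
    chols = {}
    for grp, prec in truth_precisions.items():
        if prec.shape != (p, p) or not np.allclose(prec, prec.T):
            raise ValueError(f"precision for {grp!r} is not symmetric of size {p}")
        eig = np.linalg.eigvalsh(prec)
        if eig.min() <= 0:
            raise ValueError(f"precision for {grp!r} is not positive definite")
        chols[grp] = np.linalg.cholesky(np.linalg.inv(prec))

    nx_, ny_ = grid_shape
    xs, ys = np.meshgrid(np.arange(nx_), np.arange(ny_), indexing="ij")
    coords = pd.DataFrame({"x": xs.ravel(), "y": ys.ravel()},
                          index=[f"spot{i:04d}" for i in range(nx_ * ny_)])
    field = _smooth_field(nx_, ny_)

    rng = np.random.default_rng(seed)
    sections = []
    for grp in sorted(n_sections_per_group):
        for s in range(n_sections_per_group[grp]):
            z = rng.standard_normal((len(coords), p)) @ chols[grp].T
            if anticorr_pair is not None and grp == "LSGN" and field_scale > 0:
                ia, ib = names.index(anticorr_pair[0]), names.index(anticorr_pair[1])
                z[:, ia] += field_scale * field
                z[:, ib] -= field_scale * field
            z = z - z.min()  # shift, never clip: covariance preserved
            sections.append(SyntheticSection(
                coords=coords.copy(),
                intensities=pd.DataFrame(z, index=coords.index, columns=names),
                group=grp, truth_precision=truth_precisions[grp].copy(),
                anticorr_pair=anticorr_pair, seed=seed))
    return sections
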