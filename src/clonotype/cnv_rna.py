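"""CNV inference from single-cell RNA-seq and clone-level subtype scoring.

Copy-number changes leave a broad positional footprint in expression:
averaging mean-normalized log2(TPM+1) values over a window of 101
chromosomally adjacent genes smooths out single-gene variation and reveals
whole-chromosome (or arm-scale) gains and losses.  Profiles are clipped,
centred per cell, referenced to a baseline built from normal cells (only
deviations beyond a dead zone of 0.3, about a 23% expression change, are
recorded), and cells are grouped into clones by Ward hierarchical
clustering of the Euclidean distances between profiles.  Per-cell subtype
and stemness scores (mean expression of a classifier gene set minus the
cell's global mean) are compared across clones with a Kruskal-Wallis test,
and scored for significance against random gene sets of matching size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

__all__ = [
    "CNVProfiles",
    "cnv_profiles",
    "baseline_profile",
    "normalize_to_baseline",
    "cluster_cells_into_clones",
    "linkage_to_newick",
    "subtype_scores",
    "score_significance",
    "compare_clone_scores",
    "read_expression_matrix",
    "read_gmt",
]


@dataclass
class CNVProfiles:
    """Sliding-window CNV values: windows x cells, plus window coordinates."""

    values: pd.DataFrame
    windows: pd.DataFrame
    """Per window: chromosome, start/end positional index of member genes."""


def cnv_profiles(
    expr: pd.DataFrame,
    gene_order: pd.DataFrame,
    window: int = 101,
    clip: float = 3.0,
) -> CNVProfiles:
    """Sliding-window expression averages as a copy-number proxy.

    ``expr`` is a genes x cells frame of per-gene mean-normalized
    log2(TPM+1); ``gene_order`` carries columns gene/chromosome/position.
    Values are clipped to [-clip, clip]; a mean over ``window`` genes
    slides one gene at a time, confined within each chromosome (events are
    chromosome-bounded, so windows do not straddle boundaries); each
    cell's profile is then centred at zero, removing residual per-cell
    expression offsets.
    """
    order = gene_order[gene_order["gene"].isin(expr.index)].copy()
    order = order.sort_values(["chromosome", "position"], kind="stable")
    clipped = expr.loc[order["gene"]].to_numpy(dtype=float).clip(-clip, clip)

    chroms = order["chromosome"].to_numpy()
    rows, meta = [], []
    for chrom in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == chrom)
        if len(idx) < window:
            warnings.warn(
                f"chromosome {chrom} has {len(idx)} genes (< window {window}); skipped"
            )
            continue
        block = clipped[idx]
        csum = np.cumsum(block, axis=0)
        csum = np.vstack([np.zeros((1, block.shape[1])), csum])
        means = (csum[window:] - csum[:-window]) / window
        rows.append(means)
        for start in range(len(idx) - window + 1):
            meta.append({"chromosome": chrom, "start": start, "end": start + window - 1})
    if not rows:
        raise ValueError("no chromosome has enough genes for one window")
    values = np.vstack(rows)
    values = values - values.mean(axis=0, keepdims=True)  # centre per cell
    windows = pd.DataFrame(meta)
    return CNVProfiles(
        values=pd.DataFrame(values, columns=expr.columns), windows=windows
    )


def baseline_profile(profiles: CNVProfiles, normal_cells: Sequence[str]) -> pd.Series:
    """Average CNV profile of the declared normal cells."""
    missing = [c for c in normal_cells if c not in profiles.values.columns]
    if missing:
        raise ValueError(f"normal cells not in profiles: {missing[:5]}")
    return profiles.values[list(normal_cells)].mean(axis=1)


def normalize_to_baseline(
    profiles: CNVProfiles,
    baseline: pd.Series,
    dead_zone: float = 0.3,
) -> CNVProfiles:
    """Deviation from the normal-cell baseline, zeroed inside the dead zone.

    d = CNV - CNV_base per position; values with |d| <= dead_zone are set
    to 0 (0.3 in log2 corresponds to ~23% expression change, below which a
    deviation is not called).
    """
    if len(baseline) != len(profiles.values):
        raise ValueError("baseline does not match profile positions")
    d = profiles.values.sub(np.asarray(baseline), axis=0)
    out = d.where(d.abs() > dead_zone, 0.0)
    return CNVProfiles(values=out, windows=profiles.windows.copy())


def cluster_cells_into_clones(
    profiles: CNVProfiles,
    k: int | None = 4,
    height: float | None = None,
) -> tuple[pd.Series, np.ndarray]:
    """Ward clustering of cells on Euclidean distance between CNV profiles.

    Returns integer clone labels per cell (cut at ``k`` clusters, or at
    ``height`` if given) and the scipy linkage matrix.
    """
    x = profiles.values.to_numpy().T
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells to cluster")
    link = hierarchy.linkage(x, method="ward", metric="euclidean")
    if height is not None:
        labels = hierarchy.fcluster(link, t=height, criterion="distance")
    else:
        if k is None or not (1 <= k <= n):
            raise ValueError(f"k must be in [1, {n}]")
        labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    return pd.Series(labels, index=profiles.values.columns, name="clone"), link


def linkage_to_newick(link: np.ndarray, leaf_names: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string."""
    tree = hierarchy.to_tree(link)

    def walk(node) -> str:
        if node.is_leaf():
            return leaf_names[node.id]
        left, right = walk(node.left), walk(node.right)
        dl = node.dist - node.left.dist
        dr = node.dist - node.right.dist
        return f"({left}:{dl:.6g},{right}:{dr:.6g})"

    return walk(tree) + ";"


def subtype_scores(
    expr: pd.DataFrame,
    gene_sets: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Per-cell program scores: mean over the gene set minus the cell mean.

    By construction the score of the all-genes set is zero for every cell.
    Returns cells x gene sets.
    """
    cell_mean = expr.mean(axis=0)
    out = {}
    for name, genes in gene_sets.items():
        present = [g for g in genes if g in expr.index]
        if not present:
            raise ValueError(f"gene set {name!r} has no measured genes")
        out[name] = expr.loc[present].mean(axis=0) - cell_mean
    return pd.DataFrame(out)


def score_significance(
    expr: pd.DataFrame,
    gene_set: Sequence[str],
    n_random: int = 100,
    level: float = 0.95,
    seed: int | None = None,
) -> pd.Series:
    """Call each cell's score enriched/depleted/neither vs random gene sets.

    ``n_random`` random sets of the same size are drawn from the measured
    genes; a cell is enriched if its real score exceeds the ``level``
    quantile of its random scores, depleted if below the 1-level quantile.
    """
    if n_random < 20:
        warnings.warn("n_random < 20 gives unstable percentile calls")
    present = [g for g in gene_set if g in expr.index]
    if not present:
        raise ValueError("gene set has no measured genes")
    rng = np.random.default_rng(seed)
    real = subtype_scores(expr, {"real": present})["real"]
    mat = expr.to_numpy()
    cell_mean = mat.mean(axis=0)
    rand_scores = np.empty((n_random, expr.shape[1]))
    for r in range(n_random):
        idx = rng.choice(expr.shape[0], size=len(present), replace=False)
        rand_scores[r] = mat[idx].mean(axis=0) - cell_mean
    hi = np.quantile(rand_scores, level, axis=0)
    lo = np.quantile(rand_scores, 1 - level, axis=0)
    call = np.where(real > hi, "enriched", np.where(real < lo, "depleted", "neither"))
    return pd.Series(call, index=expr.columns, name="call")


def compare_clone_scores(
    scores: pd.DataFrame,
    clone_labels: pd.Series,
    min_cells: int = 2,
) -> pd.DataFrame:
    """Kruskal-Wallis comparison of score distributions across clones.

    Clones with fewer than ``min_cells`` cells are excluded with a
    warning.  Returns H statistic and p-value per gene set.
    """
    labels = clone_labels.loc[scores.index]
    counts = labels.value_counts()
    keep = counts[counts >= min_cells].index
    dropped = counts[counts < min_cells]
    if len(dropped):
        warnings.warn(f"excluding clones with < {min_cells} cells: {list(dropped.index)}")
    if len(keep) < 2:
        raise ValueError("need at least 2 clones with enough cells")
    rows = []
    for name in scores.columns:
        groups = [
            scores.loc[labels == clone, name].to_numpy() for clone in keep
        ]
        h, p = stats.kruskal(*groups)
        rows.append({"gene_set": name, "H": h, "p_value": p})
    return pd.DataFrame(rows).set_index("gene_set")


def read_expression_matrix(path, gene_order: pd.DataFrame | None = None,
                           cells_path=None) -> pd.DataFrame:
    """Load a genes x cells expression matrix from TSV or MatrixMarket.

    TSV: first column gene names, header row cell names (the layout of
    public mean-normalized log2(TPM+1) matrices).  MTX: genes on rows,
    with row names taken from ``gene_order`` (in file order) and optional
    cell names one-per-line in ``cells_path``.
    """
    from pathlib import Path as _Path

    path = _Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread

        mat = np.asarray(mmread(path).todense())
        if gene_order is None or len(gene_order) != mat.shape[0]:
            raise ValueError("MTX input requires a gene_order table matching rows")
        if cells_path is not None:
            cells = [l.strip() for l in open(cells_path) if l.strip()]
        else:
            cells = [f"cell_{i:05d}" for i in range(mat.shape[1])]
        return pd.DataFrame(mat, index=list(gene_order["gene"]), columns=cells)
    return pd.read_csv(path, sep="\t", index_col=0)


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
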