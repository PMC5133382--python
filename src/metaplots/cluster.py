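"""Clustering and ordering of heatmap rows.

Three algorithms are offered — Lloyd k-means with a seeded greedy
farthest-point initialization, agglomerative Ward clustering, and a batch
self-organizing map — all over the same assembled input: the column-wise
concatenation of the matrices selected by an inclusion mask (so a heatmap
of four signals can be clustered on just one of them), with missing entries
imputed as 0.0 for distance computations only.

Clusters are renumbered 1..C by decreasing mean row strength, so cluster 1
is always the strongest; rows are ordered by cluster and, optionally, by
descending strength within each cluster. This makes numbering and row
order deterministic and comparable across methods and runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .core import FeatureSet, GenomicInterval
from .formats import write_bed
from .matrix import ProfileMatrix


@dataclass(frozen=True)
class ClusterRequest:
    """What to cluster and how.

    method: kmeans | hierarchical | som | none. `k` applies to kmeans and
    hierarchical; `som_grid` is the (rows, cols) neuron grid — a bare
    neuron count n means a 1 x n grid. `include_mask` selects which of the
    display matrices feed the clustering. `sort_within` additionally sorts
    rows by descending strength inside each cluster.
    """

    method: str = "kmeans"
    k: int = 3
    som_grid: tuple[int, int] = (1, 6)
    include_mask: tuple[bool, ...] | None = None
    sort_within: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("kmeans", "hierarchical", "som", "none"):
            raise ValueError(f"unknown clustering method {self.method!r}")
        if self.method in ("kmeans", "hierarchical") and self.k < 1:
            raise ValueError("k must be >= 1")
        if self.method == "som":
            r, c = self.som_grid
            if r < 1 or c < 1:
                raise ValueError("som_grid dimensions must be >= 1")


@dataclass
class ClusterResult:
    """Row labels, display order and provenance of one clustering run.

    labels are 1..C in strength order (cluster 1 strongest); `order` is the
    display permutation (top row first); `boundaries` are display positions
    where the cluster changes.
    """

    labels: np.ndarray
    order: np.ndarray
    boundaries: list[int]
    method_used: str
    seed: int = 0
    include_mask: tuple[bool, ...] | None = None

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) if self.labels.size else 0

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)


def assemble_cluster_input(
    matrices: list[ProfileMatrix], include_mask=None
) -> np.ndarray:
    """Column-wise concatenation of the included matrices, missing -> 0.0.

    The display matrices themselves are untouched; zeros are neutral for
    coverage-like data and keep distance computations defined.
    """
    if include_mask is None:
        include_mask = [True] * len(matrices)
    if len(include_mask) != len(matrices):
        raise ValueError("include_mask length must match number of matrices")
    chosen = [m for m, inc in zip(matrices, include_mask) if inc]
    if not chosen:
        raise ValueError("at least one matrix must be included")
    n_rows = chosen[0].n_features
    for m in chosen:
        if m.n_features != n_rows:
            raise ValueError(
                f"row-count mismatch: {m.n_features} vs {n_rows} "
                "(all matrices must share the same feature set)"
            )
    block = np.hstack([m.values for m in chosen])
    return np.nan_to_num(block, nan=0.0)


# ---------------------------------------------------------------------------
# k-means


def _farthest_point_init(x: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Greedy farthest-point centers: seeded random first pick, then each
    next center is the row farthest from its nearest chosen center.
    Deterministic given the seed."""
    rng = np.random.default_rng(seed)
    centers = [x[rng.integers(x.shape[0])]]
    d2 = np.sum((x - centers[0]) ** 2, axis=1)
    for _ in range(1, k):
        idx = int(np.argmax(d2))
        centers.append(x[idx])
        d2 = np.minimum(d2, np.sum((x - centers[-1]) ** 2, axis=1))
    return np.vstack(centers)


def _lloyd(x: np.ndarray, centers: np.ndarray, max_iter=300, tol=1e-6):
    k = centers.shape[0]
    for _ in range(max_iter):
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        assign = np.argmin(d2, axis=1)
        new_centers = centers.copy()
        for c in range(k):
            members = assign == c
            if members.any():
                new_centers[c] = x[members].mean(axis=0)
            else:
                # re-seed an emptied cluster at the worst-fit point
                new_centers[c] = x[np.argmax(d2.min(axis=1))]
        shift = np.sqrt(((new_centers - centers) ** 2).sum(axis=1)).max()
        centers = new_centers
        if shift < tol:
            break
    d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)


def kmeans_rows(
    x: np.ndarray, k: int, seed: int = 0, sort_within: bool = False
) -> ClusterResult:
    """Lloyd k-means on the assembled input (rows = features)."""
    if k > x.shape[0]:
        raise ValueError(f"k={k} exceeds the number of rows ({x.shape[0]})")
    centers = _farthest_point_init(x, k, seed)
    raw = _lloyd(x, centers)
    return _finalize(x, raw, "kmeans", seed=seed, sort_within=sort_within)


def hierarchical_rows(
    x: np.ndarray, k: int, sort_within: bool = False
) -> ClusterResult:
    """Agglomerative clustering: Euclidean distance, Ward linkage, tree cut
    to k clusters. Deterministic given the input; Ward shares k-means'
    variance objective so the two are directly comparable."""
    if k > x.shape[0]:
        raise ValueError(f"k={k} exceeds the number of rows ({x.shape[0]})")
    if x.shape[0] == 1:
        raw = np.zeros(1, dtype=int)
    else:
        z = linkage(x, method="ward", metric="euclidean")
        raw = fcluster(z, t=k, criterion="maxclust") - 1
    return _finalize(x, raw, "hierarchical", sort_within=sort_within)


# ---------------------------------------------------------------------------
# self-organizing map


def som_bmus(
    x: np.ndarray,
    som_grid: tuple[int, int] = (1, 6),
    seed: int = 0,
    epochs: int = 100,
) -> np.ndarray:
    """Best-matching unit index (row-major grid order) per input row after
    batch SOM training.

    Codebook vectors start at seeded random rows of the input. Each epoch
    assigns every row to its nearest unit, then replaces every codebook
    vector by the neighborhood-weighted mean of all rows, with a Gaussian
    neighborhood on the grid whose radius decays linearly from
    max(grid dims)/2 to 0.5 over the epochs.
    """
    rows, cols = som_grid
    n_units = rows * cols
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    pick = rng.choice(n, size=n_units, replace=n_units > n)
    codebook = x[pick].astype(float).copy()
    grid = np.array([(r, c) for r in range(rows) for c in range(cols)], dtype=float)
    grid_d2 = ((grid[:, None, :] - grid[None, :, :]) ** 2).sum(axis=2)
    sigma0 = max(rows, cols) / 2.0
    sigma1 = 0.5
    for t in range(epochs):
        frac = t / (epochs - 1) if epochs > 1 else 1.0
        sigma = sigma0 + (sigma1 - sigma0) * frac
        d2 = ((x[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=2)
        bmu = np.argmin(d2, axis=1)
        h = np.exp(-grid_d2 / (2.0 * sigma**2))  # units x units
        w = h[:, bmu]  # units x rows
        denom = w.sum(axis=1)
        nonzero = denom > 0
        codebook[nonzero] = (w[nonzero] @ x) / denom[nonzero, None]
    d2 = ((x[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)


def som_rows(
    x: np.ndarray,
    som_grid: tuple[int, int] = (1, 6),
    seed: int = 0,
    sort_within: bool = False,
    epochs: int = 100,
) -> ClusterResult:
    """Cluster rows by a batch-trained rectangular SOM (see
    :func:`som_bmus`); units with no assigned rows are dropped before
    cluster numbering, so numbering is dense."""
    bmu = som_bmus(x, som_grid, seed=seed, epochs=epochs)
    # drop empty units, keep grid order of the survivors
    used = np.unique(bmu)
    remap = {u: i for i, u in enumerate(used)}
    raw = np.array([remap[u] for u in bmu])
    return _finalize(x, raw, "som", seed=seed, sort_within=sort_within)


# ---------------------------------------------------------------------------
# numbering, ordering, dispatch


def _finalize(
    x: np.ndarray,
    raw_labels: np.ndarray,
    method: str,
    seed: int = 0,
    sort_within: bool = False,
    include_mask=None,
) -> ClusterResult:
    """Renumber clusters by decreasing mean strength and build the display
    order (cluster blocks; within a block, descending strength if
    sort_within, else original row order)."""
    strength = x.mean(axis=1)
    uniq = np.unique(raw_labels)
    means = {c: strength[raw_labels == c].mean() for c in uniq}
    # decreasing strength; mean then raw id as a deterministic tie-break
    ranked = sorted(uniq, key=lambda c: (-means[c], c))
    newnum = {c: i + 1 for i, c in enumerate(ranked)}
    labels = np.array([newnum[c] for c in raw_labels])
    idx = np.arange(x.shape[0])
    if sort_within:
        key = np.lexsort((idx, -strength, labels))
    else:
        key = np.lexsort((idx, labels))
    order = idx[key]
    ordered = labels[order]
    boundaries = [
        int(i) for i in range(1, len(ordered)) if ordered[i] != ordered[i - 1]
    ]
    return ClusterResult(
        labels=labels,
        order=order,
        boundaries=boundaries,
        method_used=method,
        seed=seed,
        include_mask=tuple(include_mask) if include_mask is not None else None,
    )


def cluster_rows(
    matrices: list[ProfileMatrix], request: ClusterRequest
) -> ClusterResult:
    """Dispatch a ClusterRequest over display matrices."""
    x = assemble_cluster_input(matrices, request.include_mask)
    if request.method == "kmeans":
        res = kmeans_rows(x, request.k, seed=request.seed, sort_within=request.sort_within)
    elif request.method == "hierarchical":
        res = hierarchical_rows(x, request.k, sort_within=request.sort_within)
    elif request.method == "som":
        res = som_rows(
            x, request.som_grid, seed=request.seed, sort_within=request.sort_within
        )
    else:  # none: single pseudo-cluster, optionally strength-sorted
        labels = np.ones(x.shape[0], dtype=int)
        strength = x.mean(axis=1)
        idx = np.arange(x.shape[0])
        order = idx[np.lexsort((idx, -strength))] if request.sort_within else idx
        res = ClusterResult(
            labels=labels,
            order=order,
            boundaries=[],
            method_used="none",
            seed=request.seed,
        )
    res.include_mask = (
        tuple(request.include_mask) if request.include_mask is not None else None
    )
    return res


# ---------------------------------------------------------------------------
# export


def export_clusters(result: ClusterResult, features: FeatureSet, out_path) -> Path:
    """Write the cluster spreadsheet: one row per feature in display order.

    Columns: chrom, start (0-based), end, name, strand, cluster,
    display_rank. Filtering to one cluster and converting to BED feeds the
    re-upload workflow (see :func:`cluster_to_bed`).
    """
    if len(features) != result.labels.shape[0]:
        raise ValueError("result rows do not match the feature set")
    out_path = Path(out_path)
    rows = []
    for rank, i in enumerate(result.order, start=1):
        iv = features[int(i)]
        rows.append(
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "name": iv.name,
                "strand": iv.strand,
                "cluster": int(result.labels[i]),
                "display_rank": rank,
            }
        )
    pd.DataFrame(rows).to_csv(out_path, index=False)
    return out_path


def cluster_to_bed(csv_path, cluster: int, bed_path) -> Path:
    """Extract one cluster from an exported spreadsheet as a BED file."""
    df = pd.read_csv(csv_path, keep_default_na=False, dtype={"name": str})
    sub = df[df["cluster"] == cluster]
    # BED row order follows the spreadsheet (display order)
    ivs = [
        GenomicInterval(
            str(row["chrom"]),
            int(row["start"]),
            int(row["end"]),
            name=str(row["name"]),
            strand=str(row["strand"]),
        )
        for _, row in sub.iterrows()
    ]
    fs = FeatureSet(ivs, source_path=str(csv_path))
    return write_bed(fs, bed_path)
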