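"""Lipid-droplet cluster detection and per-cell morphometry statistics.

Two droplets belong to the same cluster when the minimum distance
between their boundaries is at most ``threshold_px`` pixels (default
2 px, i.e. 0.266 μm at the default 0.133 μm/px calibration), extended
transitively: a cluster is a connected component of the pairwise-gap
graph with at least two members.  Cluster statistics (mean area and its
sample standard deviation) quantify the size and size heterogeneity of
clustered droplets; cluster abundance is reported per 100 droplets per
cell, broken down by cluster cardinality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .segmentation import DropletRecord, _bbox_gap

__all__ = [
    "Cluster",
    "boundary_gap",
    "find_clusters",
    "cluster_size_stats",
    "clusters_per_100_lds",
    "size_histogram",
    "DEFAULT_THRESHOLD_PX",
    "DEFAULT_BIN_EDGES_UM2",
    "CARDINALITY_BUCKETS",
]

#: boundary-gap threshold in pixels (0.266 μm at 0.133 μm/px)
DEFAULT_THRESHOLD_PX = 2.0

#: default area bin edges in μm² (last bin open-ended)
DEFAULT_BIN_EDGES_UM2 = (0.0, 0.5, 1.0, 1.5, 2.0, np.inf)

#: cluster-cardinality buckets for the per-100-LD rates
CARDINALITY_BUCKETS = (2, 3, 4, 5, "6+")


@dataclass
class Cluster:
    """A maximal set of >= 2 mutually gap-linked droplets in one cell."""

    member_ids: frozenset[int]
    cell_id: int | None
    n_lds: int
    mean_area_um2: float
    sd_area_um2: float


def boundary_gap(drop_a: DropletRecord, drop_b: DropletRecord) -> float:
    """Minimum Euclidean distance between pixel centres of two masks.

    Zero when the masks overlap.  The minimum over full masks is
    attained on boundary pixels for disjoint masks, so boundary pixel
    sets are used for speed, with an explicit overlap check first.
    """
    if drop_a.n_pixels == 0 or drop_b.n_pixels == 0:
        raise ValueError("boundary_gap requires non-empty masks")
    enc_a = drop_a.rows.astype(np.int64) * (1 << 32) + drop_a.cols
    enc_b = drop_b.rows.astype(np.int64) * (1 << 32) + drop_b.cols
    if np.intersect1d(enc_a, enc_b, assume_unique=False).size:
        return 0.0
    tree = cKDTree(np.column_stack([drop_b.boundary_rows, drop_b.boundary_cols]))
    d, _ = tree.query(
        np.column_stack([drop_a.boundary_rows, drop_a.boundary_cols]), k=1
    )
    return float(d.min())


def find_clusters(
    droplets: Sequence[DropletRecord],
    threshold_px: float = DEFAULT_THRESHOLD_PX,
) -> list[Cluster]:
    """Connected components of the boundary-gap graph, per cell.

    Droplets with ``cell_id`` None are excluded; clusters never span two
    cells.  Components of size 1 are singletons, not clusters, and are
    not returned (they are recoverable as droplets absent from every
    cluster).
    """
    by_cell: dict[int, list[DropletRecord]] = {}
    for d in droplets:
        if d.cell_id is not None:
            by_cell.setdefault(d.cell_id, []).append(d)

    clusters: list[Cluster] = []
    for cell_id in sorted(by_cell):
        members = by_cell[cell_id]
        n = len(members)
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if _bbox_gap(members[i].bbox, members[j].bbox) > threshold_px:
                    continue
                if boundary_gap(members[i], members[j]) <= threshold_px:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[max(ri, rj)] = min(ri, rj)
        groups: dict[int, list[DropletRecord]] = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(members[i])
        for grp in groups.values():
            if len(grp) < 2:
                continue
            areas = [g.area_um2 for g in grp]
            mean, sd = cluster_size_stats(areas)
            clusters.append(
                Cluster(
                    member_ids=frozenset(g.id for g in grp),
                    cell_id=cell_id,
                    n_lds=len(grp),
                    mean_area_um2=mean,
                    sd_area_um2=sd,
                )
            )
    return clusters


def cluster_size_stats(areas_um2: Sequence[float], ddof: int = 1) -> tuple[float, float]:
    """Mean and sample (n-1) standard deviation of member areas, μm²."""
    areas = np.asarray(areas_um2, dtype=float)
    if areas.size < 2:
        raise ValueError("a cluster has at least two members")
    if np.ptp(areas) == 0:  # exactly zero spread for identical areas
        return float(areas[0]), 0.0
    return float(areas.mean()), float(areas.std(ddof=ddof))


def clusters_per_100_lds(
    cell_droplets: Sequence[DropletRecord],
    clusters: Iterable[Cluster],
) -> dict[int | str, float] | None:
    """Cluster abundance per 100 droplets in one cell, by cardinality.

    ``rate_k = 100 * (#clusters of size k) / (#droplets in the cell)``
    for k in 2..5 plus a ``"6+"`` bucket.  Returns None (missing, not
    zero) for a cell without droplets.
    """
    n_lds = len(cell_droplets)
    if n_lds == 0:
        return None
    cell_ids = {d.cell_id for d in cell_droplets}
    if len(cell_ids) != 1:
        raise ValueError("clusters_per_100_lds expects the droplets of one cell")
    (cell_id,) = cell_ids
    counts: dict[int | str, int] = {k: 0 for k in CARDINALITY_BUCKETS}
    for cl in clusters:
        if cl.cell_id != cell_id:
            continue
        key: int | str = cl.n_lds if cl.n_lds <= 5 else "6+"
        counts[key] += 1
    return {k: 100.0 * c / n_lds for k, c in counts.items()}


def size_histogram(
    droplets: Sequence[DropletRecord],
    bin_edges_um2: Sequence[float] = DEFAULT_BIN_EDGES_UM2,
) -> pd.DataFrame:
    """Left-closed right-open area histogram ``[e_i, e_{i+1})`` per cell.

    Returns a DataFrame indexed by cell id (droplets outside any cell
    appear under id 0) with one column per bin, plus a ``"total"`` row
    with population counts and a ``"fraction"`` row with population
    fractions.
    """
    edges = np.asarray(bin_edges_um2, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges_um2 must be strictly increasing")
    labels = [
        f"[{edges[i]:g},{edges[i + 1]:g})" for i in range(edges.size - 1)
    ]
    cells = sorted({d.cell_id if d.cell_id is not None else 0 for d in droplets})
    table = pd.DataFrame(0, index=pd.Index(cells, name="cell_id"), columns=labels, dtype=float)
    for d in droplets:
        # digitize with right=False: index i means edges[i-1] <= a < edges[i]
        i = int(np.digitize(d.area_um2, edges, right=False))
        if i == 0 or i >= edges.size:
            continue  # below the first edge or at/above the last
        table.loc[d.cell_id if d.cell_id is not None else 0, labels[i - 1]] += 1
    total = table.sum(axis=0)
    frac = total / total.sum() if total.sum() > 0 else total * 0.0
    table.loc["total"] = total
    table.loc["fraction"] = frac
    return table
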