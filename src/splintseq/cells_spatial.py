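"""Cell segmentation, amplicon-to-cell assignment and spatial statistics.

Nuclei are segmented on the z-projected DAPI image (top-hat, Otsu,
distance-transform watershed); perinuclear zones are obtained by sequential
dilations of the nucleus labels with nearest-nucleus collision handling.
Amplicons inside a zone belong to that cell; the remainder are attributed
by affinity-propagation clustering of amplicon and nucleus positions with a
negative-squared-distance similarity, with the preference tuned by bisection
until the cluster count equals the nucleus count.

Downstream statistics operate on the cell-by-gene count matrix and cell
centroids: detection filters, a distance-pruned Delaunay proximity network,
a label-reshuffling interaction-enrichment test, and a permutation-null
gene-gene proximity matrix.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import Delaunay, cKDTree
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.morphology import disk, white_tophat
from skimage.segmentation import expand_labels, watershed
from sklearn.cluster import AffinityPropagation

__all__ = [
    "CellRecord",
    "segment_nuclei",
    "perinuclear_zones",
    "assign_amplicons",
    "build_count_matrix",
    "filter_matrix",
    "delaunay_network",
    "interaction_enrichment",
    "gene_proximity",
]


@dataclass
class CellRecord:
    """One segmented cell on the z-projected grid."""

    cell_id: int
    centroid: tuple[float, float]  # (y, x) in pixels
    n_pixels: int
    label: str | None = None  # cell-type label (post-clustering)


# ---------------------------------------------------------------------------
# nucleus segmentation
# ---------------------------------------------------------------------------

def _structure_tensor_energy(image: np.ndarray, sigma: float = 2.0) -> np.ndarray:
    """Trace of the structure tensor (optional pre-filter)."""
    gy, gx = np.gradient(image.astype(np.float64))
    return (
        ndimage.gaussian_filter(gy * gy, sigma)
        + ndimage.gaussian_filter(gx * gx, sigma)
    )


def segment_nuclei(
    dapi_image: np.ndarray,
    tophat_radius: int = 25,
    min_distance: int = 10,
    min_size: int = 30,
    use_structure_tensor: bool = False,
) -> tuple[np.ndarray, list[CellRecord]]:
    """Segment nuclei on a 2D z-projected DAPI image.

    White top-hat filtering removes the smooth background, Otsu's method
    binarizes, and touching nuclei are split by a watershed on the distance
    transform seeded at its local maxima. The structure-tensor energy
    pre-filter is optional and off by default.
    """
    img = np.asarray(dapi_image, dtype=np.float64)
    if use_structure_tensor:
        img = _structure_tensor_energy(img)
    filtered = white_tophat(img, footprint=disk(tophat_radius))
    if not np.any(filtered > 0):
        warnings.warn("blank DAPI image; no nuclei found")
        return np.zeros(img.shape, dtype=np.int32), []
    mask = filtered > threshold_otsu(filtered)
    if not mask.any():
        warnings.warn("no foreground after thresholding; no nuclei found")
        return np.zeros(img.shape, dtype=np.int32), []
    dist = ndimage.distance_transform_edt(mask)
    peaks = peak_local_max(dist, min_distance=min_distance, labels=mask,
                           exclude_border=False)
    markers = np.zeros(img.shape, dtype=np.int32)
    for i, p in enumerate(peaks, start=1):
        markers[tuple(p)] = i
    labels = watershed(-dist, markers=markers, mask=mask)
    # drop specks and relabel contiguously
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    keep = ids[counts >= min_size]
    remap = np.zeros(labels.max() + 1 if labels.size else 1, dtype=np.int32)
    remap[keep] = np.arange(1, len(keep) + 1)
    labels = remap[labels]
    records = []
    for lab, cen in zip(
        range(1, len(keep) + 1),
        ndimage.center_of_mass(labels > 0, labels, range(1, len(keep) + 1)),
    ):
        records.append(
            CellRecord(lab, (float(cen[0]), float(cen[1])),
                       int((labels == lab).sum()))
        )
    return labels, records


def perinuclear_zones(nucleus_labels: np.ndarray, n_dilations: int) -> np.ndarray:
    """Dilate each nucleus ``n_dilations`` steps into a perinuclear zone.

    Collision pixels go to the nearest nucleus, so zones stay disjoint and
    each zone contains its nucleus (n_dilations=0 returns the nuclei).
    """
    if n_dilations < 0:
        raise ValueError("n_dilations must be >= 0")
    if n_dilations == 0:
        return nucleus_labels.copy()
    return expand_labels(nucleus_labels, distance=n_dilations)


# ---------------------------------------------------------------------------
# amplicon -> cell assignment
# ---------------------------------------------------------------------------

def _affinity_propagation_k(
    points: np.ndarray, k: int, damping: float = 0.9, max_iter: int = 1000,
    bisect_steps: int = 25, random_state: int = 0,
) -> np.ndarray | None:
    """Affinity propagation with the preference bisected to yield k clusters.

    Similarity is the negative squared Euclidean distance. Returns cluster
    labels, or None if no preference in the bracket produced exactly k
    exemplars (apclusterK-style search).
    """
    d2 = ((points[:, None, :] - points[None, :, :]) ** 2).sum(-1)
    sim = -d2
    off = sim[~np.eye(len(points), dtype=bool)]
    lo, hi = float(off.min()) * 2, float(off.max())
    best = None

    def run(pref):
        ap = AffinityPropagation(
            damping=damping, max_iter=max_iter, preference=pref,
            affinity="euclidean", random_state=random_state,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            labels = ap.fit_predict(points)
        n = len(np.unique(labels[labels >= 0]))
        return labels, n

    for _ in range(bisect_steps):
        mid = (lo + hi) / 2
        labels, n = run(mid)
        if n == k:
            return labels
        if n < k:
            lo = mid  # larger preference -> more exemplars
        else:
            hi = mid
        best = labels
    return None


def assign_amplicons(
    amplicon_xy: np.ndarray,
    nucleus_centroids: np.ndarray,
    zone_labels: np.ndarray,
    damping: float = 0.9,
    max_iter: int = 1000,
) -> np.ndarray:
    """Assign each amplicon (2D position, (y, x)) to a cell id (1..K).

    Amplicons falling inside a perinuclear zone take that zone's cell
    directly. The rest are clustered jointly with the nucleus centroids by
    affinity propagation targeting K = number of nuclei; each cluster is
    attributed to the nucleus it contains (or the nearest nucleus if it
    contains none or several). If the preference search fails, assignment
    falls back to the nearest nucleus with a warning.
    """
    amplicon_xy = np.atleast_2d(np.asarray(amplicon_xy, dtype=float))
    nucleus_centroids = np.atleast_2d(np.asarray(nucleus_centroids, dtype=float))
    k = len(nucleus_centroids)
    if k == 0:
        raise ValueError("need at least one nucleus")
    n = len(amplicon_xy)
    assignment = np.zeros(n, dtype=int)

    # point-in-zone rule first
    yy = np.clip(np.round(amplicon_xy[:, 0]).astype(int), 0,
                 zone_labels.shape[0] - 1)
    xx = np.clip(np.round(amplicon_xy[:, 1]).astype(int), 0,
                 zone_labels.shape[1] - 1)
    in_zone = zone_labels[yy, xx]
    assignment[in_zone > 0] = in_zone[in_zone > 0]

    free = np.nonzero(assignment == 0)[0]
    if len(free) == 0:
        return assignment
    if k == 1:
        assignment[free] = 1
        return assignment

    points = np.vstack([amplicon_xy[free], nucleus_centroids])
    labels = _affinity_propagation_k(points, k, damping=damping,
                                     max_iter=max_iter)
    tree = cKDTree(nucleus_centroids)
    if labels is None:
        warnings.warn(
            "affinity propagation did not reach the target cluster count; "
            "falling back to nearest-nucleus assignment"
        )
        _, nearest = tree.query(amplicon_xy[free])
        assignment[free] = nearest + 1
        return assignment

    nucleus_cluster = labels[len(free):]
    cluster_to_cell: dict[int, int] = {}
    for cell_idx, cl in enumerate(nucleus_cluster, start=1):
        if cl in cluster_to_cell:
            continue  # two nuclei in one cluster: first wins, rest by distance
        cluster_to_cell[cl] = cell_idx
    for i, cl in zip(free, labels[: len(free)]):
        cell = cluster_to_cell.get(cl)
        if cell is None:
            _, nearest = tree.query(amplicon_xy[i])
            cell = int(nearest) + 1
        assignment[i] = cell
    return assignment


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------

def build_count_matrix(
    cell_ids: Sequence[int],
    genes: Sequence[str | None],
    statuses: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Cell-by-gene raw count matrix from per-amplicon assignments.

    Only decoded amplicons (status perfect or corrected) with a cell
    assignment contribute; discarded decodes and unassigned amplicons are
    excluded.
    """
    rows = []
    for i, (cell, gene) in enumerate(zip(cell_ids, genes)):
        if gene is None or cell is None or cell <= 0:
            continue
        if statuses is not None and statuses[i] not in {"perfect", "corrected"}:
            continue
        rows.append((cell, gene))
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame(rows, columns=["cell", "gene"])
    mat = df.groupby(["cell", "gene"]).size().unstack(fill_value=0)
    mat.index.name = "cell"
    mat.columns.name = "gene"
    return mat


def filter_matrix(
    matrix: pd.DataFrame,
    expression_threshold: int = 1,
    gene_det_in_min_cells: int = 5,
    min_det_genes_per_cell: int = 15,
) -> pd.DataFrame:
    """Detection filters on the count matrix, genes first then cells.

    A gene is detected in a cell iff its count is at least
    ``expression_threshold``. Genes detected in fewer than
    ``gene_det_in_min_cells`` cells are dropped; then cells with fewer than
    ``min_det_genes_per_cell`` detected (surviving) genes are dropped.
    """
    detected = matrix >= expression_threshold
    genes_ok = detected.sum(axis=0) >= gene_det_in_min_cells
    out = matrix.loc[:, genes_ok]
    cells_ok = (out >= expression_threshold).sum(axis=1) >= min_det_genes_per_cell
    out = out.loc[cells_ok]
    if out.empty:
        warnings.warn("filter_matrix removed every cell or gene")
    return out


# ---------------------------------------------------------------------------
# spatial statistics
# ---------------------------------------------------------------------------

def delaunay_network(
    centroids: np.ndarray,
    cutoff: float = 400.0,
    min_nn: int = 2,
    node_ids: Sequence | None = None,
) -> nx.Graph:
    """Distance-pruned Delaunay proximity graph over cell centroids.

    Delaunay edges longer than ``cutoff`` are removed unless they are among
    a node's ``min_nn`` shortest edges (so no node drops below ``min_nn``
    neighbors). Fewer than 3 points (or a degenerate configuration) falls
    back to the complete graph with a warning.
    """
    centroids = np.asarray(centroids, dtype=float)
    n = len(centroids)
    if node_ids is None:
        node_ids = list(range(n))
    g = nx.Graph()
    for i in range(n):
        g.add_node(node_ids[i], pos=tuple(centroids[i]))

    def length(i, j):
        return float(np.linalg.norm(centroids[i] - centroids[j]))

    edges: set[tuple[int, int]] = set()
    if n < 3:
        edges = {(i, j) for i in range(n) for j in range(i + 1, n)}
        if n >= 2:
            warnings.warn("fewer than 3 centroids; using complete graph")
    else:
        try:
            tri = Delaunay(centroids)
            for simplex in tri.simplices:
                for i, j in itertools.combinations(simplex, 2):
                    edges.add((min(i, j), max(i, j)))
        except Exception:
            warnings.warn("degenerate centroid geometry; using complete graph")
            edges = {(i, j) for i in range(n) for j in range(i + 1, n)}

    # protect each node's min_nn shortest incident edges from pruning
    incident: dict[int, list[tuple[float, tuple[int, int]]]] = {
        i: [] for i in range(n)
    }
    for e in edges:
        l = length(*e)
        incident[e[0]].append((l, e))
        incident[e[1]].append((l, e))
    protected: set[tuple[int, int]] = set()
    for i, lst in incident.items():
        lst.sort()
        protected.update(e for _, e in lst[:min_nn])
    for e in edges:
        l = length(*e)
        if l > cutoff and e not in protected:
            continue
        g.add_edge(node_ids[e[0]], node_ids[e[1]], length=l)
    return g


def interaction_enrichment(
    graph: nx.Graph,
    labels: Mapping,
    n_sim: int = 2000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Observed/expected cell-type interaction frequencies on a spatial graph.

    ``labels`` maps node -> cell-type label. The observed statistic is the
    edge count per unordered label pair; the null reshuffles the labels over
    the nodes uniformly (label counts preserved) ``n_sim`` times. Reported
    per pair: observed count, expected count (null mean), their ratio, the
    null 2.5%/97.5% band and a two-sided empirical p-value.
    """
    nodes = list(graph.nodes)
    if any(node not in labels for node in nodes):
        raise ValueError("every node must be labeled")
    label_names = sorted({labels[v] for v in nodes})
    code = {l: i for i, l in enumerate(label_names)}
    lab = np.array([code[labels[v]] for v in nodes])
    idx = {v: i for i, v in enumerate(nodes)}
    edges = np.array([(idx[u], idx[v]) for u, v in graph.edges], dtype=int)
    L = len(label_names)
    pairs = [(i, j) for i in range(L) for j in range(i, L)]
    pair_index = {p: k for k, p in enumerate(pairs)}

    def pair_counts(lab_vec):
        a = lab_vec[edges[:, 0]]
        b = lab_vec[edges[:, 1]]
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        flat = lo * L + hi
        counts = np.zeros(len(pairs), dtype=float)
        for k, (i, j) in enumerate(pairs):
            counts[k] = np.count_nonzero(flat == i * L + j)
        return counts

    if len(edges) == 0:
        raise ValueError("graph has no edges")
    observed = pair_counts(lab)
    rng = np.random.default_rng(seed)
    sims = np.empty((n_sim, len(pairs)))
    for s in range(n_sim):
        sims[s] = pair_counts(rng.permutation(lab))
    expected = sims.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(expected > 0, observed / expected, np.nan)
    lo_band = np.quantile(sims, 0.025, axis=0)
    hi_band = np.quantile(sims, 0.975, axis=0)
    centered = np.abs(sims - expected)
    pvals = (1 + (centered >= np.abs(observed - expected)).sum(axis=0)) / (
        n_sim + 1
    )
    return pd.DataFrame(
        {
            "label_a": [label_names[i] for i, _ in pairs],
            "label_b": [label_names[j] for _, j in pairs],
            "observed": observed,
            "expected": expected,
            "ratio": ratio,
            "null_lo95": lo_band,
            "null_hi95": hi_band,
            "p_value": pvals,
        }
    )


def gene_proximity(
    positions: np.ndarray,
    genes: Sequence[str],
    radius: float = 50.0,
    n_sim: int = 500,
    seed: int | None = None,
) -> pd.DataFrame:
    """Gene-gene spatial proximity matrix with a label-permutation null.

    proximity(g1, g2) = (number of amplicon pairs, one of each gene, within
    ``radius``) / (mean of that count under ``n_sim`` permutations of gene
    labels over amplicon positions). The matrix is symmetric; rows for genes
    with fewer than two amplicons are flagged low-support via the returned
    frame's ``attrs['low_support']``.
    """
    positions = np.asarray(positions, dtype=float)
    genes = np.asarray(genes)
    names = sorted(set(genes.tolist()))
    code = {g: i for i, g in enumerate(names)}
    lab = np.array([code[g] for g in genes])
    G = len(names)

    tree = cKDTree(positions)
    raw_pairs = tree.query_pairs(radius, output_type="ndarray")

    def matrix_counts(lab_vec):
        m = np.zeros((G, G), dtype=float)
        if len(raw_pairs):
            a = lab_vec[raw_pairs[:, 0]]
            b = lab_vec[raw_pairs[:, 1]]
            np.add.at(m, (a, b), 1)
            np.add.at(m, (b, a), 1)
        return m

    observed = matrix_counts(lab)
    rng = np.random.default_rng(seed)
    expected = np.zeros((G, G), dtype=float)
    for _ in range(n_sim):
        expected += matrix_counts(rng.permutation(lab))
    expected /= max(n_sim, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(expected > 0, observed / expected, np.nan)
    out = pd.DataFrame(ratio, index=names, columns=names)
    support = pd.Series(
        [(lab == i).sum() for i in range(G)], index=names, dtype=int
    )
    out.attrs["low_support"] = list(support.index[support < 2])
    return out
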