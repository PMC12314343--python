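"""Clustering raster neighbourhoods into tissue regions.

Neighbourhood composition vectors (per-class counts, normalised) are
clustered with a one-dimensional batch self-organising map (SOM) — or
k-means as an alternative — into *regions*: recurring local tissue
architectures such as tumour parenchyma, infiltrated parenchyma or the
vessel-rich tumour border. The number of regions is chosen from the
Davies-Bouldin and Calinski-Harabasz indices by a plateau ("elbow") rule.

Both indices are computed from their definitions here; library
implementations serve as cross-checks in the test suite only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .neighborhoods import Neighborhood, RasterGrid, nearest_neighborhood

__all__ = [
    "RegionModel",
    "KSelection",
    "normalize_compositions",
    "cluster_neighborhoods",
    "davies_bouldin",
    "calinski_harabasz",
    "select_num_regions",
    "plateau_choice",
    "region_composition",
    "region_interaction",
    "assign_cell_regions",
    "distribution_by_region",
    "suggest_region_names",
]

#: Region archetypes of an immunogenic tumour section, used to suggest
#: human-readable names from prototype compositions: pockets dominated by
#: one population, poorly infiltrated parenchyma, the mixed border band and
#: infiltrated parenchyma.
ARCHETYPE_DESCRIPTIONS = {
    "CD8": {"CD8T": "high"},
    "cDC1": {"cDC1": "high"},
    "vessel": {"vessel": "high", "CD8T": "mid"},
    "Tumour": {"tumour": "high"},
    "Border": {"CD8T": "mid", "cDC1": "mid", "vessel": "mid", "tumour": "mid"},
    "infTumour": {"tumour": "high", "CD8T": "mid", "vessel": "mid"},
}


@dataclass
class RegionModel:
    """Fitted region clustering: prototypes in normalised composition space."""

    k: int
    prototypes: np.ndarray  # (k, n_classes)
    classes: list[str]
    normalization: str
    scale: np.ndarray  # per-class divisors applied before clustering
    names: dict[int, str] = field(default_factory=dict)

    def predict(self, counts: np.ndarray) -> np.ndarray:
        """Label raw count rows by the nearest prototype."""
        x = np.asarray(counts, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            xn = np.where(self.scale > 0, x / self.scale, 0.0)
        if self.normalization == "p95":
            xn = np.clip(xn, None, 1.0)
        d2 = ((xn[:, None, :] - self.prototypes[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d2, axis=1)


@dataclass
class KSelection:
    """Cluster-number scan: quality indices per k and the chosen k."""

    k_range: list[int]
    db_values: np.ndarray
    ch_values: np.ndarray
    chosen_k: int
    delta: float
    warning: bool = False


def neighborhood_count_matrix(
    nbhds: list[Neighborhood], classes: list[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Stack neighbourhood counts into an (n, n_classes) matrix."""
    if classes is None:
        classes = sorted({c for nb in nbhds for c in nb.counts})
    mat = np.zeros((len(nbhds), len(classes)), dtype=float)
    for i, nb in enumerate(nbhds):
        for j, c in enumerate(classes):
            mat[i, j] = nb.counts.get(c, 0)
    return mat, classes


def normalize_compositions(
    counts: np.ndarray, mode: str = "p95"
) -> tuple[np.ndarray, np.ndarray]:
    """Normalise a neighbourhood-by-class count matrix.

    Modes: ``none`` (identity), ``max`` (divide by column max), ``p95``
    (divide by the column 95th percentile, clip at 1; all-zero columns stay
    0), ``zscore``. Returns the normalised matrix and the per-class scale
    divisors (1 for ``none``/``zscore``).
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 2 or len(x) < 1:
        raise ValueError("need a 2D matrix with at least one neighbourhood row")
    if mode == "none":
        return x.copy(), np.ones(x.shape[1])
    if mode == "max":
        scale = x.max(axis=0)
    elif mode == "p95":
        scale = np.percentile(x, 95, axis=0)
    elif mode == "zscore":
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        return (x - mu) / sd, np.ones(x.shape[1])
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    out = np.zeros_like(x)
    nz = scale > 0
    out[:, nz] = x[:, nz] / scale[nz]
    if mode == "p95":
        out = np.clip(out, None, 1.0)
    return out, np.where(nz, scale, 1.0)


def _batch_som_1d(
    x: np.ndarray, k: int, seed: int, epochs: int = 200, restarts: int = 4
) -> tuple[np.ndarray, np.ndarray]:
    """Batch-train a 1 x k SOM lattice on rows of ``x``.

    Nodes live on a line; at each epoch every row is assigned to its best
    matching node and nodes are re-estimated as neighbourhood-weighted
    means with a Gaussian lattice kernel whose width shrinks geometrically
    from k/2 to 0.05 lattice units over ``epochs``, followed by plain
    Lloyd refinement (the sigma -> 0 limit). The first restart initialises
    nodes at evenly spaced quantiles along the first principal axis;
    further restarts sample k distinct rows. The restart with the lowest
    quantisation error wins. Fully deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    n = len(x)
    x = np.ascontiguousarray(x, dtype=float)
    x_sq = (x**2).sum(axis=1)
    lattice = np.arange(k, dtype=float)
    sigma0, sigma_end = max(k / 2.0, 0.5), 0.05

    def _bmu_d2(nodes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # squared distances via the expansion, avoiding (n, k, dim) temporaries
        d2 = x_sq[:, None] - 2.0 * (x @ nodes.T) + (nodes**2).sum(axis=1)[None, :]
        return np.argmin(d2, axis=1), d2

    def _node_stats(bmu: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        counts = np.bincount(bmu, minlength=k).astype(float)
        sums = np.column_stack(
            [np.bincount(bmu, weights=x[:, d], minlength=k) for d in range(x.shape[1])]
        )
        return counts, sums

    centred = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    order = np.argsort(centred @ vt[0], kind="stable")
    pca_init = x[order[np.linspace(0, n - 1, k).round().astype(int)]].copy()

    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for r in range(max(restarts, 1)):
        if r == 0:
            nodes = pca_init + 1e-9 * rng.standard_normal(pca_init.shape)
        else:
            # k-means++-style seeding: draw each next node proportional to
            # squared distance from the nodes chosen so far
            idx = [int(rng.integers(n))]
            d2min = ((x - x[idx[0]]) ** 2).sum(axis=1)
            for _ in range(k - 1):
                total = d2min.sum()
                if total == 0:
                    idx.append(int(rng.integers(n)))
                    continue
                nxt = int(rng.choice(n, p=d2min / total))
                idx.append(nxt)
                d2min = np.minimum(d2min, ((x - x[nxt]) ** 2).sum(axis=1))
            nodes = x[idx].copy() + 1e-9 * rng.standard_normal((k, x.shape[1]))
        if r == 0:
            # canonical annealed batch phase; later restarts keep their
            # k-means++ seeding and run only the sigma -> 0 (Lloyd) limit,
            # since any lattice mixing would erase the seeding again
            for t in range(epochs):
                sigma = sigma0 * (sigma_end / sigma0) ** (t / max(epochs - 1, 1))
                bmu, _ = _bmu_d2(nodes)
                h = np.exp(
                    -((lattice[:, None] - lattice[None, :]) ** 2) / (2 * sigma**2)
                )
                counts, sums = _node_stats(bmu)
                denom = h @ counts
                num = h @ sums
                ok = denom > 0
                nodes[ok] = num[ok] / denom[ok, None]
        prev = None
        for _ in range(100):
            bmu, d2 = _bmu_d2(nodes)
            if prev is not None and np.array_equal(bmu, prev):
                break
            prev = bmu
            counts, sums = _node_stats(bmu)
            ok = counts > 0
            nodes[ok] = sums[ok] / counts[ok, None]
        bmu, d2 = _bmu_d2(nodes)
        sse = float(d2[np.arange(n), bmu].sum())
        if best is None or sse < best[0]:
            best = (sse, bmu, nodes)
    return best[1], best[2]


def cluster_neighborhoods(
    matrix: np.ndarray,
    k: int,
    method: str = "som",
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster normalised composition rows into ``k`` regions.

    ``method`` is ``som`` (1 x k batch self-organising map, default) or
    ``kmeans``. Deterministic for a fixed seed. Returns (labels,
    prototypes).
    """
    x = np.asarray(matrix, dtype=float)
    if k < 2:
        raise ValueError("k must be at least 2")
    n_distinct = len(np.unique(x, axis=0))
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct rows")
    if method == "som":
        return _batch_som_1d(x, k, seed)
    if method == "kmeans":
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(x)
        return km.labels_.astype(int), km.cluster_centers_
    raise ValueError(f"unknown clustering method {method!r}")


def davies_bouldin(matrix: np.ndarray, labels: np.ndarray) -> float:
    """Davies-Bouldin index: mean over clusters of the worst
    (scatter_i + scatter_j) / centroid-distance ratio. Lower is better."""
    x = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    cents = []
    scatter = []
    for u in uniq:
        pts = x[labels == u]
        if len(pts) == 0:
            raise ValueError(f"cluster {u} has no members")
        c = pts.mean(axis=0)
        cents.append(c)
        scatter.append(np.linalg.norm(pts - c, axis=1).mean())
    cents = np.asarray(cents)
    scatter = np.asarray(scatter)
    k = len(uniq)
    total = 0.0
    for i in range(k):
        worst = -np.inf
        for j in range(k):
            if i == j:
                continue
            m = np.linalg.norm(cents[i] - cents[j])
            if m == 0:
                raise ValueError(
                    f"clusters {uniq[i]} and {uniq[j]} have coincident centroids"
                )
            worst = max(worst, (scatter[i] + scatter[j]) / m)
        total += worst
    return total / k


def calinski_harabasz(matrix: np.ndarray, labels: np.ndarray) -> float:
    """Calinski-Harabasz index: between- over within-cluster dispersion,
    each per degree of freedom. Higher is better; zero within-cluster
    scatter yields +inf."""
    x = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    n, k = len(x), len(uniq)
    if not (2 <= k < n):
        raise ValueError("need 2 <= k < n")
    grand = x.mean(axis=0)
    between = 0.0
    within = 0.0
    for u in uniq:
        pts = x[labels == u]
        c = pts.mean(axis=0)
        between += len(pts) * float(np.sum((c - grand) ** 2))
        within += float(np.sum((pts - c) ** 2))
    if within == 0:
        return float("inf")
    return (between / (k - 1)) / (within / (n - k))


def select_num_regions(
    matrix: np.ndarray,
    k_range: range | list[int] = range(2, 11),
    seeds: list[int] = (0,),
    method: str = "som",
    delta: float = 0.10,
) -> KSelection:
    """Scan k and pick the plateau of the Davies-Bouldin / Calinski-Harabasz
    curves.

    For each k the indices are averaged over clustering ``seeds``. The
    chosen k is the smallest k whose DB is within ``delta`` of the best
    (lowest) DB among k' >= k *and* whose CH is within ``delta`` of the best
    (highest) CH among k' >= k — i.e. the first k at which both curves have
    stabilised. If no k satisfies both, the DB minimiser is returned with a
    warning flag.
    """
    ks = list(k_range)
    n = len(np.asarray(matrix))
    if not ks or min(ks) < 2 or max(ks) > n - 1:
        raise ValueError("k_range must lie within [2, n-1]")
    db = np.zeros(len(ks))
    ch = np.zeros(len(ks))
    for i, k in enumerate(ks):
        dvals, cvals = [], []
        for s in seeds:
            labels, _ = cluster_neighborhoods(matrix, k, method=method, seed=s)
            dvals.append(davies_bouldin(matrix, labels))
            cvals.append(calinski_harabasz(matrix, labels))
        db[i] = np.mean(dvals)
        ch[i] = np.mean(cvals)
    chosen, warning = plateau_choice(ks, db, ch, delta)
    if warning:
        warnings.warn("no k satisfies the plateau rule; returning argmin DB")
    return KSelection(
        k_range=ks, db_values=db, ch_values=ch, chosen_k=chosen,
        delta=delta, warning=warning,
    )


def plateau_choice(
    ks: list[int], db: np.ndarray, ch: np.ndarray, delta: float = 0.10
) -> tuple[int, bool]:
    """Smallest k at which both index curves have stabilised.

    k qualifies when DB(k) <= (1+delta) * min and CH(k) >= (1-delta) * max
    of the respective curves over k' >= k. The largest k is not eligible —
    a plateau needs at least one later k attesting it — so monotone,
    featureless curves select the DB minimiser with a warning instead.
    """
    db = np.asarray(db, dtype=float)
    ch = np.asarray(ch, dtype=float)
    db_fwd = np.minimum.accumulate(db[::-1])[::-1]
    ch_fwd = np.maximum.accumulate(ch[::-1])[::-1]
    ok = (db <= (1 + delta) * db_fwd) & (ch >= (1 - delta) * ch_fwd)
    ok[-1] = False
    if ok.any():
        return ks[int(np.argmax(ok))], False
    return ks[int(np.argmin(db))], True


def region_composition(
    nbhds: list[Neighborhood],
    labels: np.ndarray,
    classes: list[str] | None = None,
) -> pd.DataFrame:
    """Mean raw counts per class for each region (composition heatmap).

    Regions with no neighbourhoods are excluded.
    """
    mat, classes = neighborhood_count_matrix(nbhds, classes)
    labels = np.asarray(labels)
    rows = {}
    for u in np.unique(labels):
        rows[u] = mat[labels == u].mean(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index", columns=classes).sort_index()


def region_interaction(grid: RasterGrid, labels: np.ndarray) -> pd.DataFrame:
    """Percentage of shared lattice borders between regions.

    Considering all 4-adjacent pairs of lattice cells, entry (i, j != i) is
    the number of i-j edges as a percentage of all edges touching region i;
    the diagonal is the percentage of region-i edges internal to it. Rows
    therefore sum to 100 for every region that has at least one edge.
    """
    ny, nx = grid.shape
    lab = np.asarray(labels).reshape(ny, nx)
    uniq = np.unique(lab)
    index = {u: i for i, u in enumerate(uniq)}
    k = len(uniq)
    edge_counts = np.zeros((k, k))
    # horizontal and vertical 4-adjacency edges
    for a, b in [(lab[:, :-1], lab[:, 1:]), (lab[:-1, :], lab[1:, :])]:
        for u, v in zip(a.ravel(), b.ravel()):
            edge_counts[index[u], index[v]] += 1
            if u != v:
                edge_counts[index[v], index[u]] += 1
    # edge_counts[i, i] counts each internal edge once; row totals count
    # every edge touching region i once
    totals = edge_counts.sum(axis=1)
    pct = np.zeros_like(edge_counts)
    nzrow = totals > 0
    pct[nzrow] = 100.0 * edge_counts[nzrow] / totals[nzrow, None]
    return pd.DataFrame(pct, index=uniq, columns=uniq)


def assign_cell_regions(
    cells: np.ndarray, grid: RasterGrid, labels: np.ndarray
) -> np.ndarray:
    """Label each cell with the region of its nearest neighbourhood centre."""
    labels = np.asarray(labels)
    if len(labels) != len(grid):
        raise ValueError("labels must cover every grid neighbourhood")
    idx = nearest_neighborhood(cells, grid)
    return labels[idx]


def distribution_by_region(
    cell_labels: pd.DataFrame,
    group_col: str = "object_class",
    region_col: str = "region",
    section_col: str = "section_id",
) -> pd.DataFrame:
    """Per-section percentage of each group's cells falling in each region.

    ``cell_labels`` has one row per cell with section, group (class or
    state) and region columns. Percentages sum to 100 within each
    (section, group); empty groups are simply absent.
    """
    counts = (
        cell_labels.groupby([section_col, group_col, region_col], observed=True)
        .size()
        .rename("n")
        .reset_index()
    )
    totals = counts.groupby([section_col, group_col], observed=True)["n"].transform("sum")
    counts["percent"] = 100.0 * counts["n"] / totals
    return counts


def suggest_region_names(
    composition: pd.DataFrame, high: float = 0.5
) -> dict[int, str]:
    """Heuristic region names from a composition table.

    Matches each region's normalised mean composition against the known
    archetypes (single-population pockets, poorly infiltrated tumour,
    mixed border, infiltrated tumour). Intended as a starting point for a
    manual annotation config, not as a definitive call.
    """
    comp = composition.copy()
    # single table-wide scale: per-column scaling would inflate classes
    # that are uniformly rare into spurious "high" signals
    scale = float(comp.to_numpy().max()) or 1.0
    norm = comp / scale
    names: dict[int, str] = {}
    for region, row in norm.iterrows():
        best_name, best_score = "unnamed", -np.inf
        for name, profile in ARCHETYPE_DESCRIPTIONS.items():
            target = pd.Series(0.15, index=norm.columns)
            for cls, level in profile.items():
                if cls in target.index:
                    target[cls] = 0.9 if level == "high" else 0.5
            score = -float(((row - target) ** 2).sum())
            if score > best_score:
                best_name, best_score = name, score
        names[int(region)] = best_name
    return names
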