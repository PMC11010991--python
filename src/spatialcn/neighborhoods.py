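"""Cellular-neighborhood (CN) discovery from k-nearest-neighbor windows.

For every cell, a composition window is built from the cell itself plus its
nearest neighbors within the same tissue spot (default: center + 9 others,
Euclidean distance on centroid coordinates). The windows' cell-type
frequency vectors are pooled across all spots and clustered with
mini-batch k-means (default k = 10); clusters with similar centroid
compositions are then merged — either by an explicit user map or by
average-linkage agglomeration on centroid cosine distance — into the final
CNs, and every cell inherits the final CN of its own window. A per-type
z-score of mean composition across final CNs (the enrichment matrix) labels
what each CN is made of.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import cKDTree
from sklearn.cluster import MiniBatchKMeans

from spatialcn.phenotyping import CELL_TYPES

logger = logging.getLogger(__name__)

__all__ = [
    "CNConfig",
    "CompositionWindow",
    "NeighborhoodModel",
    "build_windows",
    "composition_matrix",
    "cluster_windows",
    "merge_neighborhoods",
    "enrichment_scores",
    "assign_cells",
    "cn_frequencies",
    "voronoi_export",
    "fit_neighborhoods",
]


@dataclass
class CNConfig:
    """Knobs of the CN algorithm.

    window_size counts the central cell, so the default 10 means the center
    plus its nine nearest neighbors. merge_mode is either "auto_threshold"
    (average-linkage agglomeration on centroid cosine distance, cut at
    merge_cosine_threshold) or "explicit_map" (a user-supplied
    initial-cluster -> final-CN mapping applied verbatim).
    """

    window_size: int = 10
    n_initial_clusters: int = 10
    clustering_seed: int = 0
    mini_batch_size: int = 8192
    merge_mode: str = "auto_threshold"
    merge_cosine_threshold: float = 0.20
    explicit_merge_map: dict[int, int] | None = None

    def __post_init__(self) -> None:
        if self.window_size < 2:
            raise ValueError("window_size must be >= 2")
        if self.n_initial_clusters < 2:
            raise ValueError("n_initial_clusters must be >= 2")
        if self.merge_mode not in ("auto_threshold", "explicit_map"):
            raise ValueError(f"unknown merge_mode {self.merge_mode!r}")
        if not 0.0 <= self.merge_cosine_threshold <= 1.0:
            raise ValueError("merge_cosine_threshold must lie in [0, 1]")


@dataclass
class CompositionWindow:
    """A central cell plus its nearest same-spot cells.

    member_cell_ids holds the center first, then neighbors ordered by
    (distance, cell_id). composition is filled by composition_matrix.
    """

    center_cell_id: str
    member_cell_ids: tuple[str, ...]
    spot_id: str
    composition: np.ndarray | None = None


@dataclass
class NeighborhoodModel:
    """Fitted CN model: initial clustering, merge, and enrichment."""

    centroids: pd.DataFrame  # initial cluster x cell type
    window_centers: list[str]  # cell_id of each window's center
    window_assignments: np.ndarray  # initial cluster id per window
    merge_map: dict[int, int]  # initial cluster id -> final CN id
    cn_labels: dict[int, str]  # final CN id -> display label
    enrichment: pd.DataFrame  # final CN x cell type, column-standardized
    dropped_clusters: list[int] = field(default_factory=list)

    @property
    def n_final(self) -> int:
        return len(set(self.merge_map.values()))


def _require_unique_ids(cells: pd.DataFrame) -> None:
    if cells["cell_id"].duplicated().any():
        dup = cells.loc[cells["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise ValueError(f"duplicate cell_id within a spot: {dup!r}")


def _spot_windows(spot: pd.DataFrame, window_size: int) -> list[CompositionWindow]:
    n = len(spot)
    ids = spot["cell_id"].to_numpy(dtype=object)
    xy = spot[["x_um", "y_um"]].to_numpy(dtype=float)
    if not np.isfinite(xy).all():
        raise ValueError("non-finite coordinates in spot")
    spot_id = str(spot["spot_id"].iloc[0])

    k = window_size
    if n < window_size:
        logger.warning(
            "spot %s has %d cells < window_size %d; using full-spot windows",
            spot_id, n, window_size,
        )
        k = n

    # rank of each cell in ascending cell_id order, for deterministic ties
    id_rank = np.empty(n, dtype=np.int64)
    id_rank[np.argsort(ids, kind="stable")] = np.arange(n)

    tree = cKDTree(xy)
    kq = min(n, k + 1)  # +1 so self can be discarded even under coincidence
    dist, idx = tree.query(xy, k=kq)
    dist = np.atleast_2d(dist)
    idx = np.atleast_2d(idx)

    windows: list[CompositionWindow] = []
    need = k - 1  # neighbors besides the center
    for i in range(n):
        row_idx = idx[i]
        row_d = dist[i]
        mask = row_idx != i
        cand_i = row_idx[mask]
        cand_d = row_d[mask]
        # coincident duplicates of the query point make several zero
        # distances; self was removed by index above, which is what matters
        order = np.lexsort((id_rank[cand_i], cand_d))
        cand_i, cand_d = cand_i[order], cand_d[order]
        if need and len(cand_i) > need:
            boundary = cand_d[need - 1]
            tol = 1e-9 * (1.0 + boundary)
            if cand_d[need] <= boundary + tol:
                # tie at the window boundary: re-gather every candidate at
                # that radius and resolve by (distance, cell_id)
                ball = np.array(tree.query_ball_point(xy[i], boundary + tol), dtype=int)
                ball = ball[ball != i]
                bd = np.hypot(*(xy[ball] - xy[i]).T)
                order = np.lexsort((id_rank[ball], bd))
                cand_i = ball[order]
        members = (ids[i], *ids[cand_i[:need]])
        windows.append(CompositionWindow(ids[i], members, spot_id))
    return windows


def build_windows(cells: pd.DataFrame, window_size: int = 10) -> list[CompositionWindow]:
    """One window per cell: the cell plus its nearest same-spot neighbors.

    Windows never cross spot boundaries. Distance ties at the window
    boundary are broken by ascending cell_id. Spots with fewer than
    window_size cells yield full-spot windows (logged).
    """
    if len(cells) < 2:
        raise ValueError("need at least 2 cells to build windows")
    windows: list[CompositionWindow] = []
    for _, spot in cells.groupby("spot_id", sort=False):
        _require_unique_ids(spot)
        windows.extend(_spot_windows(spot, window_size))
    return windows


def composition_matrix(
    windows: list[CompositionWindow],
    cells: pd.DataFrame,
    vocabulary: tuple[str, ...] = CELL_TYPES,
) -> np.ndarray:
    """Windows x types frequency matrix; row i is window i's composition.

    Every member cell must carry a label from the vocabulary; rows sum to 1.
    The per-window composition vectors are also written back onto the
    CompositionWindow objects.
    """
    if "cell_type" not in cells.columns:
        raise ValueError("cells must carry a 'cell_type' column")
    type_code = {t: i for i, t in enumerate(vocabulary)}
    labels = cells["cell_type"]
    bad = ~labels.isin(vocabulary)
    if bad.any():
        raise ValueError(f"unlabeled or out-of-vocabulary cell type: {labels[bad].iloc[0]!r}")
    code_of = dict(zip(cells["cell_id"], (type_code[t] for t in labels)))

    mat = np.zeros((len(windows), len(vocabulary)))
    for i, w in enumerate(windows):
        for cid in w.member_cell_ids:
            try:
                mat[i, code_of[cid]] += 1.0
            except KeyError:
                raise ValueError(f"window member {cid!r} missing from labeled cells") from None
        mat[i] /= len(w.member_cell_ids)
        w.composition = mat[i]
    return mat


def cluster_windows(
    matrix: np.ndarray, config: CNConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Mini-batch k-means on raw window frequencies.

    Returns (window_assignments, centroids). Deterministic for a fixed
    clustering_seed and input order.
    """
    n_windows = matrix.shape[0]
    k = config.n_initial_clusters
    if n_windows < k:
        raise ValueError(
            f"{n_windows} windows < {k} clusters; lower n_initial_clusters"
        )
    km = MiniBatchKMeans(
        n_clusters=k,
        random_state=config.clustering_seed,
        batch_size=config.mini_batch_size,
        n_init=20,
        max_iter=300,
    )
    assignments = km.fit_predict(matrix)
    return assignments, km.cluster_centers_


def merge_neighborhoods(
    centroids: np.ndarray,
    config: CNConfig,
    window_counts: np.ndarray | None = None,
) -> dict[int, int]:
    """Map initial cluster ids to final CN ids.

    explicit_map mode applies config.explicit_merge_map verbatim (it must
    cover every initial cluster). auto_threshold mode drops zero-window
    clusters, agglomerates the remaining centroids with average linkage on
    cosine distance, cuts the dendrogram at merge_cosine_threshold, and
    relabels the final CNs 1..n_final by descending total window count.
    """
    k = centroids.shape[0]
    if config.merge_mode == "explicit_map":
        m = config.explicit_merge_map
        if m is None or set(m) != set(range(k)):
            raise ValueError(
                f"explicit merge map must cover all {k} initial clusters, got {m}"
            )
        return {int(a): int(b) for a, b in m.items()}

    if window_counts is None:
        window_counts = np.ones(k)
    alive = np.flatnonzero(window_counts > 0)
    dropped = sorted(set(range(k)) - set(alive.tolist()))
    if dropped:
        logger.warning("dropping zero-window clusters before merging: %s", dropped)
    if len(alive) == 1:
        return {int(alive[0]): 1}

    z = linkage(centroids[alive], method="average", metric="cosine")
    groups = fcluster(z, t=config.merge_cosine_threshold, criterion="distance")

    # rank merged groups by total window count, descending; final ids 1..n
    totals: dict[int, float] = {}
    for c, g in zip(alive, groups):
        totals[g] = totals.get(g, 0.0) + float(window_counts[c])
    order = sorted(totals, key=lambda g: (-totals[g], g))
    final_of_group = {g: i + 1 for i, g in enumerate(order)}
    return {int(c): final_of_group[g] for c, g in zip(alive, groups)}


def enrichment_scores(
    window_assignments: np.ndarray,
    matrix: np.ndarray,
    merge_map: dict[int, int],
    vocabulary: tuple[str, ...] = CELL_TYPES,
) -> pd.DataFrame:
    """Scaled enrichment: per-type z-score of mean composition across CNs.

    Entry (c, t) standardizes the mean frequency of type t within CN c
    against the other CNs (population moments per type column). A type with
    zero variance across CNs scores 0 everywhere. CNs that received no
    windows are excluded with a warning.
    """
    final = np.array(
        [merge_map[int(a)] if int(a) in merge_map else -1 for a in window_assignments]
    )
    cn_ids = sorted(set(merge_map.values()))
    means = []
    kept = []
    for cn in cn_ids:
        rows = matrix[final == cn]
        if len(rows) == 0:
            logger.warning("final CN %d has zero windows; excluded from enrichment", cn)
            continue
        means.append(rows.mean(axis=0))
        kept.append(cn)
    m = np.asarray(means)
    if len(kept) > 1:
        mu = m.mean(axis=0)
        sd = m.std(axis=0)  # population std: unit variance across CNs
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(sd > 0, (m - mu) / sd, 0.0)
    else:
        z = np.zeros_like(m)
    return pd.DataFrame(z, index=pd.Index(kept, name="cn_final"), columns=list(vocabulary))


def assign_cells(
    cells: pd.DataFrame,
    windows: list[CompositionWindow],
    window_assignments: np.ndarray,
    merge_map: dict[int, int],
) -> pd.DataFrame:
    """Give each cell the final CN of its own window.

    Adds cn_initial and cn_final columns; merging is a coarsening, so cells
    sharing an initial cluster always share a final CN.
    """
    initial_of = {w.center_cell_id: int(a) for w, a in zip(windows, window_assignments)}
    out = cells.copy()
    out["cn_initial"] = out["cell_id"].map(initial_of)
    if out["cn_initial"].isna().any():
        missing = out.loc[out["cn_initial"].isna(), "cell_id"].iloc[0]
        raise ValueError(f"cell {missing!r} has no window")
    out["cn_initial"] = out["cn_initial"].astype(int)
    out["cn_final"] = out["cn_initial"].map(merge_map).astype(int)
    return out


def cn_frequencies(cells: pd.DataFrame, by: str = "patient_id") -> pd.DataFrame:
    """Per-patient (or per-spot) fraction of cells in each final CN.

    Rows sum to 1 over the CN columns; groups with no cells simply do not
    appear.
    """
    if "cn_final" not in cells.columns:
        raise ValueError("cells must carry a 'cn_final' column")
    counts = pd.crosstab(cells[by], cells["cn_final"])
    freq = counts.div(counts.sum(axis=1), axis=0)
    freq.columns = [f"CN{c}" for c in freq.columns]
    return freq


def voronoi_export(
    cells: pd.DataFrame,
    spot_center: tuple[float, float],
    spot_radius: float,
) -> dict:
    """Voronoi tessellation of cell centroids clipped to the spot disk.

    Returns a GeoJSON FeatureCollection; each polygon carries its cell's
    cell_id and final CN. Requires at least 3 non-collinear cells.
    """
    xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    if len(xy) < 3:
        raise ValueError("need >= 3 cells for a Voronoi tessellation")
    spread = xy - xy[0]
    cross = spread[1, 0] * spread[2:, 1] - spread[1, 1] * spread[2:, 0]
    if np.abs(cross).max(initial=0.0) < 1e-12:
        raise ValueError("degenerate geometry: cells are collinear")

    points = shapely.multipoints(xy)
    cells_poly = shapely.voronoi_polygons(points, extend_to=points.buffer(2 * spot_radius), ordered=True)
    disk = shapely.Point(spot_center).buffer(spot_radius, quad_segs=90)
    features = []
    cns = cells["cn_final"].tolist() if "cn_final" in cells.columns else [None] * len(xy)
    for cid, cn, poly in zip(cells["cell_id"], cns, cells_poly.geoms):
        clipped = poly.intersection(disk)
        if clipped.is_empty:
            continue
        features.append(
            {
                "type": "Feature",
                "geometry": shapely.geometry.mapping(clipped),
                "properties": {"cell_id": cid, "cn_final": None if cn is None else int(cn)},
            }
        )
    return {"type": "FeatureCollection", "features": features}


def fit_neighborhoods(
    cells: pd.DataFrame, config: CNConfig | None = None
) -> tuple[pd.DataFrame, NeighborhoodModel]:
    """Run the full CN algorithm on a labeled multi-spot cell table.

    Windows from all spots are pooled into one clustering so CN identities
    are comparable across patients. Returns the cell table with cn_initial /
    cn_final columns and the fitted NeighborhoodModel.
    """
    config = config or CNConfig()
    windows = build_windows(cells, config.window_size)
    matrix = composition_matrix(windows, cells)
    assignments, centroids = cluster_windows(matrix, config)
    counts = np.bincount(assignments, minlength=config.n_initial_clusters).astype(float)
    merge_map = merge_neighborhoods(centroids, config, window_counts=counts)
    enrichment = enrichment_scores(assignments, matrix, merge_map)
    labeled = assign_cells(cells, windows, assignments, merge_map)
    model = NeighborhoodModel(
        centroids=pd.DataFrame(centroids, columns=list(CELL_TYPES)),
        window_centers=[w.center_cell_id for w in windows],
        window_assignments=assignments,
        merge_map=merge_map,
        cn_labels={cn: f"CN{cn}" for cn in sorted(set(merge_map.values()))},
        enrichment=enrichment,
        dropped_clusters=sorted(set(range(config.n_initial_clusters)) - set(merge_map)),
    )
    return labeled, model
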