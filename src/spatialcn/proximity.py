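"""Nearest-cell distances between phenotype strata and the spatial score.

All distances are Euclidean on cell centroid coordinates in µm, computed
within a tissue spot (spots are physically separate cores). The spatial
score of a center cell is the ratio of its distance to the nearest cell of
identity A over its distance to the nearest cell of identity B: a score
above 1 means the cell sits closer to B than to A. With CD8 T cells as
centers, A = tumor and B = CD4 T, a high per-spot score reads as CD8 T
cells clustering with CD4 T cells rather than approaching tumor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceQuery",
    "SpatialScoreSpec",
    "nearest_distances",
    "mean_nearest_distance",
    "spatial_scores",
    "spatial_scores_by_patient",
    "distances_by_cn",
]


@dataclass(frozen=True)
class DistanceQuery:
    """Nearest-neighbor distance query between two cell strata.

    source/target select cells by phenotype, optionally restricted to a
    final CN. exclude_self makes a cell ineligible as its own target when
    the strata overlap.
    """

    source_type: str
    target_type: str
    source_cn: int | None = None
    target_cn: int | None = None
    exclude_self: bool = True


@dataclass(frozen=True)
class SpatialScoreSpec:
    """Per-cell ratio spec: nearest-A distance over nearest-B distance."""

    center_type: str = "CD8_T"
    identity_a: str = "Tumor"
    identity_b: str = "CD4_T"
    aggregation: str = "mean_of_ratios"  # or "ratio_of_means"

    def __post_init__(self) -> None:
        if self.aggregation not in ("mean_of_ratios", "ratio_of_means"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")


def _select(cells: pd.DataFrame, cell_type: str, cn: int | None) -> pd.DataFrame:
    mask = cells["cell_type"] == cell_type
    if cn is not None:
        mask &= cells["cn_final"] == cn
    return cells.loc[mask]


def _nearest(
    src_xy: np.ndarray,
    src_ids: np.ndarray,
    tgt_xy: np.ndarray,
    tgt_ids: np.ndarray,
    exclude_self: bool,
) -> np.ndarray:
    """Min distance from each source to the targets (self excluded on id)."""
    tree = cKDTree(tgt_xy)
    if not exclude_self:
        d, _ = tree.query(src_xy, k=1)
        return np.atleast_1d(d)
    k = min(2, len(tgt_xy))
    d, idx = tree.query(src_xy, k=k)
    d = np.atleast_2d(d.reshape(len(src_xy), k))
    idx = np.atleast_2d(idx.reshape(len(src_xy), k))
    out = np.full(len(src_xy), np.nan)
    tgt_id_arr = np.asarray(tgt_ids, dtype=object)
    for i in range(len(src_xy)):
        for j in range(k):
            if tgt_id_arr[idx[i, j]] != src_ids[i]:
                out[i] = d[i, j]
                break
        else:
            # every returned neighbor was the source itself (k exhausted):
            # only possible when the target set is just this cell
            out[i] = np.nan
    return out


def nearest_distances(spot: pd.DataFrame, query: DistanceQuery) -> pd.Series:
    """Per-source-cell distance to the nearest eligible target in the spot.

    Returns a Series indexed by source cell_id. If the spot has no eligible
    target, all source distances are undefined (NaN) and the exclusion is
    logged; callers drop NaNs before aggregating.
    """
    if spot["spot_id"].nunique() > 1:
        raise ValueError("nearest_distances operates on a single spot")
    src = _select(spot, query.source_type, query.source_cn)
    tgt = _select(spot, query.target_type, query.target_cn)
    if len(src) == 0:
        return pd.Series(dtype=float, name="distance_um")
    eligible = tgt
    if query.exclude_self:
        # a lone target identical to the source cell leaves it targetless
        pass
    if len(eligible) == 0 or (
        query.exclude_self
        and len(eligible) == 1
        and eligible["cell_id"].iloc[0] in set(src["cell_id"])
        and len(src) == 1
    ):
        logger.info(
            "spot %s: no eligible %s targets for %d %s sources",
            spot["spot_id"].iloc[0], query.target_type, len(src), query.source_type,
        )
        return pd.Series(
            np.nan, index=pd.Index(src["cell_id"], name="cell_id"), name="distance_um"
        )
    d = _nearest(
        src[["x_um", "y_um"]].to_numpy(float),
        src["cell_id"].to_numpy(object),
        eligible[["x_um", "y_um"]].to_numpy(float),
        eligible["cell_id"].to_numpy(object),
        query.exclude_self,
    )
    n_undef = int(np.isnan(d).sum())
    if n_undef:
        logger.info("spot %s: %d source cells with undefined distance", spot["spot_id"].iloc[0], n_undef)
    return pd.Series(d, index=pd.Index(src["cell_id"], name="cell_id"), name="distance_um")


def mean_nearest_distance(
    cells: pd.DataFrame, query: DistanceQuery, by: str = "patient_id"
) -> pd.Series:
    """Per-spot (per-patient) mean of defined nearest distances.

    Spots where every source distance is undefined are excluded.
    """
    means = {}
    for key, spot in cells.groupby(by, sort=True):
        d = nearest_distances(spot, query).dropna()
        if len(d):
            means[key] = float(d.mean())
    return pd.Series(means, name="mean_distance_um").rename_axis(by)


def spatial_scores(
    spot: pd.DataFrame, spec: SpatialScoreSpec
) -> tuple[pd.Series, float]:
    """Per-center-cell spatial scores and the per-spot aggregate.

    score(cell) = d(nearest identity-A) / d(nearest identity-B). Cells with
    a zero denominator (coincident coordinates) are excluded with a logged
    count. The per-spot value is the mean of defined per-cell ratios
    (default) or the ratio of the two mean distances; NaN when either
    population is missing from the spot.
    """
    qa = DistanceQuery(spec.center_type, spec.identity_a, exclude_self=True)
    qb = DistanceQuery(spec.center_type, spec.identity_b, exclude_self=True)
    da = nearest_distances(spot, qa)
    db = nearest_distances(spot, qb)
    if len(da) == 0 or da.isna().all() or db.isna().all():
        return pd.Series(dtype=float, name="spatial_score"), float("nan")
    zero_den = db == 0
    if zero_den.any():
        logger.info("excluding %d center cells with zero denominator distance", int(zero_den.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = da / db
    ratio[zero_den] = np.nan
    ratio = ratio.rename("spatial_score")
    defined = ratio.dropna()
    if spec.aggregation == "mean_of_ratios":
        agg = float(defined.mean()) if len(defined) else float("nan")
    else:
        agg = float(da.dropna().mean() / db[db > 0].mean())
    return ratio, agg


def spatial_scores_by_patient(
    cells: pd.DataFrame, spec: SpatialScoreSpec, by: str = "patient_id"
) -> pd.Series:
    """Per-patient spatial score; patients with undefined scores excluded."""
    out = {}
    for key, spot in cells.groupby(by, sort=True):
        _, agg = spatial_scores(spot, spec)
        if np.isfinite(agg):
            out[key] = agg
    return pd.Series(out, name="spatial_score").rename_axis(by)


def distances_by_cn(
    cells: pd.DataFrame,
    query: DistanceQuery,
    designated_cn: int | None = None,
    by: str = "spot_id",
) -> tuple[dict[int, np.ndarray], dict[str, np.ndarray] | None]:
    """Partition per-cell nearest distances by the source cell's final CN.

    Returns ({cn: distances}, and — when designated_cn is given — a binary
    {"in": ..., "out": ...} split of the same distances). Empty strata come
    back as empty arrays. Distances are computed per spot against the full
    target stratum (targets are not CN-restricted unless the query says so).
    """
    if "cn_final" not in cells.columns:
        raise ValueError("cells must carry a 'cn_final' column")
    pieces = []
    for _, spot in cells.groupby(by, sort=True):
        d = nearest_distances(spot, query).dropna()
        if len(d) == 0:
            continue
        cn_of = spot.set_index("cell_id")["cn_final"]
        pieces.append(pd.DataFrame({"distance_um": d, "cn_final": cn_of.reindex(d.index)}))
    if pieces:
        table = pd.concat(pieces)
    else:
        table = pd.DataFrame(columns=["distance_um", "cn_final"])
    strata = {
        int(cn): grp["distance_um"].to_numpy(float)
        for cn, grp in table.groupby("cn_final", sort=True)
    }
    split = None
    if designated_cn is not None:
        in_mask = table["cn_final"] == designated_cn
        split = {
            "in": table.loc[in_mask, "distance_um"].to_numpy(float),
            "out": table.loc[~in_mask, "distance_um"].to_numpy(float),
        }
    return strata, split
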