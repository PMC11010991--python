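"""Threshold gating of segmented cells into eight phenotype labels.

Each cell carries mean fluorescence intensities for a nuclear counterstain
(DAPI) and seven lineage markers (PanCK, CD3, CD4, CD8, CD20, CD31, CD68).
A cell is "positive" for a marker when its intensity strictly exceeds the
marker's global threshold. Labels are assigned by the first matching rule
in a fixed priority order, so every DAPI-positive cell receives exactly one
of the eight labels; DAPI-negative objects are treated as segmentation
debris and dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Marker panel, fixed column order for intensity tables.
MARKERS: tuple[str, ...] = (
    "DAPI",
    "PanCK",
    "CD3",
    "CD4",
    "CD8",
    "CD20",
    "CD31",
    "CD68",
)

#: Closed eight-label phenotype vocabulary; this ordering is used for every
#: downstream composition vector.
CELL_TYPES: tuple[str, ...] = (
    "Tumor",
    "Endothelial",
    "CD8_T",
    "CD4_T",
    "Other_T",
    "Macrophage",
    "B_cell",
    "Stroma",
)

#: Defining (positive) non-DAPI markers per phenotype. Stroma is the
#: fallback: DAPI-positive with no other positive marker.
TYPE_POSITIVE_MARKERS: dict[str, tuple[str, ...]] = {
    "Tumor": ("PanCK",),
    "Endothelial": ("CD31",),
    "CD8_T": ("CD3", "CD8"),
    "CD4_T": ("CD3", "CD4"),
    "Other_T": ("CD3",),
    "Macrophage": ("CD68",),
    "B_cell": ("CD20",),
    "Stroma": (),
}


@dataclass(frozen=True)
class GatingRule:
    """One gate: label granted if all `positive` markers exceed threshold
    and all `negative` markers do not."""

    label: str
    positive: tuple[str, ...]
    negative: tuple[str, ...] = ()


@dataclass
class GatingScheme:
    """Priority-ordered gating rules plus per-marker positivity thresholds.

    Rules are evaluated top-down; the first match wins. Exactly one rule
    (the fallback, Stroma) requires no positive non-DAPI marker.
    """

    thresholds: dict[str, float]
    rules: list[GatingRule] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [m for m in MARKERS if m not in self.thresholds]
        if missing:
            raise ValueError(f"missing thresholds for markers: {missing}")
        labels = [r.label for r in self.rules]
        if sorted(labels) != sorted(CELL_TYPES):
            raise ValueError(
                f"rules must cover the eight-type vocabulary exactly once, got {labels}"
            )
        fallbacks = [r for r in self.rules if not r.positive]
        if len(fallbacks) != 1:
            raise ValueError("exactly one rule must be the markerless fallback")

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.rules]

    def to_dict(self) -> dict:
        """Plain-dict form for YAML/JSON config round-trips."""
        return {
            "thresholds": dict(self.thresholds),
            "rules": [
                {
                    "label": r.label,
                    "positive": list(r.positive),
                    "negative": list(r.negative),
                }
                for r in self.rules
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GatingScheme":
        rules = [
            GatingRule(r["label"], tuple(r["positive"]), tuple(r.get("negative", ())))
            for r in d["rules"]
        ]
        return cls(thresholds={k: float(v) for k, v in d["thresholds"].items()}, rules=rules)


def default_gating_scheme(thresholds: dict[str, float]) -> GatingScheme:
    """Build the standard priority-ordered scheme from per-marker thresholds.

    Priority: Tumor (PanCK+) > Endothelial (CD31+) > CD8 T (CD3+CD8+) >
    CD4 T (CD3+CD4+) > other T (CD3+CD8-CD4-) > Macrophage (CD68+) >
    B cell (CD20+) > Stroma (DAPI+ only). Multi-positive cells resolve to
    the first matching rule; within the T lineage CD8 is checked before CD4,
    so a CD3+CD8+CD4+ cell gates as CD8_T.

    Parameters
    ----------
    thresholds
        Positivity threshold per marker, for all eight markers.
    """
    rules = [
        GatingRule("Tumor", ("PanCK",)),
        GatingRule("Endothelial", ("CD31",)),
        GatingRule("CD8_T", ("CD3", "CD8")),
        GatingRule("CD4_T", ("CD3", "CD4")),
        GatingRule("Other_T", ("CD3",), negative=("CD8", "CD4")),
        GatingRule("Macrophage", ("CD68",)),
        GatingRule("B_cell", ("CD20",)),
        GatingRule("Stroma", ()),
    ]
    return GatingScheme(thresholds=dict(thresholds), rules=rules)


def _intensity_columns(cells: pd.DataFrame) -> dict[str, str]:
    cols = {}
    for m in MARKERS:
        for cand in (f"{m}_intensity", m):
            if cand in cells.columns:
                cols[m] = cand
                break
        else:
            raise ValueError(f"cell table lacks an intensity column for marker {m!r}")
    return cols


def assign_cell_types(cells: pd.DataFrame, scheme: GatingScheme) -> pd.DataFrame:
    """Gate every cell to one phenotype; drop DAPI-negative cells.

    Returns a copy of the retained rows with a ``cell_type`` column added.
    The number of dropped DAPI-negative cells is logged at INFO. NaN or
    infinite intensities are rejected.
    """
    cols = _intensity_columns(cells)
    inten = cells[[cols[m] for m in MARKERS]].to_numpy(dtype=float)
    if not np.isfinite(inten).all():
        bad = np.argwhere(~np.isfinite(inten))
        r, c = bad[0]
        raise ValueError(
            f"non-finite intensity at row {cells.index[r]}, marker {MARKERS[c]!r}"
        )

    thr = np.array([scheme.thresholds[m] for m in MARKERS])
    positive = inten > thr  # (n_cells, n_markers) boolean
    pos = {m: positive[:, i] for i, m in enumerate(MARKERS)}

    keep = pos["DAPI"]
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d DAPI-negative cells of %d", n_dropped, len(cells))

    labels = np.empty(len(cells), dtype=object)
    unassigned = keep.copy()
    for rule in scheme.rules:
        match = unassigned.copy()
        for m in rule.positive:
            match &= pos[m]
        for m in rule.negative:
            match &= ~pos[m]
        if not rule.positive:  # fallback: any still-unassigned DAPI+ cell
            match = unassigned.copy()
        labels[match] = rule.label
        unassigned &= ~match

    out = cells.loc[keep].copy()
    out["cell_type"] = labels[keep]
    out.attrs["n_dropped_dapi_negative"] = n_dropped
    return out
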