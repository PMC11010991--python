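"""Seeded synthetic TMA cohorts with planted cellular-neighborhood structure.

The generator emulates the kind of data a multiplexed-imaging study of a
tissue microarray produces after segmentation: one circular 1.5 mm spot per
patient, a few thousand cells per spot with centroid coordinates in µm and
eight per-marker mean intensities, and a patient-level survival table.

Planted structure: each spot is partitioned into spatially contiguous
regions (a Voronoi mosaic over random seed points, or concentric radial
bands), every region is tagged with one of ``n_planted_cns`` neighborhood
archetypes, and cell types inside a region are drawn i.i.d. from that
archetype's composition row. Marker intensities follow a two-channel
log-normal emission model (positive channel for a type's defining markers
and DAPI, negative channel otherwise). Survival times are exponential with
a log-hazard proportional to the patient's true frequency of a designated
risk archetype, with independent administrative censoring.

Everything is driven by a single integer seed through
``numpy.random.SeedSequence`` spawning; identical configs give
byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from spatialcn.phenotyping import CELL_TYPES, MARKERS, TYPE_POSITIVE_MARKERS

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "default_archetypes",
    "default_marker_emission",
    "default_thresholds",
    "generate_spot",
    "generate_cohort",
    "generate_survival",
]

#: Archetype composition rows (planted CN x cell type, columns ordered as
#: CELL_TYPES). The six defaults sketch the canonical compartments of a
#: desmoplastic tumor microenvironment: a pure stroma barrier, the bulk
#: tumor, a lymphocyte-enriched region whose top components are CD4 T,
#: stroma and CD8 T cells, a perivascular region, a macrophage niche, and a
#: reactive (immune-infiltrated) stroma.
_DEFAULT_ARCHETYPES = {
    #            Tumor  Endo  CD8   CD4   OthT  Mac   B     Stroma
    "pure_stroma":      [0.01, 0.01, 0.01, 0.01, 0.01, 0.02, 0.01, 0.92],
    "bulk_tumor":       [0.90, 0.01, 0.01, 0.01, 0.01, 0.01, 0.01, 0.04],
    "lymphocyte":       [0.01, 0.01, 0.25, 0.45, 0.10, 0.02, 0.10, 0.06],
    "perivascular":     [0.03, 0.75, 0.02, 0.02, 0.01, 0.04, 0.01, 0.12],
    "macrophage_niche": [0.05, 0.03, 0.02, 0.02, 0.01, 0.78, 0.01, 0.08],
    "reactive_stroma":  [0.05, 0.04, 0.03, 0.02, 0.01, 0.30, 0.30, 0.25],
}

#: Log-space (location, scale) of the log-normal intensity channels.
#: Negative channel: median 5 a.u.; positive channel: median 60 a.u. The
#: ~4 sigma separation in log space keeps the channels gateable with a
#: single global threshold at their log-midpoint (~17.3 a.u.).
_NEG_CHANNEL = (float(np.log(5.0)), 0.3)
_POS_CHANNEL = (float(np.log(60.0)), 0.3)


def default_archetypes(n: int = 6) -> tuple[list[str], np.ndarray]:
    """Return (names, n x 8 composition matrix) for up to six planted CNs."""
    if not 1 <= n <= len(_DEFAULT_ARCHETYPES):
        raise ValueError(f"default archetypes available for 1..6 planted CNs, got {n}")
    names = list(_DEFAULT_ARCHETYPES)[:n]
    return names, np.array([_DEFAULT_ARCHETYPES[k] for k in names], dtype=float)


def default_marker_emission() -> dict[str, dict[str, tuple[float, float]]]:
    """Per-marker log-normal (location, scale) for both channels."""
    return {
        m: {"positive": _POS_CHANNEL, "negative": _NEG_CHANNEL} for m in MARKERS
    }


def default_thresholds() -> dict[str, float]:
    """Gating thresholds at the log-midpoint of the two emission channels."""
    mid = float(np.exp((_NEG_CHANNEL[0] + _POS_CHANNEL[0]) / 2.0))
    return {m: mid for m in MARKERS}


@dataclass
class SyntheticConfig:
    """Cohort-scale knobs for the synthetic TMA generator.

    Defaults follow the study design being emulated: 64 patients, one
    1.5 mm spot each, six planted neighborhood archetypes over eight cell
    types, and an exponential survival model whose log-hazard is
    ``survival_beta`` times the patient's true risk-CN frequency.
    """

    n_patients: int = 64
    spot_diameter: float = 1500.0  # µm
    cells_per_spot: int | tuple[int, int] = (1500, 3000)
    n_planted_cns: int = 6
    archetype_matrix: np.ndarray | None = None  # n_planted_cns x 8, rows on simplex
    archetype_names: list[str] | None = None
    region_layout: str = "voronoi_seeds"  # or "radial_bands"
    n_region_seeds_per_cn: int = 1
    marker_emission: dict | None = None
    risk_cn: int = 3  # 1-based planted CN id driving the hazard (lymphocyte region)
    survival_baseline: float = 0.03  # events / month
    survival_beta: float = 3.0  # log-hazard per unit risk-CN frequency
    censoring_rate: float = 0.2
    max_followup_months: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.archetype_matrix is None:
            names, mat = default_archetypes(self.n_planted_cns)
            self.archetype_matrix = mat
            if self.archetype_names is None:
                self.archetype_names = names
        else:
            self.archetype_matrix = np.asarray(self.archetype_matrix, dtype=float)
        if self.archetype_names is None:
            self.archetype_names = [f"archetype_{i + 1}" for i in range(self.n_planted_cns)]
        if self.marker_emission is None:
            self.marker_emission = default_marker_emission()
        self.validate()

    def validate(self) -> None:
        if self.n_patients <= 0 or self.n_planted_cns <= 0 or self.n_region_seeds_per_cn <= 0:
            raise ValueError("all counts must be positive")
        if self.spot_diameter <= 0:
            raise ValueError("spot_diameter must be > 0")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must lie in [0, 1)")
        if self.survival_baseline <= 0 or self.max_followup_months <= 0:
            raise ValueError("survival_baseline and max_followup_months must be > 0")
        mat = self.archetype_matrix
        if mat.shape != (self.n_planted_cns, len(CELL_TYPES)):
            raise ValueError(
                f"archetype_matrix must be {self.n_planted_cns} x {len(CELL_TYPES)}, got {mat.shape}"
            )
        if (mat < 0).any() or not np.allclose(mat.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("archetype rows must be non-negative and sum to 1 within 1e-9")
        if not 1 <= self.risk_cn <= self.n_planted_cns:
            raise ValueError("risk_cn must index a planted CN (1-based)")
        if self.region_layout not in ("voronoi_seeds", "radial_bands"):
            raise ValueError(f"unknown region_layout {self.region_layout!r}")
        lo, hi = self._cell_range()
        if lo < 1 or hi < lo:
            raise ValueError("cells_per_spot must be a positive count or (lo, hi) range")

    def _cell_range(self) -> tuple[int, int]:
        if isinstance(self.cells_per_spot, (tuple, list)):
            lo, hi = self.cells_per_spot
            return int(lo), int(hi)
        return int(self.cells_per_spot), int(self.cells_per_spot)

    def with_(self, **kwargs) -> "SyntheticConfig":
        """Copy with fields replaced (re-validated)."""
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Planted labels the generator knows but the pipeline must recover."""

    cell_cn: pd.Series  # planted CN id (1-based) indexed by cell_id
    regions: pd.DataFrame  # one row per region: patient_id, region_id, planted_cn
    risk_cn_frequency: pd.Series = field(
        default_factory=lambda: pd.Series(dtype=float)
    )  # per-patient true frequency of the risk CN


def _uniform_disk(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    r = radius * np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _region_ids_voronoi(
    xy: np.ndarray, rng: np.random.Generator, radius: float, n_cns: int, seeds_per_cn: int
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-seed Voronoi mosaic; returns (cell region ids, region CN ids)."""
    n_seeds = n_cns * seeds_per_cn
    seed_cns = np.repeat(np.arange(1, n_cns + 1), seeds_per_cn)
    for _ in range(20):
        seeds = _uniform_disk(rng, n_seeds, radius)
        d2 = ((xy[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
        region = d2.argmin(axis=1)
        if len(np.unique(region)) == n_seeds:
            return region, seed_cns
    raise RuntimeError(
        f"could not place {n_seeds} region seeds with non-empty regions in 20 attempts; "
        "increase cells_per_spot or reduce n_region_seeds_per_cn"
    )


def _region_ids_radial(
    xy: np.ndarray, radius: float, n_cns: int, bands_per_cn: int
) -> tuple[np.ndarray, np.ndarray]:
    """Equal-area concentric bands, CN ids assigned cyclically outward."""
    n_bands = n_cns * bands_per_cn
    r = np.hypot(xy[:, 0], xy[:, 1])
    # equal-area annuli: band k spans radii radius*sqrt(k/n)..sqrt((k+1)/n)
    band = np.minimum((n_bands * (r / radius) ** 2).astype(int), n_bands - 1)
    band_cns = (np.arange(n_bands) % n_cns) + 1
    if len(np.unique(band)) < n_bands:
        raise RuntimeError("radial band layout produced an empty band; add cells")
    return band, band_cns


def generate_spot(
    config: SyntheticConfig, patient_id: str, rng: np.random.Generator
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate one circular TMA spot for one patient.

    Returns the cell table (coordinates in a per-spot frame with origin at
    the spot's bounding-box corner) and the spot's ground-truth slice.
    """
    lo, hi = config._cell_range()
    n_cells = int(rng.integers(lo, hi + 1))
    radius = config.spot_diameter / 2.0
    xy = _uniform_disk(rng, n_cells, radius)

    if config.region_layout == "voronoi_seeds":
        region, region_cns = _region_ids_voronoi(
            xy, rng, radius, config.n_planted_cns, config.n_region_seeds_per_cn
        )
    else:
        region, region_cns = _region_ids_radial(
            xy, radius, config.n_planted_cns, config.n_region_seeds_per_cn
        )
    cell_cn = region_cns[region]  # 1-based planted CN per cell

    # cell types: i.i.d. from the archetype row of each cell's region CN
    cum = np.cumsum(config.archetype_matrix, axis=1)
    u = rng.uniform(size=n_cells)
    type_idx = (u[:, None] > cum[cell_cn - 1]).sum(axis=1)
    type_idx = np.minimum(type_idx, len(CELL_TYPES) - 1)
    cell_types = np.array(CELL_TYPES, dtype=object)[type_idx]

    # marker intensities: positive channel for DAPI and the type's defining
    # markers, negative channel otherwise
    inten = np.empty((n_cells, len(MARKERS)))
    for j, marker in enumerate(MARKERS):
        pos_mask = np.array(
            [marker == "DAPI" or marker in TYPE_POSITIVE_MARKERS[t] for t in cell_types]
        )
        mu_p, sd_p = config.marker_emission[marker]["positive"]
        mu_n, sd_n = config.marker_emission[marker]["negative"]
        z = rng.normal(size=n_cells)
        inten[:, j] = np.where(
            pos_mask, np.exp(mu_p + sd_p * z), np.exp(mu_n + sd_n * z)
        )

    cell_ids = [f"{patient_id}_c{i:05d}" for i in range(n_cells)]
    cells = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "patient_id": patient_id,
            "spot_id": patient_id,  # one spot per patient
            "x_um": xy[:, 0] + radius,
            "y_um": xy[:, 1] + radius,
        }
    )
    for j, marker in enumerate(MARKERS):
        cells[f"{marker}_intensity"] = inten[:, j]
    cells["true_cell_type"] = cell_types
    cells["true_cn"] = cell_cn

    regions = pd.DataFrame(
        {
            "patient_id": patient_id,
            "region_id": np.arange(len(region_cns)),
            "planted_cn": region_cns,
        }
    )
    gt = GroundTruth(
        cell_cn=pd.Series(cell_cn, index=pd.Index(cell_ids, name="cell_id"), name="true_cn"),
        regions=regions,
    )
    return cells, gt


def generate_survival(
    risk_frequencies: pd.Series, config: SyntheticConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw the survival table given per-patient true risk-CN frequencies.

    Time-to-event is exponential with rate
    ``survival_baseline * exp(survival_beta * frequency)`` (months). Each
    patient is independently subject, with probability ``censoring_rate``,
    to an administrative cutoff drawn uniform on (0, max_followup_months);
    ``event`` is 1 when death is observed before any cutoff.
    """
    freqs = risk_frequencies.to_numpy(dtype=float)
    rate = config.survival_baseline * np.exp(config.survival_beta * freqs)
    t_event = rng.exponential(1.0 / rate)
    censored_draw = rng.uniform(size=len(freqs)) < config.censoring_rate
    t_censor = rng.uniform(0.0, config.max_followup_months, size=len(freqs))
    t_censor = np.where(censored_draw, t_censor, np.inf)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    return pd.DataFrame(
        {
            "patient_id": risk_frequencies.index,
            "time_months": time,
            "event": event,
        }
    ).reset_index(drop=True)


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate the full cohort: cell table, survival table, ground truth.

    One spot per patient; all randomness flows from ``config.seed`` through
    spawned child generators, so the output is a pure function of config.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_patients + 1)
    cell_frames: list[pd.DataFrame] = []
    gt_cns: list[pd.Series] = []
    gt_regions: list[pd.DataFrame] = []
    risk_freqs: dict[str, float] = {}

    for i in range(config.n_patients):
        pid = f"P{i + 1:03d}"
        rng = np.random.default_rng(children[i])
        cells, gt = generate_spot(config, pid, rng)
        cell_frames.append(cells)
        gt_cns.append(gt.cell_cn)
        gt_regions.append(gt.regions)
        risk_freqs[pid] = float((gt.cell_cn == config.risk_cn).mean())

    cell_table = pd.concat(cell_frames, ignore_index=True)
    risk = pd.Series(risk_freqs, name="risk_cn_frequency").rename_axis("patient_id")
    surv_rng = np.random.default_rng(children[-1])
    survival = generate_survival(risk, config, surv_rng)
    ground_truth = GroundTruth(
        cell_cn=pd.concat(gt_cns),
        regions=pd.concat(gt_regions, ignore_index=True),
        risk_cn_frequency=risk,
    )
    return cell_table, survival, ground_truth
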