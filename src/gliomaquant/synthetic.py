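"""Synthetic cohorts, stained-core images, cell tracks and spheroid series.

Every downstream stage of the pipeline (IHC scoring, association testing,
track analytics, spheroid migration indexing) is validated against data from
this module, for which the ground truth is known by construction:

* :func:`gen_cohort` emits a clinical cohort whose per-covariate
  cross-tabulations either replay a supplied count table exactly or are
  sampled from it.
* :func:`gen_core_image` renders a circular DAB/haematoxylin-stained tissue
  core with a known stained-pixel fraction and staining intensity, mixing
  the two stains in optical-density space so that stain separation is
  exactly invertible when noise is zero.
* :func:`gen_tracks` simulates persistent random walks with a set speed and
  heading-persistence time.
* :func:`gen_spheroid_series` rasterizes spheroid masks whose migration-front
  and migration-edge radii grow linearly at known rates.

All generators are deterministic given their spec (seeds are mandatory
fields with a documented default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from ._util import DEFAULT_SEED
from .tracks import CellTrack

__all__ = [
    "CohortSpec",
    "CoreImageSpec",
    "PRWParams",
    "SpheroidSimSpec",
    "CoreImage",
    "CellImage",
    "gen_cohort",
    "gen_core_image",
    "gen_cell_image",
    "gen_fluorescence_cell",
    "gen_tracks",
    "gen_spheroid_series",
    "spheroid_rates_for_mi",
    "HEMATOXYLIN_OD_VECTOR",
    "DAB_OD_VECTOR",
    "INTENSITY_DAB_OD",
    "TISSUE_HEMATOXYLIN_OD",
]

# Ruifrok & Johnston reference stain vectors (unit RGB absorbance) for
# haematoxylin and DAB. The IHC scoring module defaults to the same pair, so
# rendering and unmixing are mutually inverse.
HEMATOXYLIN_OD_VECTOR = np.array([0.650, 0.704, 0.286])
HEMATOXYLIN_OD_VECTOR /= np.linalg.norm(HEMATOXYLIN_OD_VECTOR)
DAB_OD_VECTOR = np.array([0.268, 0.570, 0.776])
DAB_OD_VECTOR /= np.linalg.norm(DAB_OD_VECTOR)

#: DAB optical density rendered for each ordinal staining-intensity grade
#: (0 none, 1 weak, 2 medium, 3 strong).
INTENSITY_DAB_OD = (0.0, 0.3, 0.6, 1.0)

#: Haematoxylin counterstain OD applied to every tissue pixel.
TISSUE_HEMATOXYLIN_OD = 0.55


# --------------------------------------------------------------------------
# cohort generator
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Counts for a cohort keyed ``covariate -> (category, class) -> n``.

    ``mode="replay"`` reproduces every per-covariate cross-tabulation
    exactly; ``mode="sample"`` draws a cohort of the same size whose cell
    counts are multinomial with expectation proportional to the given
    counts. ``class_variable`` names the column holding the class labels
    (``expression_class`` for low/high dichotomies, ``tumor_type`` for the
    localization-vs-malignancy table, ...).
    """

    category_counts: Mapping[str, Mapping[tuple[str, str], int]]
    mode: str = "replay"
    class_variable: str = "expression_class"
    seed: int = DEFAULT_SEED

    def class_totals(self) -> dict[str, int]:
        """Per-class cohort sizes, validated to agree across covariates."""
        totals: dict[str, int] | None = None
        for cov, cells in self.category_counts.items():
            t: dict[str, int] = {}
            for (cat, cls), n in cells.items():
                if n < 0:
                    raise ValueError(
                        f"negative count {n} in covariate {cov!r}, "
                        f"cell ({cat!r}, {cls!r})"
                    )
                t[cls] = t.get(cls, 0) + int(n)
            if totals is None:
                totals = t
            elif t != totals:
                raise ValueError(
                    f"class totals for covariate {cov!r} ({t}) disagree with "
                    f"{totals}; replay requires consistent column sums"
                )
        if totals is None:
            raise ValueError("category_counts is empty")
        return totals


def gen_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Emit one record per subject; columns: core_id, covariates, class.

    In replay mode, ``pd.crosstab(df[cov], df[class_variable])`` equals the
    spec counts exactly for every covariate. Category assignment across
    covariates is independent within each class (the marginal tables are all
    the information the source tables carry).
    """
    if spec.mode not in ("replay", "sample"):
        raise ValueError(f"unknown mode {spec.mode!r}")
    totals = spec.class_totals()
    rng = np.random.default_rng(spec.seed)
    classes = list(totals)
    n = sum(totals.values())

    cols: dict[str, list] = {}
    if spec.mode == "replay":
        class_col: list[str] = []
        for cls in classes:
            class_col += [cls] * totals[cls]
        for cov, cells in spec.category_counts.items():
            col: list[str] = []
            for cls in classes:
                cats: list[str] = []
                for (cat, c), cnt in cells.items():
                    if c == cls:
                        cats += [cat] * cnt
                rng.shuffle(cats)
                col += cats
            cols[cov] = col
    else:
        probs = np.array([totals[c] for c in classes], dtype=float)
        class_col = list(rng.choice(classes, size=n, p=probs / probs.sum()))
        for cov, cells in spec.category_counts.items():
            col = [""] * n
            for cls in classes:
                idx = [i for i, c in enumerate(class_col) if c == cls]
                cats = sorted({cat for (cat, c) in cells if c == cls})
                w = np.array([cells.get((cat, cls), 0) for cat in cats], float)
                if w.sum() == 0:
                    w = np.ones_like(w)
                draws = rng.choice(cats, size=len(idx), p=w / w.sum())
                for i, d in zip(idx, draws):
                    col[i] = d
            cols[cov] = col

    df = pd.DataFrame({"core_id": [f"core_{i + 1:04d}" for i in range(n)]})
    for cov, col in cols.items():
        df[cov] = col
    df[spec.class_variable] = class_col
    return df


# --------------------------------------------------------------------------
# stained-core image generator
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CoreImageSpec:
    """Parameters for one synthetic DAB-stained tissue core."""

    intensity_level: int
    stained_fraction: float  # percent of tissue pixels carrying DAB
    core_diameter_px: int = 200
    pixel_size: float = 0.5  # um / px
    noise_sd: float = 0.0  # Gaussian noise SD in OD units
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.intensity_level not in (0, 1, 2, 3):
            raise ValueError(f"intensity_level must be 0..3, got {self.intensity_level}")
        if not 0.0 <= self.stained_fraction <= 100.0:
            raise ValueError(
                f"stained_fraction must be in [0, 100], got {self.stained_fraction}"
            )
        if self.core_diameter_px < 8:
            raise ValueError("core_diameter_px too small to rasterize a core")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class CoreImage:
    """A rendered core plus its ground-truth masks and OD maps."""

    rgb: np.ndarray  # (H, W, 3) uint8
    tissue_mask: np.ndarray  # (H, W) bool
    positive_mask: np.ndarray  # (H, W) bool — pixels rendered with DAB
    dab_od: np.ndarray  # (H, W) float, pre-quantization ground truth
    hematoxylin_od: np.ndarray
    spec: CoreImageSpec


def _render_od(h_od: np.ndarray, d_od: np.ndarray) -> np.ndarray:
    """Beer–Lambert rendering of two stain OD maps to an 8-bit RGB image.

    The inverse convention is OD = −log10((v + 1) / 256), so the forward map
    is v = 256·10^(−OD) − 1 rounded to the nearest admissible level.
    """
    od_rgb = (
        h_od[..., None] * HEMATOXYLIN_OD_VECTOR
        + d_od[..., None] * DAB_OD_VECTOR
    )
    v = 256.0 * np.power(10.0, -od_rgb) - 1.0
    return np.clip(np.rint(v), 0, 255).astype(np.uint8)


def _disc_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def gen_core_image(spec: CoreImageSpec) -> CoreImage:
    """Render a circular tissue core on a white background.

    Tissue pixels carry the haematoxylin counterstain; a random
    ``stained_fraction`` percent of them additionally carry DAB at the OD
    mapped from ``intensity_level``. Gaussian OD noise (``noise_sd``) is
    added inside the tissue on both stain channels.
    """
    d = spec.core_diameter_px
    shape = (d + 4, d + 4)
    center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    tissue = _disc_mask(shape, center, d / 2.0)

    rng = np.random.default_rng(spec.seed)
    idx = np.flatnonzero(tissue)
    n_pos = int(round(spec.stained_fraction / 100.0 * idx.size))
    pos_idx = rng.choice(idx, size=n_pos, replace=False)
    positive = np.zeros(shape, dtype=bool)
    positive.ravel()[pos_idx] = True

    h_od = np.where(tissue, TISSUE_HEMATOXYLIN_OD, 0.0)
    d_od = np.where(positive, INTENSITY_DAB_OD[spec.intensity_level], 0.0)
    if spec.noise_sd > 0:
        h_od = h_od + np.where(tissue, rng.normal(0, spec.noise_sd, shape), 0.0)
        d_od = d_od + np.where(tissue, rng.normal(0, spec.noise_sd, shape), 0.0)
    h_od = np.clip(h_od, 0.0, None)
    d_od = np.clip(d_od, 0.0, None)

    return CoreImage(
        rgb=_render_od(h_od, d_od),
        tissue_mask=tissue,
        positive_mask=positive,
        dab_od=d_od,
        hematoxylin_od=h_od,
        spec=spec,
    )


@dataclass(frozen=True)
class CellImage:
    """A rendered single cell with compartment masks for localization tests."""

    rgb: np.ndarray
    cell_mask: np.ndarray
    membrane_mask: np.ndarray
    cytoplasm_mask: np.ndarray
    pattern: str


def gen_cell_image(
    pattern: str,
    *,
    cell_radius_px: int = 40,
    membrane_width_px: int = 4,
    dab_od: float = 0.8,
    noise_sd: float = 0.0,
    seed: int = DEFAULT_SEED,
) -> CellImage:
    """Render one cell with DAB confined to the membrane ring, the
    cytoplasm, or absent (``pattern`` in {"membranous", "cytoplasmic",
    "negative"}); haematoxylin covers the whole cell."""
    if pattern not in ("membranous", "cytoplasmic", "negative"):
        raise ValueError(f"unknown stain pattern {pattern!r}")
    r = cell_radius_px
    shape = (2 * r + 8, 2 * r + 8)
    center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    cell = _disc_mask(shape, center, r)
    interior = _disc_mask(shape, center, r - membrane_width_px)
    membrane = cell & ~interior

    h_od = np.where(cell, TISSUE_HEMATOXYLIN_OD, 0.0)
    d_od = np.zeros(shape)
    if pattern == "membranous":
        d_od[membrane] = dab_od
    elif pattern == "cytoplasmic":
        d_od[interior] = dab_od
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        h_od = np.clip(h_od + np.where(cell, rng.normal(0, noise_sd, shape), 0), 0, None)
        d_od = np.clip(d_od + np.where(cell, rng.normal(0, noise_sd, shape), 0), 0, None)

    return CellImage(
        rgb=_render_od(h_od, d_od),
        cell_mask=cell,
        membrane_mask=membrane,
        cytoplasm_mask=interior,
        pattern=pattern,
    )


def gen_fluorescence_cell(
    signal_total: float,
    background_mean: float,
    *,
    cell_radius_px: int = 30,
    noise_sd: float = 0.0,
    seed: int = DEFAULT_SEED,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a float fluorescence image: uniform background plus a disc cell
    whose summed above-background signal equals ``signal_total``.

    Returns ``(image, cell_mask)``; the corrected total cell fluorescence of
    the cell is ``signal_total`` by construction.
    """
    r = cell_radius_px
    shape = (2 * r + 20, 2 * r + 20)
    center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    cell = _disc_mask(shape, center, r)
    img = np.full(shape, float(background_mean))
    img[cell] += signal_total / cell.sum()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0, noise_sd, shape)
    return img, cell


# --------------------------------------------------------------------------
# persistent-random-walk track generator
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PRWParams:
    """Persistent random walk: fixed step speed, OU-style heading drift.

    Per frame the heading turns by a Gaussian angle of variance
    ``2·dt/persistence_time``, giving step-to-step directional correlation
    exp(−dt/persistence_time); step length is ``speed·dt``. Units: μm and
    minutes, matching time-lapse tracking exports.
    """

    speed: float  # um / min
    persistence_time: float  # min; math.inf -> straight lines
    dt: float = 1.0  # min between frames
    duration: float = 4320.0  # min (72 h)
    n_cells: int = 50
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.speed < 0:
            raise ValueError("speed must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration < self.dt:
            raise ValueError("duration must be at least one frame interval")
        if self.persistence_time <= 0:
            raise ValueError("persistence_time must be positive (may be inf)")
        if self.n_cells < 1:
            raise ValueError("n_cells must be positive")


def gen_tracks(params: PRWParams) -> list[CellTrack]:
    """Simulate ``n_cells`` independent persistent random walks."""
    rng = np.random.default_rng(params.seed)
    n_steps = int(round(params.duration / params.dt))
    t = np.arange(n_steps + 1) * params.dt
    step = params.speed * params.dt
    if math.isinf(params.persistence_time):
        turn_sd = 0.0
    else:
        turn_sd = math.sqrt(2.0 * params.dt / params.persistence_time)

    theta0 = rng.uniform(0.0, 2.0 * math.pi, size=params.n_cells)
    turns = rng.normal(0.0, turn_sd, size=(params.n_cells, n_steps)) if turn_sd else np.zeros((params.n_cells, n_steps))
    theta = theta0[:, None] + np.cumsum(turns, axis=1)

    dx = step * np.cos(theta)
    dy = step * np.sin(theta)
    x = np.concatenate([np.zeros((params.n_cells, 1)), np.cumsum(dx, axis=1)], axis=1)
    y = np.concatenate([np.zeros((params.n_cells, 1)), np.cumsum(dy, axis=1)], axis=1)

    return [
        CellTrack(cell_id=f"cell_{i + 1:04d}", t=t.copy(), x=x[i], y=y[i])
        for i in range(params.n_cells)
    ]


# --------------------------------------------------------------------------
# spheroid series generator
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SpheroidSimSpec:
    """Linear-outgrowth spheroid: front/edge radii grow at constant μm/h.

    ``scatter_density`` is the occupancy of individually migrating cells in
    the annulus between the dense migration front and the outermost edge;
    it must stay below the front-detection threshold used at measurement.
    """

    core_radius0: float  # um
    front_rate: float  # um / h
    edge_rate: float  # um / h
    timepoints: tuple[float, ...] = (0.0, 24.0, 48.0, 72.0)
    pixel_size: float = 2.0  # um / px
    scatter_density: float = 0.05
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.core_radius0 <= 0:
            raise ValueError("core_radius0 must be positive")
        if not 0 <= self.front_rate <= self.edge_rate:
            raise ValueError("rates must satisfy 0 <= front_rate <= edge_rate")
        if len(self.timepoints) == 0 or self.timepoints[0] != 0:
            raise ValueError("timepoints must start at 0")
        if any(b <= a for a, b in zip(self.timepoints, self.timepoints[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


def spheroid_rates_for_mi(
    core_radius0: float, mi_front: float, mi_edge: float, t_final: float = 72.0
) -> tuple[float, float]:
    """Rates (μm/h) that put the front/edge migration indexes at the given
    values at ``t_final`` hours; use to calibrate simulations to reported
    MI magnitudes."""
    return (mi_front * core_radius0 / t_final, mi_edge * core_radius0 / t_final)


def gen_spheroid_series(spec: SpheroidSimSpec):
    """Rasterize per-timepoint masks of a radially growing spheroid.

    Returns ``(truth, masks)`` where ``truth`` is a
    :class:`~gliomaquant.spheroid.SpheroidSeries` carrying the analytic
    radii and ``masks`` is a list of boolean arrays (one per timepoint):
    a filled disc out to the front radius, sparse single-cell pixels out to
    the edge radius, and a guaranteed pixel at the edge itself.
    """
    from .spheroid import SpheroidFrame, SpheroidSeries  # local: avoid cycle

    rng = np.random.default_rng(spec.seed)
    t_max = spec.timepoints[-1]
    max_edge_px = (spec.core_radius0 + spec.edge_rate * t_max) / spec.pixel_size
    half = int(math.ceil(max_edge_px)) + 6
    shape = (2 * half + 1, 2 * half + 1)
    center = (float(half), float(half))
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    rr = np.hypot(yy - center[0], xx - center[1])

    frames = []
    masks: list[np.ndarray] = []
    for t in spec.timepoints:
        front_um = spec.core_radius0 + spec.front_rate * t
        edge_um = spec.core_radius0 + spec.edge_rate * t
        front_px = front_um / spec.pixel_size
        edge_px = edge_um / spec.pixel_size

        mask = rr <= front_px
        annulus = (rr > front_px) & (rr <= edge_px - 1.0)
        if annulus.any() and spec.scatter_density > 0:
            scatter = rng.random(shape) < spec.scatter_density
            mask |= annulus & scatter
        if edge_px > front_px:
            # guarantee the outermost cells actually sit at the edge radius
            for ang in np.linspace(0.0, 2.0 * math.pi, 8, endpoint=False):
                iy = int(round(center[0] + edge_px * math.sin(ang)))
                ix = int(round(center[1] + edge_px * math.cos(ang)))
                if 0 <= iy < shape[0] and 0 <= ix < shape[1]:
                    mask[iy, ix] = True
        masks.append(mask)
        frames.append(
            SpheroidFrame(
                t=t,
                core_radius=spec.core_radius0,
                front_radius=front_um,
                edge_radius=edge_um,
            )
        )

    truth = SpheroidSeries(spheroid_id="synthetic", condition="", frames=frames)
    return truth, masks
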