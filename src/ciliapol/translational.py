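"""Translational planar-cell-polarity quantification.

Each multiciliated cell is represented by its apical outline polygon
(pixel coordinates, image convention: origin top-left, y increasing
downwards) and by the centroid of its basal-body patch.  The per-cell
polarity vector points from the area-weighted polygon centroid to the
basal-body centroid.  Angles are reported in the mathematical convention
(counter-clockwise from +x) after flipping the y axis, i.e.
``angle = atan2(-dy, dx) mod 360``; magnitudes are in micrometres.

The summary statistics mirror how this measurement is reported in the
ependyma literature: per-cell deviations from the mean vector direction,
the fraction of cells whose deviation stays within a bound (45 degrees by
default), and apical-area statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .circular import AngularSample, circular_mean_resultant, wrap_difference
from .errors import (
    DegeneratePolygonError,
    InvalidParameterError,
    SelfIntersectingPolygonError,
)

__all__ = [
    "CellRecord",
    "CellApicalMap",
    "PolarityVector",
    "TranslationalSummary",
    "polygon_centroid",
    "apical_area",
    "translational_vectors",
    "summarize_translational",
    "analyze_map",
]

logger = logging.getLogger(__name__)

#: vectors shorter than this (micrometres) are flagged degenerate
DEFAULT_EPSILON_UM = 0.1

#: deviation bound defining the "polarised" fraction, degrees
DEFAULT_BOUND_DEG = 45.0

#: default number of histogram bins over the signed deviation range (15 deg wide)
DEFAULT_N_BINS = 24

#: minimum cells per image expected for a well-powered summary
DEFAULT_MIN_CELLS = 30


@dataclass
class CellRecord:
    cell_id: str
    polygon: np.ndarray  # (n_vertices, 2) pixel coordinates
    bb_centroid: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.polygon = np.asarray(self.polygon, dtype=float)
        if self.polygon.ndim != 2 or self.polygon.shape[1] != 2 or len(self.polygon) < 3:
            raise InvalidParameterError(
                f"cell {self.cell_id!r}: polygon needs >= 3 (x, y) vertices"
            )


@dataclass
class CellApicalMap:
    """One image's apical surface: cell outlines plus basal-body centroids."""

    image_id: str
    cells: list[CellRecord]
    pixel_size: float  # micrometres per pixel

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or not math.isfinite(self.pixel_size):
            raise InvalidParameterError("pixel_size must be positive and finite")
        ids = [c.cell_id for c in self.cells]
        if len(set(ids)) != len(ids):
            raise InvalidParameterError(f"duplicate cell_ids in image {self.image_id!r}")

    @property
    def n_cells(self) -> int:
        return len(self.cells)


@dataclass
class PolarityVector:
    cell_id: str
    angle_deg: float  # [0, 360), CCW from +x after y flip
    magnitude_um: float
    degenerate: bool


@dataclass
class TranslationalSummary:
    deviations: AngularSample  # absolute deviations from reference, [0, 180]
    fraction_within_bound: float
    bound_deg: float
    reference_angle_deg: float
    mean_area_um2: float
    sem_area_um2: float
    n_cells: int
    n_degenerate: int
    n_missing_bb: int
    histogram_edges_deg: np.ndarray  # signed deviations, [-180, 180)
    histogram_counts: np.ndarray
    warnings: list[str] = field(default_factory=list)

    @property
    def fraction_within_45(self) -> float:
        # convenience accessor for the conventional 45-degree bound
        if self.bound_deg == 45.0:
            return self.fraction_within_bound
        dev = self.deviations.angles_deg
        return float(np.mean(dev <= 45.0))


# ---------------------------------------------------------------------------
# polygon geometry
# ---------------------------------------------------------------------------


def _shoelace_signed_area(polygon: np.ndarray) -> float:
    x, y = polygon[:, 0], polygon[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _segments_properly_intersect(p1, p2, q1, q2) -> bool:
    """Proper crossing test for two open segments (shared endpoints allowed)."""

    def orient(a, b, c):
        return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])

    d1, d2 = orient(q1, q2, p1), orient(q1, q2, p2)
    d3, d4 = orient(p1, p2, q1), orient(p1, p2, q2)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))


def _check_simple(polygon: np.ndarray) -> None:
    """O(n^2) edge-crossing check; polygons here have a handful of vertices."""
    n = len(polygon)
    edges = [(polygon[i], polygon[(i + 1) % n]) for i in range(n)]
    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # adjacent through the wrap-around vertex
            if _segments_properly_intersect(*edges[i], *edges[j]):
                raise SelfIntersectingPolygonError(
                    f"polygon edges {i} and {j} cross; outline is not simple"
                )


def polygon_centroid(polygon) -> tuple[float, float]:
    """Area-weighted centroid of a simple polygon (shoelace formula)."""
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
        raise InvalidParameterError("polygon needs >= 3 (x, y) vertices")
    a = _shoelace_signed_area(poly)
    if abs(a) < 1e-12:
        raise DegeneratePolygonError("polygon has (numerically) zero area")
    x, y = poly[:, 0], poly[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    cx = float(np.sum((x + xn) * cross) / (6.0 * a))
    cy = float(np.sum((y + yn) * cross) / (6.0 * a))
    return cx, cy


def apical_area(polygon, pixel_size: float) -> float:
    """Polygon area in square micrometres (shoelace area times pixel_size^2)."""
    if pixel_size <= 0:
        raise InvalidParameterError("pixel_size must be positive")
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
        raise InvalidParameterError("polygon needs >= 3 (x, y) vertices")
    _check_simple(poly)
    a = abs(_shoelace_signed_area(poly))
    if a < 1e-12:
        raise DegeneratePolygonError("polygon has (numerically) zero area")
    return a * pixel_size * pixel_size


# ---------------------------------------------------------------------------
# vectors and summaries
# ---------------------------------------------------------------------------


def translational_vectors(
    cell_map: CellApicalMap, epsilon_um: float = DEFAULT_EPSILON_UM
) -> list[PolarityVector]:
    """Per-cell vectors from apical centre to basal-body centroid.

    Cells lacking a basal-body centroid are skipped (and counted in the
    log); vectors shorter than ``epsilon_um`` are flagged degenerate.
    """
    if cell_map.n_cells == 0:
        raise InvalidParameterError(f"image {cell_map.image_id!r}: empty cell map")
    vectors: list[PolarityVector] = []
    n_missing = 0
    for cell in cell_map.cells:
        if cell.bb_centroid is None:
            n_missing += 1
            continue
        cx, cy = polygon_centroid(cell.polygon)
        dx = cell.bb_centroid[0] - cx
        dy = cell.bb_centroid[1] - cy
        magnitude = math.hypot(dx, dy) * cell_map.pixel_size
        degenerate = magnitude < epsilon_um
        # flip y so angles follow the math convention despite y-down images
        angle = math.degrees(math.atan2(-dy, dx)) % 360.0 if not degenerate else 0.0
        vectors.append(
            PolarityVector(cell.cell_id, angle, magnitude, degenerate)
        )
    if n_missing:
        logger.info(
            "image %s: skipped %d cells without basal-body centroid",
            cell_map.image_id, n_missing,
        )
    return vectors


def summarize_translational(
    vectors: list[PolarityVector],
    reference: str = "per_image_mean",
    fixed_angle_deg: float | None = None,
    bound_deg: float = DEFAULT_BOUND_DEG,
    n_bins: int = DEFAULT_N_BINS,
    areas_um2: np.ndarray | None = None,
    n_missing_bb: int = 0,
    min_cells: int = DEFAULT_MIN_CELLS,
) -> TranslationalSummary:
    """Deviation statistics of the polarity vectors around a reference.

    ``reference`` is either ``"per_image_mean"`` (circular mean of the
    non-degenerate vector angles) or ``"fixed_angle"`` (an externally
    supplied direction, e.g. a known ground-truth mean).  Deviations are
    absolute wrapped differences in [0, 180]; the reported fraction is
    the share of deviations <= ``bound_deg``.  Degenerate vectors are
    excluded and counted.
    """
    angles = np.array([v.angle_deg for v in vectors if not v.degenerate])
    n_degenerate = sum(v.degenerate for v in vectors)
    if angles.size == 0:
        raise InvalidParameterError("all vectors are degenerate; no directions to summarise")

    if reference == "per_image_mean":
        ref, _ = circular_mean_resultant(AngularSample(angles))
        if math.isnan(ref):
            ref = 0.0  # balanced sample: reference arbitrary, deviations still defined
    elif reference == "fixed_angle":
        if fixed_angle_deg is None:
            raise InvalidParameterError("fixed_angle reference requires fixed_angle_deg")
        ref = float(fixed_angle_deg)
    else:
        raise InvalidParameterError(f"unknown reference {reference!r}")

    signed = wrap_difference(angles, ref, "directional_360")
    signed = np.atleast_1d(signed)
    deviations = np.abs(signed)
    fraction = float(np.mean(deviations <= bound_deg))
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    counts, _ = np.histogram(signed, bins=edges)

    warnings: list[str] = []
    n_cells = int(angles.size)
    if n_cells < min_cells:
        warnings.append(
            f"only {n_cells} usable cells; fewer than the configured minimum of {min_cells}"
        )

    if areas_um2 is not None and len(areas_um2) > 0:
        areas = np.asarray(areas_um2, dtype=float)
        mean_area = float(np.mean(areas))
        sem_area = float(np.std(areas, ddof=1) / math.sqrt(len(areas))) if len(areas) > 1 else 0.0
    else:
        mean_area = float("nan")
        sem_area = float("nan")

    return TranslationalSummary(
        deviations=AngularSample(deviations, "directional_360", label="deviations"),
        fraction_within_bound=fraction,
        bound_deg=bound_deg,
        reference_angle_deg=float(ref % 360.0),
        mean_area_um2=mean_area,
        sem_area_um2=sem_area,
        n_cells=n_cells,
        n_degenerate=int(n_degenerate),
        n_missing_bb=int(n_missing_bb),
        histogram_edges_deg=edges,
        histogram_counts=counts,
        warnings=warnings,
    )


def analyze_map(
    cell_map: CellApicalMap,
    reference: str = "per_image_mean",
    fixed_angle_deg: float | None = None,
    bound_deg: float = DEFAULT_BOUND_DEG,
    epsilon_um: float = DEFAULT_EPSILON_UM,
    n_bins: int = DEFAULT_N_BINS,
    min_cells: int = DEFAULT_MIN_CELLS,
) -> tuple[list[PolarityVector], TranslationalSummary]:
    """Full translational-polarity analysis of one image's map."""
    vectors = translational_vectors(cell_map, epsilon_um=epsilon_um)
    areas = np.array(
        [apical_area(c.polygon, cell_map.pixel_size) for c in cell_map.cells]
    )
    n_missing = sum(c.bb_centroid is None for c in cell_map.cells)
    summary = summarize_translational(
        vectors,
        reference=reference,
        fixed_angle_deg=fixed_angle_deg,
        bound_deg=bound_deg,
        n_bins=n_bins,
        areas_um2=areas,
        n_missing_bb=n_missing,
        min_cells=min_cells,
    )
    return vectors, summary


def plot_polar_histogram(summary: TranslationalSummary, path) -> None:
    """Save a rose plot of the signed deviation histogram."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    edges = np.deg2rad(summary.histogram_edges_deg)
    widths = np.diff(edges)
    centers = edges[:-1] + widths / 2.0
    fig = plt.figure(figsize=(4, 4))
    ax = fig.add_subplot(projection="polar")
    ax.bar(centers, summary.histogram_counts, width=widths, bottom=0.0,
           color="#3572b0", edgecolor="white", alpha=0.9)
    ax.set_theta_zero_location("E")
    ax.set_title("basal-body vector deviation from mean")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
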