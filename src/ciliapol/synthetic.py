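"""Synthetic inputs with recorded ground truth.

Every input the analysis pipeline consumes can be generated here so that
all downstream stages are testable end to end without microscopy or
expression data:

* apical-surface cell maps with basal-body centroids displaced along
  von Mises-distributed angles (translational polarity),
* per-image cilium orientation fields drawn from a von Mises
  distribution (rotational polarity),
* time-lapse stacks whose intensity along a known line ROI oscillates
  sinusoidally at a known beat frequency plus Gaussian noise,
* population x gene expression-profile sets with a designed shared
  signature-block structure, hence a known similarity ordering.

All generators take an explicit seed and are bit-for-bit reproducible;
per-cell/per-image randomness comes from sub-streams spawned
deterministically from that seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .beat import ImageStack, LineROI
from .circular import AngularSample
from .errors import AliasingError, InvalidParameterError
from .similarity import ExpressionProfileSet
from .translational import CellApicalMap, CellRecord, polygon_centroid, _shoelace_signed_area

__all__ = [
    "GroundTruth",
    "gen_apical_map",
    "gen_orientation_field",
    "gen_beat_recording",
    "gen_population_profiles",
]

#: vertex jitter is capped at this fraction of the cell side so that the
#: perturbed grid quads stay simple (non-self-intersecting)
MAX_JITTER_FRAC = 0.25

#: uniform vertex jitter of half-width j gives an area CV of about
#: sqrt(2/3) * j / side; this constant inverts that relation
_JITTER_PER_CV = math.sqrt(3.0 / 2.0)


@dataclass
class GroundTruth:
    """What the generator actually drew, for parameter-recovery tests."""

    kind: str  # polarity_map | orientation_field | beat_recording | profile_set
    parameters: dict
    per_item: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {"kind": self.kind, "parameters": self.parameters, "per_item": self.per_item},
                fh, indent=2, sort_keys=True,
            )

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(kind=d["kind"], parameters=d["parameters"], per_item=d["per_item"])


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise InvalidParameterError(msg)


# ---------------------------------------------------------------------------
# apical map (translational polarity substrate)
# ---------------------------------------------------------------------------


def gen_apical_map(
    n_cells: int,
    mean_area: float = 60.0,
    area_cv: float = 0.15,
    mu: float = 0.0,
    kappa: float = 4.0,
    displacement_frac: float = 0.3,
    pixel_size: float = 0.2,
    seed: int = 0,
    image_id: str = "synthetic",
) -> tuple[CellApicalMap, GroundTruth]:
    """Perturbed-grid tessellation with von Mises basal-body displacements.

    Cells are convex quadrilaterals from a rectangular grid whose
    interior vertices are jittered (boundary vertices stay fixed, so the
    union of a full grid is exactly the bounding rectangle).  Each
    cell's basal-body centroid is displaced from the polygon centroid by
    ``displacement_frac * sqrt(area/pi)`` along an angle drawn from von
    Mises(mu, kappa); the drawn angle (math convention, degrees) is
    recorded per cell in the ground truth.

    ``mean_area`` is in square micrometres, ``pixel_size`` in
    micrometres per pixel, ``area_cv`` the approximate coefficient of
    variation of cell areas realised through vertex jitter.
    """
    _require(n_cells >= 1, "n_cells must be >= 1")
    _require(mean_area > 0, "mean_area must be positive")
    _require(area_cv >= 0, "area_cv must be >= 0")
    _require(kappa >= 0, "kappa must be >= 0")
    _require(0.0 <= displacement_frac < 1.0, "displacement_frac must be in [0, 1)")
    _require(pixel_size > 0, "pixel_size must be positive")

    side_px = math.sqrt(mean_area) / pixel_size
    n_cols = math.ceil(math.sqrt(n_cells))
    n_rows = math.ceil(n_cells / n_cols)
    jitter_frac = min(MAX_JITTER_FRAC, _JITTER_PER_CV * area_cv)
    jitter = jitter_frac * side_px

    geom_seed, angle_seed = np.random.SeedSequence(seed).spawn(2)
    geom_rng = np.random.default_rng(geom_seed)
    angle_streams = angle_seed.spawn(n_cells)

    # grid vertices, jitter only the interior ones
    gx, gy = np.meshgrid(
        np.arange(n_cols + 1) * side_px, np.arange(n_rows + 1) * side_px
    )
    vx = gx.copy()
    vy = gy.copy()
    if jitter > 0 and n_rows > 1:
        vy[1:-1, :] += geom_rng.uniform(-jitter, jitter, size=vy[1:-1, :].shape)
    if jitter > 0 and n_cols > 1:
        vx[:, 1:-1] += geom_rng.uniform(-jitter, jitter, size=vx[:, 1:-1].shape)

    cells: list[CellRecord] = []
    truths: list[dict] = []
    idx = 0
    for r in range(n_rows):
        for c in range(n_cols):
            if idx >= n_cells:
                break
            poly = np.array(
                [
                    (vx[r, c], vy[r, c]),
                    (vx[r, c + 1], vy[r, c + 1]),
                    (vx[r + 1, c + 1], vy[r + 1, c + 1]),
                    (vx[r + 1, c], vy[r + 1, c]),
                ]
            )
            cx, cy = polygon_centroid(poly)
            area_px = abs(_shoelace_signed_area(poly))
            radius_px = math.sqrt(area_px / math.pi)
            cell_rng = np.random.default_rng(angle_streams[idx])
            theta = float(cell_rng.vonmises(math.radians(mu), kappa))
            d = displacement_frac * radius_px
            # y is flipped so that the recovered math-convention angle equals theta
            bb = (cx + d * math.cos(theta), cy - d * math.sin(theta))
            cell_id = f"cell{idx:04d}"
            cells.append(CellRecord(cell_id=cell_id, polygon=poly, bb_centroid=bb))
            truths.append(
                {"cell_id": cell_id, "true_angle_deg": math.degrees(theta) % 360.0}
            )
            idx += 1

    cell_map = CellApicalMap(image_id=image_id, cells=cells, pixel_size=pixel_size)
    truth = GroundTruth(
        kind="polarity_map",
        parameters={
            "n_cells": n_cells, "mean_area": mean_area, "area_cv": area_cv,
            "mu_deg": mu, "kappa": kappa, "displacement_frac": displacement_frac,
            "pixel_size": pixel_size, "seed": seed,
        },
        per_item=truths,
    )
    return cell_map, truth


# ---------------------------------------------------------------------------
# orientation fields (rotational polarity substrate)
# ---------------------------------------------------------------------------


def gen_orientation_field(
    n_images: int = 10,
    cilia_per_image: int = 12,
    mu: float = 0.0,
    kappa: float = 4.0,
    seed: int = 0,
) -> tuple[list[AngularSample], GroundTruth]:
    """Per-image central-pair angle lists drawn from von Mises(mu, kappa).

    Angles are directional (360-degree period), degrees in [0, 360).
    """
    _require(n_images >= 1, "n_images must be >= 1")
    _require(cilia_per_image >= 1, "cilia_per_image must be >= 1")
    _require(kappa >= 0, "kappa must be >= 0")

    streams = np.random.SeedSequence(seed).spawn(n_images)
    samples: list[AngularSample] = []
    per_item: list[dict] = []
    for i, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        angles = np.degrees(rng.vonmises(math.radians(mu), kappa, size=cilia_per_image))
        sample = AngularSample(angles, "directional_360", label=f"img{i:03d}")
        samples.append(sample)
        per_item.append({"image_id": sample.label, "n_cilia": cilia_per_image})
    truth = GroundTruth(
        kind="orientation_field",
        parameters={
            "n_images": n_images, "cilia_per_image": cilia_per_image,
            "mu_deg": mu, "kappa": kappa, "seed": seed,
        },
        per_item=per_item,
    )
    return samples, truth


# ---------------------------------------------------------------------------
# beat recordings
# ---------------------------------------------------------------------------


def gen_beat_recording(
    freq_hz: float = 9.0,
    fps: float = 60.0,
    duration_s: float = 2.0,
    line_len: int = 32,
    amplitude: float = 100.0,
    noise_sd: float = 0.0,
    offset: float = 120.0,
    seed: int = 0,
) -> tuple[ImageStack, GroundTruth]:
    """Time-lapse stack whose intensity along a known line beats at ``freq_hz``.

    A 3-pixel-high band centred on the ROI line carries
    ``offset + amplitude * sin(2 pi f t)``; the rest of the frame is flat
    at ``offset``.  Gaussian noise of ``noise_sd`` is added everywhere.
    Frequencies at or above Nyquist (fps/2) raise :class:`AliasingError`.
    The ground truth records the frequency and the ROI endpoints.
    """
    _require(freq_hz > 0, "freq_hz must be positive")
    _require(fps > 0, "fps must be positive")
    _require(duration_s > 0, "duration_s must be positive")
    _require(line_len >= 2, "line_len must be >= 2")
    _require(amplitude > 0, "amplitude must be positive")
    _require(noise_sd >= 0, "noise_sd must be >= 0")
    if freq_hz >= fps / 2.0:
        raise AliasingError(
            f"freq_hz={freq_hz} is at or above the Nyquist limit fps/2={fps / 2.0}"
        )

    n_frames = int(round(fps * duration_s))
    _require(n_frames >= 2, "duration too short for the given fps")
    margin = 4
    height = 16
    width = line_len + 2 * margin
    y_line = height // 2
    t = np.arange(n_frames) / fps
    beat = amplitude * np.sin(2.0 * math.pi * freq_hz * t)  # (T,)

    frames = np.full((n_frames, height, width), offset, dtype=float)
    frames[:, y_line - 1 : y_line + 2, margin : margin + line_len] += beat[:, None, None]
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        frames += rng.normal(0.0, noise_sd, size=frames.shape)

    roi = LineROI(x0=margin, y0=y_line, x1=margin + line_len - 1, y1=y_line)
    stack = ImageStack(frames=frames, fps=fps, pixel_size=1.0)
    truth = GroundTruth(
        kind="beat_recording",
        parameters={
            "freq_hz": freq_hz, "fps": fps, "duration_s": duration_s,
            "line_len": line_len, "amplitude": amplitude, "noise_sd": noise_sd,
            "offset": offset, "seed": seed,
        },
        per_item=[{
            "roi": {"x0": roi.x0, "y0": roi.y0, "x1": roi.x1, "y1": roi.y1,
                    "roi_id": roi.roi_id},
            "trace": list(offset + beat),
        }],
    )
    return stack, truth


# ---------------------------------------------------------------------------
# expression-profile sets
# ---------------------------------------------------------------------------


def gen_population_profiles(
    block_design: dict[str, str],
    n_genes: int = 500,
    block_size: int = 40,
    effect: float = 5.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    blocks: dict[str, list[int]] | None = None,
) -> tuple[ExpressionProfileSet, GroundTruth]:
    """Profile set with a designed shared-signature block structure.

    ``block_design`` maps each population name to the signature block it
    carries.  Each block owns a disjoint set of ``block_size`` genes
    (contiguous ranges by default, or explicit index lists via
    ``blocks``); a population's vector is ``effect`` on its block's
    genes plus N(0, noise_sd) everywhere.  Populations sharing a block
    are the designed high-correlation pairs, recorded in the truth.
    """
    _require(len(block_design) >= 2, "need >= 2 populations")
    _require(effect > 0, "effect must be positive")
    _require(noise_sd >= 0, "noise_sd must be >= 0")
    block_names = sorted(set(block_design.values()))
    if blocks is None:
        _require(
            n_genes >= len(block_names) * block_size,
            f"n_genes must be >= n_blocks * block_size = {len(block_names) * block_size}",
        )
        blocks = {
            name: list(range(i * block_size, (i + 1) * block_size))
            for i, name in enumerate(block_names)
        }
    else:
        _require(set(blocks) >= set(block_names), "blocks must cover every designed block")
        seen: set[int] = set()
        for name in block_names:
            idx = set(blocks[name])
            _require(max(idx, default=-1) < n_genes and min(idx, default=0) >= 0,
                     f"block {name!r} has gene indices outside [0, n_genes)")
            if seen & idx:
                raise InvalidParameterError(
                    f"block {name!r} overlaps another block's genes"
                )
            seen |= idx

    populations = list(block_design)
    genes = [f"g{k:05d}" for k in range(n_genes)]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    values = rng.normal(0.0, noise_sd, size=(len(populations), n_genes)) if noise_sd > 0 \
        else np.zeros((len(populations), n_genes))
    for i, pop in enumerate(populations):
        values[i, list(blocks[block_design[pop]])] += effect

    pset = ExpressionProfileSet(pd.DataFrame(values, index=populations, columns=genes))
    shared_pairs = sorted(
        tuple(sorted((a, b)))
        for i, a in enumerate(populations)
        for b in populations[i + 1:]
        if block_design[a] == block_design[b]
    )
    truth = GroundTruth(
        kind="profile_set",
        parameters={
            "n_pop": len(populations), "n_genes": n_genes, "block_size": block_size,
            "effect": effect, "noise_sd": noise_sd, "seed": seed,
            "block_design": dict(block_design),
        },
        per_item=[{"shared_block_pairs": [list(p) for p in shared_pairs]}],
    )
    return pset, truth
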