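"""File formats.

All tables are UTF-8 comma-separated with a header row; angles are
always stored in degrees.  TIFF stacks carry a JSON sidecar with units
stated explicitly (``fps`` in Hz, ``pixel_size`` in micrometres per
pixel); a missing required field is an error, never a silent default.

Cell-map schema (one row per cell)::

    cell_id,polygon,bb_x,bb_y
    cell0001,"0.0,0.0;38.7,0.0;38.7,38.7;0.0,38.7",21.3,17.9

The ``polygon`` column is a semicolon-separated list of ``x,y`` vertex
pairs in pixels; ``bb_x``/``bb_y`` may be empty when no basal-body
centroid was assigned.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .beat import ImageStack, LineROI
from .circular import AngularSample
from .errors import MissingMetadataError, ParseError
from .similarity import ExpressionProfileSet, SimilarityResult
from .translational import CellApicalMap, CellRecord

__all__ = [
    "read_cell_map", "write_cell_map",
    "read_angles", "write_angles",
    "read_stack", "write_stack",
    "read_rois", "write_rois",
    "read_profiles", "write_profiles",
    "write_similarity",
]


def _format_polygon(polygon: np.ndarray) -> str:
    return ";".join(f"{x:.10g},{y:.10g}" for x, y in polygon)


def _parse_polygon(text: str, row: int, errors: list[str]) -> np.ndarray | None:
    try:
        pts = [tuple(float(v) for v in pair.split(",")) for pair in str(text).split(";")]
        if any(len(p) != 2 for p in pts):
            raise ValueError("vertex is not an x,y pair")
    except ValueError as exc:
        errors.append(f"row {row}: malformed polygon field ({exc})")
        return None
    if len(pts) < 3:
        errors.append(f"row {row}: polygon has {len(pts)} vertices, need >= 3")
        return None
    return np.asarray(pts, dtype=float)


def write_cell_map(cell_map: CellApicalMap, path) -> None:
    rows = []
    for cell in cell_map.cells:
        bb = cell.bb_centroid
        rows.append({
            "cell_id": cell.cell_id,
            "polygon": _format_polygon(cell.polygon),
            "bb_x": "" if bb is None else f"{bb[0]:.10g}",
            "bb_y": "" if bb is None else f"{bb[1]:.10g}",
        })
    pd.DataFrame(rows).to_csv(path, index=False)
    sidecar = {"image_id": cell_map.image_id, "pixel_size_um_per_px": cell_map.pixel_size}
    Path(path).with_suffix(".json").write_text(json.dumps(sidecar, sort_keys=True))


def read_cell_map(path, pixel_size: float | None = None, image_id: str | None = None) -> CellApicalMap:
    """Parse a cell-map table; malformed rows are reported with line numbers.

    ``pixel_size`` may be given explicitly or read from the JSON sidecar
    written by :func:`write_cell_map`; having neither is an error.
    """
    df = pd.read_csv(path, dtype={"cell_id": str})
    required = {"cell_id", "polygon", "bb_x", "bb_y"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(required - set(df.columns))}")

    sidecar_path = Path(path).with_suffix(".json")
    if pixel_size is None or image_id is None:
        sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
        if pixel_size is None:
            pixel_size = sidecar.get("pixel_size_um_per_px")
        if image_id is None:
            image_id = sidecar.get("image_id", Path(path).stem)
    if pixel_size is None:
        raise MissingMetadataError(
            f"{path}: pixel_size not given and no sidecar {sidecar_path.name}"
        )

    errors: list[str] = []
    cells: list[CellRecord] = []
    for i, rec in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        poly = _parse_polygon(rec.polygon, i, errors)
        if poly is None:
            continue
        bb = None
        has_x, has_y = pd.notna(rec.bb_x) and rec.bb_x != "", pd.notna(rec.bb_y) and rec.bb_y != ""
        if has_x != has_y:
            errors.append(f"row {i}: bb_x/bb_y must be both present or both empty")
            continue
        if has_x:
            try:
                bb = (float(rec.bb_x), float(rec.bb_y))
            except ValueError:
                errors.append(f"row {i}: bb_x/bb_y not numeric")
                continue
        cells.append(CellRecord(cell_id=str(rec.cell_id), polygon=poly, bb_centroid=bb))
    if errors:
        raise ParseError(f"{path}: " + "; ".join(errors))
    return CellApicalMap(image_id=image_id, cells=cells, pixel_size=float(pixel_size))


def write_angles(samples: list[AngularSample], path) -> None:
    rows = [
        {"image_id": s.label, "angle_deg": a}
        for s in samples
        for a in s.angles_deg
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_angles(path, periodicity: str = "directional_360") -> list[AngularSample]:
    df = pd.read_csv(path)
    if not {"image_id", "angle_deg"}.issubset(df.columns):
        raise ParseError(f"{path}: need columns image_id, angle_deg")
    bad = df.index[~np.isfinite(pd.to_numeric(df["angle_deg"], errors="coerce"))]
    if len(bad):
        raise ParseError(f"{path}: non-numeric angle_deg at rows {[i + 2 for i in bad]}")
    return [
        AngularSample(grp["angle_deg"].to_numpy(dtype=float), periodicity, label=str(img))
        for img, grp in df.groupby("image_id", sort=True)
    ]


def write_stack(stack: ImageStack, path, rois: list[LineROI] | None = None) -> None:
    """Multi-page TIFF (float32) plus a JSON sidecar with fps and pixel size."""
    tifffile.imwrite(path, stack.frames.astype(np.float32), photometric="minisblack")
    sidecar = {
        "fps_hz": stack.fps,
        "pixel_size_um_per_px": stack.pixel_size,
    }
    if rois is not None:
        sidecar["rois"] = [
            {"roi_id": r.roi_id, "x0": r.x0, "y0": r.y0, "x1": r.x1, "y1": r.y1}
            for r in rois
        ]
    Path(path).with_suffix(".json").write_text(json.dumps(sidecar, sort_keys=True))


def read_stack(path) -> tuple[ImageStack, list[LineROI]]:
    sidecar_path = Path(path).with_suffix(".json")
    if not sidecar_path.exists():
        raise MissingMetadataError(f"{path}: sidecar {sidecar_path.name} not found")
    sidecar = json.loads(sidecar_path.read_text())
    if "fps_hz" not in sidecar:
        raise MissingMetadataError(f"{sidecar_path}: required field fps_hz missing")
    frames = tifffile.imread(path)
    rois = [
        LineROI(x0=r["x0"], y0=r["y0"], x1=r["x1"], y1=r["y1"], roi_id=r.get("roi_id", f"roi{i}"))
        for i, r in enumerate(sidecar.get("rois", []))
    ]
    stack = ImageStack(
        frames=frames,
        fps=float(sidecar["fps_hz"]),
        pixel_size=float(sidecar.get("pixel_size_um_per_px", 1.0)),
    )
    return stack, rois


def write_rois(rois: list[LineROI], path, image_id: str = "") -> None:
    pd.DataFrame([
        {"image_id": image_id, "roi_id": r.roi_id,
         "x0": r.x0, "y0": r.y0, "x1": r.x1, "y1": r.y1}
        for r in rois
    ]).to_csv(path, index=False)


def read_rois(path) -> list[LineROI]:
    df = pd.read_csv(path)
    needed = {"x0", "y0", "x1", "y1"}
    if not needed.issubset(df.columns):
        raise ParseError(f"{path}: need columns {sorted(needed)}")
    return [
        LineROI(x0=float(r.x0), y0=float(r.y0), x1=float(r.x1), y1=float(r.y1),
                roi_id=str(getattr(r, "roi_id", f"roi{i}")))
        for i, r in enumerate(df.itertuples(index=False))
    ]


def write_profiles(pset: ExpressionProfileSet, path) -> None:
    """Genes as rows, populations as columns, first column the gene symbol."""
    df = pset.values.T.copy()
    df.insert(0, "gene", df.index)
    df.to_csv(path, index=False)


def read_profiles(path, scale: str = "log2fc") -> ExpressionProfileSet:
    df = pd.read_csv(path)
    if df.shape[1] < 2 or df.columns[0] != "gene":
        raise ParseError(f"{path}: first column must be 'gene', then one column per population")
    values = df.set_index("gene").T
    values.columns.name = None
    values.index.name = None
    return ExpressionProfileSet(values=values.astype(float), scale=scale)


def write_similarity(result: SimilarityResult, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.distance.to_csv(outdir / "distance.csv")
    result.correlation.to_csv(outdir / "correlation.csv")
    (outdir / "cluster_order.json").write_text(json.dumps({
        "cluster_order": result.cluster_order,
        "n_genes_used": result.n_genes_used,
        "excluded": result.excluded,
    }, indent=2, sort_keys=True))
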