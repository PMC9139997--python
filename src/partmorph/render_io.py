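"""Reading and writing artifact formats: JSON shape specs, SVG/PNG stimuli,
and CSV trial/response tables.

SVG is the canonical stimulus format (resolution independent, filled path,
no stroke); PNG is derived by rasterisation.  CSV files are UTF-8,
comma-separated, with a header row and '.' decimals.  All outputs are
deterministic given seed and config: no timestamps enter data files.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from .skeleton_core import (
    GrowthParams,
    InvalidParameterError,
    Part,
    Shape,
    compose_shape,
    make_main_body,
)

__all__ = [
    "RenderConfig",
    "SchemaVersionError",
    "ResponseValidationError",
    "serialize_shape",
    "load_shape",
    "save_shape_json",
    "load_shape_json",
    "shape_to_svg",
    "shape_to_png",
    "write_trials",
    "read_responses",
]

SCHEMA_VERSION = 1

_SHAPE_FIELDS = {"schema_version", "body", "parts", "meta"}
_PART_FIELDS = {
    "local_joints",
    "growth",
    "order",
    "parent",
    "attach_t",
    "side",
    "width_scale",
    "pair_id",
    "part_id",
}


class SchemaVersionError(ValueError):
    """The shape document was written by an incompatible schema version."""


class ResponseValidationError(ValueError):
    """One or more response rows failed validation; row indices are listed."""

    def __init__(self, errors: list[tuple[int, str]]):
        self.errors = errors
        msg = "; ".join(f"row {i}: {m}" for i, m in errors[:10])
        if len(errors) > 10:
            msg += f" (and {len(errors) - 10} more)"
        super().__init__(msg)


@dataclass(frozen=True)
class RenderConfig:
    canvas_px: int = 512
    margin: float = 0.08
    fill: str = "#1a1a1a"
    background: str = "#ffffff"
    dpi: int = 96
    skeleton_overlay: bool = False

    def __post_init__(self) -> None:
        if self.canvas_px < 64:
            raise InvalidParameterError("canvas_px must be >= 64")
        if not (0.0 <= self.margin < 0.4):
            raise InvalidParameterError("margin must lie in [0, 0.4)")


# --------------------------------------------------------------------------
# JSON shape specs

def serialize_shape(shape: Shape) -> dict:
    """Serialise a shape to a JSON-ready document (lossless round trip)."""
    return {
        "schema_version": SCHEMA_VERSION,
        "body": dict(shape.body.params),
        "parts": [
            {
                "local_joints": np.asarray(p.local_joints).tolist(),
                "growth": asdict(p.growth),
                "order": p.order,
                "parent": p.parent,
                "attach_t": p.attach_t,
                "side": p.side,
                "width_scale": p.width_scale,
                "pair_id": p.pair_id,
                "part_id": p.part_id,
            }
            for p in shape.parts
        ],
        "meta": _jsonable(shape.meta),
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def load_shape(doc: dict) -> Shape:
    """Rebuild a shape from its JSON document.

    Unknown extra fields are accepted with a warning (forward
    compatibility); a schema-version mismatch raises
    :class:`SchemaVersionError`.  Regeneration reproduces the silhouette
    exactly because all geometry is stored explicitly.
    """
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SchemaVersionError(
            f"document schema_version={version!r}, expected {SCHEMA_VERSION}"
        )
    extra = set(doc) - _SHAPE_FIELDS
    if extra:
        warnings.warn(f"ignoring unknown shape fields: {sorted(extra)}")
    body = make_main_body(**doc.get("body", {}))
    parts = []
    for i, pdoc in enumerate(doc.get("parts", [])):
        extra = set(pdoc) - _PART_FIELDS
        if extra:
            warnings.warn(f"ignoring unknown part fields in part {i}: {sorted(extra)}")
        growth_doc = dict(pdoc["growth"])
        for key in ("angle_magnitude_range_deg", "seg_length_range", "width_profile"):
            if growth_doc.get(key) is not None:
                growth_doc[key] = tuple(growth_doc[key])
        parts.append(
            Part(
                local_joints=np.asarray(pdoc["local_joints"], dtype=float),
                growth=GrowthParams(**growth_doc),
                order=int(pdoc["order"]),
                parent=pdoc["parent"],
                attach_t=float(pdoc["attach_t"]),
                side=pdoc["side"],
                width_scale=float(pdoc["width_scale"]),
                pair_id=pdoc.get("pair_id"),
                part_id=pdoc.get("part_id", ""),
            )
        )
    return compose_shape(body, parts, meta=doc.get("meta", {}))


def save_shape_json(shape: Shape, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(serialize_shape(shape), indent=1))


def load_shape_json(path: Union[str, Path]) -> Shape:
    return load_shape(json.loads(Path(path).read_text()))


# --------------------------------------------------------------------------
# SVG / PNG rendering

def _canvas_transform(shape: Shape, config: RenderConfig):
    minx, miny, maxx, maxy = shape.silhouette.bounds
    span = max(maxx - minx, maxy - miny)
    usable = config.canvas_px * (1.0 - 2.0 * config.margin)
    scale = usable / span
    cx, cy = (minx + maxx) / 2.0, (miny + maxy) / 2.0
    half = config.canvas_px / 2.0

    def to_px(pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        out = np.empty_like(pts)
        out[:, 0] = (pts[:, 0] - cx) * scale + half
        out[:, 1] = half - (pts[:, 1] - cy) * scale  # y-up canvas -> y-down pixels
        return out

    return to_px


def shape_to_svg(
    shape: Shape, config: RenderConfig, path: Union[str, Path]
) -> Path:
    """Write the filled silhouette (and optional skeleton overlay) as SVG."""
    to_px = _canvas_transform(shape, config)
    coords = np.asarray(shape.silhouette.exterior.coords)[:-1]
    px = to_px(coords)
    d = "M " + " L ".join(f"{x:.3f},{y:.3f}" for x, y in px) + " Z"
    lines = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{config.canvas_px}" '
        f'height="{config.canvas_px}" viewBox="0 0 {config.canvas_px} {config.canvas_px}">',
        f'<rect width="100%" height="100%" fill="{config.background}"/>',
        f'<path d="{d}" fill="{config.fill}" stroke="none"/>',
    ]
    if config.skeleton_overlay:
        skel = [shape.body.skeleton.joints] + [
            shape.global_joints(i) for i in range(shape.n_parts)
        ]
        for joints in skel:
            pts = to_px(joints)
            poly = " ".join(f"{x:.2f},{y:.2f}" for x, y in pts)
            lines.append(
                f'<polyline points="{poly}" fill="none" stroke="#2b6cb0" stroke-width="1.5"/>'
            )
            for x, y in pts:
                lines.append(f'<circle cx="{x:.2f}" cy="{y:.2f}" r="2.5" fill="#111"/>')
        for x, y in to_px(shape.seg_points) if shape.n_parts else []:
            lines.append(f'<circle cx="{x:.2f}" cy="{y:.2f}" r="3" fill="#c53030"/>')
    lines.append("</svg>")
    out = Path(path)
    out.write_text("\n".join(lines))
    return out


def shape_to_png(
    shape: Shape, config: RenderConfig, path: Union[str, Path]
) -> Path:
    """Rasterise the filled silhouette to PNG at the configured canvas size."""
    to_px = _canvas_transform(shape, config)
    img = Image.new("RGB", (config.canvas_px, config.canvas_px), config.background)
    draw = ImageDraw.Draw(img)
    coords = to_px(np.asarray(shape.silhouette.exterior.coords)[:-1])
    draw.polygon([tuple(p) for p in coords], fill=config.fill)
    for interior in shape.silhouette.interiors:
        hole = to_px(np.asarray(interior.coords)[:-1])
        draw.polygon([tuple(p) for p in hole], fill=config.background)
    out = Path(path)
    img.save(out, dpi=(config.dpi, config.dpi))
    return out


# --------------------------------------------------------------------------
# CSV tables

def write_trials(table: pd.DataFrame, path: Union[str, Path]) -> Path:
    """Write a trial or response table as UTF-8 comma-separated CSV."""
    out = Path(path)
    table.to_csv(out, index=False)
    return out


def read_responses(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a response CSV.

    2-AFC files must carry a ``choice`` column with values 'left'/'right';
    slider files a ``rating`` column with values in [0, 1].  Offending rows
    are reported by index in a :class:`ResponseValidationError`.
    """
    df = pd.read_csv(path)
    errors: list[tuple[int, str]] = []
    if "choice" in df.columns:
        bad = ~df["choice"].isin(["left", "right"])
        errors += [(int(i), f"choice {df.loc[i, 'choice']!r} not in left/right")
                   for i in df.index[bad]]
    if "rating" in df.columns:
        vals = pd.to_numeric(df["rating"], errors="coerce")
        bad = vals.isna() | (vals < 0.0) | (vals > 1.0)
        errors += [(int(i), f"rating {df.loc[i, 'rating']!r} outside [0, 1]")
                   for i in df.index[bad]]
    if "choice" not in df.columns and "rating" not in df.columns:
        raise ResponseValidationError([(0, "no 'choice' or 'rating' column")])
    if errors:
        raise ResponseValidationError(sorted(errors))
    return df
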