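"""Generative growth of skeletal parts and their composition into shapes.

A shape is built the way many organisms grow: a vertically elongated main
body, plus limbs ("parts") that sprout from it.  Each part is generated as a
*skeletal path* -- a chain of joints produced by a random walk in heading
space -- which is then smoothed and inflated into a silhouette ribbon of
locally specified width.  Parts can in turn carry their own children
(second-order parts), giving the branching hierarchies typical of plants.

All geometry lives in continuous 2-D Cartesian coordinates with y pointing
up, and the canvas is normalised so that the main body is one unit tall.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from shapely.geometry import MultiPolygon, Polygon
from shapely.geometry.polygon import orient
from shapely.ops import unary_union
from shapely.validation import make_valid

log = logging.getLogger(__name__)

__all__ = [
    "GrowthParams",
    "SkeletalPath",
    "Part",
    "MainBody",
    "Shape",
    "InvalidParameterError",
    "CompositionError",
    "UnknownParentError",
    "grow_path",
    "smooth_path",
    "build_silhouette",
    "make_main_body",
    "attach_part",
    "compose_shape",
    "part_global_joints",
    "part_frame",
    "polyline_point_at",
]


class InvalidParameterError(ValueError):
    """A growth or manipulation parameter violates its contract."""


class CompositionError(RuntimeError):
    """The boolean union of body and parts did not yield one connected polygon."""


class UnknownParentError(KeyError):
    """A part references a parent that does not exist in the shape."""


# --------------------------------------------------------------------------
# small vector helpers

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.hypot(v[0], v[1])
    if n < 1e-300:
        raise ValueError("cannot normalise zero vector")
    return v / n


def _rot90(v: np.ndarray) -> np.ndarray:
    """Rotate a 2-vector by +90 degrees (counterclockwise)."""
    return np.array([-v[1], v[0]])


def _rot_minus90(v: np.ndarray) -> np.ndarray:
    return np.array([v[1], -v[0]])


def _wrap_deg(a):
    """Wrap angles to (-180, 180]."""
    return -((-np.asarray(a) + 180.0) % 360.0 - 180.0)


# --------------------------------------------------------------------------
# growth parameters

@dataclass(frozen=True)
class GrowthParams:
    """Parameters controlling the stochastic growth of a single part.

    Attributes
    ----------
    n_joints:
        Number of skeletal joints (>= 2).
    angle_range_deg:
        Symmetric half-range for heading deviations: each new segment
        deviates from the previous heading by a value drawn uniformly in
        ``[-angle_range_deg, +angle_range_deg]``.
    angle_magnitude_range_deg:
        Optional ``(lo, hi)`` in degrees.  When set, every turning angle
        *after the first segment* has its magnitude drawn uniformly in
        ``[lo, hi]`` with a random sign, giving uniformly curved limbs.
        The first segment's deviation from the start angle still uses
        ``angle_range_deg`` (attachment jitter).
    seg_length_range:
        ``(min, max)`` distance between consecutive joints, in canvas units
        (before any rescaling applied at attachment time).
    width_profile:
        Width factors at stations spaced evenly along the path; values in
        between are linearly interpolated.
    taper:
        Terminal-width fraction in [0, 1]; the width factor at the tip is
        multiplied by this, so ``taper=0`` produces a pointed tip.
    rel_width:
        Overall width relative to the parent part (dimensionless).
    rel_length:
        Overall length relative to the parent part; the grown path is
        rescaled so its summed segment length equals
        ``rel_length * parent_length`` exactly.
    """

    n_joints: int = 4
    angle_range_deg: float = 60.0
    angle_magnitude_range_deg: Optional[tuple[float, float]] = None
    seg_length_range: tuple[float, float] = (0.08, 0.16)
    width_profile: tuple[float, ...] = (1.0, 1.0)
    taper: float = 1.0
    rel_width: float = 0.22
    rel_length: float = 0.6

    def __post_init__(self) -> None:
        if self.n_joints < 2:
            raise InvalidParameterError("n_joints must be >= 2")
        if self.angle_range_deg < 0:
            raise InvalidParameterError("angle_range_deg must be >= 0")
        if self.angle_magnitude_range_deg is not None:
            lo, hi = self.angle_magnitude_range_deg
            if not (0 <= lo <= hi):
                raise InvalidParameterError("bad angle_magnitude_range_deg")
        lo, hi = self.seg_length_range
        if not (0 < lo <= hi):
            raise InvalidParameterError("seg_length_range must satisfy 0 < min <= max")
        if len(self.width_profile) < 1 or any(w <= 0 for w in self.width_profile):
            raise InvalidParameterError("width_profile factors must be > 0")
        if not (0.0 <= self.taper <= 1.0):
            raise InvalidParameterError("taper must lie in [0, 1]")
        if self.rel_width <= 0 or self.rel_length < 0:
            raise InvalidParameterError("rel_width must be > 0 and rel_length >= 0")


# --------------------------------------------------------------------------
# skeletal paths

@dataclass(frozen=True)
class SkeletalPath:
    """An ordered chain of 2-D joints.

    Derived quantities (segment lengths, headings, signed turning angles)
    are computed on demand from the joint coordinates.
    """

    joints: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        j = np.asarray(self.joints, dtype=float)
        if j.ndim != 2 or j.shape[1] != 2 or j.shape[0] < 2:
            raise InvalidParameterError("joints must be an (n>=2, 2) array")
        j = np.ascontiguousarray(j)
        j.setflags(write=False)
        object.__setattr__(self, "joints", j)

    @property
    def n_joints(self) -> int:
        return self.joints.shape[0]

    @property
    def segment_vectors(self) -> np.ndarray:
        return np.diff(self.joints, axis=0)

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.hypot(*np.diff(self.joints, axis=0).T)

    @property
    def headings_deg(self) -> np.ndarray:
        d = self.segment_vectors
        return np.degrees(np.arctan2(d[:, 1], d[:, 0]))

    @property
    def turning_angles_deg(self) -> np.ndarray:
        """Signed deviation between consecutive segment directions; 0 = straight."""
        h = self.headings_deg
        return _wrap_deg(np.diff(h))

    @property
    def length(self) -> float:
        return float(self.segment_lengths.sum())


def grow_path(
    start: Sequence[float],
    start_angle_deg: float,
    params: GrowthParams,
    rng: np.random.Generator,
) -> SkeletalPath:
    """Grow a skeletal path by a random walk in heading space.

    The first segment direction deviates from ``start_angle_deg`` by a
    uniform draw within ``±angle_range_deg``; each subsequent direction
    deviates from the previous one by a draw from the same range (or, if
    ``angle_magnitude_range_deg`` is set, by a random-sign magnitude from
    that range).  Segment lengths are uniform in ``seg_length_range``.
    """
    n = params.n_joints
    m = n - 1  # number of segments
    devs = np.empty(m)
    devs[0] = rng.uniform(-params.angle_range_deg, params.angle_range_deg)
    if m > 1:
        if params.angle_magnitude_range_deg is not None:
            lo, hi = params.angle_magnitude_range_deg
            mags = rng.uniform(lo, hi, size=m - 1)
            signs = rng.choice([-1.0, 1.0], size=m - 1)
            devs[1:] = mags * signs
        else:
            devs[1:] = rng.uniform(
                -params.angle_range_deg, params.angle_range_deg, size=m - 1
            )
    headings = np.radians(start_angle_deg + np.cumsum(devs))
    lengths = rng.uniform(*params.seg_length_range, size=m)
    steps = np.stack([np.cos(headings), np.sin(headings)], axis=1) * lengths[:, None]
    joints = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)]) + np.asarray(
        start, dtype=float
    )
    return SkeletalPath(joints)


def smooth_path(path: SkeletalPath, samples_per_segment: int = 12) -> np.ndarray:
    """Interpolate a skeletal path with a natural cubic spline.

    The spline is parameterised by cumulative chord length and passes through
    every joint exactly; the returned dense polyline has
    ``(n_joints - 1) * samples_per_segment + 1`` vertices, with joints at
    multiples of ``samples_per_segment``.
    """
    if samples_per_segment < 1:
        raise InvalidParameterError("samples_per_segment must be >= 1")
    joints = path.joints
    s = np.concatenate([[0.0], np.cumsum(path.segment_lengths)])
    if s[-1] < 1e-15:
        # degenerate zero-length path: all vertices coincide
        return np.repeat(joints[:1], (path.n_joints - 1) * samples_per_segment + 1, axis=0)
    spline = CubicSpline(s, joints, bc_type="natural", axis=0)
    ts = np.concatenate(
        [
            np.linspace(s[i], s[i + 1], samples_per_segment, endpoint=False)
            for i in range(len(s) - 1)
        ]
        + [s[-1:]]
    )
    dense = spline(ts)
    # interpolation guarantees exact endpoints up to rounding; pin them
    dense[0] = joints[0]
    dense[-1] = joints[-1]
    return dense


# --------------------------------------------------------------------------
# silhouettes

def _interp_widths(arc_frac: np.ndarray, params: GrowthParams, width_scale: float) -> np.ndarray:
    prof = np.asarray(params.width_profile, dtype=float)
    if prof.size == 1:
        prof = np.repeat(prof, 2)
    prof = prof.copy()
    prof[-1] *= params.taper  # taper only narrows the terminal station
    stations = np.linspace(0.0, 1.0, prof.size)
    w = np.interp(arc_frac, stations, prof)
    return w * width_scale


def build_silhouette(
    polyline: np.ndarray,
    params: GrowthParams,
    width_scale: float = 1.0,
    cap_samples: int = 17,
) -> Polygon:
    """Inflate a dense polyline into a closed silhouette polygon.

    Each vertex is offset perpendicular to the local tangent by ± half the
    locally interpolated width (per-joint width factors, linearly
    interpolated along arc length, scaled by ``width_scale`` and tapered at
    the tip); the two offset chains are closed with round end caps.  Micro
    self-intersections from high curvature are removed with a validity
    cleanup; a cleanup yielding several disconnected components raises
    :class:`CompositionError`.

    ``cap_samples`` should be odd so that each cap contains the vertex on
    the path axis exactly (used for the mirror-symmetric main body).
    """
    p = np.asarray(polyline, dtype=float)
    if p.ndim != 2 or p.shape[0] < 2:
        raise InvalidParameterError("polyline must have >= 2 vertices")
    seglen = np.hypot(*np.diff(p, axis=0).T)
    total = seglen.sum()
    if total < 1e-15:
        raise InvalidParameterError("polyline has zero length")
    arc = np.concatenate([[0.0], np.cumsum(seglen)]) / total

    # vertex tangents: central differences inside, one-sided at the ends
    tang = np.empty_like(p)
    tang[1:-1] = p[2:] - p[:-2]
    tang[0] = p[1] - p[0]
    tang[-1] = p[-1] - p[-2]
    norms = np.hypot(tang[:, 0], tang[:, 1])
    norms[norms == 0] = 1.0
    tang /= norms[:, None]
    normal = np.stack([-tang[:, 1], tang[:, 0]], axis=1)  # +90 deg

    half = 0.5 * _interp_widths(arc, params, width_scale)
    left = p + normal * half[:, None]
    right = p - normal * half[:, None]

    def cap(center, from_pt, radius, n=cap_samples):
        a0 = np.arctan2(from_pt[1] - center[1], from_pt[0] - center[0])
        angles = np.linspace(a0, a0 - np.pi, n + 2)[1:-1]
        return center + radius * np.stack([np.cos(angles), np.sin(angles)], axis=1)

    end_cap = cap(p[-1], left[-1], half[-1]) if half[-1] > 1e-12 else np.empty((0, 2))
    start_cap = cap(p[0], right[0], half[0]) if half[0] > 1e-12 else np.empty((0, 2))
    ring = np.vstack([left, end_cap, right[::-1], start_cap])

    poly = Polygon(ring)
    if not poly.is_valid:
        # high curvature folded the offset ribbon onto itself; rebuild it as
        # the union of per-segment quads plus the two cap fans, which is
        # connected by construction, then fill any self-loop enclosures
        pieces = []
        for i in range(len(p) - 1):
            quad = Polygon([left[i], left[i + 1], right[i + 1], right[i]])
            if not quad.is_valid:
                fixed = make_valid(quad)
                geoms = getattr(fixed, "geoms", [fixed])
                pieces.extend(g for g in geoms if g.geom_type == "Polygon")
            elif not quad.is_empty:
                pieces.append(quad)
        if len(end_cap):
            pieces.append(Polygon(np.vstack([[left[-1]], end_cap, [right[-1]]])))
        if len(start_cap):
            pieces.append(Polygon(np.vstack([[right[0]], start_cap, [left[0]]])))
        union = unary_union(pieces)
        if union.geom_type == "GeometryCollection":
            union = unary_union(
                [g for g in union.geoms if g.geom_type in ("Polygon", "MultiPolygon")]
            )
        if isinstance(union, MultiPolygon):
            # folded lobes may touch only at a point; close the hairline gap
            eps = 1e-3 * float(np.max(half))
            union = union.buffer(eps).buffer(-eps)
        if isinstance(union, MultiPolygon):
            parts = sorted(union.geoms, key=lambda g: g.area, reverse=True)
            if sum(g.area for g in parts[1:]) > 1e-9 * parts[0].area:
                raise CompositionError(
                    "silhouette cleanup produced %d components" % len(parts)
                )
            union = parts[0]
        poly = Polygon(union.exterior)
    return orient(poly, 1.0)


# --------------------------------------------------------------------------
# parts and main body

@dataclass(frozen=True)
class Part:
    """A limb, described in its local attachment frame.

    ``local_joints`` places the root joint at the origin with the local
    +x axis pointing outward from the parent (orthogonal to the parent's
    tangent at the attachment point).  ``order`` is 1 for limbs attached to
    the main body and 2 for sprouts attached to another limb; ``parent`` is
    the index of the host part, or ``None`` for the main body.  ``attach_t``
    is the arc-length fraction along the parent (perimeter fraction for the
    main body, skeletal fraction for a host limb), and ``pair_id`` tags the
    two members of a nominally mirror-symmetric pair.
    """

    local_joints: np.ndarray
    growth: GrowthParams
    order: int
    parent: Optional[int]
    attach_t: float
    side: str  # 'left' | 'right' | 'none'
    width_scale: float
    pair_id: Optional[int] = None
    part_id: str = ""

    def __post_init__(self) -> None:
        j = np.ascontiguousarray(np.asarray(self.local_joints, dtype=float))
        j.setflags(write=False)
        object.__setattr__(self, "local_joints", j)
        if self.order not in (1, 2):
            raise InvalidParameterError("order must be 1 or 2")
        if self.order == 2 and self.parent is None:
            raise InvalidParameterError("order-2 parts need a Part parent")
        if not (0.0 <= self.attach_t <= 1.0):
            raise InvalidParameterError("attach_t must lie in [0, 1]")
        if self.side not in ("left", "right", "none"):
            raise InvalidParameterError("side must be left/right/none")

    @property
    def path(self) -> SkeletalPath:
        return SkeletalPath(self.local_joints)

    @property
    def length(self) -> float:
        return self.path.length


@dataclass
class MainBody:
    """A simple elongated body in upright orientation.

    The boundary is stored as an open CCW vertex loop whose first vertex is
    the topmost boundary point; arc length along it (counterclockwise, i.e.
    down the left flank, around the bottom, and up the right flank) defines
    the perimeter parameterisation used for limb attachment.
    """

    silhouette: Polygon
    boundary: np.ndarray  # (m, 2) CCW, first vertex = topmost point
    axis_x: float
    width_scale: float
    skeleton: SkeletalPath
    params: dict = field(default_factory=dict)  # construction parameters
    _cumlen: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        closed = np.vstack([self.boundary, self.boundary[:1]])
        seg = np.hypot(*np.diff(closed, axis=0).T)
        self._cumlen = np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def perimeter(self) -> float:
        return float(self._cumlen[-1])

    def perimeter_point(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        """Boundary point and unit tangent at arc-length fraction ``t``.

        ``t`` wraps modulo 1, so ``t=0`` and ``t=1`` return the same point.
        """
        s = (t % 1.0) * self.perimeter
        closed = np.vstack([self.boundary, self.boundary[:1]])
        i = int(np.searchsorted(self._cumlen, s, side="right") - 1)
        i = min(i, len(self.boundary) - 1)
        seg = closed[i + 1] - closed[i]
        seglen = np.hypot(seg[0], seg[1])
        frac = 0.0 if seglen == 0 else (s - self._cumlen[i]) / seglen
        point = closed[i] + frac * seg
        return point, _unit(seg)

    def outward_normal(self, t: float) -> np.ndarray:
        """Unit normal pointing out of the body at perimeter fraction ``t``."""
        _, tang = self.perimeter_point(t)
        return _rot_minus90(tang)  # interior lies left of a CCW boundary

    def bottom_t(self) -> float:
        """Perimeter fraction of the bottommost boundary vertex."""
        i = int(np.argmin(self.boundary[:, 1]))
        return float(self._cumlen[i] / self.perimeter)


def make_main_body(
    height: float = 1.0,
    width: float = 0.32,
    width_profile: tuple[float, ...] = (0.78, 1.0, 0.78),
    taper: float = 0.9,
    n_joints: int = 3,
    samples_per_segment: int = 14,
) -> MainBody:
    """Construct the deterministic main body: a vertically elongated blob.

    Built with the same machinery as the limbs -- a straight vertical
    skeletal path with a mild mid-bulge width profile -- then rescaled so
    the bounding-box height is exactly ``height`` and centred on the origin.
    """
    params = dict(
        height=height,
        width=width,
        width_profile=tuple(width_profile),
        taper=taper,
        n_joints=n_joints,
        samples_per_segment=samples_per_segment,
    )
    skel_len = height - width  # round caps add ~width/2 at each end
    if skel_len <= 0:
        raise InvalidParameterError("height must exceed width for an elongated body")
    ys = np.linspace(-skel_len / 2.0, skel_len / 2.0, n_joints)
    joints = np.stack([np.zeros(n_joints), ys], axis=1)
    path = SkeletalPath(joints)
    gp = GrowthParams(
        n_joints=n_joints,
        angle_range_deg=0.0,
        seg_length_range=(skel_len / (n_joints - 1),) * 2,
        width_profile=tuple(width_profile),
        taper=taper,
        rel_width=1.0,
        rel_length=1.0,
    )
    dense = smooth_path(path, samples_per_segment)
    poly = build_silhouette(dense, gp, width_scale=width)

    minx, miny, maxx, maxy = poly.bounds
    scale = height / (maxy - miny)
    cx, cy = (minx + maxx) / 2.0, (miny + maxy) / 2.0
    coords = (np.asarray(poly.exterior.coords)[:-1] - [cx, cy]) * scale
    # enforce exact bilateral symmetry of the vertex loop about x = 0
    coords[:, 0] -= (coords[:, 0].max() + coords[:, 0].min()) / 2.0
    poly = orient(Polygon(coords), 1.0)
    boundary = np.asarray(poly.exterior.coords)[:-1]
    top = int(np.argmax(boundary[:, 1]))
    boundary = np.roll(boundary, -top, axis=0)
    skel = SkeletalPath((path.joints - [cx, cy]) * scale)
    return MainBody(
        silhouette=Polygon(boundary),
        boundary=boundary,
        axis_x=0.0,
        width_scale=width * scale,
        skeleton=skel,
        params=params,
    )


# --------------------------------------------------------------------------
# composition

def polyline_point_at(polyline: np.ndarray, t: float) -> tuple[np.ndarray, np.ndarray]:
    """Point and unit tangent at arc-length fraction ``t`` of an open polyline."""
    p = np.asarray(polyline, dtype=float)
    seg = np.hypot(*np.diff(p, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if cum[-1] < 1e-15:
        return p[0].copy(), np.array([1.0, 0.0])
    s = np.clip(t, 0.0, 1.0) * cum[-1]
    i = int(np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1))
    frac = (s - cum[i]) / seg[i] if seg[i] > 0 else 0.0
    point = p[i] + frac * (p[i + 1] - p[i])
    return point, _unit(p[i + 1] - p[i])


def part_frame(
    body: MainBody, parts: Sequence[Part], index: int
) -> tuple[np.ndarray, np.ndarray]:
    """Root point and outward unit axis (local +x) of ``parts[index]``."""
    part = parts[index]
    if part.parent is None:
        root, _ = body.perimeter_point(part.attach_t)
        e1 = body.outward_normal(part.attach_t)
    else:
        if not (0 <= part.parent < len(parts)):
            raise UnknownParentError(part.parent)
        host_joints = part_global_joints(body, parts, part.parent)
        root, tang = polyline_point_at(host_joints, part.attach_t)
        e1 = _rot90(tang) if part.side == "left" else _rot_minus90(tang)
    return root, e1


def part_global_joints(body: MainBody, parts: Sequence[Part], index: int) -> np.ndarray:
    """Joints of ``parts[index]`` in global canvas coordinates."""
    part = parts[index]
    root, e1 = part_frame(body, parts, index)
    e2 = _rot90(e1)
    local = part.local_joints
    return root + local[:, :1] * e1 + local[:, 1:] * e2


@dataclass
class Shape:
    """A composed shape: main body + part tree + union silhouette.

    ``seg_points`` holds one skeleton intersection point per part (the
    part's root, which lies on both the part skeleton and the parent
    boundary/skeleton); these are the points used for part segmentation.
    """

    body: MainBody
    parts: list[Part]
    silhouette: Polygon
    seg_points: np.ndarray
    part_polygons: list[Optional[Polygon]]
    meta: dict = field(default_factory=dict)

    @property
    def n_parts(self) -> int:
        return len(self.parts)

    def global_joints(self, index: int) -> np.ndarray:
        return part_global_joints(self.body, self.parts, index)


def _part_polygon(
    body: MainBody,
    parts: Sequence[Part],
    index: int,
    samples_per_segment: int,
) -> Optional[Polygon]:
    part = parts[index]
    gj = part_global_joints(body, parts, index)
    path = SkeletalPath(gj)
    if path.length < 1e-12:
        return None
    dense = smooth_path(path, samples_per_segment)
    return build_silhouette(dense, part.growth, width_scale=part.width_scale)


def compose_shape(
    body: MainBody,
    parts: Sequence[Part],
    samples_per_segment: int = 12,
    meta: Optional[dict] = None,
) -> Shape:
    """Union the body with all part silhouettes into one connected shape.

    Raises :class:`CompositionError` if the union is disconnected (a part
    floats free of its parent).  Sibling overlaps are permitted; the union
    resolves them.
    """
    parts = list(parts)
    polys: list[Optional[Polygon]] = []
    roots = []
    for i in range(len(parts)):
        polys.append(_part_polygon(body, parts, i, samples_per_segment))
        root, _ = part_frame(body, parts, i)
        roots.append(root)
    union = unary_union([body.silhouette] + [p for p in polys if p is not None])
    if isinstance(union, MultiPolygon):
        raise CompositionError(
            "composition produced %d disconnected components" % len(union.geoms)
        )
    seg_points = np.asarray(roots, dtype=float) if roots else np.empty((0, 2))
    return Shape(
        body=body,
        parts=parts,
        silhouette=union,
        seg_points=seg_points,
        part_polygons=polys,
        meta=dict(meta or {}),
    )


def attach_part(
    shape: Shape,
    parent_id,
    attach_t: float,
    side: str,
    params: GrowthParams,
    rng: np.random.Generator,
    pair_id: Optional[int] = None,
    part_id: str = "",
    samples_per_segment: int = 12,
) -> Shape:
    """Grow a new part on ``parent_id`` ('body' or a part index) and recompose.

    The part's local frame has +x orthogonal to the parent's tangent at the
    attachment point, pointing outward; its start angle therefore deviates
    from that outward direction only by the growth jitter.  The grown path
    is rescaled so its total length equals ``rel_length`` times the parent's
    skeletal length, and its width scale is ``rel_width`` times the parent's.
    """
    if not (0.0 <= attach_t <= 1.0):
        raise InvalidParameterError("attach_t must lie in [0, 1]")
    if parent_id == "body" or parent_id is None:
        parent_idx = None
        order = 1
        parent_len = shape.body.skeleton.length
        parent_ws = shape.body.width_scale
    else:
        if not isinstance(parent_id, (int, np.integer)) or not (
            0 <= parent_id < len(shape.parts)
        ):
            raise UnknownParentError(parent_id)
        parent_idx = int(parent_id)
        host = shape.parts[parent_idx]
        order = host.order + 1
        parent_len = host.length
        parent_ws = host.width_scale

    local = grow_path((0.0, 0.0), 0.0, params, rng)
    cur_len = local.length
    target = params.rel_length * parent_len
    joints = local.joints * (target / cur_len if cur_len > 0 else 0.0)
    part = Part(
        local_joints=joints,
        growth=params,
        order=order,
        parent=parent_idx,
        attach_t=float(attach_t),
        side=side,
        width_scale=parent_ws * params.rel_width,
        pair_id=pair_id,
        part_id=part_id or f"p{len(shape.parts)}",
    )
    return compose_shape(
        shape.body, shape.parts + [part], samples_per_segment, meta=shape.meta
    )
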