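"""Manipulations of part structure: symmetry displacement, straightening,
and sprouting (transplantation or direct sprout growth).

These are the three operations that push a shape along the animal--plant
axis.  Displacement breaks the bilateral symmetry of a limb pair by sliding
one member along the body perimeter; straightening scales every turning
angle of a limb toward zero while keeping segment lengths fixed; sprouting
adds (or re-roots) second-order limbs, the branching hierarchy typical of
plants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .skeleton_core import (
    GrowthParams,
    InvalidParameterError,
    MainBody,
    Part,
    Shape,
    SkeletalPath,
    compose_shape,
    grow_path,
)

log = logging.getLogger(__name__)

__all__ = [
    "DisplacementSpec",
    "StraightenSpec",
    "SproutSpec",
    "InvalidTargetError",
    "InvalidOperationError",
    "DISPLACEMENT_LEVELS",
    "STRAIGHTEN_LEVELS",
    "CURVED_ANGLE_RANGE_DEG",
    "mirror_limb",
    "displace_limb",
    "straighten_limb",
    "curved_limb_params",
    "transplant_limbs",
    "add_sprout",
    "rebuild_local_joints",
]

#: Perimeter-fraction displacement levels used in the symmetry condition.
DISPLACEMENT_LEVELS = (0.025, 0.05, 0.075, 0.10, 0.125)
#: Straightening factors used in the curvedness condition.
STRAIGHTEN_LEVELS = (0.05, 0.10, 0.15, 0.20, 0.25)
#: Turning-angle magnitude range (degrees) of curved limbs.
CURVED_ANGLE_RANGE_DEG = (50.0, 100.0)

#: Perimeter fraction kept clear of the body's top and bottom cap regions
#: when displacing a limb root (a limb sliding across a pole of the body
#: would be biologically nonsensical, so the shift clamps there instead).
CAP_MARGIN = 0.02


class InvalidTargetError(ValueError):
    """The operation was applied to a part it does not support."""


class InvalidOperationError(ValueError):
    """The operation's arguments are inconsistent (e.g. donor == host)."""


@dataclass(frozen=True)
class DisplacementSpec:
    """How far (perimeter fraction) and which way to slide a limb root."""

    fraction: float
    direction: str = "random"  # 'up' | 'down' | 'random'

    def __post_init__(self) -> None:
        if not (0.0 < self.fraction <= 0.5):
            raise InvalidParameterError("fraction must lie in (0, 0.5]")
        if self.direction not in ("up", "down", "random"):
            raise InvalidParameterError("direction must be up/down/random")


@dataclass(frozen=True)
class StraightenSpec:
    """Multiplier applied to every turning angle of a limb."""

    factor: float

    def __post_init__(self) -> None:
        if not (0.0 < self.factor <= 1.0):
            raise InvalidParameterError("factor must lie in (0, 1]")


@dataclass(frozen=True)
class SproutSpec:
    """Specification of second-order (sprouting) limbs on a parent limb."""

    size_scale: float  # total length as fraction of parent length
    placement: str = "random"  # 'random' | 'fixed'
    fixed_t: float = 0.5  # used when placement == 'fixed'
    symmetric_pairing: bool = False
    count_per_parent: int = 1
    growth: Optional[GrowthParams] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.size_scale <= 1.0):
            raise InvalidParameterError("size_scale must lie in [0, 1]")
        if self.placement not in ("random", "fixed"):
            raise InvalidParameterError("placement must be random/fixed")
        if self.count_per_parent < 0:
            raise InvalidParameterError("count_per_parent must be >= 0")


# --------------------------------------------------------------------------
# mirroring

def mirror_limb(part: Part, body: MainBody) -> Part:
    """Return the mirror-symmetric counterpart of a first-order limb.

    The mirrored limb attaches at the reflected perimeter position
    (``t -> 1 - t``; the perimeter origin sits on the symmetry axis) on the
    opposite side, and its skeletal path is the reflection of the input
    about the body axis: identical segment lengths and widths, turning
    angles of equal magnitude and flipped sign.
    """
    if part.parent is not None or part.order != 1:
        raise InvalidTargetError("only first-order limbs on the main body can be mirrored")
    flipped = part.local_joints * np.array([1.0, -1.0])
    side = {"left": "right", "right": "left", "none": "none"}[part.side]
    return replace(
        part,
        local_joints=flipped,
        attach_t=(1.0 - part.attach_t) % 1.0,
        side=side,
        part_id=part.part_id + "_m" if part.part_id else "",
    )


# --------------------------------------------------------------------------
# displacement

def _displaced_attach_t(
    body: MainBody, attach_t: float, spec: DisplacementSpec, rng: np.random.Generator
) -> float:
    """New perimeter fraction after sliding by ``spec.fraction`` up or down."""
    t_bottom = body.bottom_t()
    on_left = attach_t < t_bottom  # CCW from the top: left flank first
    if spec.direction == "random":
        upward = bool(rng.integers(2))
    else:
        upward = spec.direction == "up"
    # CCW arc length increases downward on the left flank, upward on the right
    sign = -1.0 if (upward == on_left) else 1.0
    new_t = attach_t + sign * spec.fraction
    lo, hi = (
        (CAP_MARGIN, t_bottom - CAP_MARGIN)
        if on_left
        else (t_bottom + CAP_MARGIN, 1.0 - CAP_MARGIN)
    )
    clamped = float(np.clip(new_t, lo, hi))
    if clamped != new_t:
        log.warning(
            "displacement clamped at body cap region: t=%.4f -> %.4f (requested %.4f)",
            attach_t,
            clamped,
            new_t,
        )
    return clamped


def displace_limb(
    shape: Shape,
    part_index: int,
    spec: DisplacementSpec,
    rng: np.random.Generator,
    samples_per_segment: int = 12,
) -> Shape:
    """Slide one limb's root along the body perimeter and recompose.

    The limb's geometry (path, widths) is untouched; only ``attach_t``
    changes, by ± ``spec.fraction`` of the total perimeter arc length.
    Shifts that would carry the root across the body's top or bottom cap
    are clamped there and logged.
    """
    part = shape.parts[part_index]
    if part.parent is not None:
        raise InvalidTargetError("only first-order limbs can be displaced")
    new_t = _displaced_attach_t(shape.body, part.attach_t, spec, rng)
    parts = list(shape.parts)
    parts[part_index] = replace(part, attach_t=new_t)
    return compose_shape(shape.body, parts, samples_per_segment, meta=shape.meta)


# --------------------------------------------------------------------------
# straightening

def rebuild_local_joints(
    segment_lengths: np.ndarray,
    first_heading_deg: float,
    turning_angles_deg: np.ndarray,
) -> np.ndarray:
    """Forward-reconstruct joints from lengths, initial heading and turnings."""
    headings = np.radians(
        first_heading_deg + np.concatenate([[0.0], np.cumsum(turning_angles_deg)])
    )
    steps = (
        np.stack([np.cos(headings), np.sin(headings)], axis=1)
        * np.asarray(segment_lengths)[:, None]
    )
    return np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])


def straighten_limb(part: Part, spec: StraightenSpec) -> Part:
    """Scale every turning angle of a limb by ``spec.factor``.

    Joints are repositioned by forward reconstruction from the root with
    the reduced angles; segment lengths and the first segment's direction
    are preserved exactly.  A factor of 0.25 applied to a 100° joint angle
    yields a 25° angle.
    """
    path = part.path
    if path.n_joints < 3:
        return part
    new_turn = path.turning_angles_deg * spec.factor
    joints = rebuild_local_joints(path.segment_lengths, path.headings_deg[0], new_turn)
    return replace(part, local_joints=joints)


# --------------------------------------------------------------------------
# curved limbs

def curved_limb_params(
    rng: np.random.Generator,
    n_joints: Optional[int] = None,
    **overrides,
) -> GrowthParams:
    """Growth parameters for a highly curved limb.

    Turning-angle magnitudes are drawn uniformly in [50°, 100°] with random
    sign; the joint count is drawn from 3–5 unless given.  The first
    segment's deviation from the outward attachment direction keeps a mild
    ±30° jitter.
    """
    if n_joints is None:
        n_joints = int(rng.integers(3, 6))
    defaults = dict(
        n_joints=n_joints,
        angle_range_deg=30.0,
        angle_magnitude_range_deg=CURVED_ANGLE_RANGE_DEG,
        width_profile=(1.0, 0.85),
        taper=0.25,
    )
    defaults.update(overrides)
    return GrowthParams(**defaults)


# --------------------------------------------------------------------------
# transplantation

def transplant_limbs(
    shape: Shape,
    donor_pair_id: int,
    host_pair_id: int,
    rng: np.random.Generator,
    attach_range: tuple[float, float] = (0.3, 0.8),
    samples_per_segment: int = 12,
) -> Shape:
    """Re-root a symmetric pair of first-order limbs onto another pair.

    Each donor limb is detached from the main body and attached at a random
    skeletal fraction of the host limb on its own side of the body, its
    order becoming 2.  Donor path geometry is preserved in the new root
    frame, and the total part count is unchanged — this turns an insect-like
    arrangement into a tree-like one.
    """
    if donor_pair_id == host_pair_id:
        raise InvalidOperationError("donor and host pair must differ")
    donors = [i for i, p in enumerate(shape.parts) if p.pair_id == donor_pair_id]
    hosts = [i for i, p in enumerate(shape.parts) if p.pair_id == host_pair_id]
    if not donors or not hosts:
        raise InvalidTargetError("donor or host pair not found")
    if any(shape.parts[i].parent is not None for i in donors + hosts):
        raise InvalidTargetError("transplant requires first-order pairs")

    # pair donors with hosts on the same body side where possible
    host_by_side = {shape.parts[i].side: i for i in hosts}
    parts = list(shape.parts)
    for d in donors:
        donor = parts[d]
        host_idx = host_by_side.get(donor.side, hosts[0])
        t = float(rng.uniform(*attach_range))
        side = str(rng.choice(["left", "right"]))
        parts[d] = replace(donor, parent=host_idx, order=2, attach_t=t, side=side)
    return compose_shape(shape.body, parts, samples_per_segment, meta=shape.meta)


# --------------------------------------------------------------------------
# sprouting

def _default_sprout_growth(rng: np.random.Generator) -> GrowthParams:
    return curved_limb_params(rng, n_joints=3, rel_width=0.8, rel_length=1.0)


def make_sprout_part(
    parent_index: int,
    parent: Part,
    attach_t: float,
    side: str,
    growth: GrowthParams,
    size_scale: float,
    rng: np.random.Generator,
    part_id: str = "",
    pair_id: Optional[int] = None,
) -> Part:
    """Grow one order-2 sprout part (not yet composed into a shape)."""
    local = grow_path((0.0, 0.0), 0.0, growth, rng)
    cur = local.length
    target = size_scale * parent.length
    joints = local.joints * (target / cur if cur > 0 else 0.0)
    return Part(
        local_joints=joints,
        growth=growth,
        order=2,
        parent=parent_index,
        attach_t=float(attach_t),
        side=side,
        width_scale=parent.width_scale * growth.rel_width,
        pair_id=pair_id,
        part_id=part_id,
    )


def add_sprout(
    shape: Shape,
    parent_index: int,
    spec: SproutSpec,
    rng: np.random.Generator,
    samples_per_segment: int = 12,
) -> Shape:
    """Add order-2 sprout(s) to a first-order limb and recompose.

    Sprouts root at random (or fixed) skeletal fractions of the parent with
    total length ``size_scale`` × parent length, starting orthogonal to the
    parent's tangent.  With ``symmetric_pairing`` and a mirrored parent
    pair, an exactly mirrored sprout is added to the partner at the same
    skeletal fraction on the flipped side.  ``size_scale = 0`` adds a
    degenerate ("non-existent") sprout that contributes no geometry but is
    recorded in the part list and shape metadata.
    """
    parent = shape.parts[parent_index]
    if parent.order != 1:
        raise InvalidTargetError("sprouts grow on first-order limbs")
    parts = list(shape.parts)
    meta = dict(shape.meta)
    partner_index = None
    if spec.symmetric_pairing and parent.pair_id is not None:
        for i, p in enumerate(shape.parts):
            if i != parent_index and p.pair_id == parent.pair_id:
                partner_index = i
                break

    for k in range(spec.count_per_parent):
        t = (
            float(rng.uniform(0.15, 0.85))
            if spec.placement == "random"
            else spec.fixed_t
        )
        side = str(rng.choice(["left", "right"]))
        growth = spec.growth or _default_sprout_growth(rng)
        sprout = make_sprout_part(
            parent_index,
            parent,
            t,
            side,
            growth,
            spec.size_scale,
            rng,
            part_id=f"{parent.part_id}_s{k}",
        )
        parts.append(sprout)
        if spec.size_scale == 0.0:
            meta.setdefault("zero_size_sprouts", []).append(sprout.part_id)
        if partner_index is not None:
            mirrored_side = {"left": "right", "right": "left"}[side]
            partner = shape.parts[partner_index]
            mirrored = replace(
                sprout,
                local_joints=sprout.local_joints * np.array([1.0, -1.0]),
                parent=partner_index,
                side=mirrored_side,
                width_scale=partner.width_scale * growth.rel_width,
                part_id=f"{partner.part_id}_s{k}",
            )
            parts.append(mirrored)
            if spec.size_scale == 0.0:
                meta.setdefault("zero_size_sprouts", []).append(mirrored.part_id)
    return compose_shape(shape.body, parts, samples_per_segment, meta=meta)
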