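"""Five-step animal-to-plant morph sequences.

A morph sequence keeps the identity of every part fixed and co-varies three
aspects of part structure across five steps: symmetric limb pairs are
increasingly displaced, limbs become continuously straighter, and sprouting
(second-order) limbs either grow from non-existent to large at random
points on their parents ("growing" condition) or keep a fixed size and form
mirrored pairs where the parent does ("symmetrical" condition).  All
schedules are linear in the step index.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .part_manipulation import (
    CAP_MARGIN,
    StraightenSpec,
    curved_limb_params,
    mirror_limb,
    rebuild_local_joints,
    straighten_limb,
)
from .skeleton_core import (
    GrowthParams,
    InvalidParameterError,
    MainBody,
    Part,
    Shape,
    SkeletalPath,
    compose_shape,
    grow_path,
    make_main_body,
)

__all__ = ["MorphSpec", "MorphSequence", "morph_step_params", "build_morph_sequence"]

N_STEPS = 5

#: Perimeter zone (left flank, CCW fractions) in which first-order limb
#: roots are placed; chosen so the largest displacement never reaches the
#: body's top or bottom cap, keeping the asymmetry schedule unclamped.
ATTACH_ZONE = (0.16, 0.345)


@dataclass(frozen=True)
class MorphSpec:
    """Design of one morph sequence.

    ``n_first_order`` limbs (2–6, constant along the sequence) form
    mirrored pairs, with an odd limb left unpaired.  Displacement runs
    linearly from 0 to ``max_displacement``; the straightening factor from
    ``straighten_endpoints[0]`` (curved) to ``straighten_endpoints[1]``
    (nearly straight); sprout size from 0 to ``sprout_size_endpoints[1]``
    in the growing condition, or fixed at that maximum in the symmetrical
    condition.
    """

    n_first_order: int
    condition: str  # 'growing' | 'symmetrical'
    max_displacement: float = 0.125
    straighten_endpoints: tuple[float, float] = (1.0, 0.05)
    sprout_size_endpoints: tuple[float, float] = (0.0, 0.6)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (2 <= self.n_first_order <= 6):
            raise InvalidParameterError("n_first_order must lie in 2..6")
        if self.condition not in ("growing", "symmetrical"):
            raise InvalidParameterError("condition must be growing/symmetrical")
        if not (0.0 <= self.max_displacement <= 0.5):
            raise InvalidParameterError("max_displacement must lie in [0, 0.5]")
        if self.sprout_size_endpoints[0] != 0.0 and self.condition == "growing":
            raise InvalidParameterError("growing sprouts start from size 0")


@dataclass
class MorphSequence:
    """Five shapes sharing part identity, plus their parameter schedule."""

    spec: MorphSpec
    steps: list[Shape]
    schedule: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.steps)


def morph_step_params(spec: MorphSpec, step: int) -> dict:
    """Deterministic per-step parameter values (``step`` in 1..5).

    Step 1 is the most animal-like (no displacement, fully curved, sprouts
    absent in the growing condition); step 5 the most plant-like.
    """
    if not (1 <= step <= N_STEPS):
        raise InvalidParameterError(f"step must lie in 1..{N_STEPS}")
    u = (step - 1) / (N_STEPS - 1)
    s0, s1 = spec.straighten_endpoints
    if spec.condition == "growing":
        sprout = u * spec.sprout_size_endpoints[1]
    else:
        sprout = spec.sprout_size_endpoints[1]
    return {
        "step": step,
        "displacement": u * spec.max_displacement,
        "straighten": s0 + u * (s1 - s0),
        "sprout_size": sprout,
    }


def _base_limb_layout(spec: MorphSpec, rng: np.random.Generator):
    """Attachment slots, pairing plan and displacement plan for one sequence."""
    n_pairs, odd = divmod(spec.n_first_order, 2)
    n_slots = n_pairs + odd
    lo, hi = ATTACH_ZONE
    slots = np.linspace(lo, hi, max(n_slots, 2))[:n_slots]
    slots = slots + rng.uniform(-0.008, 0.008, size=n_slots)
    return n_pairs, odd, slots


def build_morph_sequence(spec: MorphSpec, samples_per_segment: int = 12) -> MorphSequence:
    """Generate the five shapes of one morph sequence.

    One base shape is drawn (main body, ``n_first_order`` curved limbs in
    mirrored pairs, one sprout per first-order limb); the per-step schedule
    is then applied to that fixed geometry, so parts keep their identity
    and only the three morph parameters change.  In the growing condition
    each sprout is articulated independently of its parent's mirror partner;
    in the symmetrical condition sprouts on paired parents form exact
    mirror pairs.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_layout, rng_limbs, rng_sprouts = [
        np.random.default_rng(s) for s in ss.spawn(3)
    ]
    body = make_main_body()
    n_pairs, odd, slots = _base_limb_layout(spec, rng_layout)

    # ---- base first-order limbs (fully curved; straightened per step) ----
    base_parts: list[Part] = []
    pair_of: list[Optional[int]] = []
    for k in range(n_pairs):
        growth = curved_limb_params(rng_limbs)
        local = grow_path((0.0, 0.0), 0.0, growth, rng_limbs)
        scale = growth.rel_length * body.skeleton.length / local.length
        left = Part(
            local_joints=local.joints * scale,
            growth=growth,
            order=1,
            parent=None,
            attach_t=float(slots[k]),
            side="left",
            width_scale=body.width_scale * growth.rel_width,
            pair_id=k,
            part_id=f"L{k}",
        )
        base_parts += [left, mirror_limb(left, body)]
        pair_of += [k, k]
    if odd:
        growth = curved_limb_params(rng_limbs)
        local = grow_path((0.0, 0.0), 0.0, growth, rng_limbs)
        scale = growth.rel_length * body.skeleton.length / local.length
        t = float(slots[n_pairs])
        on_right = bool(rng_layout.integers(2))
        odd_part = Part(
            local_joints=local.joints * (scale * np.array([1.0, -1.0]) if on_right else scale),
            growth=growth,
            order=1,
            parent=None,
            attach_t=(1.0 - t) % 1.0 if on_right else t,
            side="right" if on_right else "left",
            width_scale=body.width_scale * growth.rel_width,
            pair_id=None,
            part_id="Lodd",
        )
        # shift the unpaired limb off any mirrored slot
        odd_t = odd_part.attach_t + (0.015 if not on_right else -0.015)
        base_parts.append(replace(odd_part, attach_t=odd_t))
        pair_of.append(None)

    # ---- displacement plan: one limb per pair, side and direction fixed ----
    displaced: dict[int, str] = {}  # part index -> direction
    for k in range(n_pairs):
        members = [i for i, p in enumerate(base_parts) if p.pair_id == k]
        target = int(rng_layout.choice(members))
        direction = "up" if rng_layout.integers(2) else "down"
        displaced[target] = direction

    # ---- sprout plan: one per first-order limb, geometry drawn once ----
    sprout_plan = []  # (parent_idx, attach_t, side, growth, unit_local, mirrored_of)
    if spec.condition == "symmetrical":
        done = set()
        for i, p in enumerate(base_parts):
            if i in done:
                continue
            t = float(rng_sprouts.uniform(0.15, 0.85))
            side = str(rng_sprouts.choice(["left", "right"]))
            growth = curved_limb_params(rng_sprouts, n_joints=3, rel_width=0.8, rel_length=1.0)
            unit = grow_path((0.0, 0.0), 0.0, growth, rng_sprouts).joints
            unit = unit / SkeletalPath(unit).length
            sprout_plan.append((i, t, side, growth, unit))
            done.add(i)
            if p.pair_id is not None:
                j = next(
                    jj for jj, q in enumerate(base_parts) if jj != i and q.pair_id == p.pair_id
                )
                mirrored_side = {"left": "right", "right": "left"}[side]
                sprout_plan.append((j, t, mirrored_side, growth, unit * [1.0, -1.0]))
                done.add(j)
    else:  # growing: independent articulation per sprout
        for i in range(len(base_parts)):
            t = float(rng_sprouts.uniform(0.15, 0.85))
            side = str(rng_sprouts.choice(["left", "right"]))
            growth = curved_limb_params(rng_sprouts, n_joints=3, rel_width=0.8, rel_length=1.0)
            unit = grow_path((0.0, 0.0), 0.0, growth, rng_sprouts).joints
            unit = unit / SkeletalPath(unit).length
            sprout_plan.append((i, t, side, growth, unit))

    # ---- realise the five steps ----
    steps: list[Shape] = []
    schedule: list[dict] = []
    t_bottom = body.bottom_t()
    for step in range(1, N_STEPS + 1):
        pars = morph_step_params(spec, step)
        factor = pars["straighten"]
        parts: list[Part] = []
        for i, base in enumerate(base_parts):
            p = straighten_limb(base, StraightenSpec(factor)) if factor < 1.0 else base
            if i in displaced and pars["displacement"] > 0:
                on_left = base.attach_t < t_bottom
                upward = displaced[i] == "up"
                sign = -1.0 if (upward == on_left) else 1.0
                new_t = base.attach_t + sign * pars["displacement"]
                lo, hi = (
                    (CAP_MARGIN, t_bottom - CAP_MARGIN)
                    if on_left
                    else (t_bottom + CAP_MARGIN, 1.0 - CAP_MARGIN)
                )
                p = replace(p, attach_t=float(np.clip(new_t, lo, hi)))
            parts.append(p)
        for parent_idx, t, side, growth, unit in sprout_plan:
            host = parts[parent_idx]
            joints = unit * (pars["sprout_size"] * host.length)
            sprout = Part(
                local_joints=joints,
                growth=growth,
                order=2,
                parent=parent_idx,
                attach_t=t,
                side=side,
                width_scale=host.width_scale * growth.rel_width,
                pair_id=None,
                part_id=f"{host.part_id}_s",
            )
            if factor < 1.0:
                sprout = straighten_limb(sprout, StraightenSpec(factor))
            parts.append(sprout)
        shape = compose_shape(
            body,
            parts,
            samples_per_segment,
            meta={
                "step": step,
                "condition": spec.condition,
                "n_first_order": spec.n_first_order,
                "schedule": pars,
                "seed": spec.seed,
            },
        )
        steps.append(shape)
        schedule.append(pars)
    return MorphSequence(spec=spec, steps=steps, schedule=schedule)
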