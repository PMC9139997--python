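"""Stimulus designs of the three experiments.

Experiment 1 crosses limb count (2–5) with five manipulation levels and 20
replicates, separately for a symmetry condition (mirrored vs displaced limb
pairs) and a curvedness condition (curved vs straightened limbs): 400 shape
pairs per condition.  Experiment 2 crosses symmetry × curvedness of the
limbs with the presence of sprouting, 125 pairs per cell: 500 pairs, each
contrasting an insect-like arrangement (two symmetric first-order pairs)
with a tree-like one (one pair transplanted onto the other).  Experiment 3
builds 110 five-step morph sequences (550 shapes) spanning limb counts 2–6
and both sprouting conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .morphing import ATTACH_ZONE, MorphSequence, MorphSpec, build_morph_sequence
from .part_manipulation import (
    DISPLACEMENT_LEVELS,
    STRAIGHTEN_LEVELS,
    DisplacementSpec,
    StraightenSpec,
    curved_limb_params,
    displace_limb,
    mirror_limb,
    straighten_limb,
    transplant_limbs,
)
from .skeleton_core import (
    GrowthParams,
    MainBody,
    Part,
    Shape,
    compose_shape,
    grow_path,
    make_main_body,
)

__all__ = [
    "ShapePair",
    "EXP1_LIMB_COUNTS",
    "build_experiment1",
    "build_experiment2",
    "build_experiment3",
    "trial_table_2afc",
    "presentation_order_exp3",
]

EXP1_LIMB_COUNTS = (2, 3, 4, 5)
#: Displacement applied to the asymmetric Experiment 2 stimulus types.
EXP2_DISPLACEMENT = 0.10
#: Straightening factor for the straight Experiment 2 stimulus types.
EXP2_STRAIGHTEN = 0.05


@dataclass
class ShapePair:
    """Two shapes differing only in one manipulated property.

    ``a`` is the reference member (symmetric / curved / untransplanted) and
    ``b`` the manipulated one; ``placement_swapped`` records the randomised
    left/right screen placement, exposed through the ``left`` and ``right``
    properties.
    """

    a: Shape
    b: Shape
    condition: str  # 'symmetry' | 'curvedness' | 'sprouting'
    level: object
    n_limbs: int
    pair_id: str
    placement_swapped: bool = False

    @property
    def left(self) -> Shape:
        return self.b if self.placement_swapped else self.a

    @property
    def right(self) -> Shape:
        return self.a if self.placement_swapped else self.b


_BODY: Optional[MainBody] = None


def _body() -> MainBody:
    """The shared deterministic main body (identical across all stimuli)."""
    global _BODY
    if _BODY is None:
        _BODY = make_main_body()
    return _BODY


def _grow_first_order(
    body: MainBody,
    n_limbs: int,
    rng: np.random.Generator,
    growth_factory,
) -> list[Part]:
    """Mirrored limb pairs (plus an unpaired odd limb) on the main body."""
    n_pairs, odd = divmod(n_limbs, 2)
    n_slots = n_pairs + odd
    lo, hi = ATTACH_ZONE
    slots = np.linspace(lo, hi, max(n_slots, 2))[:n_slots]
    slots = slots + rng.uniform(-0.008, 0.008, size=n_slots)
    parts: list[Part] = []
    for k in range(n_pairs):
        growth = growth_factory(rng)
        local = grow_path((0.0, 0.0), 0.0, growth, rng)
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
        parts += [left, mirror_limb(left, body)]
    if odd:
        growth = growth_factory(rng)
        local = grow_path((0.0, 0.0), 0.0, growth, rng)
        scale = growth.rel_length * body.skeleton.length / local.length
        on_right = bool(rng.integers(2))
        t = float(slots[n_pairs]) + (0.015 if not on_right else -0.015)
        parts.append(
            Part(
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
        )
    return parts


def _default_limb_growth(rng: np.random.Generator) -> GrowthParams:
    """Moderately articulated limbs for the symmetry condition."""
    return GrowthParams(
        n_joints=int(rng.integers(3, 6)),
        angle_range_deg=45.0,
        width_profile=(1.0, 0.85),
        taper=0.25,
    )


def build_experiment1(
    condition: str,
    seed: int,
    n_reps: int = 20,
    limb_counts: Sequence[int] = EXP1_LIMB_COUNTS,
) -> list[ShapePair]:
    """Shape pairs for Experiment 1: ``len(limb_counts) × 5 levels × n_reps``.

    Symmetry condition: member A has mirror-symmetric limb pairs; in member
    B one limb of each pair is displaced up or down the perimeter by the
    level fraction.  Curvedness condition: member A has curved limbs
    (turning angles 50–100°); member B has the same limbs straightened by
    the level factor.  Everything else — body, attachments, widths, segment
    lengths — is shared within a pair.
    """
    if condition not in ("symmetry", "curvedness"):
        raise ValueError("condition must be 'symmetry' or 'curvedness'")
    levels = DISPLACEMENT_LEVELS if condition == "symmetry" else STRAIGHTEN_LEVELS
    body = _body()
    ss = np.random.SeedSequence(seed)
    design_rng = np.random.default_rng(ss.spawn(1)[0])
    pairs: list[ShapePair] = []
    for n_limbs in limb_counts:
        for level in levels:
            for rep in range(n_reps):
                rng = np.random.default_rng(ss.spawn(1)[0])
                factory = (
                    _default_limb_growth if condition == "symmetry" else curved_limb_params
                )
                parts = _grow_first_order(body, n_limbs, rng, factory)
                shape_a = compose_shape(
                    body, parts, meta={"n_first_order": n_limbs, "member": "a"}
                )
                if condition == "symmetry":
                    shape_b = shape_a
                    n_pairs = n_limbs // 2
                    for k in range(n_pairs):
                        members = [
                            i for i, p in enumerate(shape_b.parts) if p.pair_id == k
                        ]
                        target = int(rng.choice(members))
                        shape_b = displace_limb(
                            shape_b,
                            target,
                            DisplacementSpec(level, "random"),
                            rng,
                        )
                else:
                    spec = StraightenSpec(level)
                    straightened = [
                        straighten_limb(p, spec) if p.order == 1 else p
                        for p in shape_a.parts
                    ]
                    shape_b = compose_shape(
                        body, straightened, meta={"n_first_order": n_limbs, "member": "b"}
                    )
                shape_b.meta["member"] = "b"
                pairs.append(
                    ShapePair(
                        a=shape_a,
                        b=shape_b,
                        condition=condition,
                        level=level,
                        n_limbs=n_limbs,
                        pair_id=f"e1-{condition}-{n_limbs}-{level}-{rep}",
                        placement_swapped=bool(design_rng.integers(2)),
                    )
                )
    return pairs


def build_experiment2(seed: int, n_reps: int = 125) -> list[ShapePair]:
    """Shape pairs for Experiment 2: 4 stimulus types × ``n_reps``.

    Each member A is an insect-like shape (main body + two symmetric
    first-order pairs); member B has one pair transplanted onto the other,
    tree-like.  The four types cross symmetrical/asymmetrical with
    curved/straight limbs, applied identically to both members before the
    transplant.
    """
    body = _body()
    ss = np.random.SeedSequence(seed)
    design_rng = np.random.default_rng(ss.spawn(1)[0])
    pairs: list[ShapePair] = []
    for symmetric in (True, False):
        for curved in (True, False):
            label = ("sym" if symmetric else "asym") + "-" + (
                "curved" if curved else "straight"
            )
            for rep in range(n_reps):
                rng = np.random.default_rng(ss.spawn(1)[0])
                parts = _grow_first_order(body, 4, rng, curved_limb_params)
                if not curved:
                    spec = StraightenSpec(EXP2_STRAIGHTEN)
                    parts = [straighten_limb(p, spec) for p in parts]
                shape = compose_shape(body, parts, meta={"n_first_order": 4})
                if not symmetric:
                    for k in (0, 1):
                        members = [
                            i for i, p in enumerate(shape.parts) if p.pair_id == k
                        ]
                        target = int(rng.choice(members))
                        shape = displace_limb(
                            shape,
                            target,
                            DisplacementSpec(EXP2_DISPLACEMENT, "random"),
                            rng,
                        )
                shape_b = transplant_limbs(
                    shape, donor_pair_id=1, host_pair_id=0, rng=rng
                )
                pairs.append(
                    ShapePair(
                        a=shape,
                        b=shape_b,
                        condition="sprouting",
                        level=label,
                        n_limbs=4,
                        pair_id=f"e2-{label}-{rep}",
                        placement_swapped=bool(design_rng.integers(2)),
                    )
                )
    return pairs


def build_experiment3(
    seed: int,
    n_replicates: int = 11,
    limb_counts: Sequence[int] = (2, 3, 4, 5, 6),
    conditions: Sequence[str] = ("growing", "symmetrical"),
) -> list[MorphSequence]:
    """The 110 morph sequences of Experiment 3 (balanced factorial design).

    ``len(limb_counts) × len(conditions) × n_replicates`` sequences of five
    shapes each; every shape's metadata records its sequence, step,
    condition and limb count, and step-1 shapes always have zero
    displacement.
    """
    ss = np.random.SeedSequence(seed)
    sequences: list[MorphSequence] = []
    for n_limbs in limb_counts:
        for condition in conditions:
            for rep in range(n_replicates):
                child_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
                spec = MorphSpec(
                    n_first_order=n_limbs, condition=condition, seed=child_seed
                )
                seq = build_morph_sequence(spec)
                seq_id = f"e3-{condition}-{n_limbs}-{rep}"
                for step_idx, shape in enumerate(seq.steps, start=1):
                    shape.meta["sequence_id"] = seq_id
                    shape.meta["shape_id"] = f"{seq_id}-step{step_idx}"
                sequences.append(seq)
    return sequences


def trial_table_2afc(pairs: Sequence[ShapePair], seed: int) -> pd.DataFrame:
    """Randomised 2-AFC trial table (order and left/right placement)."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    rows = []
    for trial, idx in enumerate(order):
        p = pairs[idx]
        rows.append(
            {
                "trial_index": trial,
                "pair_id": p.pair_id,
                "condition": p.condition,
                "level": p.level,
                "n_limbs": p.n_limbs,
                "left_id": p.pair_id + ("-b" if p.placement_swapped else "-a"),
                "right_id": p.pair_id + ("-a" if p.placement_swapped else "-b"),
                "manipulated_side": "left" if p.placement_swapped else "right",
            }
        )
    return pd.DataFrame(rows)


def presentation_order_exp3(
    sequences: Sequence[MorphSequence], seed: int
) -> pd.DataFrame:
    """Flattened, shuffled single-shape presentation order (slider task)."""
    rng = np.random.default_rng(seed)
    entries = [
        (shape.meta["shape_id"], shape.meta["sequence_id"], step + 1,
         seq.spec.condition, seq.spec.n_first_order)
        for seq in sequences
        for step, shape in enumerate(seq.steps)
    ]
    order = rng.permutation(len(entries))
    rows = [
        {
            "trial_index": trial,
            "shape_id": entries[i][0],
            "sequence_id": entries[i][1],
            "step": entries[i][2],
            "condition": entries[i][3],
            "n_limbs": entries[i][4],
        }
        for trial, i in enumerate(order)
    ]
    return pd.DataFrame(rows)
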