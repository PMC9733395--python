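"""Task structure and geometry of the fruit-reaching experiments.

Two experiment variants are encoded: ``exp1`` (healthy elderly participants,
102 fruits in 8 blocks, hand-held controller) and ``exp2`` (brain-injured
patients using an arm weight-support device, 48 fruits in 6 blocks, a larger
home sphere and a workspace shifted to an easily reachable volume).

Coordinates use a right-handed workspace frame: x = horizontal (screen
right), y = vertical (screen up), z = depth (away from the participant).
All lengths are meters, all times seconds.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "FruitKind",
    "DepthClass",
    "WorkspaceSpec",
    "ColliderSpec",
    "TargetLocation",
    "BlockSpec",
    "ExperimentProtocol",
    "TrialPlanEntry",
    "build_protocol",
    "classify_depth_usage",
    "generate_location_set",
    "plan_trial_sequence",
    "protocol_to_yaml",
    "protocol_from_yaml",
]


class FruitKind(str, Enum):
    ORANGE = "orange"
    APPLE = "apple"
    PEAR = "pear"


class DepthClass(str, Enum):
    NO_DEPTH = "no_depth"
    ONLY_DEPTH = "only_depth"
    COMBINED_DEPTH = "combined_depth"


@dataclass(frozen=True)
class WorkspaceSpec:
    """Axis-aligned reachable volume, centered at ``center_offset``.

    ``center_offset`` is (right, down, forward) in meters relative to the
    participant's eyes.
    """

    width: float
    height: float
    depth: float
    center_offset: tuple[float, float, float]

    def __post_init__(self):
        if not (self.width > 0 and self.height > 0 and self.depth > 0):
            raise ValueError("workspace extents must be positive")

    @property
    def half_extent(self) -> np.ndarray:
        return np.array([self.width, self.height, self.depth]) / 2.0


@dataclass(frozen=True)
class ColliderSpec:
    """Contact geometry of a fruit.

    Oranges and apples are plain spheres. The pear is the union of a lower
    sphere and an upper capsule (axis vertical, sitting on top of the
    sphere); ``capsule_height`` is the full capsule height including its
    hemispherical end caps, Unity-style.
    """

    shape: str  # "sphere" | "sphere_plus_capsule"
    sphere_diameter: float
    capsule_height: float | None = None
    capsule_diameter: float | None = None

    def __post_init__(self):
        if self.shape not in ("sphere", "sphere_plus_capsule"):
            raise ValueError(f"unknown collider shape {self.shape!r}")
        if self.shape == "sphere_plus_capsule":
            if self.capsule_height is None or self.capsule_diameter is None:
                raise ValueError("capsule dimensions required")


@dataclass(frozen=True)
class TargetLocation:
    """A fruit location, as an offset from the workspace center.

    The fruit kind shown at a location is randomized per trial sequence, so
    the canonical location set leaves ``fruit_kind`` unset.
    """

    offset: tuple[float, float, float]
    depth_class: DepthClass
    fruit_kind: FruitKind | None = None


@dataclass(frozen=True)
class BlockSpec:
    n_fruits: int
    allowed_categories: frozenset[FruitKind]

    def __post_init__(self):
        if self.n_fruits <= 0:
            raise ValueError("n_fruits must be positive")
        if not self.allowed_categories:
            raise ValueError("allowed_categories must be non-empty")


@dataclass(frozen=True)
class TrialPlanEntry:
    block_index: int  # 1-based
    fruit_kind: FruitKind
    location: TargetLocation


@dataclass(frozen=True)
class ExperimentProtocol:
    experiment_id: str
    workspace: WorkspaceSpec
    blocks: tuple[BlockSpec, ...]
    locations: tuple[TargetLocation, ...]
    dwell_interval: tuple[float, float]
    home_sphere_diameter: float
    cursor_sphere_diameter: float
    colliders: dict[FruitKind, ColliderSpec]

    @property
    def total_fruits(self) -> int:
        return sum(b.n_fruits for b in self.blocks)


#: Printed collider dimensions, shared by both experiments.
COLLIDERS: dict[FruitKind, ColliderSpec] = {
    FruitKind.ORANGE: ColliderSpec("sphere", 0.10),
    FruitKind.APPLE: ColliderSpec("sphere", 0.0752),
    FruitKind.PEAR: ColliderSpec(
        "sphere_plus_capsule", 0.0578, capsule_height=0.0731, capsule_diameter=0.0238
    ),
}

_ALL_KINDS = frozenset(FruitKind)
_PEAR_ONLY = frozenset({FruitKind.PEAR})
_PEAR_ORANGE = frozenset({FruitKind.PEAR, FruitKind.ORANGE})

_WORKSPACE_EXTENT = (0.3588, 0.2847, 0.3726)  # width x height x depth


def build_protocol(experiment_id: str, location_seed: int = 0) -> ExperimentProtocol:
    """Return the fully populated protocol for ``exp1`` or ``exp2``.

    ``location_seed`` fixes the canonical 22-location set (the within-class
    placement jitter); the class structure is identical for every seed.
    """
    if experiment_id == "exp1":
        workspace = WorkspaceSpec(*_WORKSPACE_EXTENT, center_offset=(0.198, 0.1998, 0.444))
        sizes = [6, 12, 12, 12, 18, 18, 18, 6]
        allowed = [_PEAR_ONLY] + [_ALL_KINDS] * 6 + [_PEAR_ONLY]
        home_d = 0.04
    elif experiment_id == "exp2":
        workspace = WorkspaceSpec(*_WORKSPACE_EXTENT, center_offset=(0.0, 0.31, 0.40))
        sizes = [6, 6, 6, 12, 12, 6]
        allowed = [_PEAR_ONLY, _PEAR_ORANGE, _ALL_KINDS, _PEAR_ORANGE, _ALL_KINDS, _PEAR_ONLY]
        home_d = 0.05
    else:
        raise ValueError(f"unknown experiment_id {experiment_id!r}")

    blocks = tuple(BlockSpec(n, a) for n, a in zip(sizes, allowed))
    locations = tuple(generate_location_set(workspace, seed=location_seed))
    return ExperimentProtocol(
        experiment_id=experiment_id,
        workspace=workspace,
        blocks=blocks,
        locations=locations,
        dwell_interval=(0.4, 0.6),
        home_sphere_diameter=home_d,
        cursor_sphere_diameter=0.04,
        colliders=dict(COLLIDERS),
    )


def classify_depth_usage(offset: Sequence[float], tol: float = 0.001) -> DepthClass:
    """Classify a target by whether reaching it requires the depth axis.

    ``no_depth``: motion only along horizontal and/or vertical axes;
    ``only_depth``: motion only along the depth axis; ``combined_depth``:
    depth together with at least one other axis. A target at the workspace
    center (all components within ``tol``) is degenerate and rejected.
    """
    h, v, d = (abs(float(c)) for c in offset)
    uses_depth = d > tol
    uses_other = h > tol or v > tol
    if not uses_depth and not uses_other:
        raise ValueError("degenerate target at workspace center")
    if not uses_depth:
        return DepthClass.NO_DEPTH
    if not uses_other:
        return DepthClass.ONLY_DEPTH
    return DepthClass.COMBINED_DEPTH


# Grid-aligned placement fractions of the half-extent used on each active
# axis; the seed only selects among these, so every location stays inside
# the workspace and exactly on-axis components are exact zeros.
_FRACTIONS = np.array([1 / 3, 2 / 3])


def generate_location_set(workspace: WorkspaceSpec, seed: int) -> list[TargetLocation]:
    """Generate the canonical 22-target set with the depth-usage taxonomy.

    Class structure: 8 no-depth (2 horizontal-only, 2 vertical-only,
    4 horizontal+vertical), 2 only-depth (one nearer / one farther than the
    center), 12 combined-depth (8 using all three axes, 4 depth+horizontal).
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    hx, hy, hz = workspace.half_extent

    def mag(h):
        return float(rng.choice(_FRACTIONS) * h)

    locs: list[TargetLocation] = []

    def add(x, y, z):
        locs.append(TargetLocation((x, y, z), classify_depth_usage((x, y, z))))

    # no_depth: 2 horizontal-only, 2 vertical-only, 4 horizontal+vertical
    for s in (+1, -1):
        add(s * mag(hx), 0.0, 0.0)
    for s in (+1, -1):
        add(0.0, s * mag(hy), 0.0)
    for sx in (+1, -1):
        for sy in (+1, -1):
            add(sx * mag(hx), sy * mag(hy), 0.0)
    # only_depth: one nearer, one farther than center
    add(0.0, 0.0, mag(hz))
    add(0.0, 0.0, -mag(hz))
    # combined_depth: 8 three-axis, 4 depth+horizontal
    for sx in (+1, -1):
        for sy in (+1, -1):
            for sz in (+1, -1):
                add(sx * mag(hx), sy * mag(hy), sz * mag(hz))
    for sx in (+1, -1):
        for sz in (+1, -1):
            add(sx * mag(hx), 0.0, sz * mag(hz))

    assert len(locs) == 22
    return locs


def plan_trial_sequence(
    protocol: ExperimentProtocol, seed: int
) -> list[TrialPlanEntry]:
    """Draw a randomized fruit/location sequence honoring the block rules.

    Every block that allows multiple categories contains at least one fruit
    of each allowed category; pear-only blocks contain only pears.
    Locations are drawn uniformly (with replacement) from the canonical set.
    Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    entries: list[TrialPlanEntry] = []
    for i, block in enumerate(protocol.blocks, start=1):
        allowed = sorted(block.allowed_categories, key=lambda k: k.value)
        if block.n_fruits < len(allowed):
            raise ValueError(
                f"block {i}: {block.n_fruits} fruits cannot cover "
                f"{len(allowed)} required categories"
            )
        kinds = list(allowed)  # one of each required category
        kinds += list(rng.choice([k.value for k in allowed], size=block.n_fruits - len(allowed)))
        kinds = [FruitKind(k) for k in kinds]
        rng.shuffle(kinds)
        loc_idx = rng.integers(0, len(protocol.locations), size=block.n_fruits)
        for kind, j in zip(kinds, loc_idx):
            entries.append(TrialPlanEntry(i, kind, protocol.locations[int(j)]))
    return entries


# ---------------------------------------------------------------------------
# Serialization: explicit units, floats stored as decimal strings so the
# round trip is bit-exact.


def _f(x: float) -> str:
    return repr(float(x))


def protocol_to_dict(p: ExperimentProtocol) -> dict:
    return {
        "experiment_id": p.experiment_id,
        "units": {"length": "m", "time": "s"},
        "workspace": {
            "width": _f(p.workspace.width),
            "height": _f(p.workspace.height),
            "depth": _f(p.workspace.depth),
            "center_offset": [_f(c) for c in p.workspace.center_offset],
        },
        "blocks": [
            {"n_fruits": b.n_fruits, "allowed": sorted(k.value for k in b.allowed_categories)}
            for b in p.blocks
        ],
        "locations": [
            {"offset": [_f(c) for c in l.offset], "depth_class": l.depth_class.value}
            for l in p.locations
        ],
        "dwell_interval": [_f(t) for t in p.dwell_interval],
        "home_sphere_diameter": _f(p.home_sphere_diameter),
        "cursor_sphere_diameter": _f(p.cursor_sphere_diameter),
        "colliders": {
            k.value: {
                "shape": c.shape,
                "sphere_diameter": _f(c.sphere_diameter),
                "capsule_height": None if c.capsule_height is None else _f(c.capsule_height),
                "capsule_diameter": None if c.capsule_diameter is None else _f(c.capsule_diameter),
            }
            for k, c in p.colliders.items()
        },
    }


def protocol_from_dict(d: dict) -> ExperimentProtocol:
    ws = d["workspace"]
    workspace = WorkspaceSpec(
        float(ws["width"]), float(ws["height"]), float(ws["depth"]),
        tuple(float(c) for c in ws["center_offset"]),
    )
    blocks = tuple(
        BlockSpec(b["n_fruits"], frozenset(FruitKind(k) for k in b["allowed"]))
        for b in d["blocks"]
    )
    locations = tuple(
        TargetLocation(tuple(float(c) for c in l["offset"]), DepthClass(l["depth_class"]))
        for l in d["locations"]
    )
    colliders = {
        FruitKind(k): ColliderSpec(
            c["shape"], float(c["sphere_diameter"]),
            None if c["capsule_height"] is None else float(c["capsule_height"]),
            None if c["capsule_diameter"] is None else float(c["capsule_diameter"]),
        )
        for k, c in d["colliders"].items()
    }
    return ExperimentProtocol(
        experiment_id=d["experiment_id"],
        workspace=workspace,
        blocks=blocks,
        locations=locations,
        dwell_interval=tuple(float(t) for t in d["dwell_interval"]),
        home_sphere_diameter=float(d["home_sphere_diameter"]),
        cursor_sphere_diameter=float(d["cursor_sphere_diameter"]),
        colliders=colliders,
    )


def protocol_to_yaml(p: ExperimentProtocol, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(protocol_to_dict(p), fh, sort_keys=False)


def protocol_from_yaml(path) -> ExperimentProtocol:
    with open(path, encoding="utf-8") as fh:
        return protocol_from_dict(yaml.safe_load(fh))
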