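"""2D world model and synthetic scene generators.

A :class:`Scene` is a rectangle of world space containing
:class:`SceneObject`\\ s.  Each object owns a closed polygonal footprint and a
set of point :class:`Reflector`\\ s that stand in for its acoustic surface:
a smooth man-made object is a few strong specular glints, while vegetation is
a cloud of many weak scatterers producing a diffuse echo train.

Conventions (used everywhere in the package): x right, y up, meters; robot
heading measured counter-clockwise from +x; target azimuth is positive to
the robot's LEFT (counter-clockwise).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from shapely.geometry import Point, Polygon

SPECULAR = "specular"
DIFFUSE = "diffuse_member"
PLANT = "plant"
NON_PLANT = "non_plant"


@dataclass
class Reflector:
    """A point scatterer: world position [m] and reflection gain in (0, 1]."""

    position: Tuple[float, float]
    strength: float
    kind: str = SPECULAR

    def __post_init__(self) -> None:
        if not (self.strength > 0):
            raise ValueError("reflector strength must be positive")
        if not all(math.isfinite(c) for c in self.position):
            raise ValueError("reflector position must be finite")
        if self.kind not in (SPECULAR, DIFFUSE):
            raise ValueError(f"unknown reflector kind {self.kind!r}")


@dataclass
class SceneObject:
    """A physical object: footprint polygon, its reflectors, and a label."""

    footprint: List[Tuple[float, float]]
    reflectors: List[Reflector]
    label: str = NON_PLANT
    id: str = ""

    def polygon(self) -> Polygon:
        return Polygon(self.footprint)

    def validate(self) -> None:
        poly = self.polygon()
        if not poly.is_valid:
            raise ValueError(f"object {self.id!r}: self-intersecting footprint")
        if self.label not in (PLANT, NON_PLANT):
            raise ValueError(f"object {self.id!r}: unknown label {self.label!r}")
        eps = 1e-9
        for r in self.reflectors:
            if poly.buffer(eps).distance(Point(r.position)) > 1e-6:
                raise ValueError(
                    f"object {self.id!r}: reflector {r.position} outside footprint"
                )


@dataclass
class Scene:
    """A bounded 2D world plus per-side ground-truth contours.

    ``ground_truth_contours`` maps a side name ("left"/"right" relative to
    the nominal direction of travel) to an (N, 2) polyline tracing the
    free-space-facing edge of the objects on that side.
    """

    objects: List[SceneObject]
    bounds: Tuple[float, float, float, float]  # xmin, ymin, xmax, ymax
    ground_truth_contours: Dict[str, np.ndarray] = field(default_factory=dict)

    def validate(self) -> None:
        xmin, ymin, xmax, ymax = self.bounds
        if not (xmax > xmin and ymax > ymin):
            raise ValueError("degenerate scene bounds")
        box = Polygon([(xmin, ymin), (xmax, ymin), (xmax, ymax), (xmin, ymax)])
        for obj in self.objects:
            obj.validate()
            if not box.buffer(1e-6).contains(obj.polygon()):
                raise ValueError(f"object {obj.id!r} outside scene bounds")

    def all_reflectors(self) -> List[Reflector]:
        return [r for obj in self.objects for r in obj.reflectors]

    # -- JSON serialization (explicit units: all lengths in meters) --------

    def to_dict(self) -> dict:
        return {
            "units": "meters",
            "bounds": list(self.bounds),
            "objects": [
                {
                    "id": o.id,
                    "label": o.label,
                    "footprint": [list(v) for v in o.footprint],
                    "reflectors": [
                        {
                            "position": list(r.position),
                            "strength": r.strength,
                            "kind": r.kind,
                        }
                        for r in o.reflectors
                    ],
                }
                for o in self.objects
            ],
            "ground_truth_contours": {
                k: np.asarray(v).tolist()
                for k, v in self.ground_truth_contours.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Scene":
        objects = [
            SceneObject(
                footprint=[tuple(v) for v in o["footprint"]],
                reflectors=[
                    Reflector(tuple(r["position"]), r["strength"], r["kind"])
                    for r in o["reflectors"]
                ],
                label=o.get("label", NON_PLANT),
                id=o.get("id", ""),
            )
            for o in d["objects"]
        ]
        contours = {
            k: np.asarray(v, dtype=float)
            for k, v in d.get("ground_truth_contours", {}).items()
        }
        return cls(objects=objects, bounds=tuple(d["bounds"]), ground_truth_contours=contours)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "Scene":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def _square(center: Tuple[float, float], half: float) -> List[Tuple[float, float]]:
    cx, cy = center
    return [
        (cx - half, cy - half),
        (cx + half, cy - half),
        (cx + half, cy + half),
        (cx - half, cy + half),
    ]


def make_single_reflector_scene(range_m: float, azimuth_deg: float) -> Scene:
    """One specular reflector at polar (range, azimuth) from the origin pose.

    The virtual robot sits at the origin facing +x; positive azimuth is to
    its left (+y).  Used for localization-accuracy protocols.
    """
    if not (0.2 <= range_m <= 6.0):
        raise ValueError("range_m must be in [0.2, 6] m")
    if abs(azimuth_deg) > 60.0:
        raise ValueError("azimuth_deg must be within +/-60 degrees")
    az = math.radians(azimuth_deg)
    pos = (range_m * math.cos(az), range_m * math.sin(az))
    obj = SceneObject(
        footprint=_square(pos, 0.05),
        reflectors=[Reflector(pos, strength=0.8, kind=SPECULAR)],
        label=NON_PLANT,
        id="target",
    )
    pad = 1.0
    bounds = (-pad, -range_m - pad, range_m + pad, range_m + pad)
    scene = Scene(objects=[obj], bounds=bounds)
    scene.validate()
    return scene


def _wall_object(x0: float, x1: float, y_face: float, outward: float,
                 spacing: float, strength: float, obj_id: str) -> SceneObject:
    """A straight wall: reflectors on its inner face y=y_face, footprint behind."""
    n = int(math.floor((x1 - x0) / spacing)) + 1
    xs = x0 + spacing * np.arange(n)
    refl = [Reflector((float(x), y_face), strength, SPECULAR) for x in xs]
    depth = 0.2 * np.sign(outward)
    footprint = [(x0, y_face), (x1, y_face), (x1, y_face + depth), (x0, y_face + depth)]
    if outward < 0:
        footprint = footprint[::-1]
    return SceneObject(footprint=footprint, reflectors=refl, label=NON_PLANT, id=obj_id)


def make_cylinder_object(center: Tuple[float, float], diameter: float,
                         n_points: int = 16, strength: float = 0.8,
                         label: str = NON_PLANT, obj_id: str = "cylinder") -> SceneObject:
    """A cylindrical obstacle as a ring of point reflectors on its surface."""
    cx, cy = center
    r = diameter / 2.0
    ang = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    pts = [(cx + r * math.cos(a), cy + r * math.sin(a)) for a in ang]
    refl = [Reflector(p, strength, SPECULAR) for p in pts]
    return SceneObject(footprint=pts, reflectors=refl, label=label, id=obj_id)


def make_corridor_scene(length_m: float, width_m: float,
                        reflector_spacing_m: float,
                        obstacle: Optional[SceneObject] = None) -> Scene:
    """A straight corridor: two reflector walls flanking a free path.

    The corridor runs along +x from x=0 to x=length with its centerline at
    y=0; walls sit at y = +/- width/2.  Ground-truth contours trace the two
    wall faces ("left" is the +y wall for travel in +x).
    """
    if length_m < 5:
        raise ValueError("length_m must be >= 5")
    if width_m < 2:
        raise ValueError("width_m must be >= 2")
    if not (0.1 <= reflector_spacing_m <= 1.0):
        raise ValueError("reflector_spacing_m must be in [0.1, 1]")
    half = width_m / 2.0
    walls = [
        _wall_object(0.0, length_m, +half, +1.0, reflector_spacing_m, 0.8, "wall_left"),
        _wall_object(0.0, length_m, -half, -1.0, reflector_spacing_m, 0.8, "wall_right"),
    ]
    objects = list(walls)
    if obstacle is not None:
        objects.append(obstacle)
    contours = {
        "left": np.array([[0.0, half], [length_m, half]]),
        "right": np.array([[0.0, -half], [length_m, -half]]),
    }
    bounds = (-1.0, -half - 1.0, length_m + 1.0, half + 1.0)
    scene = Scene(objects=objects, bounds=bounds, ground_truth_contours=contours)
    scene.validate()
    return scene


def make_plant_object(rng: np.random.Generator, center: Tuple[float, float],
                      radius: float = 0.4, obj_id: str = "plant") -> SceneObject:
    """Vegetation-like object: many weak scatterers inside a rough disc."""
    n = int(rng.integers(15, 40))
    ang = rng.uniform(0, 2 * np.pi, n)
    rad = radius * np.sqrt(rng.uniform(0, 1, n))
    cx, cy = center
    pts = [(cx + r * math.cos(a), cy + r * math.sin(a)) for r, a in zip(rad, ang)]
    strengths = rng.uniform(0.02, 0.15, n)
    refl = [Reflector(p, float(s), DIFFUSE) for p, s in zip(pts, strengths)]
    ring = np.linspace(0, 2 * np.pi, 16, endpoint=False)
    footprint = [
        (cx + 1.05 * radius * math.cos(a), cy + 1.05 * radius * math.sin(a))
        for a in ring
    ]
    return SceneObject(footprint=footprint, reflectors=refl, label=PLANT, id=obj_id)


def make_glint_object(rng: np.random.Generator, center: Tuple[float, float],
                      radius: float = 0.3, obj_id: str = "glint") -> SceneObject:
    """Smooth man-made object: one to three strong specular glints."""
    n = int(rng.integers(1, 4))
    cx, cy = center
    offsets = rng.uniform(-0.5 * radius, 0.5 * radius, (n, 2))
    strengths = rng.uniform(0.6, 1.0, n)
    refl = [
        Reflector((cx + float(dx), cy + float(dy)), float(s), SPECULAR)
        for (dx, dy), s in zip(offsets, strengths)
    ]
    ring = np.linspace(0, 2 * np.pi, 16, endpoint=False)
    footprint = [(cx + radius * math.cos(a), cy + radius * math.sin(a)) for a in ring]
    return SceneObject(footprint=footprint, reflectors=refl, label=NON_PLANT, id=obj_id)


def make_object_echo_population(n_per_class: int, seed: int) -> List[Tuple[SceneObject, str]]:
    """A balanced population of plant / non-plant objects (deterministic in seed).

    Plants are clouds of >= 10 weak diffuse scatterers; non-plants are a few
    strong glints on a smooth footprint (maximum plant strength 0.15 is well
    under 0.3 of the maximum non-plant strength 1.0).
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    out: List[Tuple[SceneObject, str]] = []
    for i in range(n_per_class):
        out.append((make_plant_object(rng, (0.0, 0.0), obj_id=f"plant_{i}"), PLANT))
    for i in range(n_per_class):
        out.append((make_glint_object(rng, (0.0, 0.0), obj_id=f"glint_{i}"), NON_PLANT))
    return out


def place_object_scene(obj: SceneObject, range_m: float, azimuth_deg: float) -> Scene:
    """Translate a template object to polar (range, azimuth) and wrap in a Scene."""
    az = math.radians(azimuth_deg)
    dx, dy = range_m * math.cos(az), range_m * math.sin(az)
    moved = SceneObject(
        footprint=[(x + dx, y + dy) for x, y in obj.footprint],
        reflectors=[
            Reflector((r.position[0] + dx, r.position[1] + dy), r.strength, r.kind)
            for r in obj.reflectors
        ],
        label=obj.label,
        id=obj.id,
    )
    ext = range_m + 2.0
    return Scene(objects=[moved], bounds=(-ext, -ext, ext, ext))


def make_dead_end_scene(plant_direction: str = "ahead", distance_m: float = 1.0,
                        seed: int = 0) -> Scene:
    """A dead end: obstacles ahead, left and right, one of which is a plant.

    ``plant_direction`` is one of "ahead", "left", "right"; the other two
    directions get glint (non-plant) obstacles.  The robot is assumed at the
    origin facing +x.
    """
    rng = np.random.default_rng(seed)
    centers = {
        "ahead": (distance_m, 0.0),
        "left": (0.0, distance_m),
        "right": (0.0, -distance_m),
    }
    if plant_direction not in centers:
        raise ValueError("plant_direction must be ahead/left/right")
    objects = []
    for direction, center in centers.items():
        if direction == plant_direction:
            objects.append(make_plant_object(rng, center, radius=0.3,
                                             obj_id=f"plant_{direction}"))
        else:
            objects.append(make_glint_object(rng, center, radius=0.25,
                                             obj_id=f"glint_{direction}"))
    ext = distance_m + 2.0
    scene = Scene(objects=objects, bounds=(-ext, -ext, ext, ext))
    scene.validate()
    return scene
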