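"""Binary occupancy grid with iterative object inflation.

The map is a fixed 2000x2000 grid of 5x5 cm cells, world-anchored with the
mission start pose at the center cell.  Every detected object is stamped as
a 20x20-cell (1x1 m) occupied square; every few steps the squares are joined
into continuous regions by iterated morphological closing.  Cells the robot
has driven through are always free — trajectory clearing is re-applied after
every mutation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .config import MappingConfig
from .perception import DetectedObject

logger = logging.getLogger(__name__)

Pose = Tuple[float, float, float]


@dataclass
class OccupancyMap:
    """World-anchored binary grid; row i <-> y, column j <-> x.

    Cell (i, j) covers the half-open square
    [origin_x + j*res, origin_x + (j+1)*res) x [origin_y + i*res, ...).
    """

    config: MappingConfig = field(default_factory=MappingConfig)
    origin: Tuple[float, float] = (0.0, 0.0)  # world coords of cell (0, 0) corner
    grid: np.ndarray = None
    trajectory: np.ndarray = None
    trajectory_points: List[Tuple[float, float]] = field(default_factory=list)
    pending: List[Tuple[float, float]] = field(default_factory=list)  # world xy buffer

    def __post_init__(self) -> None:
        n = self.config.grid_size
        if self.grid is None:
            self.grid = np.zeros((n, n), dtype=bool)
        if self.trajectory is None:
            self.trajectory = np.zeros((n, n), dtype=bool)

    @classmethod
    def centered_on(cls, start_xy: Tuple[float, float],
                    config: Optional[MappingConfig] = None) -> "OccupancyMap":
        """A map whose center cell contains the given world point."""
        config = config or MappingConfig()
        half = config.grid_size // 2
        origin = (start_xy[0] - half * config.resolution_m,
                  start_xy[1] - half * config.resolution_m)
        return cls(config=config, origin=origin)

    # -- coordinate transforms ---------------------------------------------

    def world_to_cell(self, x: float, y: float) -> Tuple[int, int]:
        j = int(math.floor((x - self.origin[0]) / self.config.resolution_m))
        i = int(math.floor((y - self.origin[1]) / self.config.resolution_m))
        return i, j

    def cell_to_world(self, i: int, j: int) -> Tuple[float, float]:
        """Center of cell (i, j) in world meters."""
        res = self.config.resolution_m
        return self.origin[0] + (j + 0.5) * res, self.origin[1] + (i + 0.5) * res

    def in_grid(self, i: int, j: int) -> bool:
        n = self.config.grid_size
        return 0 <= i < n and 0 <= j < n

    # -- trajectory --------------------------------------------------------

    def mark_trajectory_segment(self, a: Tuple[float, float],
                                b: Tuple[float, float]) -> None:
        """Rasterize the robot's path from a to b as always-free cells."""
        ax, ay = a
        bx, by = b
        if not self.trajectory_points:
            self.trajectory_points.append((ax, ay))
        dist = math.hypot(bx - ax, by - ay)
        n = max(1, int(math.ceil(dist / (self.config.resolution_m / 2))))
        for k in range(n + 1):
            t = k / n
            i, j = self.world_to_cell(ax + t * (bx - ax), ay + t * (by - ay))
            if self.in_grid(i, j):
                self.trajectory[i, j] = True
        self.trajectory_points.append((bx, by))
        self._clear_trajectory()

    def _clear_trajectory(self) -> None:
        self.grid[self.trajectory] = False

    # -- insertion and inflation ------------------------------------------

    def insert_and_inflate(self, objects: Sequence[DetectedObject],
                           robot_pose: Pose) -> None:
        """Stamp each detection as a 20x20-cell occupied square.

        Detections are in the robot frame (range, azimuth relative to the
        robot heading); they are transformed to world cells here.  Objects
        falling outside the grid are dropped with a warning.  Trajectory
        cells are forced free afterward.
        """
        for obj in objects:
            x, y = detection_to_world(obj, robot_pose)
            self.insert_world_point(x, y)
        self._clear_trajectory()

    def insert_world_point(self, x: float, y: float) -> None:
        i, j = self.world_to_cell(x, y)
        if not self.in_grid(i, j):
            logger.warning("detection at (%.2f, %.2f) m outside the grid; dropped", x, y)
            return
        half = self.config.inflate_cells // 2
        n = self.config.grid_size
        i0, i1 = max(0, i - half), min(n, i - half + self.config.inflate_cells)
        j0, j1 = max(0, j - half), min(n, j - half + self.config.inflate_cells)
        self.grid[i0:i1, j0:j1] = True
        self._clear_trajectory()

    def connect_inflated(self, iterations: Optional[int] = None) -> None:
        """Join nearby squares by iterated 3x3 morphological closing."""
        if iterations is None:
            iterations = self.config.closing_iterations
        if iterations <= 0:
            return
        structure = np.ones((3, 3), dtype=bool)
        self.grid = ndimage.binary_closing(
            self.grid, structure=structure, iterations=iterations)
        self._clear_trajectory()

    def update_cycle(self, step_counter: int, new_objects: Sequence[DetectedObject],
                     robot_pose: Pose, every: int = 5) -> bool:
        """Buffer detections; integrate + close every `every` steps.

        Returns True when an integration actually ran.  Detections are
        converted to world points immediately (the pose at acquisition time
        is what anchors them), so buffering is pose-safe.
        """
        for obj in new_objects:
            self.pending.append(detection_to_world(obj, robot_pose))
        if step_counter % max(1, every) != 0:
            return False
        for x, y in self.pending:
            self.insert_world_point(x, y)
        self.pending.clear()
        self.connect_inflated()
        return True

    # -- contour extraction ------------------------------------------------

    def extract_contour(self, side: str) -> np.ndarray:
        """Free-space-facing boundary polyline [m] on one side of the path.

        Boundary cells (occupied cells adjacent to free space) are projected
        onto the traversed trajectory; cells on the requested side are
        binned by arc length and the cell nearest the path wins each bin, so
        the polyline traces the face of the obstacles seen from the free
        corridor.  Returns an (N, 2) array; empty (0, 2) if the side holds
        no occupied cells (a warning is logged).
        """
        if side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if not self.grid.any() or len(self.trajectory_points) < 2:
            logger.warning("no occupied cells or no trajectory; empty contour")
            return np.zeros((0, 2))
        boundary = self.grid & ~ndimage.binary_erosion(self.grid)
        ii, jj = np.nonzero(boundary)
        pts = np.stack([
            self.origin[0] + (jj + 0.5) * self.config.resolution_m,
            self.origin[1] + (ii + 0.5) * self.config.resolution_m,
        ], axis=1)
        traj = np.asarray(self.trajectory_points, dtype=float)
        s_arc, lateral = _project_onto_polyline(pts, traj)
        want = lateral > 0 if side == "left" else lateral < 0
        if not want.any():
            logger.warning("no occupied cells on side %r; empty contour", side)
            return np.zeros((0, 2))
        pts, s_arc, lateral = pts[want], s_arc[want], np.abs(lateral[want])
        bin_w = 5 * self.config.resolution_m
        bins = np.floor(s_arc / bin_w).astype(int)
        best: Dict[int, int] = {}
        for k, (b, d) in enumerate(zip(bins, lateral)):
            if b not in best or d < lateral[best[b]]:
                best[b] = k
        order = sorted(best)
        return pts[[best[b] for b in order]]


def detection_to_world(obj: DetectedObject, pose: Pose) -> Tuple[float, float]:
    """Robot-frame (range, azimuth) detection -> world xy at the given pose."""
    x, y, h = pose
    a = math.radians(h + obj.azimuth_deg)
    return x + obj.range_m * math.cos(a), y + obj.range_m * math.sin(a)


def _project_onto_polyline(points: np.ndarray,
                           poly: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Arc-length position and signed lateral offset of points w.r.t. a polyline.

    Positive lateral = left of travel direction.
    """
    seg_a = poly[:-1]
    seg_v = poly[1:] - poly[:-1]
    seg_len = np.linalg.norm(seg_v, axis=1)
    ok = seg_len > 1e-12
    seg_a, seg_v, seg_len = seg_a[ok], seg_v[ok], seg_len[ok]
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    s_out = np.zeros(len(points))
    lat_out = np.zeros(len(points))
    best_d = np.full(len(points), np.inf)
    for a, v, L, s0 in zip(seg_a, seg_v, seg_len, cum[:-1]):
        w = points - a
        t = np.clip((w @ v) / (L * L), 0.0, 1.0)
        proj = a + t[:, None] * v
        d = np.linalg.norm(points - proj, axis=1)
        closer = d < best_d
        cross = (v[0] * (points[:, 1] - a[1]) - v[1] * (points[:, 0] - a[0])) / L
        s_out[closer] = s0 + t[closer] * L
        lat_out[closer] = cross[closer]
        best_d[closer] = d[closer]
    return s_out, lat_out
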