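"""Digital embryo morphologies.

A morphology is the averaged outline of the embryonic cell layer at one
developmental stage: two closed loops of 2-D points (outer = ectoderm surface,
inner = endoderm-facing surface) plus an anchor index marking the oral pole.
Coordinates are pixel units with the origin at the top-left corner, x running
rightward and y downward.  Loops are stored counter-clockwise starting at the
aboral pole, with the first point repeated at the end to close the loop.  The
inner loop may overlap itself where endoderm and ectoderm are zipped up during
gastrulation, so only the outer loop is required to be simple.

Correspondence between morphologies (same number of points, same landmark
ordering, aligned oral anchors) is a precondition of averaging and
interpolation, not something solved automatically here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from shapely.geometry import LineString


class MorphologyError(ValueError):
    """Raised when a morphology violates its structural invariants."""


def _as_closed_loop(points: Sequence, name: str, *, require_simple: bool = False) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise MorphologyError(f"{name} must be an (N, 2) point array")
    if not np.all(np.isfinite(pts)):
        raise MorphologyError(f"{name} contains non-finite coordinates")
    if not np.allclose(pts[0], pts[-1]):
        raise MorphologyError(f"{name} is not closed (first point != last point)")
    if len(pts) - 1 < 8:
        raise MorphologyError(f"{name} needs at least 8 distinct points, got {len(pts) - 1}")
    pts[-1] = pts[0]  # enforce exact closure
    if require_simple and not LineString(pts).is_simple:
        raise MorphologyError(f"{name} is self-intersecting")
    return pts


@dataclass(frozen=True)
class Morphology:
    """Cell-layer outline of an embryo at one developmental stage.

    Parameters
    ----------
    outer_loop, inner_loop
        Closed loops as (N, 2) arrays with ``loop[0] == loop[-1]``.
    oral_anchor
        Index into the loop path (0-based, < N-1) marking the oral pole.
    stage_hours
        Developmental age in hours post-fertilization (16 degrees C scale).
    """

    outer_loop: np.ndarray
    inner_loop: np.ndarray
    oral_anchor: int
    stage_hours: float

    def __post_init__(self) -> None:
        outer = _as_closed_loop(self.outer_loop, "outer_loop", require_simple=True)
        inner = _as_closed_loop(self.inner_loop, "inner_loop")
        object.__setattr__(self, "outer_loop", outer)
        object.__setattr__(self, "inner_loop", inner)
        if not (0 <= int(self.oral_anchor) < len(outer) - 1):
            raise MorphologyError("oral_anchor outside loop index range")
        object.__setattr__(self, "oral_anchor", int(self.oral_anchor))
        if self.stage_hours < 0:
            raise MorphologyError("stage_hours must be non-negative")
        object.__setattr__(self, "stage_hours", float(self.stage_hours))

    @property
    def n_points(self) -> int:
        """Number of distinct points per loop (closure point excluded)."""
        return len(self.outer_loop) - 1

    def oral_fraction(self) -> float:
        """Arc-length fraction of the oral anchor along the outer loop."""
        lengths = np.linalg.norm(np.diff(self.outer_loop, axis=0), axis=1)
        total = lengths.sum()
        return float(lengths[: self.oral_anchor].sum() / total)

    def translated(self, dx: float, dy: float) -> "Morphology":
        shift = np.array([dx, dy], dtype=float)
        return Morphology(self.outer_loop + shift, self.inner_loop + shift,
                          self.oral_anchor, self.stage_hours)

    def to_dict(self) -> dict:
        return {
            "stage_hours": self.stage_hours,
            "outer_loop": self.outer_loop.tolist(),
            "inner_loop": self.inner_loop.tolist(),
            "oral_anchor": self.oral_anchor,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Morphology":
        return cls(np.asarray(d["outer_loop"], float), np.asarray(d["inner_loop"], float),
                   int(d["oral_anchor"]), float(d["stage_hours"]))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_json(cls, path: str | Path) -> "Morphology":
        return cls.from_dict(json.loads(Path(path).read_text()))


def path_length(loop: np.ndarray) -> float:
    """Total arc length of a polyline."""
    loop = np.asarray(loop, float)
    return float(np.linalg.norm(np.diff(loop, axis=0), axis=1).sum())


def resample_path(loop: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed loop at ``n`` points equally spaced by arc length.

    Returns an ``(n + 1, 2)`` array whose last row repeats the first so the
    result is again a closed loop.  The start point of the input is preserved
    as the start of the output.
    """
    if n < 8:
        raise MorphologyError("resampling needs n >= 8")
    pts = np.asarray(loop, dtype=float)
    if not np.allclose(pts[0], pts[-1]):
        pts = np.vstack([pts, pts[0]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = seg.sum()
    if total <= 0:
        raise MorphologyError("cannot resample a zero-length path")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, total, n + 1)
    x = np.interp(targets, cum, pts[:, 0])
    y = np.interp(targets, cum, pts[:, 1])
    out = np.column_stack([x, y])
    out[-1] = out[0]
    return out


def average_geometries(morphologies: Sequence[Morphology]) -> Morphology:
    """Point-wise average of >= 2 corresponding morphologies.

    All inputs must have the same number of points per loop and the same oral
    anchor index; the averaging assumes the landmarks already correspond.
    The stage of the result is the mean of the input stages.
    """
    morphs = list(morphologies)
    if len(morphs) < 2:
        raise MorphologyError("averaging needs at least 2 morphologies")
    n = morphs[0].n_points
    anchor = morphs[0].oral_anchor
    for m in morphs[1:]:
        if m.n_points != n or len(m.inner_loop) != len(morphs[0].inner_loop):
            raise MorphologyError("point counts differ; no automatic correspondence solving")
        if m.oral_anchor != anchor:
            raise MorphologyError("oral anchors differ; align landmarks before averaging")
    outer = np.mean([m.outer_loop for m in morphs], axis=0)
    inner = np.mean([m.inner_loop for m in morphs], axis=0)
    stage = float(np.mean([m.stage_hours for m in morphs]))
    return Morphology(outer, inner, anchor, stage)


def interpolate_morphologies(m1: Morphology, m2: Morphology, alpha: float) -> Morphology:
    """Linear interpolation between two corresponding morphologies.

    ``alpha = 0`` returns ``m1`` exactly and ``alpha = 1`` returns ``m2``;
    stage_hours is interpolated the same way.
    """
    if not 0.0 <= alpha <= 1.0:
        raise MorphologyError("alpha must lie in [0, 1]")
    if m1.n_points != m2.n_points or len(m1.inner_loop) != len(m2.inner_loop):
        raise MorphologyError("point counts differ; cannot interpolate")
    if m1.oral_anchor != m2.oral_anchor:
        raise MorphologyError("oral anchors differ; cannot interpolate")
    outer = (1 - alpha) * m1.outer_loop + alpha * m2.outer_loop
    inner = (1 - alpha) * m1.inner_loop + alpha * m2.inner_loop
    stage = (1 - alpha) * m1.stage_hours + alpha * m2.stage_hours
    return Morphology(outer, inner, m1.oral_anchor, stage)


def annulus_morphology(center: tuple[float, float] = (100.0, 100.0),
                       r_inner: float = 40.0,
                       r_outer: float = 60.0,
                       n_points: int = 128,
                       stage_hours: float = 24.0) -> Morphology:
    """Idealized circular cell layer (annulus) used for synthesis and tests.

    Loops start at the aboral pole (leftmost point) and run counter-clockwise
    in image coordinates; the oral pole sits at the rightmost point, i.e. at
    arc fraction 0.5, matching the oriented-oral-right convention.
    """
    if r_inner <= 0 or r_outer <= r_inner:
        raise MorphologyError("need 0 < r_inner < r_outer")
    cx, cy = center
    theta = np.pi + np.linspace(0.0, 2 * np.pi, n_points + 1)
    outer = np.column_stack([cx + r_outer * np.cos(theta), cy + r_outer * np.sin(theta)])
    inner = np.column_stack([cx + r_inner * np.cos(theta), cy + r_inner * np.sin(theta)])
    outer[-1] = outer[0]
    inner[-1] = inner[0]
    return Morphology(outer, inner, oral_anchor=n_points // 2, stage_hours=stage_hours)
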