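"""2D shape supports for phantom compartments (voxel-center convention).

Coordinates are in mm; a voxel (i, j) has its center at
((i + 0.5) * dy, (j + 0.5) * dx).  Masks are produced by testing voxel
centers against the analytic shape, so every voxel belongs to at most one
support provided the shapes themselves are disjoint.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def voxel_centers(shape: tuple[int, int], voxel_size: tuple[float, float]):
    ny, nx = shape
    dy, dx = voxel_size
    y = (np.arange(ny) + 0.5) * dy
    x = (np.arange(nx) + 0.5) * dx
    return np.meshgrid(y, x, indexing="ij")


@dataclass(frozen=True)
class Shape2D:
    def mask(self, shape: tuple[int, int], voxel_size: tuple[float, float]) -> np.ndarray:
        raise NotImplementedError


@dataclass(frozen=True)
class Disk(Shape2D):
    center: tuple[float, float]  # (y, x) mm
    radius: float

    def mask(self, shape, voxel_size):
        yy, xx = voxel_centers(shape, voxel_size)
        return (yy - self.center[0]) ** 2 + (xx - self.center[1]) ** 2 <= self.radius**2


@dataclass(frozen=True)
class Ellipse(Shape2D):
    center: tuple[float, float]
    semi_axes: tuple[float, float]  # (ry, rx) mm

    def mask(self, shape, voxel_size):
        yy, xx = voxel_centers(shape, voxel_size)
        ry, rx = self.semi_axes
        return ((yy - self.center[0]) / ry) ** 2 + ((xx - self.center[1]) / rx) ** 2 <= 1.0


@dataclass(frozen=True)
class Annulus(Shape2D):
    """Ring, e.g. the LV myocardium around the blood pool."""

    center: tuple[float, float]
    r_inner: float
    r_outer: float

    def __post_init__(self):
        if not 0 <= self.r_inner < self.r_outer:
            raise ValueError("annulus requires 0 <= r_inner < r_outer")

    def mask(self, shape, voxel_size):
        yy, xx = voxel_centers(shape, voxel_size)
        r2 = (yy - self.center[0]) ** 2 + (xx - self.center[1]) ** 2
        return (r2 > self.r_inner**2) & (r2 <= self.r_outer**2)


@dataclass(frozen=True)
class Wedge(Shape2D):
    """Angular sector of an annulus — the interventricular-septum stand-in."""

    center: tuple[float, float]
    r_inner: float
    r_outer: float
    theta0: float  # radians, measured from +x axis
    theta1: float

    def mask(self, shape, voxel_size):
        yy, xx = voxel_centers(shape, voxel_size)
        dy = yy - self.center[0]
        dx = xx - self.center[1]
        r2 = dy**2 + dx**2
        ring = (r2 > self.r_inner**2) & (r2 <= self.r_outer**2)
        theta = np.mod(np.arctan2(dy, dx), 2 * np.pi)
        t0 = np.mod(self.theta0, 2 * np.pi)
        t1 = np.mod(self.theta1, 2 * np.pi)
        if t0 <= t1:
            ang = (theta >= t0) & (theta < t1)
        else:  # wraps through 0
            ang = (theta >= t0) | (theta < t1)
        return ring & ang
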