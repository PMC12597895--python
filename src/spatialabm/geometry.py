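"""Planar geometries, area-uniform samplers, and affine coordinate transforms.

All lengths are micrometres (µm). Geometries are immutable value objects;
samplers draw from a caller-supplied :class:`numpy.random.Generator` so that
every placement is reproducible from a seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np

from .errors import ValidationError

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class Disc:
    """Closed disc of given ``radius`` around ``center``."""

    center: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValidationError(f"disc radius must be > 0, got {self.radius}")

    def contains(self, xy: np.ndarray) -> np.ndarray:
        d2 = (xy[:, 0] - self.center[0]) ** 2 + (xy[:, 1] - self.center[1]) ** 2
        return d2 <= self.radius**2 * (1 + 1e-12)

    @property
    def bounds(self) -> "Rectangle":
        cx, cy = self.center
        r = self.radius
        return Rectangle(cx - r, cy - r, cx + r, cy + r)


@dataclass(frozen=True)
class Annulus:
    """Closed annulus ``r_inner <= r <= r_outer`` around ``center``."""

    center: tuple[float, float]
    r_inner: float
    r_outer: float

    def __post_init__(self) -> None:
        if not (0 <= self.r_inner < self.r_outer):
            raise ValidationError(
                f"annulus requires 0 <= r_inner < r_outer, got "
                f"[{self.r_inner}, {self.r_outer}]"
            )

    def contains(self, xy: np.ndarray) -> np.ndarray:
        d2 = (xy[:, 0] - self.center[0]) ** 2 + (xy[:, 1] - self.center[1]) ** 2
        return (d2 >= self.r_inner**2 * (1 - 1e-12)) & (
            d2 <= self.r_outer**2 * (1 + 1e-12)
        )

    @property
    def bounds(self) -> "Rectangle":
        cx, cy = self.center
        r = self.r_outer
        return Rectangle(cx - r, cy - r, cx + r, cy + r)


@dataclass(frozen=True)
class Rectangle:
    """Axis-aligned rectangle; also used for simulation domain bounds."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValidationError(
                f"degenerate rectangle [{self.x_min},{self.x_max}]x"
                f"[{self.y_min},{self.y_max}]"
            )

    def contains(self, xy: np.ndarray) -> np.ndarray:
        return (
            (xy[:, 0] >= self.x_min)
            & (xy[:, 0] <= self.x_max)
            & (xy[:, 1] >= self.y_min)
            & (xy[:, 1] <= self.y_max)
        )

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    @property
    def bounds(self) -> "Rectangle":
        return self

    def padded(self, pad: float) -> "Rectangle":
        return Rectangle(
            self.x_min - pad, self.y_min - pad, self.x_max + pad, self.y_max + pad
        )


Geometry = Union[Disc, Annulus, Rectangle]


def sample_uniform_in_geometry(
    n: int, geom: Geometry, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` points uniform by area in ``geom``; returns an (n, 2) array.

    Disc sampling uses the inverse-CDF radius r = R * sqrt(u); the annulus
    uses r = sqrt(r_in^2 + u * (r_out^2 - r_in^2)); rectangles are sampled
    coordinate-wise. Angles are uniform on [0, 2*pi).
    """
    if n < 0:
        raise ValidationError(f"sample size must be >= 0, got {n}")
    if n == 0:
        return np.empty((0, 2), dtype=float)
    if isinstance(geom, Disc):
        u = rng.random(n)
        theta = rng.random(n) * TWO_PI
        r = geom.radius * np.sqrt(u)
        return np.column_stack(
            (geom.center[0] + r * np.cos(theta), geom.center[1] + r * np.sin(theta))
        )
    if isinstance(geom, Annulus):
        u = rng.random(n)
        theta = rng.random(n) * TWO_PI
        r = np.sqrt(geom.r_inner**2 + u * (geom.r_outer**2 - geom.r_inner**2))
        return np.column_stack(
            (geom.center[0] + r * np.cos(theta), geom.center[1] + r * np.sin(theta))
        )
    if isinstance(geom, Rectangle):
        x = rng.uniform(geom.x_min, geom.x_max, n)
        y = rng.uniform(geom.y_min, geom.y_max, n)
        return np.column_stack((x, y))
    raise ValidationError(f"unsupported geometry: {geom!r}")


@dataclass(frozen=True)
class AffineTransform2D:
    """Similarity transform p -> scale * R(rotation) @ p + translation."""

    scale: float = 1.0
    rotation: float = 0.0  # radians
    translation: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValidationError(f"scale must be > 0, got {self.scale}")

    def apply(self, xy: np.ndarray) -> np.ndarray:
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        x = self.scale * (c * xy[:, 0] - s * xy[:, 1]) + self.translation[0]
        y = self.scale * (s * xy[:, 0] + c * xy[:, 1]) + self.translation[1]
        return np.column_stack((x, y))

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls()


def reflect_into(xy: np.ndarray, rect: Rectangle) -> None:
    """Reflect out-of-bounds rows of ``xy`` back into ``rect``, in place.

    Rows already inside the rectangle are left bit-identical (important for
    frozen-system reproducibility); reflection folds arbitrarily large
    excursions.
    """
    for axis, (lo, hi) in enumerate(
        ((rect.x_min, rect.x_max), (rect.y_min, rect.y_max))
    ):
        col = xy[:, axis]
        out = (col < lo) | (col > hi)
        if not out.any():
            continue
        width = hi - lo
        folded = np.mod(col[out] - lo, 2.0 * width)
        folded = np.where(folded > width, 2.0 * width - folded, folded)
        xy[out, axis] = lo + folded
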