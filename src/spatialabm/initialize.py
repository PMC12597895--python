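"""Initial-condition builders for the tumor-immune model.

Three strategies mirror the three study conditions:

* **well-mixed** — every cell type uniform by area in one disc;
* **structured** — epithelial types (cancer + healthy) uniform in an inner
  disc, immune types uniform in a surrounding annulus;
* **spatial-informed** — agents placed at the measured coordinates of a
  spatial cell table through a pure affine map, with no jitter or
  resampling, so the virtual tissue matches the measured one exactly at t=0.

A fourth, generic builder places cells from a *non-spatial* table into
user-chosen geometries in proportion to their measured abundances.

Overlaps are not resolved here; the repulsion mechanics relax them from the
first simulation step, which preserves the measured positions at t=0.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .errors import ValidationError
from .geometry import (
    AffineTransform2D,
    Annulus,
    Disc,
    Geometry,
    Rectangle,
    sample_uniform_in_geometry,
)
from .io import CellTable


@dataclass
class InitialState:
    """Placed model cells ready for simulation or export."""

    xy: np.ndarray  # (n, 2) float µm
    types: np.ndarray  # (n,) str model type names
    domain: Rectangle

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        self.types = np.asarray(self.types, dtype=object)
        if len(self.types) != len(self.xy):
            raise ValidationError("types and xy length mismatch")
        if len(self.xy) and not self.domain.contains(self.xy).all():
            n_out = int((~self.domain.contains(self.xy)).sum())
            raise ValidationError(f"{n_out} cells outside the domain bounds")

    def __len__(self) -> int:
        return len(self.types)

    def counts(self) -> dict[str, int]:
        names, counts = np.unique(self.types.astype(str), return_counts=True)
        return dict(zip(names.tolist(), counts.tolist()))


def _domain_from_points(xy: np.ndarray, padding: float) -> Rectangle:
    if len(xy) == 0:
        return Rectangle(-padding, -padding, padding, padding)
    return Rectangle(
        float(xy[:, 0].min() - padding),
        float(xy[:, 1].min() - padding),
        float(xy[:, 0].max() + padding),
        float(xy[:, 1].max() + padding),
    )


def _check_counts(counts: Mapping[str, int]) -> None:
    for name, n in counts.items():
        if n < 0:
            raise ValidationError(f"negative count for type {name!r}: {n}")


def init_well_mixed(
    counts: Mapping[str, int],
    disc: Disc,
    rng: np.random.Generator,
    domain: Optional[Rectangle] = None,
) -> InitialState:
    """All cell types uniform by area in one disc.

    Types are placed in sorted-name order so a fixed seed gives a fixed
    state. ``domain`` defaults to the disc's bounding box padded by 50 µm.
    """
    if not isinstance(disc, Disc):
        raise ValidationError("well-mixed initialization requires a disc")
    _check_counts(counts)
    if domain is None:
        domain = disc.bounds.padded(50.0)
    xs, ts = [], []
    for name in sorted(counts):
        pts = sample_uniform_in_geometry(counts[name], disc, rng)
        xs.append(pts)
        ts.extend([name] * counts[name])
    xy = np.vstack(xs) if xs else np.empty((0, 2))
    return InitialState(xy=xy, types=np.array(ts, dtype=object), domain=domain)


def init_structured(
    counts: Mapping[str, int],
    inner: Disc,
    ring: Annulus,
    epithelial_types: set[str],
    immune_types: set[str],
    rng: np.random.Generator,
    domain: Optional[Rectangle] = None,
) -> InitialState:
    """Epithelium (cancer + healthy interleaved) in a disc, immune in an annulus.

    The disc and annulus must be concentric with the annulus starting at or
    outside the disc edge, and every counted type must belong to exactly one
    of the two compartments.
    """
    if inner.center != ring.center:
        raise ValidationError("inner disc and annulus must share a center")
    if ring.r_inner < inner.radius:
        raise ValidationError(
            f"annulus r_inner ({ring.r_inner}) must be >= disc radius "
            f"({inner.radius})"
        )
    _check_counts(counts)
    both = epithelial_types & immune_types
    if both:
        raise ValidationError(f"types in both compartments: {sorted(both)}")
    missing = set(counts) - epithelial_types - immune_types
    if missing:
        raise ValidationError(f"types in neither compartment: {sorted(missing)}")
    if domain is None:
        domain = ring.bounds.padded(50.0)
    xs, ts = [], []
    for name in sorted(counts):
        geom: Geometry = inner if name in epithelial_types else ring
        pts = sample_uniform_in_geometry(counts[name], geom, rng)
        xs.append(pts)
        ts.extend([name] * counts[name])
    xy = np.vstack(xs) if xs else np.empty((0, 2))
    return InitialState(xy=xy, types=np.array(ts, dtype=object), domain=domain)


def init_spatial_informed(
    table: CellTable,
    transform: Optional[AffineTransform2D] = None,
    domain_padding: float = 50.0,
) -> InitialState:
    """Place one agent per measured cell at its (affinely mapped) coordinates.

    No jitter, no resampling: with the identity transform output positions
    are bit-identical to the inputs. When ``transform`` is omitted the
    measured centroid is translated to the origin (scale 1, no rotation),
    which only re-frames the data. Domain bounds are the transformed
    bounding box padded by ``domain_padding``.
    """
    if not table.is_spatial:
        raise ValidationError("spatial-informed initialization needs coordinates")
    if transform is None:
        cx, cy = (
            (float(table.xy[:, 0].mean()), float(table.xy[:, 1].mean()))
            if len(table)
            else (0.0, 0.0)
        )
        transform = AffineTransform2D(translation=(-cx, -cy))
    xy = transform.apply(table.xy)
    domain = _domain_from_points(xy, domain_padding)
    return InitialState(
        xy=xy, types=table.type_labels.copy(), domain=domain
    )


def largest_remainder_quotas(
    weights: Mapping[str, int], total: int
) -> dict[str, int]:
    """Apportion ``total`` seats proportionally to integer ``weights``.

    Largest-remainder (Hamilton) method; remainder ties broken by
    lexicographic type-name order so the result is deterministic.
    """
    if total < 0:
        raise ValidationError(f"total must be >= 0, got {total}")
    wsum = sum(weights.values())
    if wsum <= 0:
        raise ValidationError("weights must have a positive sum")
    names = sorted(weights)
    quotas = {n: total * weights[n] / wsum for n in names}
    placed = {n: int(np.floor(quotas[n])) for n in names}
    seats = total - sum(placed.values())
    by_remainder = sorted(names, key=lambda n: (-(quotas[n] - placed[n]), n))
    for n in by_remainder[:seats]:
        placed[n] += 1
    return placed


def abundance_placement(
    table: CellTable,
    total_n: int,
    assignments: Mapping[str, Geometry],
    rng: np.random.Generator,
    domain: Optional[Rectangle] = None,
) -> InitialState:
    """Place ``total_n`` cells by the table's relative type abundances.

    For non-spatial data: each type receives round(total_n * share) seats
    (largest-remainder corrected so counts sum exactly to ``total_n``) and
    is sampled uniformly in its assigned geometry.
    """
    if total_n > 0 and len(table) == 0:
        raise ValidationError("cannot place cells from an empty table")
    abundances = table.abundances()
    for name in abundances:
        if name not in assignments:
            raise ValidationError(f"no geometry assigned for type {name!r}")
    if total_n == 0:
        dom = domain or Rectangle(-50.0, -50.0, 50.0, 50.0)
        return InitialState(
            xy=np.empty((0, 2)), types=np.array([], dtype=object), domain=dom
        )
    placed = largest_remainder_quotas(abundances, total_n)
    if domain is None:
        bounds = [assignments[n].bounds for n in sorted(abundances)]
        domain = Rectangle(
            min(b.x_min for b in bounds) - 50.0,
            min(b.y_min for b in bounds) - 50.0,
            max(b.x_max for b in bounds) + 50.0,
            max(b.y_max for b in bounds) + 50.0,
        )
    xs, ts = [], []
    for name in sorted(abundances):
        pts = sample_uniform_in_geometry(placed[name], assignments[name], rng)
        xs.append(pts)
        ts.extend([name] * placed[name])
    return InitialState(
        xy=np.vstack(xs), types=np.array(ts, dtype=object), domain=domain
    )
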