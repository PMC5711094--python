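"""Core 2D data model: dose/reading planes, 1D profiles, rectangular ROIs.

Conventions (used everywhere in this package):

* physical coordinates are in millimetres;
* array axis 0 is *y* (in-plane, increasing toward gun), axis 1 is *x*
  (cross-plane);
* ``origin`` is the physical coordinate of the centre of pixel ``(0, 0)``,
  so pixel ``(i, j)`` sits at ``origin + (i * spacing_y, j * spacing_x)``;
* ROIs are half-open: a pixel centre belongs to the ROI iff
  ``x_min <= x < x_max`` and ``y_min <= y < y_max``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = ["DosePlane", "Profile", "ROI", "extract_profile", "roi_stats"]

#: allowed values for :attr:`DosePlane.quantity`
QUANTITIES = ("dose", "reading", "od", "gamma")

AXES = ("cross-plane", "in-plane")


@dataclass(frozen=True)
class DosePlane:
    """A 2D scalar grid (dose in Gy, detector reading, OD, or a gamma map).

    Parameters
    ----------
    values
        2D float array, at least 2x2, all finite.
    spacing
        ``(row, col)`` pixel pitch in mm, both strictly positive.
    origin
        Physical ``(y, x)`` coordinate in mm of the centre of pixel (0, 0).
    quantity
        One of ``{"dose", "reading", "od", "gamma"}``.
    meta
        Free-form annotations (delivery metadata, provenance); never used
        in computation.
    """

    values: np.ndarray
    spacing: tuple[float, float]
    origin: tuple[float, float] = (0.0, 0.0)
    quantity: str = "dose"
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] < 2 or values.shape[1] < 2:
            raise ValueError(f"plane must be at least 2x2, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("plane values must be finite")
        spacing = (float(self.spacing[0]), float(self.spacing[1]))
        if spacing[0] <= 0 or spacing[1] <= 0:
            raise ValueError(f"spacing must be positive, got {spacing}")
        if self.quantity not in QUANTITIES:
            raise ValueError(f"quantity must be one of {QUANTITIES}, got {self.quantity!r}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", (float(self.origin[0]), float(self.origin[1])))

    # -- geometry ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def ys(self) -> np.ndarray:
        """Physical y coordinate (mm) of each row centre."""
        return self.origin[0] + np.arange(self.shape[0]) * self.spacing[0]

    @property
    def xs(self) -> np.ndarray:
        """Physical x coordinate (mm) of each column centre."""
        return self.origin[1] + np.arange(self.shape[1]) * self.spacing[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(x_min, x_max, y_min, y_max) spanned by pixel centres."""
        return (self.xs[0], self.xs[-1], self.ys[0], self.ys[-1])

    def same_geometry(self, other: "DosePlane", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def with_values(self, values: np.ndarray, quantity: str | None = None) -> "DosePlane":
        """Copy of this plane with new values on the same grid."""
        return replace(
            self, values=np.asarray(values, float), quantity=quantity or self.quantity
        )

    @classmethod
    def centered(
        cls,
        values: np.ndarray,
        spacing: tuple[float, float],
        quantity: str = "dose",
        meta: Mapping[str, object] | None = None,
    ) -> "DosePlane":
        """Build a plane whose physical origin is the grid centre."""
        values = np.asarray(values, float)
        origin = (
            -(values.shape[0] - 1) / 2 * spacing[0],
            -(values.shape[1] - 1) / 2 * spacing[1],
        )
        return cls(values, spacing, origin, quantity, meta or {})


@dataclass(frozen=True)
class Profile:
    """A 1D physical profile: strictly increasing positions (mm) + values."""

    positions: np.ndarray
    values: np.ndarray
    axis: str = "cross-plane"

    def __post_init__(self) -> None:
        positions = np.asarray(self.positions, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if positions.ndim != 1 or positions.shape != values.shape:
            raise ValueError("positions and values must be 1D and equal length")
        if not np.all(np.diff(positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if self.axis not in AXES:
            raise ValueError(f"axis must be one of {AXES}, got {self.axis!r}")
        object.__setattr__(self, "positions", positions)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class ROI:
    """Axis-aligned rectangle in physical mm, half-open on the max edges."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(f"degenerate ROI: {self}")

    def translated(self, dx: float, dy: float) -> "ROI":
        return ROI(self.x_min + dx, self.x_max + dx, self.y_min + dy, self.y_max + dy)

    def mask(self, plane: DosePlane) -> np.ndarray:
        """Boolean mask of pixels whose centres fall inside the ROI."""
        in_x = (plane.xs >= self.x_min) & (plane.xs < self.x_max)
        in_y = (plane.ys >= self.y_min) & (plane.ys < self.y_max)
        return np.outer(in_y, in_x)


def extract_profile(
    plane: DosePlane,
    axis: str,
    position: float,
    averaging_width: float = 0.0,
) -> Profile:
    """Extract a 1D profile from a plane, averaged across a band.

    ``axis="cross-plane"`` runs along x at the given y ``position``;
    ``axis="in-plane"`` runs along y at the given x. The band of half-width
    ``averaging_width / 2`` around ``position`` must lie inside the plane.
    """
    if axis not in AXES:
        raise ValueError(f"axis must be one of {AXES}, got {axis!r}")
    if averaging_width < 0:
        raise ValueError("averaging_width must be >= 0")
    half = averaging_width / 2.0
    perp = plane.ys if axis == "cross-plane" else plane.xs
    lo, hi = position - half, position + half
    if lo < perp[0] - 1e-9 or hi > perp[-1] + 1e-9:
        raise ValueError(
            f"band [{lo:g}, {hi:g}] mm outside plane range [{perp[0]:g}, {perp[-1]:g}] mm"
        )
    band = (perp >= lo - 1e-9) & (perp <= hi + 1e-9)
    if not band.any():  # zero width between two samples: take nearest line
        band[np.argmin(np.abs(perp - position))] = True
    if axis == "cross-plane":
        values = plane.values[band, :].mean(axis=0)
        positions = plane.xs
    else:
        values = plane.values[:, band].mean(axis=1)
        positions = plane.ys
    return Profile(positions, values, axis)


def roi_stats(plane: DosePlane, roi: ROI) -> tuple[float, float, int]:
    """Mean, sample SD (n-1 denominator) and count of pixels inside ``roi``.

    Raises ``ValueError`` if the ROI covers no pixel centres; SD is reported
    as NaN when only a single pixel falls inside.
    """
    mask = roi.mask(plane)
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"ROI {roi} contains no pixel centres")
    pix = plane.values[mask]
    mean = float(pix.mean())
    sd = float(pix.std(ddof=1)) if n >= 2 else float("nan")
    return mean, sd, n
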