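"""Synthetic acquisition generators with known ground truth.

Every generator is a pure function of its spec and seed, and returns the
ground truth alongside the data so downstream analyses can be validated
without re-deriving the truth from the generated image.

Beam planes use an analytic box-convolved-with-Gaussian edge (error
function penumbra). FFF mode multiplies in a linear radial falloff
``peak * (1 - k*r)``, clipped at zero, which captures the forward-peaked
shape without attempting a physical source model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import erf

from .film import CalibrationCurve
from .grid import DosePlane, ROI

__all__ = [
    "BeamModel",
    "PicketFenceSpec",
    "StripPatternSpec",
    "CaseTableSpec",
    "FilmScan",
    "gen_beam_plane",
    "gen_picket_fence",
    "gen_strip_pair",
    "gen_film_scan",
    "gen_case_table",
    "gen_plane_pair",
]


def _box_transmission(u: np.ndarray, half_width: float, sigma: float) -> np.ndarray:
    """Ideal box of half-width ``half_width`` convolved with a Gaussian."""
    if sigma <= 0:
        return ((u >= -half_width) & (u < half_width)).astype(float)
    s = sigma * np.sqrt(2.0)
    return 0.5 * (erf((half_width - u) / s) + erf((half_width + u) / s))


@dataclass(frozen=True)
class BeamModel:
    """Open-field fluence model: flat (FF) or radially peaked (FFF)."""

    mode: str = "FF"
    field_size: tuple[float, float] = (140.0, 140.0)  # (x, y) mm
    peak: float = 1.0
    penumbra_sigma: float = 1.5  # mm
    k: float | None = None  # per-mm FFF falloff slope

    def __post_init__(self) -> None:
        if self.mode not in ("FF", "FFF"):
            raise ValueError(f"mode must be FF or FFF, got {self.mode!r}")
        if self.penumbra_sigma <= 0:
            raise ValueError("penumbra_sigma must be > 0")
        k = self.k
        if self.mode == "FF":
            if k not in (None, 0.0):
                raise ValueError("FF beams must have k = 0")
            k = 0.0
        elif k is None:
            k = 0.003  # 70% of centre value at 100 mm off-axis
        if k < 0:
            raise ValueError("k must be >= 0")
        object.__setattr__(self, "k", float(k))
        object.__setattr__(
            self, "field_size", (float(self.field_size[0]), float(self.field_size[1]))
        )

    def fluence(self, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        """Noiseless fluence sampled on the tensor grid ``ys x xs``."""
        tx = _box_transmission(np.asarray(xs, float), self.field_size[0] / 2, self.penumbra_sigma)
        ty = _box_transmission(np.asarray(ys, float), self.field_size[1] / 2, self.penumbra_sigma)
        out = self.peak * np.outer(ty, tx)
        if self.k > 0:
            r = np.hypot.outer(np.asarray(ys, float), np.asarray(xs, float))
            out = out * np.clip(1.0 - self.k * r, 0.0, None)
        return out


@dataclass(frozen=True)
class PicketFenceSpec:
    """Geometry of a picket-fence delivery: narrow gaps at regular spacing."""

    gap: float = 1.0  # mm, open picket width
    spacing: float = 15.0  # mm, picket-to-picket pitch
    count: int = 5
    offsets: tuple[float, ...] | None = None  # per-picket position errors, mm
    blur_sigma: float = 0.3  # mm, detector/source blur
    noise_sd: float = 0.0  # multiplicative noise fraction
    background: float = 0.02  # inter-picket leaf transmission

    def __post_init__(self) -> None:
        if self.gap <= 0:
            raise ValueError("gap must be > 0")
        if self.spacing <= self.gap:
            raise ValueError("spacing must exceed gap")
        if self.count < 1:
            raise ValueError("count must be >= 1")
        offsets = self.offsets
        if offsets is None:
            offsets = (0.0,) * self.count
        offsets = tuple(float(o) for o in offsets)
        if len(offsets) != self.count:
            raise ValueError(f"need {self.count} offsets, got {len(offsets)}")
        object.__setattr__(self, "offsets", offsets)

    @property
    def centers(self) -> np.ndarray:
        """True picket centres (mm), including injected offsets."""
        base = (np.arange(self.count) - (self.count - 1) / 2) * self.spacing
        return base + np.asarray(self.offsets)


@dataclass(frozen=True)
class StripPatternSpec:
    """Equal-dose strip delivery: n contiguous strips along x."""

    n_strips: int = 7
    strip_width: float = 18.0  # mm
    scales: tuple[float, ...] | None = None  # per-strip true fluence factors
    noise_sd: float = 0.0
    # kept small so edge blur is negligible inside the default 60% ROIs
    blur_sigma: float = 0.5
    annotations: dict = field(default_factory=dict)  # delivery metadata, not simulated

    def __post_init__(self) -> None:
        if self.n_strips < 1:
            raise ValueError("n_strips must be >= 1")
        if self.strip_width <= 0:
            raise ValueError("strip_width must be > 0")
        scales = self.scales
        if scales is None:
            scales = (1.0,) * self.n_strips
        scales = tuple(float(s) for s in scales)
        if len(scales) != self.n_strips:
            raise ValueError(f"need {self.n_strips} scales, got {len(scales)}")
        if any(s <= 0 for s in scales):
            raise ValueError("scale factors must be > 0")
        object.__setattr__(self, "scales", scales)

    @property
    def edges(self) -> np.ndarray:
        """Strip boundary x positions (mm), centred on the axis."""
        total = self.n_strips * self.strip_width
        return -total / 2 + np.arange(self.n_strips + 1) * self.strip_width


@dataclass(frozen=True)
class CaseTableSpec:
    """Per-case point-dose measurement table with known bias and spread."""

    n_cases: int = 5
    bias: float = 0.0  # systematic difference, fraction of prescription
    sd: float = 0.0  # random difference SD
    prescription: float = 2.0  # Gy

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.prescription <= 0:
            raise ValueError("prescription must be > 0")


# ---------------------------------------------------------------------------


def _apply_mult_noise(values: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    if noise_sd <= 0:
        return values
    return values * (1.0 + rng.normal(0.0, noise_sd, size=values.shape))


def gen_beam_plane(
    model: BeamModel,
    spacing: float | tuple[float, float] = 1.0,
    margin: float = 20.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> DosePlane:
    """Open-field plane for ``model`` on a centred grid.

    The grid covers the field plus ``margin`` mm on every side. Noise is
    multiplicative Gaussian with fractional SD ``noise_sd``.
    """
    if np.isscalar(spacing):
        spacing = (float(spacing), float(spacing))
    rng = np.random.default_rng(seed)
    nx = int(np.ceil((model.field_size[0] + 2 * margin) / spacing[1])) + 1
    ny = int(np.ceil((model.field_size[1] + 2 * margin) / spacing[0])) + 1
    xs = (np.arange(nx) - (nx - 1) / 2) * spacing[1]
    ys = (np.arange(ny) - (ny - 1) / 2) * spacing[0]
    values = _apply_mult_noise(model.fluence(xs, ys), noise_sd, rng)
    return DosePlane.centered(values, spacing, quantity="reading", meta={"beam_mode": model.mode})


def gen_picket_fence(
    spec: PicketFenceSpec,
    beam: BeamModel,
    spacing: float | tuple[float, float] = 0.25,
    seed: int | None = None,
) -> tuple[DosePlane, np.ndarray]:
    """Picket-fence image plus the true picket centre positions (mm).

    Pickets are vertical (along y) open gaps in an otherwise nearly-closed
    MLC bank, modulating the open-field fluence of ``beam``. Injected
    per-picket ``offsets`` shift the true centres, which are returned.
    """
    centers = spec.centers
    if np.any(np.diff(centers) <= spec.gap):
        raise ValueError("pickets overlap: adjacent centres closer than the gap width")
    if np.max(np.abs(centers)) + spec.gap / 2 > beam.field_size[0] / 2:
        raise ValueError("pickets do not fit inside the beam field")
    if np.isscalar(spacing):
        spacing = (float(spacing), float(spacing))
    rng = np.random.default_rng(seed)

    nx = int(np.ceil((centers[-1] - centers[0] + spec.spacing + 20.0) / spacing[1])) + 1
    ny = int(np.ceil(min(beam.field_size[1], 60.0) / spacing[0])) + 1
    xs = (np.arange(nx) - (nx - 1) / 2) * spacing[1]
    ys = (np.arange(ny) - (ny - 1) / 2) * spacing[0]

    pattern = np.full(nx, spec.background)
    for c in centers:
        pattern = pattern + (1.0 - spec.background) * _box_transmission(
            xs - c, spec.gap / 2, spec.blur_sigma
        )
    values = beam.fluence(xs, ys) * pattern[np.newaxis, :]
    values = _apply_mult_noise(values, spec.noise_sd, rng)
    plane = DosePlane.centered(values, spacing, quantity="reading", meta={"beam_mode": beam.mode})
    return plane, centers


def gen_strip_pair(
    spec: StripPatternSpec,
    beam: BeamModel,
    spacing: float | tuple[float, float] = 0.5,
    seed: int | None = None,
) -> tuple[DosePlane, DosePlane]:
    """Strip-test plane and its matched open-field plane on the same grid.

    The strip plane is the open plane modulated by the per-strip true scale
    factors (soft strip edges of width ``blur_sigma``); independent noise is
    drawn for the two planes from one seeded stream.
    """
    edges = spec.edges
    if edges[-1] - edges[0] > beam.field_size[0]:
        raise ValueError("strip pattern wider than the beam field")
    if np.isscalar(spacing):
        spacing = (float(spacing), float(spacing))
    rng = np.random.default_rng(seed)

    nx = int(np.ceil((edges[-1] - edges[0] + 30.0) / spacing[1])) + 1
    ny = int(np.ceil(min(beam.field_size[1], 80.0) / spacing[0])) + 1
    xs = (np.arange(nx) - (nx - 1) / 2) * spacing[1]
    ys = (np.arange(ny) - (ny - 1) / 2) * spacing[0]

    open_values = beam.fluence(xs, ys)
    modulation = np.zeros(nx)
    half = spec.strip_width / 2
    for i, scale in enumerate(spec.scales):
        center = (edges[i] + edges[i + 1]) / 2
        modulation = modulation + scale * _box_transmission(xs - center, half, spec.blur_sigma)
    strip_values = open_values * modulation[np.newaxis, :]

    strip_values = _apply_mult_noise(strip_values, spec.noise_sd, rng)
    open_values = _apply_mult_noise(open_values, spec.noise_sd, rng)
    meta = {"beam_mode": beam.mode, **spec.annotations}
    strip_plane = DosePlane.centered(strip_values, spacing, quantity="reading", meta=meta)
    open_plane = DosePlane.centered(open_values, spacing, quantity="reading", meta=meta)
    return strip_plane, open_plane


@dataclass(frozen=True)
class FilmScan:
    """A synthetic film scan: float transmission planes plus ground truth.

    ``channels`` hold unquantized detector values (``i0 * 10**-OD``); use
    :meth:`to_rgb` for a 16-bit export suitable for TIFF writing.
    """

    channels: dict[str, DosePlane]
    patch_rois: tuple[ROI, ...]
    doses: tuple[float, ...]
    true_od: dict[str, tuple[float, ...]]  # noiseless OD per patch, per channel
    i0: float
    dpi: float

    def to_rgb(self) -> np.ndarray:
        """Quantized (H, W, 3) uint16 array in R, G, B order."""
        stack = np.stack([self.channels[c].values for c in "RGB"], axis=-1)
        return np.clip(np.round(stack), 0, 2**16 - 1).astype(np.uint16)


def gen_film_scan(
    doses: Sequence[float],
    true_curve: CalibrationCurve | dict[str, CalibrationCurve],
    patch_size: float = 20.0,
    od_noise_frac: float = 0.0,
    seed: int | None = None,
    dpi: float = 75.0,
    i0: float = 50000.0,
) -> FilmScan:
    """Calibration-film scan: a 3x3 grid of uniform dose patches.

    Patch ODs are obtained by numerically inverting ``true_curve``
    (dose -> OD); noise is additive Gaussian on OD with per-pixel SD
    ``od_noise_frac * OD``. Unexposed film (outside patches) sits at the
    curve's zero-dose OD. Returned patch ROIs cover the central 60% of
    each patch.
    """
    doses = tuple(float(d) for d in doses)
    if len(doses) != 9:
        raise ValueError(f"expected 9 patch doses, got {len(doses)}")
    curves = true_curve if isinstance(true_curve, dict) else {c: true_curve for c in "RGB"}
    if set(curves) != set("RGB"):
        raise ValueError("need a calibration curve per R, G, B channel")
    rng = np.random.default_rng(seed)

    px = 25.4 / dpi
    pitch = patch_size * 1.5
    size_mm = 3 * pitch + patch_size  # margin of half a patch all round
    n = int(np.ceil(size_mm / px)) + 1
    xs = np.arange(n) * px
    ys = np.arange(n) * px

    patch_rois = []
    patch_slices = []
    for p in range(9):
        row, col = divmod(p, 3)
        cx = (col + 0.5) * pitch + patch_size / 2
        cy = (row + 0.5) * pitch + patch_size / 2
        half_roi = 0.6 * patch_size / 2
        patch_rois.append(ROI(cx - half_roi, cx + half_roi, cy - half_roi, cy + half_roi))
        in_x = (xs >= cx - patch_size / 2) & (xs < cx + patch_size / 2)
        in_y = (ys >= cy - patch_size / 2) & (ys < cy + patch_size / 2)
        patch_slices.append(np.ix_(in_y, in_x))

    channels: dict[str, DosePlane] = {}
    true_od: dict[str, tuple[float, ...]] = {}
    for channel, curve in curves.items():
        base_od = float(curve.od(0.0))
        od_map = np.full((n, n), base_od)
        ods = []
        for p, dose in enumerate(doses):
            od = float(curve.od(dose))
            ods.append(od)
            od_map[patch_slices[p]] = od
        if od_noise_frac > 0:
            od_map = od_map + rng.normal(0.0, od_noise_frac * np.abs(od_map))
        values = i0 * np.power(10.0, -od_map)
        channels[channel] = DosePlane(values, (px, px), (0.0, 0.0), "reading")
        true_od[channel] = tuple(ods)

    return FilmScan(channels, tuple(patch_rois), doses, true_od, float(i0), float(dpi))


def gen_case_table(spec: CaseTableSpec, seed: int | None = None) -> pd.DataFrame:
    """Measured/planned/prescription table with Normal(bias, sd) differences."""
    rng = np.random.default_rng(seed)
    diffs = rng.normal(spec.bias, spec.sd, size=spec.n_cases) if spec.sd > 0 else np.full(
        spec.n_cases, spec.bias
    )
    planned = np.full(spec.n_cases, spec.prescription)
    measured = planned + diffs * spec.prescription
    return pd.DataFrame(
        {
            "case": [f"case{i + 1}" for i in range(spec.n_cases)],
            "measured": measured,
            "planned": planned,
            "prescription": spec.prescription,
        }
    )


def gen_plane_pair(
    base: DosePlane,
    dose_error: float = 0.0,
    shift: tuple[float, float] = (0.0, 0.0),
) -> tuple[DosePlane, DosePlane]:
    """(reference, evaluated) pair for gamma testing.

    The evaluated plane is ``base`` scaled by ``1 + dose_error`` and then
    rigidly translated by ``shift = (dx, dy)`` mm (bilinear resampling on
    the same grid, edge values extended).
    """
    from scipy import ndimage

    scaled = base.values * (1.0 + dose_error)
    dx, dy = shift
    if dx == 0.0 and dy == 0.0:
        evaluated = scaled
    else:
        shift_px = (dy / base.spacing[0], dx / base.spacing[1])
        evaluated = ndimage.shift(scaled, shift_px, order=1, mode="nearest")
    return base, base.with_values(evaluated)
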