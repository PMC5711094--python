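"""Radiochromic film dosimetry: optical density, cubic calibration, dose
mapping, and film-to-plan rigid registration.

The calibration direction follows common practice for flatbed-scanner film
protocols: dose is fitted as a cubic polynomial in net optical density,
channel by channel. Only the channel being fitted is ever read.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .grid import DosePlane

__all__ = [
    "CalibrationCurve",
    "RegistrationTransform",
    "PROTOCOL_UNCERTAINTY",
    "compute_od",
    "fit_calibration",
    "apply_calibration",
    "register",
]

#: overall film-protocol dosimetric uncertainty (reporting constant, not a model)
PROTOCOL_UNCERTAINTY = 0.02

SATURATED = 2**16 - 1


@dataclass(frozen=True)
class CalibrationCurve:
    """Per-channel cubic map ``dose = c0 + c1*OD + c2*OD^2 + c3*OD^3``."""

    channel: str
    coefficients: tuple[float, float, float, float]
    dose_range: tuple[float, float]  # Gy, valid span of the fit
    od_span: tuple[float, float]  # OD span covered by the fit
    rms_residual: float = 0.0  # Gy
    monotone: bool = True

    def __post_init__(self) -> None:
        if self.channel not in ("R", "G", "B"):
            raise ValueError(f"channel must be R, G or B, got {self.channel!r}")
        if len(self.coefficients) != 4:
            raise ValueError("need exactly 4 polynomial coefficients")
        object.__setattr__(self, "coefficients", tuple(float(c) for c in self.coefficients))

    def dose(self, od):
        """Evaluate the polynomial at OD (scalar or array)."""
        return np.polynomial.polynomial.polyval(np.asarray(od, float), self.coefficients)

    def od(self, dose):
        """Numerical inverse: OD producing the given dose.

        Valid for monotone curves; inverts on a fine grid spanning the
        fitted OD range (extended slightly so the zero-dose intercept is
        reachable).
        """
        lo, hi = self.od_span
        pad = 0.25 * (hi - lo) + 1e-6
        grid = np.linspace(lo - pad, hi + pad, 20001)
        dose_grid = self.dose(grid)
        if dose_grid[0] > dose_grid[-1]:
            grid, dose_grid = grid[::-1], dose_grid[::-1]
        # keep the longest increasing stretch so interp is well defined
        inc = np.diff(dose_grid) > 0
        if not inc.all():
            start = int(np.argmax(inc))
            stop = start + int(np.argmin(inc[start:])) if not inc[start:].all() else len(grid) - 1
            grid, dose_grid = grid[start : stop + 1], dose_grid[start : stop + 1]
        target = np.asarray(dose, float)
        od = np.interp(target, dose_grid, grid)
        # Newton polish: the interp seed is ~1e-9 off, which matters when
        # the result feeds an ill-conditioned downstream fit
        dcoef = np.polynomial.polynomial.polyder(np.asarray(self.coefficients))
        for _ in range(4):
            slope = np.polynomial.polynomial.polyval(od, dcoef)
            slope = np.where(np.abs(slope) < 1e-12, 1e-12, slope)
            od = od - (self.dose(od) - target) / slope
        return od

    # -- JSON persistence -------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "channel": self.channel,
                "coefficients": list(self.coefficients),
                "dose_range_gy": list(self.dose_range),
                "od_span": list(self.od_span),
                "rms_residual_gy": self.rms_residual,
                "monotone": self.monotone,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "CalibrationCurve":
        d = json.loads(text)
        return cls(
            d["channel"],
            tuple(d["coefficients"]),
            tuple(d["dose_range_gy"]),
            tuple(d["od_span"]),
            d.get("rms_residual_gy", 0.0),
            d.get("monotone", True),
        )


@dataclass(frozen=True)
class RegistrationTransform:
    """Rigid 2D transform: translation (mm) + rotation (deg) about centre."""

    tx: float
    ty: float
    rotation: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.rotation) > 10.0:
            raise ValueError(f"|rotation| must be <= 10 deg, got {self.rotation}")


def compute_od(
    scan_channel: DosePlane, i0: float
) -> tuple[DosePlane, np.ndarray]:
    """Optical density plane ``OD = log10(i0 / pixel)`` plus saturation mask.

    Pixel values are clipped at 1 before the log; pixels at the 16-bit
    ceiling are flagged in the returned boolean mask.
    """
    if i0 <= 0:
        raise ValueError("i0 must be > 0")
    pixels = scan_channel.values
    saturated = pixels >= SATURATED
    od = np.log10(i0 / np.clip(pixels, 1.0, None))
    return scan_channel.with_values(od, quantity="od"), saturated


def fit_calibration(
    od_means: np.ndarray,
    doses: np.ndarray,
    channel: str = "R",
) -> CalibrationCurve:
    """Least-squares cubic ``dose(OD)`` through the patch measurements.

    Requires at least 4 distinct OD values; duplicate ODs paired with
    different doses are rejected as inconsistent. A fit that is not
    strictly monotone over the sampled OD span is flagged (``monotone``
    False) and warned about, never silently accepted.
    """
    od = np.asarray(od_means, float)
    dose = np.asarray(doses, float)
    if od.shape != dose.shape or od.ndim != 1:
        raise ValueError("od_means and doses must be 1D and equal length")
    order = np.argsort(od)
    od, dose = od[order], dose[order]
    for i in range(len(od) - 1):
        if od[i + 1] - od[i] < 1e-12 and abs(dose[i + 1] - dose[i]) > 1e-9:
            raise ValueError(
                f"inconsistent calibration points: OD {od[i]:.6g} maps to both "
                f"{dose[i]:.6g} and {dose[i + 1]:.6g} Gy"
            )
    if len(np.unique(np.round(od, 12))) < 4:
        raise ValueError("need at least 4 distinct OD values for a cubic fit")

    design = np.vander(od, 4, increasing=True)
    coeffs, _, rank, _ = np.linalg.lstsq(design, dose, rcond=None)
    if rank < 4:
        raise ValueError("rank-deficient calibration design matrix")
    # one step of iterative refinement: recovers exact-cubic inputs to ~1e-12
    coeffs = coeffs + np.linalg.lstsq(design, dose - design @ coeffs, rcond=None)[0]
    residuals = design @ coeffs - dose
    rms = float(np.sqrt(np.mean(residuals**2)))

    span = (float(od[0]), float(od[-1]))
    fine = np.linspace(span[0], span[1], 2001)
    deriv = np.polynomial.polynomial.polyval(
        fine, np.polynomial.polynomial.polyder(coeffs)
    )
    monotone = bool(np.all(deriv > 0) or np.all(deriv < 0))
    if not monotone:
        warnings.warn(
            f"calibration fit for channel {channel} is not monotone over "
            f"OD span {span}", stacklevel=2
        )
    return CalibrationCurve(
        channel,
        tuple(coeffs),
        (float(dose.min()), float(dose.max())),
        span,
        rms,
        monotone,
    )


def apply_calibration(
    curve: CalibrationCurve, od_plane: DosePlane
) -> tuple[DosePlane, np.ndarray]:
    """Map an OD plane to dose; flag pixels outside the curve's dose range."""
    dose = curve.dose(od_plane.values)
    lo, hi = curve.dose_range
    outside = (dose < lo) | (dose > hi)
    return od_plane.with_values(dose, quantity="dose"), outside


# ---------------------------------------------------------------------------
# registration


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def _sample_plan(plan: DosePlane, film: DosePlane, tx: float, ty: float, rot_deg: float) -> np.ndarray:
    """Plan values sampled at film pixel positions moved by (rot, t)."""
    ys, xs = np.meshgrid(film.ys, film.xs, indexing="ij")
    cy = (film.ys[0] + film.ys[-1]) / 2
    cx = (film.xs[0] + film.xs[-1]) / 2
    th = np.deg2rad(rot_deg)
    dxr = (xs - cx) * np.cos(th) - (ys - cy) * np.sin(th)
    dyr = (xs - cx) * np.sin(th) + (ys - cy) * np.cos(th)
    qx = cx + dxr + tx
    qy = cy + dyr + ty
    ii = (qy - plan.origin[0]) / plan.spacing[0]
    jj = (qx - plan.origin[1]) / plan.spacing[1]
    return ndimage.map_coordinates(plan.values, [ii.ravel(), jj.ravel()], order=1, mode="nearest").reshape(film.shape)


def register(
    film_dose: DosePlane,
    plan_dose: DosePlane,
    translation_bound: float = 10.0,
    rotation_bound: float = 5.0,
) -> RegistrationTransform:
    """Rigid registration of a film dose plane onto a planned dose plane.

    Maximizes normalized cross-correlation over translations within
    ``+/- translation_bound`` mm and rotations within
    ``+/- rotation_bound`` deg (coarse grid, then Nelder-Mead refinement).
    The returned translation is the displacement of the plan content
    relative to the film: if the plan pattern sits ``(dx, dy)`` mm away
    from where the film shows it, the result is ``(tx, ty) = (dx, dy)``.

    Deterministic; raises on a flat correlation landscape (uniform input).
    """
    f_ext = film_dose.extent
    p_ext = plan_dose.extent
    if f_ext[0] > p_ext[1] or p_ext[0] > f_ext[1] or f_ext[2] > p_ext[3] or p_ext[2] > f_ext[3]:
        raise ValueError("film and plan planes do not overlap")
    if film_dose.values.std() == 0 or plan_dose.values.std() == 0:
        raise ValueError("degenerate registration: uniform image")

    film = film_dose.values

    def score(params) -> float:
        tx, ty, rot = params
        return _ncc(film, _sample_plan(plan_dose, film_dose, tx, ty, rot))

    # translation-only coarse grid
    steps = np.arange(-translation_bound, translation_bound + 0.5, 1.0)
    scores = np.array([[score((tx, ty, 0.0)) for tx in steps] for ty in steps])
    if scores.max() - scores.min() < 1e-9:
        raise ValueError("degenerate registration: correlation plateau")
    iy, ix = np.unravel_index(np.argmax(scores), scores.shape)
    best_t = (steps[ix], steps[iy])

    # rotation coarse grid at the best translation
    rots = np.arange(-rotation_bound, rotation_bound + 0.25, 0.5)
    best_rot = rots[int(np.argmax([score((best_t[0], best_t[1], r)) for r in rots]))]

    res = optimize.minimize(
        lambda p: -score(p),
        x0=[best_t[0], best_t[1], best_rot],
        method="Nelder-Mead",
        options={"xatol": 0.01, "fatol": 1e-10, "maxiter": 400},
    )
    tx, ty, rot = res.x
    tx = float(np.clip(tx, -translation_bound, translation_bound))
    ty = float(np.clip(ty, -translation_bound, translation_bound))
    rot = float(np.clip(rot, -rotation_bound, rotation_bound))
    return RegistrationTransform(tx, ty, rot)
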