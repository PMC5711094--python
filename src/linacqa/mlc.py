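"""MLC QA analyses: picket-fence peak/FWHM evaluation and the dose-rate /
gantry-speed (DR_GS) and leaf-speed / dose-rate (LS_DR) strip tests.

The strip-test correction divides the strip reading by the matched
open-field reading and scales by 100::

    R_corr = strip_mean / open_mean * 100

and per-strip deviations are ratios to the mean corrected reading across
all strips.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .grid import DosePlane, Profile, ROI, roi_stats

__all__ = [
    "PicketReport",
    "StripTestResult",
    "detect_pickets",
    "fwhm",
    "compare_pickets",
    "rcorr",
    "strip_deviations",
    "analyze_strips",
    "default_strip_rois",
]


@dataclass(frozen=True)
class PicketReport:
    """Per-picket comparison of a test image against a reference."""

    positions: np.ndarray  # test peak positions, mm
    reference_positions: np.ndarray
    deviations: np.ndarray  # test - reference, mm
    max_abs_deviation: float
    tolerance: float
    passed: bool
    flagged: np.ndarray  # |deviation| above the reporting threshold
    report_threshold: float
    fwhm: np.ndarray | None = None  # per-picket FWHM of the test image, mm

    def __post_init__(self) -> None:
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("picket positions must be strictly increasing")
        if self.fwhm is not None and np.any(np.asarray(self.fwhm) <= 0):
            raise ValueError("FWHM values must be positive")


@dataclass(frozen=True)
class StripTestResult:
    """Full strip-test table plus its summary statistics.

    ``table`` columns: position_cm, strip_mean, strip_sd, open_mean,
    open_sd, rcorr, diff_pct, passed.
    """

    table: pd.DataFrame
    mean_abs_diff: float  # %
    diff_range: tuple[float, float]  # (min, max) %
    tolerance: float
    passed: bool


def detect_pickets(profile: Profile, expected_count: int) -> np.ndarray:
    """Locate picket peak positions (mm) with sub-pixel refinement.

    Finds prominent local maxima and refines each by a 3-point parabolic
    fit. Raises if the number of prominent peaks differs from
    ``expected_count`` (the found count is included in the message).
    """
    if expected_count < 1:
        raise ValueError("expected_count must be >= 1")
    v = profile.values
    ptp = v.max() - v.min()
    if ptp <= 0:
        raise ValueError(f"no peaks found (uniform profile), expected {expected_count}")
    idx, _ = find_peaks(v, prominence=0.25 * ptp)
    if len(idx) != expected_count:
        raise ValueError(f"found {len(idx)} prominent peaks, expected {expected_count}")

    pos = profile.positions
    refined = []
    for i in idx:
        if 0 < i < len(v) - 1:
            y0, y1, y2 = v[i - 1], v[i], v[i + 1]
            denom = y0 - 2 * y1 + y2
            delta = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
            step = (pos[i + 1] - pos[i - 1]) / 2
            refined.append(pos[i] + delta * step)
        else:
            refined.append(pos[i])
    return np.asarray(refined)


def fwhm(
    profile: Profile,
    peak_position: float,
    background_window: float | None = None,
) -> float:
    """Full width at half maximum (mm) of the peak nearest ``peak_position``.

    The background is the profile minimum within ``background_window`` mm
    of the peak (whole profile if None); half-maximum crossings on either
    side are located by linear interpolation. Raises if the profile does
    not drop below half maximum on both sides.
    """
    pos, v = profile.positions, profile.values
    i_peak = int(np.argmin(np.abs(pos - peak_position)))
    if background_window is not None:
        local = np.abs(pos - pos[i_peak]) <= background_window
        background = v[local].min()
    else:
        background = v.min()
    peak_val = v[i_peak]
    half = background + 0.5 * (peak_val - background)
    if peak_val <= background:
        raise ValueError("peak is not above the local background")

    def _crossing(direction: int) -> float:
        i = i_peak
        while 0 <= i + direction < len(v):
            j = i + direction
            if v[j] < half:
                # interpolate between samples i (>= half) and j (< half)
                frac = (v[i] - half) / (v[i] - v[j])
                return pos[i] + frac * (pos[j] - pos[i])
            i = j
        raise ValueError(
            f"profile does not cross half maximum on the "
            f"{'right' if direction > 0 else 'left'} side of the peak"
        )

    return float(_crossing(+1) - _crossing(-1))


def compare_pickets(
    test_positions: np.ndarray,
    reference_positions: np.ndarray,
    tolerance_mm: float = 1.0,
    report_threshold_mm: float = 0.25,
    test_fwhm: np.ndarray | None = None,
) -> PicketReport:
    """Per-picket deviation (test - reference) with tolerance evaluation.

    Passes iff the maximum absolute deviation is within ``tolerance_mm``;
    deviations above ``report_threshold_mm`` are additionally flagged so
    sub-tolerance positional errors remain visible in reports.
    """
    test = np.asarray(test_positions, float)
    ref = np.asarray(reference_positions, float)
    if test.shape != ref.shape:
        raise ValueError(f"picket count mismatch: {test.shape} vs {ref.shape}")
    dev = test - ref
    max_abs = float(np.max(np.abs(dev)))
    return PicketReport(
        positions=test,
        reference_positions=ref,
        deviations=dev,
        max_abs_deviation=max_abs,
        tolerance=tolerance_mm,
        passed=bool(max_abs <= tolerance_mm),
        flagged=np.abs(dev) > report_threshold_mm,
        report_threshold=report_threshold_mm,
        fwhm=None if test_fwhm is None else np.asarray(test_fwhm, float),
    )


def rcorr(strip_mean: float, open_mean: float) -> float:
    """Open-field-corrected strip reading: ``strip / open * 100``."""
    if open_mean <= 0:
        raise ValueError(f"open-field mean must be > 0, got {open_mean}")
    return strip_mean / open_mean * 100.0


def strip_deviations(
    rcorr_values: np.ndarray, tolerance: float = 2.0
) -> tuple[np.ndarray, dict[str, float], np.ndarray]:
    """Percent deviation of each corrected reading from their mean.

    Returns ``(diffs, summary, passed)`` where
    ``diffs[i] = (rcorr[i] / mean(rcorr) - 1) * 100``, the summary holds
    the mean absolute deviation and the min/max, and each strip passes iff
    ``|diff| <= tolerance`` (%).
    """
    r = np.asarray(rcorr_values, float)
    if r.size < 2:
        raise ValueError("need at least 2 corrected readings")
    if np.any(r <= 0):
        raise ValueError("corrected readings must be positive")
    diffs = (r / r.mean() - 1.0) * 100.0
    summary = {
        "mean_abs_diff": float(np.mean(np.abs(diffs))),
        "min_diff": float(diffs.min()),
        "max_diff": float(diffs.max()),
    }
    return diffs, summary, np.abs(diffs) <= tolerance


def default_strip_rois(
    n_strips: int,
    strip_width: float,
    y_half: float = 15.0,
    coverage: float = 0.6,
    x_center: float = 0.0,
) -> list[ROI]:
    """Centred sampling rectangles covering the middle ``coverage`` of each
    strip width, avoiding penumbra contamination at the strip edges."""
    total = n_strips * strip_width
    half = coverage * strip_width / 2
    rois = []
    for i in range(n_strips):
        c = x_center - total / 2 + (i + 0.5) * strip_width
        rois.append(ROI(c - half, c + half, -y_half, y_half))
    return rois


def analyze_strips(
    strip_plane: DosePlane,
    open_plane: DosePlane,
    strip_rois: list[ROI],
    positions_cm: list[float] | None = None,
    tolerance: float = 2.0,
) -> StripTestResult:
    """Full strip-test analysis on a strip/open plane pair.

    Both planes must share geometry and the ROIs must be pairwise
    disjoint. Produces the per-strip table (means, SDs, corrected reading,
    percent deviation, pass flag) and its summary.
    """
    if not strip_plane.same_geometry(open_plane):
        raise ValueError("strip and open planes do not share geometry")
    for i in range(len(strip_rois)):
        for j in range(i + 1, len(strip_rois)):
            a, b = strip_rois[i], strip_rois[j]
            if a.x_min < b.x_max and b.x_min < a.x_max and a.y_min < b.y_max and b.y_min < a.y_max:
                raise ValueError(f"strip ROIs {i} and {j} overlap")
    if positions_cm is None:
        positions_cm = [round((r.x_min + r.x_max) / 20.0, 2) for r in strip_rois]
    if len(positions_cm) != len(strip_rois):
        raise ValueError("positions_cm must match the number of ROIs")

    rows = []
    for pos_cm, roi in zip(positions_cm, strip_rois):
        s_mean, s_sd, _ = roi_stats(strip_plane, roi)
        o_mean, o_sd, _ = roi_stats(open_plane, roi)
        rows.append(
            {
                "position_cm": pos_cm,
                "strip_mean": s_mean,
                "strip_sd": s_sd,
                "open_mean": o_mean,
                "open_sd": o_sd,
                "rcorr": rcorr(s_mean, o_mean),
            }
        )
    table = pd.DataFrame(rows)
    diffs, summary, passed = strip_deviations(table["rcorr"].to_numpy(), tolerance)
    table["diff_pct"] = diffs
    table["passed"] = passed
    return StripTestResult(
        table=table,
        mean_abs_diff=summary["mean_abs_diff"],
        diff_range=(summary["min_diff"], summary["max_diff"]),
        tolerance=tolerance,
        passed=bool(passed.all()),
    )
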