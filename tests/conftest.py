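import numpy as np
import pytest

from linacqa.grid import DosePlane
from linacqa.synth import BeamModel


@pytest.fixture
def ff_beam() -> BeamModel:
    return BeamModel(mode="FF", field_size=(140.0, 140.0))


@pytest.fixture
def fff_beam() -> BeamModel:
    return BeamModel(mode="FFF", field_size=(140.0, 140.0))


@pytest.fixture
def uniform_plane() -> DosePlane:
    return DosePlane.centered(np.full((20, 20), 2.0), (1.0, 1.0))


def bilinear_sample(values: np.ndarray, ys: np.ndarray, xs: np.ndarray,
                    qy: np.ndarray, qx: np.ndarray) -> np.ndarray:
    """Hand-rolled bilinear interpolation used by test oracles (deliberately
    independent of the package's interpolation path). NaN outside the grid."""
    qy = np.asarray(qy, float)
    qx = np.asarray(qx, float)
    fy = (qy - ys[0]) / (ys[1] - ys[0])
    fx = (qx - xs[0]) / (xs[1] - xs[0])
    out = np.full(qy.shape, np.nan)
    inside = (fy >= 0) & (fy <= len(ys) - 1) & (fx >= 0) & (fx <= len(xs) - 1)
    fy = np.clip(fy, 0, len(ys) - 1 - 1e-12)[inside]
    fx = np.clip(fx, 0, len(xs) - 1 - 1e-12)[inside]
    i0 = fy.astype(int)
    j0 = fx.astype(int)
    wy = fy - i0
    wx = fx - j0
    out[inside] = (
        values[i0, j0] * (1 - wy) * (1 - wx)
        + values[i0 + 1, j0] * wy * (1 - wx)
        + values[i0, j0 + 1] * (1 - wy) * wx
        + values[i0 + 1, j0 + 1] * wy * wx
    )
    return out


def gamma_oracle(reference: DosePlane, evaluated: DosePlane,
                 dose_tol_pct: float = 3.0, dta: float = 3.0,
                 threshold_pct: float = 10.0) -> np.ndarray:
    """Brute-force gamma: exhaustive shift enumeration at dta/20 over a disc
    of radius 3*dta, own bilinear interpolation, no early exit. Returns the
    flat gamma values for above-threshold reference pixels in row-major
    order."""
    norm = reference.values.max()
    dd = dose_tol_pct / 100.0 * norm
    include = reference.values >= threshold_pct / 100.0 * norm
    iy, ix = np.nonzero(include)
    ry = reference.ys[iy]
    rx = reference.xs[ix]
    rv = reference.values[include]

    step = dta / 20.0
    n = int(np.floor(3.0 * dta / step))
    offs = np.arange(-n, n + 1) * step
    best = np.full(rv.shape, np.inf)
    for dy in offs:
        for dx in offs:
            r2 = dy * dy + dx * dx
            if r2 > (3.0 * dta) ** 2:
                continue
            ev = bilinear_sample(evaluated.values, evaluated.ys, evaluated.xs,
                                 ry + dy, rx + dx)
            ok = np.isfinite(ev)
            cand = (ev[ok] - rv[ok]) ** 2 / dd**2 + r2 / dta**2
            best[ok] = np.minimum(best[ok], cand)
    return np.sqrt(best)
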