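"""TG-119 commissioning statistics.

Point-dose differences are carried as fractions of the prescription dose::

    diff = (measured - planned) / prescription

and confidence limits (CLs) follow the TG-119 definitions:

* point doses:    ``CL = |mean| + 1.96 * SD``
* gamma rates:    ``CL = 100 - mean + 1.96 * SD``

with the sample standard deviation (n - 1 denominator) throughout. The CL
is the action level within which 95% of future measurements are expected
to fall, assuming normally distributed differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PointMeasurement",
    "CLRecord",
    "dose_diff_ratio",
    "confidence_limit_point",
    "confidence_limit_gamma",
    "aggregate_cl",
    "couch_transmission_diff",
    "build_report",
    "DEFAULT_BASELINES",
]

Z95 = 1.96

ENERGIES = ("6X", "10X", "15X", "6X-FFF", "10X-FFF")
TECHNIQUES = ("IMRT", "RapidArc")
REGIONS = ("high", "low")

#: multi-institution average CLs used as the default pass/fail baseline
DEFAULT_BASELINES = {"high": 0.045, "low": 0.047}


@dataclass(frozen=True)
class PointMeasurement:
    """One ion-chamber point measurement against its plan."""

    case: str
    energy: str
    technique: str
    region: str
    measured: float  # Gy
    planned: float  # Gy
    prescription: float  # Gy

    def __post_init__(self) -> None:
        if self.prescription <= 0:
            raise ValueError("prescription dose must be > 0")
        if self.energy not in ENERGIES:
            raise ValueError(f"unknown energy {self.energy!r}")
        if self.technique not in TECHNIQUES:
            raise ValueError(f"unknown technique {self.technique!r}")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")


@dataclass(frozen=True)
class CLRecord:
    """A set of per-case inputs with its mean, SD and confidence limit."""

    inputs: tuple[float, ...]
    mean: float
    sd: float
    cl: float
    flavor: str  # "point" (fractions) or "gamma" (% passing rates)

    def __post_init__(self) -> None:
        if len(self.inputs) < 2:
            raise ValueError("need at least 2 inputs for a confidence limit")
        if self.flavor not in ("point", "gamma"):
            raise ValueError(f"unknown flavor {self.flavor!r}")
        if self.flavor == "point" and self.cl < 0:
            raise ValueError("point-dose CL cannot be negative")

    @property
    def n(self) -> int:
        return len(self.inputs)


def dose_diff_ratio(m: PointMeasurement) -> float:
    """(measured - planned) / prescription, as a fraction."""
    return (m.measured - m.planned) / m.prescription


def confidence_limit_point(diffs: np.ndarray) -> CLRecord:
    """Point-dose CL: ``|mean| + 1.96 * sample SD`` of fractional diffs."""
    d = np.asarray(diffs, float)
    if d.size < 2:
        raise ValueError("need at least 2 differences")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return CLRecord(tuple(d), mean, sd, abs(mean) + Z95 * sd, "point")


def confidence_limit_gamma(rates: np.ndarray) -> CLRecord:
    """Gamma-plane CL: ``100 - mean + 1.96 * sample SD`` of passing rates (%)."""
    r = np.asarray(rates, float)
    if r.size < 2:
        raise ValueError("need at least 2 passing rates")
    mean = float(r.mean())
    sd = float(r.std(ddof=1))
    return CLRecord(tuple(r), mean, sd, 100.0 - mean + Z95 * sd, "gamma")


def aggregate_cl(cls_: np.ndarray) -> tuple[float, float, float, float]:
    """(mean, sample SD, min, max) over a set of per-energy CLs."""
    c = np.asarray(cls_, float)
    if c.size < 2:
        raise ValueError("need at least 2 confidence limits to aggregate")
    return float(c.mean()), float(c.std(ddof=1)), float(c.min()), float(c.max())


def couch_transmission_diff(calculated: float, measured: float) -> float:
    """Percent difference of measured vs calculated couch transmission."""
    if calculated <= 0:
        raise ValueError("calculated transmission must be > 0")
    return (measured - calculated) / calculated * 100.0


def _cl_table(
    df: pd.DataFrame, value_fn, flavor: str
) -> pd.DataFrame:
    rows = []
    for (technique, energy, region), group in df.groupby(
        ["technique", "energy", "region"], sort=False
    ):
        rec = value_fn(group)
        rows.append(
            {
                "technique": technique,
                "energy": energy,
                "region": region,
                "n": rec.n,
                "mean": rec.mean,
                "sd": rec.sd,
                "cl": rec.cl,
            }
        )
    return pd.DataFrame(rows)


def build_report(
    point_table: pd.DataFrame | None = None,
    gamma_table: pd.DataFrame | None = None,
    couch_table: pd.DataFrame | None = None,
    baselines: dict[str, float] | None = None,
) -> dict[str, pd.DataFrame]:
    """Assemble the commissioning statistics report.

    Parameters
    ----------
    point_table
        Columns: case, energy, technique, region, measured, planned,
        prescription (doses in Gy).
    gamma_table
        Columns: case, energy, technique, region, passing_rate (%).
    couch_table
        Columns: energy, part ("thin"/"thick"), calculated, measured.
    baselines
        Per-region CL action levels for the point-dose pass flags.

    Returns a dict of DataFrames: ``point_cl``, ``point_aggregate``,
    ``gamma_cl``, ``gamma_aggregate``, ``couch`` (keys present only for
    supplied inputs). Raises if nothing is supplied.
    """
    if point_table is None and gamma_table is None and couch_table is None:
        raise ValueError("no input tables supplied")
    baselines = {**DEFAULT_BASELINES, **(baselines or {})}
    report: dict[str, pd.DataFrame] = {}

    if point_table is not None:
        if len(point_table) == 0:
            raise ValueError("empty point-measurement table")
        pt = point_table.copy()
        pt["diff"] = (pt["measured"] - pt["planned"]) / pt["prescription"]
        cl = _cl_table(pt, lambda g: confidence_limit_point(g["diff"].to_numpy()), "point")
        cl["baseline"] = cl["region"].map(baselines)
        cl["passed"] = cl["cl"] <= cl["baseline"]
        report["point_cl"] = cl
        report["point_aggregate"] = _aggregate_table(cl)

    if gamma_table is not None:
        if len(gamma_table) == 0:
            raise ValueError("empty gamma-rate table")
        cl = _cl_table(
            gamma_table, lambda g: confidence_limit_gamma(g["passing_rate"].to_numpy()), "gamma"
        )
        report["gamma_cl"] = cl
        report["gamma_aggregate"] = _aggregate_table(cl)

    if couch_table is not None:
        if len(couch_table) == 0:
            raise ValueError("empty couch-transmission table")
        ct = couch_table.copy()
        ct["pct_diff"] = [
            couch_transmission_diff(c, m) for c, m in zip(ct["calculated"], ct["measured"])
        ]
        avg = (
            ct.groupby("part", sort=False)["pct_diff"]
            .mean()
            .reset_index()
            .rename(columns={"pct_diff": "avg_pct_diff"})
        )
        report["couch"] = ct
        report["couch_average"] = avg

    return report


def _aggregate_table(cl: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (technique, region), group in cl.groupby(["technique", "region"], sort=False):
        if len(group) < 2:
            continue
        mean, sd, lo, hi = aggregate_cl(group["cl"].to_numpy())
        rows.append(
            {
                "technique": technique,
                "region": region,
                "n_energies": len(group),
                "cl_mean": mean,
                "cl_sd": sd,
                "cl_min": lo,
                "cl_max": hi,
            }
        )
    return pd.DataFrame(rows)
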