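"""Bundled reference dataset: published TG-119 commissioning measurements
for a TrueBeam linac (five photon energies, IMRT and RapidArc).

These are measured values transcribed from the published commissioning
report tables; they serve as worked examples and regression anchors for
the analysis routines. Loaders return plain pandas objects / dicts so the
analyses stay decoupled from how the data is stored.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "load_strip_tests",
    "load_point_dose_diffs",
    "load_gamma_rates",
    "load_couch_transmission",
]

# --------------------------------------------------------------------------
# DR_GS (dose rate / gantry speed, 7 strips) and LS_DR (leaf speed / dose
# rate, 4 strips) strip tests. EPID readings (CU) for 6X, film scanner
# values for 6X-FFF.

_STRIP_TESTS = {
    ("DR_GS", "6X"): {
        "positions_cm": [-5, -3, -1, 1, 3, 5, 7],
        "strip_mean": [74.06, 74.18, 73.95, 73.96, 73.81, 73.87, 71.73],
        "strip_sd": [0.42, 0.37, 0.42, 0.37, 0.39, 0.49, 0.57],
        "open_mean": [68.38, 69.32, 69.28, 69.42, 69.38, 69.38, 67.32],
        "open_sd": [0.16, 0.08, 0.07, 0.09, 0.08, 0.10, 0.25],
        "rcorr": [108.31, 107.01, 106.74, 106.54, 106.39, 106.47, 106.55],
    },
    ("DR_GS", "6X-FFF"): {
        "positions_cm": [-5, -3, -1, 1, 3, 5, 7],
        "strip_mean": [38354.50, 37602.75, 37124.70, 37209.20, 37278.40, 38009.60, 38792.80],
        "strip_sd": [71.70, 86.40, 63.90, 58.00, 90.70, 111.70, 91.60],
        "open_mean": [39924.80, 39358.10, 39047.50, 38985.40, 39145.20, 39614.00, 40215.60],
        "open_sd": [152.60, 113.20, 103.10, 115.00, 97.00, 219.90, 118.00],
        "rcorr": [96.07, 95.54, 95.08, 95.44, 95.23, 95.95, 96.46],
    },
    ("LS_DR", "6X"): {
        "positions_cm": [-4.5, -1.5, 1.5, 4.5],
        "strip_mean": [37.37, 37.63, 37.09, 36.15],
        "strip_sd": [0.37, 0.96, 0.34, 0.4],
        "open_mean": [67.12, 67.34, 66.78, 65.32],
        "open_sd": [0.11, 0.2, 0.06, 0.16],
        "rcorr": [55.68, 55.88, 55.54, 55.34],
    },
    ("LS_DR", "6X-FFF"): {
        "positions_cm": [-4.5, -1.5, 1.5, 4.5],
        "strip_mean": [41931.7, 41521.8, 41499.2, 41884.7],
        "strip_sd": [122.7, 110.4, 88, 122.3],
        "open_mean": [40158.9, 39626.7, 39533.6, 40153.9],
        "open_sd": [196.1, 119.6, 120, 158.6],
        "rcorr": [104.41, 104.78, 104.97, 104.31],
    },
}


def load_strip_tests(test: str, energy: str) -> pd.DataFrame:
    """Per-strip readings for one strip test.

    Parameters: ``test`` in {"DR_GS", "LS_DR"}, ``energy`` in
    {"6X", "6X-FFF"}. Columns: position_cm, strip_mean, strip_sd,
    open_mean, open_sd, rcorr (the published corrected readings).
    """
    key = (test, energy)
    if key not in _STRIP_TESTS:
        raise KeyError(f"no bundled strip test for {key}")
    d = _STRIP_TESTS[key]
    return pd.DataFrame(
        {
            "position_cm": d["positions_cm"],
            "strip_mean": d["strip_mean"],
            "strip_sd": d["strip_sd"],
            "open_mean": d["open_mean"],
            "open_sd": d["open_sd"],
            "rcorr": d["rcorr"],
        }
    )


# --------------------------------------------------------------------------
# Per-case point-dose differences, (measured - planned) / prescription,
# as fractions. Five cases in the high-dose target, six in the low-dose
# avoidance structure (the multi-target case is measured at two points).

_HIGH_CASES = ["Prostate", "H&N", "C-shape hard", "C-shape easy", "MultiTarget"]
_LOW_CASES = [
    "Prostate", "H&N", "C-shape hard", "C-shape easy",
    "MultiTarget (Sup)", "MultiTarget (Inf)",
]

_POINT_DIFFS = {
    "high": {
        "IMRT": {
            "6X": [0.015, 0.005, 0.001, 0.010, 0.016],
            "10X": [0.000, -0.019, -0.009, -0.013, -0.000],
            "15X": [0.001, -0.022, -0.021, -0.021, -0.000],
            "6X-FFF": [0.018, 0.021, 0.004, 0.014, 0.019],
            "10X-FFF": [-0.016, -0.031, -0.007, 0.002, -0.018],
        },
        "RapidArc": {
            "6X": [0.008, 0.003, 0.033, 0.029, 0.011],
            "10X": [0.000, -0.003, 0.015, 0.015, 0.004],
            "15X": [-0.002, -0.001, 0.010, 0.000, 0.011],
            "6X-FFF": [-0.003, 0.002, 0.023, 0.012, 0.010],
            "10X-FFF": [-0.009, 0.001, -0.010, 0.031, 0.004],
        },
    },
    "low": {
        "IMRT": {
            "6X": [0.025, 0.001, 0.019, 0.007, 0.012, 0.014],
            "10X": [-0.001, -0.011, 0.018, -0.004, -0.009, -0.010],
            "15X": [0.000, -0.017, 0.010, -0.006, -0.013, -0.015],
            "6X-FFF": [0.021, 0.014, 0.000, 0.001, 0.014, 0.013],
            "10X-FFF": [-0.016, -0.013, 0.013, 0.007, -0.025, -0.018],
        },
        "RapidArc": {
            "6X": [0.047, 0.020, 0.007, 0.004, 0.011, 0.008],
            "10X": [0.020, 0.012, 0.004, 0.004, 0.008, 0.003],
            "15X": [0.013, 0.010, -0.004, -0.001, 0.007, -0.001],
            "6X-FFF": [0.021, 0.017, -0.016, 0.005, 0.003, 0.002],
            "10X-FFF": [0.006, 0.011, -0.006, 0.011, -0.003, 0.001],
        },
    },
}


def load_point_dose_diffs(
    region: str, prescription: float = 2.0
) -> pd.DataFrame:
    """Point-dose measurement table for ``region`` in {"high", "low"}.

    Columns: case, energy, technique, region, measured, planned,
    prescription — reconstructed from the published fractional differences
    so that ``(measured - planned) / prescription`` reproduces them
    exactly.
    """
    if region not in _POINT_DIFFS:
        raise KeyError(f"region must be 'high' or 'low', got {region!r}")
    cases = _HIGH_CASES if region == "high" else _LOW_CASES
    rows = []
    for technique, by_energy in _POINT_DIFFS[region].items():
        for energy, diffs in by_energy.items():
            for case, diff in zip(cases, diffs):
                rows.append(
                    {
                        "case": case,
                        "energy": energy,
                        "technique": technique,
                        "region": region,
                        "measured": prescription + diff * prescription,
                        "planned": prescription,
                        "prescription": prescription,
                    }
                )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Gamma passing rates (3%/3 mm), low-dose avoidance-structure planes.
# (The high-dose plane table of the source report is internally
# inconsistent with its own summary rows and is deliberately not bundled.)

_GAMMA_LOW_CASES = ["Prostate", "H&N", "C-shape hard", "C-shape easy"]

_GAMMA_LOW = {
    "IMRT": {
        "6X": [99.1, 99.2, 99.7, 99.5],
        "10X": [99.6, 99.9, 94.2, 99.1],
        "15X": [98.1, 100.0, 96.9, 97.9],
        "6X-FFF": [98.6, 99.8, 99.5, 93.7],
        "10X-FFF": [99.1, 99.8, 95.4, 89.3],
    },
    "RapidArc": {
        "6X": [99.9, 99.8, 100.0, 96.6],
        "10X": [98.8, 99.4, 99.9, 98.1],
        "15X": [100.0, 99.8, 100.0, 100.0],
        "6X-FFF": [93.2, 99.9, 99.9, 100.0],
        "10X-FFF": [99.7, 99.9, 98.5, 99.9],
    },
}


def load_gamma_rates(region: str = "low") -> pd.DataFrame:
    """Gamma passing-rate table (3%/3 mm) for the low-dose planes.

    Columns: case, energy, technique, region, passing_rate (%).
    """
    if region != "low":
        raise KeyError("only the low-dose gamma table is bundled (region='low')")
    rows = []
    for technique, by_energy in _GAMMA_LOW.items():
        for energy, rates in by_energy.items():
            for case, rate in zip(_GAMMA_LOW_CASES, rates):
                rows.append(
                    {
                        "case": case,
                        "energy": energy,
                        "technique": technique,
                        "region": region,
                        "passing_rate": rate,
                    }
                )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Couch transmission factors (calculated vs measured) for the thin and
# thick sections of the treatment couch.

_COUCH = {
    "thick": {
        "6X": (0.9767, 0.9682),
        "10X": (0.9733, 0.9630),
        "15X": (0.9829, 0.9763),
        "6X-FFF": (0.9791, 0.9727),
        "10X-FFF": (0.9846, 0.9784),
    },
    "thin": {
        "6X": (0.9825, 0.9744),
        "10X": (0.9794, 0.9723),
        "15X": (0.9861, 0.9829),
        "6X-FFF": (0.9835, 0.9799),
        "10X-FFF": (0.9877, 0.9851),
    },
}


def load_couch_transmission() -> pd.DataFrame:
    """Couch transmission factors: energy, part, calculated, measured."""
    rows = []
    for part, by_energy in _COUCH.items():
        for energy, (calc, meas) in by_energy.items():
            rows.append(
                {"energy": energy, "part": part, "calculated": calc, "measured": meas}
            )
    return pd.DataFrame(rows)
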