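"""Degree of hydrolysis from pH-stat titration.

In a pH-stat experiment the titrant volume needed to hold the reaction pH
constant tracks the protons released by bond cleavage, so the degree of
hydrolysis follows

    DH(%) = 100 * A * N_A / ((1 - alpha) * h_TOT * M_p)

with A the cumulative titrant consumption (mL), N_A the titrant normality
(meq/mL), alpha the average dissociation degree of the alpha-carboxyl /
alpha-amino groups at the working pH (dimensionless), h_TOT the total
peptide-bond content of the substrate (meq/g protein) and M_p the protein
mass (g).  (1-alpha), h_TOT and M_p all sit in the denominator - the
standard pH-stat form.  DH is usually reported relative to the enzyme's
theoretical ceiling DH_max.

Workflow defaults mirror a peptic serum-albumin digest: alpha = 0.325,
h_TOT = 8.8 meq/g, 3 g protein, 15-minute sampling over 3 h.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


@dataclass(frozen=True)
class PhStatRecord:
    """One titration sample: time (min) and cumulative titrant volume (mL)."""

    time_min: float
    volume_ml: float

    def __post_init__(self) -> None:
        if self.time_min < 0:
            raise ValueError("time must be >= 0")
        if self.volume_ml < 0:
            raise ValueError("cumulative titrant volume must be >= 0")


@dataclass(frozen=True)
class DhParameters:
    """Constants of the pH-stat DH formula."""

    normality: float  # N_A, meq/mL
    alpha: float = 0.325
    h_tot: float = 8.8  # meq peptide bonds per g protein
    protein_mass_g: float = 3.0

    def __post_init__(self) -> None:
        if self.normality <= 0:
            raise ValueError("titrant normality must be > 0")
        if not 0 <= self.alpha < 1:
            raise ValueError("alpha must lie in [0, 1)")
        if self.h_tot <= 0 or self.protein_mass_g <= 0:
            raise ValueError("h_TOT and protein mass must be > 0")


def dh_from_titration(volume_ml: float, params: DhParameters) -> float:
    """DH(%) for a cumulative titrant consumption of *volume_ml*."""
    if volume_ml < 0:
        raise ValueError("titrant volume must be >= 0")
    return 100.0 * volume_ml * params.normality / (
        (1.0 - params.alpha) * params.h_tot * params.protein_mass_g
    )


def relative_dh(dh_percent: float, dh_max_percent: float) -> float:
    """DH expressed as a percentage of the theoretical ceiling DH_max."""
    if dh_max_percent <= 0:
        raise ValueError("dh_max must be > 0")
    return 100.0 * dh_percent / dh_max_percent


@dataclass(frozen=True)
class HydrolysisCurve:
    """A time-resolved DH curve with its parameters and DH_max reference."""

    frame: pd.DataFrame  # columns: time_min, volume_ml, dh, relative_dh
    params: DhParameters
    dh_max: float
    plateau_time_min: float | None = None


def build_curve(
    series: Sequence[PhStatRecord],
    params: DhParameters,
    dh_max: float,
    plateau_gain_percent: float = 1.0,
    plateau_interval_min: float = 15.0,
) -> HydrolysisCurve:
    """Map a titration series through the DH formula.

    The series must be time-sorted.  Decreasing titrant volumes (instrument
    jitter) are clamped to the running maximum with a warning, never
    silently.  Plateau onset is the start of the earliest run of at least
    two consecutive intervals - extending to the end of the series - in
    which relative DH gains less than *plateau_gain_percent* per
    *plateau_interval_min* minutes; series too short to show two intervals
    are never flagged.
    """
    records = list(series)
    times = [r.time_min for r in records]
    if times != sorted(times):
        raise ValueError("pH-stat series must be sorted by time")
    volumes = np.array([r.volume_ml for r in records], dtype=float)
    running = np.maximum.accumulate(volumes)
    if np.any(volumes < running):
        warnings.warn(
            "non-monotone titrant series; decreasing volumes clamped to the running maximum"
        )
    dh = np.array([dh_from_titration(v, params) for v in running])
    rel = np.array([relative_dh(d, dh_max) for d in dh])

    plateau = None
    t = np.asarray(times, dtype=float)
    if len(records) >= 3:
        dt = np.diff(t)
        gains = np.where(dt > 0, np.diff(rel) / dt * plateau_interval_min, 0.0)
        below = gains < plateau_gain_percent
        # earliest suffix of >= 2 all-below intervals
        idx = None
        for i in range(len(below) - 1, -1, -1):
            if below[i]:
                idx = i
            else:
                break
        if idx is not None and len(below) - idx >= 2:
            plateau = float(t[idx])

    frame = pd.DataFrame(
        {
            "time_min": t,
            "volume_ml": running,
            "dh": dh,
            "relative_dh": rel,
        }
    )
    return HydrolysisCurve(frame=frame, params=params, dh_max=dh_max, plateau_time_min=plateau)


@dataclass(frozen=True)
class FirstOrderFit:
    """Least-squares fit of A(t) = A_inf * (1 - exp(-k t))."""

    k: float  # 1/min
    a_inf_ml: float
    k_stderr: float
    a_inf_stderr: float

    def asymptotic_dh(self, params: DhParameters) -> float:
        return dh_from_titration(self.a_inf_ml, params)


def fit_first_order(series: Sequence[PhStatRecord]) -> FirstOrderFit:
    """Fit first-order titrant kinetics to a pH-stat series."""
    t = np.array([r.time_min for r in series], dtype=float)
    a = np.array([r.volume_ml for r in series], dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 points to fit (k, A_inf)")

    def model(tt, k, a_inf):
        return a_inf * (1.0 - np.exp(-k * tt))

    a_max = max(a.max(), 1e-9)
    popt, pcov = curve_fit(
        model, t, a, p0=[0.02, a_max], bounds=([1e-6, 1e-9], [10.0, np.inf]), maxfev=10000
    )
    err = np.sqrt(np.diag(pcov))
    return FirstOrderFit(
        k=float(popt[0]), a_inf_ml=float(popt[1]),
        k_stderr=float(err[0]), a_inf_stderr=float(err[1]),
    )


def read_phstat_csv(path: str | Path) -> list[PhStatRecord]:
    """Read a titration series from CSV/TSV columns (time_min, volume_ml)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    missing = {"time_min", "volume_ml"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        PhStatRecord(float(r.time_min), float(r.volume_ml))
        for r in df.itertuples(index=False)
    ]
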