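"""Chromatographic peak lists.

A :class:`PeakTable` is a stream's (mass, area, intensity) list keyed by
stream identity (hydrolysate / permeate / retentate, membrane label, pH).
Peak lists are read and written as CSV/TSV with columns
``mass, area, intensity, stream, membrane, ph`` (dialect chosen by file
extension), matching what the downstream identification and transmission
stages expect.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

STREAMS = ("hydrolysate", "permeate", "retentate")

PEAK_COLUMNS = ["mass", "area", "intensity", "stream", "membrane", "ph"]


@dataclass(frozen=True)
class PeakRecord:
    """One integrated peak: observed mass (Da) with area and intensity."""

    mass: float
    area: float
    intensity: float
    stream: str = "hydrolysate"
    membrane: str = ""
    ph: float | None = None

    def __post_init__(self) -> None:
        if not self.mass > 0:
            raise ValueError(f"peak mass must be > 0, got {self.mass}")
        if self.area < 0 or self.intensity < 0:
            raise ValueError("peak area and intensity must be >= 0")
        if self.stream not in STREAMS:
            raise ValueError(f"stream must be one of {STREAMS}, got {self.stream!r}")


@dataclass(frozen=True)
class PeakTable:
    """A peak list plus stream metadata."""

    records: tuple[PeakRecord, ...]
    stream: str = "hydrolysate"
    membrane: str = ""
    ph: float | None = None
    replicate: int = 1

    def __len__(self) -> int:
        return len(self.records)

    @property
    def masses(self) -> list[float]:
        return [r.mass for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "mass": r.mass,
                    "area": r.area,
                    "intensity": r.intensity,
                    "stream": r.stream,
                    "membrane": r.membrane,
                    "ph": r.ph,
                }
                for r in self.records
            ],
            columns=PEAK_COLUMNS,
        )


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_peaks(path: str | Path) -> PeakTable:
    """Read a peak table from CSV/TSV (columns mass, area, intensity, ...)."""
    df = pd.read_csv(path, sep=_sep_for(path), comment="#")
    missing = {"mass", "area", "intensity"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing peak columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            PeakRecord(
                mass=float(row.mass),
                area=float(row.area),
                intensity=float(row.intensity),
                stream=str(getattr(row, "stream", "hydrolysate")),
                membrane="" if pd.isna(getattr(row, "membrane", "")) else str(getattr(row, "membrane", "")),
                ph=None if pd.isna(getattr(row, "ph", float("nan"))) else float(getattr(row, "ph")),
            )
        )
    meta = records[0] if records else None
    return PeakTable(
        records=tuple(records),
        stream=meta.stream if meta else "hydrolysate",
        membrane=meta.membrane if meta else "",
        ph=meta.ph if meta else None,
    )


def write_peaks(table: PeakTable, path: str | Path) -> None:
    """Write a peak table in the same CSV/TSV dialect `read_peaks` accepts."""
    table.to_frame().to_csv(path, sep=_sep_for(path), index=False)


def merge_peaks(table: PeakTable, mass_window: float = 0.005) -> PeakTable:
    """Merge peaks closer than *mass_window* Da (single-linkage clusters).

    Emulates chromatogram integration of one species split across scans:
    areas and intensities are summed; the merged mass is the area-weighted
    mean.  Applied before matching so one stream never carries two records
    at instrument-indistinguishable masses.
    """
    if not table.records:
        return table
    recs = sorted(table.records, key=lambda r: r.mass)
    merged: list[PeakRecord] = []
    cluster = [recs[0]]
    for r in recs[1:]:
        if r.mass - cluster[-1].mass <= mass_window:
            cluster.append(r)
        else:
            merged.append(_collapse(cluster))
            cluster = [r]
    merged.append(_collapse(cluster))
    return replace(table, records=tuple(merged))


def _collapse(cluster: list[PeakRecord]) -> PeakRecord:
    if len(cluster) == 1:
        return cluster[0]
    area = sum(r.area for r in cluster)
    weights = [r.area if area > 0 else 1.0 for r in cluster]
    mass = sum(w * r.mass for w, r in zip(weights, cluster)) / sum(weights)
    return replace(
        cluster[0],
        mass=mass,
        area=area,
        intensity=sum(r.intensity for r in cluster),
    )


def filter_peaks(table: PeakTable, relative_threshold: float = 0.10) -> PeakTable:
    """Base-peak intensity filter.

    Retains records whose intensity is strictly greater than
    ``relative_threshold`` times the most intense peak; the base peak itself
    is always retained.
    """
    if not 0 < relative_threshold < 1:
        raise ValueError("relative_threshold must be in (0, 1)")
    if not table.records:
        raise ValueError("cannot filter an empty peak table")
    top = max(r.intensity for r in table.records)
    if top == 0:
        raise ValueError("all intensities are zero; no base peak to filter against")
    cut = relative_threshold * top
    kept = tuple(r for r in table.records if r.intensity > cut or r.intensity == top)
    return replace(table, records=kept)
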