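"""Membrane transmission and selectivity analysis.

Observed transmission of a peptide across an ultrafiltration membrane is
the permeate-to-feed peak-area ratio,

    Tr_obs(%) = 100 * A_P / A_H,

which may exceed 100% through quantitation error (such values are retained
and flagged, never truncated).  The purely steric sieving prediction uses
the solute-to-pore size ratio lambda = (MW / MWCO)**0.4:

    Tr_theo(%) = 100 * (1 - (lambda*(lambda-2))**2) * exp(-0.7146 * lambda**2)

clamped to 0 for lambda >= 1 - the raw polynomial rebounds to positive
values on 1 < lambda < 2, which is unphysical for a sieving coefficient.

The separation factor between two peptide groups is the ratio of their
mean transmissions, S_x/y = mean(Tr, x) / mean(Tr, y); by default peptides
present in the feed but undetected in the permeate contribute Tr = 0 to
their group mean (the averages run over the number of peptides comprised
in each group), with a detected-only mode available.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

#: Sieving-model exponential coefficient.
SIEVE_EXP_COEFF = 0.7146
#: Sieving-model size-ratio exponent.
SIEVE_LAMBDA_EXP = 0.4


@dataclass(frozen=True)
class MembraneSpec:
    """An ultrafiltration membrane: name and nominal MW cut-off (Da)."""

    name: str
    mwco: float
    material: str = "PES"

    def __post_init__(self) -> None:
        if self.mwco <= 0:
            raise ValueError("membrane MWCO must be > 0")


#: The two study membranes: polyethersulfone, 5 kDa and 1 kDa cut-offs.
PES5 = MembraneSpec("PES5", 5000.0)
PES1 = MembraneSpec("PES1", 1000.0)


def tr_observed(area_permeate: float, area_hydrolysate: float) -> float:
    """Observed transmission (%), permeate over feed peak area."""
    if area_hydrolysate <= 0:
        raise ValueError("peptide absent from feed (hydrolysate area is zero)")
    if area_permeate < 0:
        raise ValueError("permeate area must be >= 0")
    return 100.0 * area_permeate / area_hydrolysate


def tr_theoretical(mw: float, membrane: MembraneSpec) -> float:
    """Steric sieving transmission (%), clamped to 0 for lambda >= 1."""
    if mw <= 0:
        raise ValueError("molecular weight must be > 0")
    lam = (mw / membrane.mwco) ** SIEVE_LAMBDA_EXP
    if lam >= 1.0:
        return 0.0
    return 100.0 * (1.0 - (lam * (lam - 2.0)) ** 2) * math.exp(-SIEVE_EXP_COEFF * lam * lam)


@dataclass(frozen=True)
class TransmissionRecord:
    """Per-peptide transmission under one (membrane, pH) condition."""

    sequence: str
    membrane: str
    ph: float
    tr_obs: float
    tr_theo: float
    group: str
    detected: bool = True

    def __post_init__(self) -> None:
        if self.tr_obs < 0:
            raise ValueError("Tr_obs must be >= 0")
        if not 0 <= self.tr_theo <= 100:
            raise ValueError("Tr_theo must lie in [0, 100]")

    @property
    def over_100(self) -> bool:
        """Quantitation-anomaly flag: observed transmission above 100%."""
        return self.tr_obs > 100.0


def separation_factor(
    tr_group_x: Sequence[float], tr_group_y: Sequence[float]
) -> float:
    """Ratio of mean transmissions of group x to group y.

    Returns ``inf`` (flagged by its very value) when group y's mean is
    zero; raises on empty groups.
    """
    if not len(tr_group_x) or not len(tr_group_y):
        raise ValueError("separation factor needs both groups non-empty")
    mean_x = float(np.mean(tr_group_x))
    mean_y = float(np.mean(tr_group_y))
    if mean_y == 0.0:
        return math.inf
    return mean_x / mean_y


@dataclass(frozen=True)
class TransmissionTable:
    """All transmission records of a run, with group-wise selectivity."""

    records: tuple[TransmissionRecord, ...]

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sequence": r.sequence,
                    "membrane": r.membrane,
                    "ph": r.ph,
                    "tr_obs": r.tr_obs,
                    "tr_theo": r.tr_theo,
                    "group": r.group,
                    "detected": r.detected,
                    "over_100": r.over_100,
                }
                for r in self.records
            ]
        )

    def conditions(self) -> list[tuple[str, float]]:
        seen: dict[tuple[str, float], None] = {}
        for r in self.records:
            seen.setdefault((r.membrane, r.ph), None)
        return list(seen)

    def group_means(self, detected_only: bool = False) -> pd.DataFrame:
        """Mean Tr_obs per (membrane, pH, group)."""
        df = self.to_frame()
        if detected_only:
            df = df[df["detected"]]
        return (
            df.groupby(["membrane", "ph", "group"])["tr_obs"]
            .agg(["mean", "count"])
            .rename(columns={"mean": "mean_tr_obs", "count": "n"})
            .reset_index()
        )

    def separation_factors(self, detected_only: bool = False) -> pd.DataFrame:
        """S_x/y for every ordered group pair under every condition."""
        means = self.group_means(detected_only=detected_only)
        rows = []
        for (membrane, ph), sub in means.groupby(["membrane", "ph"]):
            by_group = dict(zip(sub["group"], sub["mean_tr_obs"]))
            for x, y in itertools.permutations(by_group, 2):
                s = math.inf if by_group[y] == 0 else by_group[x] / by_group[y]
                rows.append(
                    {"membrane": membrane, "ph": ph, "pair": f"{x}/{y}", "s": s}
                )
        return pd.DataFrame(rows)


def condition_summary(table: TransmissionTable) -> pd.DataFrame:
    """Per-condition report: overall and group mean Tr_obs, mean deltas to
    the sieving prediction, and cross-membrane overall ratios at each pH."""
    df = table.to_frame()
    if df.empty:
        raise ValueError("transmission table is empty")
    rows = []
    for (membrane, ph), sub in df.groupby(["membrane", "ph"]):
        row = {
            "membrane": membrane,
            "ph": ph,
            "n_peptides": len(sub),
            "mean_tr_obs": sub["tr_obs"].mean(),
            "mean_tr_theo": sub["tr_theo"].mean(),
            "mean_delta_obs_theo": (sub["tr_obs"] - sub["tr_theo"]).mean(),
        }
        for group, gsub in sub.groupby("group"):
            row[f"mean_tr_obs_{group}"] = gsub["tr_obs"].mean()
        rows.append(row)
    out = pd.DataFrame(rows).sort_values(["ph", "membrane"]).reset_index(drop=True)

    ratios = []
    for ph, sub in out.groupby("ph"):
        for a, b in itertools.permutations(sub.index, 2):
            denom = out.loc[b, "mean_tr_obs"]
            ratios.append(
                {
                    "ph": ph,
                    "pair": f"{out.loc[a, 'membrane']}/{out.loc[b, 'membrane']}",
                    "overall_ratio": math.inf if denom == 0 else out.loc[a, "mean_tr_obs"] / denom,
                }
            )
    out.attrs["cross_membrane_ratios"] = pd.DataFrame(ratios)
    return out


def build_transmission_records(
    peptides,  # Sequence[PeptideRecord]
    feed_areas: dict,
    permeate_areas: dict,
    membrane: MembraneSpec,
    ph: float,
) -> TransmissionTable:
    """Assemble a transmission table from per-sequence peak areas.

    *feed_areas* / *permeate_areas* map peptide sequence to peak area;
    peptides absent from the permeate map are undetected (Tr_obs = 0),
    peptides absent from the feed map are skipped (nothing to divide by).
    """
    records = []
    for p in peptides:
        feed = feed_areas.get(p.sequence)
        if feed is None or feed <= 0:
            continue
        perm = permeate_areas.get(p.sequence, 0.0)
        records.append(
            TransmissionRecord(
                sequence=p.sequence,
                membrane=membrane.name,
                ph=ph,
                tr_obs=tr_observed(perm, feed),
                tr_theo=tr_theoretical(p.mass, membrane),
                group=p.group,
                detected=perm > 0,
            )
        )
    return TransmissionTable(records=tuple(records))
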