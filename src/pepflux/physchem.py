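"""Physicochemical peptide profiling.

GRAVY (grand average of hydropathy, Kyte-Doolittle scale), net charge at
arbitrary pH by Henderson-Hasselbalch summation over ionizable groups,
isoelectric point by bisection, and the acid / basic / neutral grouping
used for hydrolysate fractionation:

* acid    - pI < 5.0
* basic   - pI > 8.0
* neutral - otherwise (boundary values 5.0 and 8.0 classify as neutral,
  the enclosing interval, since the defining inequalities are strict)

Several published pKa tables are bundled; the package default,
``table1-calibrated``, is fixed so that computed charges at pH 2 and pH 10
track the bundled reference annotation table (see ``data/pka_tables.yaml``).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .sequences import validate_residues

#: Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

POSITIVE_SIDE_CHAINS = ("H", "K", "R")
NEGATIVE_SIDE_CHAINS = ("D", "E", "C", "Y")

GROUPS = ("acid", "basic", "neutral")
GROUP_CODES = {"acid": "A", "basic": "B", "neutral": "N"}


def gravy(sequence: str) -> float:
    """Arithmetic mean of Kyte-Doolittle hydropathies over the residues."""
    validate_residues(sequence)
    return sum(KYTE_DOOLITTLE[r] for r in sequence) / len(sequence)


@dataclass(frozen=True)
class PkaTable:
    """A named set of pKa values for termini and ionizable side chains."""

    name: str
    n_term: float
    c_term: float
    side_chains: dict  # residue -> pKa for D, E, C, Y, H, K, R

    def __post_init__(self) -> None:
        values = [self.n_term, self.c_term, *self.side_chains.values()]
        if not all(0 < v < 14 for v in values):
            raise ValueError(f"pKa values must lie in (0, 14): {values}")
        missing = set(POSITIVE_SIDE_CHAINS + NEGATIVE_SIDE_CHAINS) - set(self.side_chains)
        if missing:
            raise ValueError(f"pKa table {self.name!r} missing side chains {sorted(missing)}")
        # carboxylates must sit below the amine/guanidinium pKas
        if not max(self.side_chains[r] for r in "DE") < min(self.side_chains[r] for r in "KR"):
            raise ValueError(f"pKa table {self.name!r}: D/E pKa must be below K/R pKa")


def _packaged_tables() -> dict:
    ref = resources.files("pepflux.data").joinpath("pka_tables.yaml")
    return yaml.safe_load(ref.read_text())


def available_pka_tables() -> list[str]:
    return sorted(_packaged_tables())


def load_pka_table(name: str = "table1-calibrated") -> PkaTable:
    """Load a bundled pKa table by name."""
    tables = _packaged_tables()
    if name not in tables:
        raise KeyError(f"unknown pKa table {name!r}; bundled: {available_pka_tables()}")
    doc = tables[name]
    return PkaTable(
        name=name,
        n_term=float(doc["n_term"]),
        c_term=float(doc["c_term"]),
        side_chains={k: float(v) for k, v in doc["side_chains"].items()},
    )


def default_pka_table() -> PkaTable:
    return load_pka_table("table1-calibrated")


def net_charge(sequence: str, ph: float, pka: PkaTable | None = None) -> float:
    """Net charge in elementary units at *ph*.

    Positive groups (free N-terminus, H, K, R) each contribute
    ``+1 / (1 + 10**(pH - pKa))``; negative groups (free C-terminus, D, E,
    C, Y) contribute ``-1 / (1 + 10**(pKa - pH))``.  Strictly decreasing
    in pH.
    """
    validate_residues(sequence)
    if not 0 <= ph <= 14:
        raise ValueError("pH must lie in [0, 14]")
    pka = pka or default_pka_table()
    counts = {r: sequence.count(r) for r in set(sequence)}
    charge = 1.0 / (1.0 + 10.0 ** (ph - pka.n_term))
    charge -= 1.0 / (1.0 + 10.0 ** (pka.c_term - ph))
    for r in POSITIVE_SIDE_CHAINS:
        n = counts.get(r, 0)
        if n:
            charge += n / (1.0 + 10.0 ** (ph - pka.side_chains[r]))
    for r in NEGATIVE_SIDE_CHAINS:
        n = counts.get(r, 0)
        if n:
            charge -= n / (1.0 + 10.0 ** (pka.side_chains[r] - ph))
    return charge


def isoelectric_point(
    sequence: str, pka: PkaTable | None = None, tol: float = 1e-3
) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14].

    The charge is strictly decreasing in pH, so the crossing is unique;
    with both termini free it always exists inside the interval.
    """
    pka = pka or default_pka_table()
    lo, hi = 0.0, 14.0
    f_lo = net_charge(sequence, lo, pka)
    f_hi = net_charge(sequence, hi, pka)
    if f_lo < 0 or f_hi > 0:
        raise ValueError(
            f"net charge of {sequence!r} does not cross zero in [0, 14]"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def classify_group(pi: float) -> str:
    """Map a pI to the acid / basic / neutral fractionation group."""
    if not 0 <= pi <= 14:
        raise ValueError("pI must lie in [0, 14]")
    if pi < 5.0:
        return "acid"
    if pi > 8.0:
        return "basic"
    return "neutral"


@dataclass(frozen=True)
class PeptideRecord:
    """An identified peptide with its physicochemical annotations.

    ``mass`` is the singly protonated monoisotopic mass ([M+H]+, Da);
    the bioactivity score (a [0, 1] neural-network prediction) is consumed
    as input data, never computed here.
    """

    sequence: str
    preceding: str
    following: str
    mass: float
    charge_ph2: float
    charge_ph10: float
    gravy: float
    group: str
    pi: float | None = None
    bioactivity: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if not -4.5 <= self.gravy <= 4.5:
            raise ValueError("GRAVY outside the hydropathy-scale bounds [-4.5, 4.5]")

    @property
    def flanked(self) -> str:
        return f"({self.preceding})/{self.sequence}/({self.following})"


def annotate_peptide(
    sequence: str,
    preceding: str = "-",
    following: str = "-",
    bioactivity: float | None = None,
    pka: PkaTable | None = None,
    ph_values: tuple[float, float] = (2.0, 10.0),
) -> PeptideRecord:
    """Compute the full physicochemical annotation of one peptide."""
    from .masses import peptide_mass  # local import to avoid a cycle at import time

    pka = pka or default_pka_table()
    pi = isoelectric_point(sequence, pka)
    return PeptideRecord(
        sequence=sequence,
        preceding=preceding,
        following=following,
        mass=peptide_mass(sequence, charge_form="protonated"),
        charge_ph2=net_charge(sequence, ph_values[0], pka),
        charge_ph10=net_charge(sequence, ph_values[1], pka),
        gravy=gravy(sequence),
        group=classify_group(pi),
        pi=pi,
        bioactivity=bioactivity,
    )


@dataclass(frozen=True)
class GroupSummary:
    """Per-group statistics plus the overall high-bioactivity fraction."""

    table: pd.DataFrame  # index: group; columns: n, percent, mean_mass
    high_score_fraction: float  # percent of records with bioactivity > threshold
    threshold: float


def group_summary(
    records, bioactivity_threshold: float = 0.5
) -> GroupSummary:
    """Count, composition percentage and mean mass per group.

    Also reports the percentage of records whose bioactivity score exceeds
    *bioactivity_threshold* (records without a score count as not
    exceeding it).
    """
    records = list(records)
    if not records:
        return GroupSummary(
            table=pd.DataFrame(columns=["n", "percent", "mean_mass"]),
            high_score_fraction=float("nan"),
            threshold=bioactivity_threshold,
        )
    total = len(records)
    rows = {}
    for group in GROUPS:
        members = [r for r in records if r.group == group]
        if not members:
            continue
        rows[group] = {
            "n": len(members),
            "percent": 100.0 * len(members) / total,
            "mean_mass": float(np.mean([r.mass for r in members])),
        }
    high = sum(
        1 for r in records if r.bioactivity is not None and r.bioactivity > bioactivity_threshold
    )
    return GroupSummary(
        table=pd.DataFrame.from_dict(rows, orient="index"),
        high_score_fraction=100.0 * high / total,
        threshold=bioactivity_threshold,
    )


_GROUP_FROM_CODE = {"A": "acid", "B": "basic", "N": "neutral"}


def load_reference_table() -> list[PeptideRecord]:
    """The bundled reference annotation table: 43 peptides from a BSA peptic
    hydrolysate with literature-reported masses, charges, groups, GRAVY and
    bioactivity scores (all consumed as data)."""
    ref = resources.files("pepflux.data").joinpath("table1_bsa_peptic.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", comment="#")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            PeptideRecord(
                sequence=row.sequence,
                preceding=row.preceding,
                following=row.following,
                mass=float(row.mw),
                charge_ph2=float(row.charge_ph2),
                charge_ph10=float(row.charge_ph10),
                gravy=float(row.gravy),
                group=_GROUP_FROM_CODE[row.group],
                bioactivity=float(row.bioactivity),
            )
        )
    return records


def reference_frame() -> pd.DataFrame:
    """The bundled reference table as a DataFrame (verbatim columns)."""
    ref = resources.files("pepflux.data").joinpath("table1_bsa_peptic.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")
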