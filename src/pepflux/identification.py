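"""Mass-based peptide identification.

Matches observed peak masses against a theoretical peptide pool within an
absolute tolerance (the workflow default is +/-0.3 Da on [M+H]+ masses,
minimum length 3), assigns each peak a status, and reconciles the
hydrolysate (feed) list with permeate lists:

* ``unique``    - exactly one distinct candidate sequence within tolerance;
* ``ambiguous`` - two or more distinct sequences (excluded downstream);
* ``unmatched`` - none.

Only unique hydrolysate matches are accepted.  Masses seen in a permeate
but absent from the hydrolysate are excluded ("permeate-only"), as are
ambiguous masses; every exclusion carries a reason code.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .digestion import TheoreticalPeptide
from .masses import pool_masses
from .peaks import PeakRecord, PeakTable
from .sequences import ProteinSequence

STATUSES = ("unique", "ambiguous", "unmatched")

EXCLUSION_AMBIGUOUS = "ambiguous"
EXCLUSION_PERMEATE_ONLY = "permeate-only"
EXCLUSION_UNMATCHED = "unmatched"


@dataclass(frozen=True)
class MatchCandidate:
    peptide: TheoreticalPeptide
    theoretical_mass: float
    error: float  # observed - theoretical, Da


@dataclass(frozen=True)
class MatchResult:
    """All pool candidates for one observed mass, with a status."""

    observed_mass: float
    candidates: tuple[MatchCandidate, ...]
    status: str
    peak: PeakRecord | None = None

    @property
    def distinct_sequences(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for c in self.candidates:
            seen.setdefault(c.peptide.sequence, None)
        return tuple(seen)

    @property
    def best(self) -> MatchCandidate | None:
        return self.candidates[0] if self.candidates else None


def _status_for(candidates: Sequence[MatchCandidate]) -> str:
    n = len({c.peptide.sequence for c in candidates})
    if n == 0:
        return "unmatched"
    return "unique" if n == 1 else "ambiguous"


def match_masses(
    peaks: PeakTable | Sequence[float],
    pool: Sequence[TheoreticalPeptide],
    tolerance: float = 0.3,
    min_length: int = 3,
    pool_mass_values: np.ndarray | None = None,
    parent: ProteinSequence | None = None,
    mass_kind: str = "monoisotopic",
    charge_form: str = "protonated",
) -> list[MatchResult]:
    """Match observed masses to the theoretical pool within *tolerance* Da.

    Candidates are sorted by |error| ascending, ties by start coordinate.
    Ambiguity counts distinct candidate *sequences*: repeat occurrences of
    one sequence at different coordinates still count as a single candidate.
    ``pool_mass_values`` may supply precomputed masses (same charge form as
    the peaks); otherwise they are computed, using *parent* prefix sums when
    available.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    if isinstance(peaks, PeakTable):
        peak_records: list[PeakRecord | None] = list(peaks.records)
        observed = [r.mass for r in peaks.records]
    else:
        observed = [float(m) for m in peaks]
        peak_records = [None] * len(observed)

    keep = [i for i, p in enumerate(pool) if len(p.sequence) >= min_length]
    pool = [pool[i] for i in keep]
    if pool_mass_values is None:
        masses = pool_masses(pool, parent=parent, kind=mass_kind, charge_form=charge_form)
    else:
        masses = np.asarray(pool_mass_values, dtype=float)[keep]
    if len(pool) == 0:
        warnings.warn("empty theoretical pool; every mass will be unmatched")
        return [
            MatchResult(observed_mass=m, candidates=(), status="unmatched", peak=pr)
            for m, pr in zip(observed, peak_records)
        ]

    order = np.argsort(masses, kind="stable")
    sorted_masses = masses[order]

    results = []
    for m, pr in zip(observed, peak_records):
        lo = int(np.searchsorted(sorted_masses, m - tolerance, side="left"))
        hi = int(np.searchsorted(sorted_masses, m + tolerance, side="right"))
        cands = []
        for k in range(lo, hi):
            idx = int(order[k])
            err = m - float(masses[idx])
            if abs(err) <= tolerance:
                cands.append(MatchCandidate(pool[idx], float(masses[idx]), err))
        cands.sort(key=lambda c: (abs(c.error), c.peptide.start, c.peptide.end))
        results.append(
            MatchResult(
                observed_mass=m,
                candidates=tuple(cands),
                status=_status_for(cands),
                peak=pr,
            )
        )
    return results


@dataclass(frozen=True)
class Exclusion:
    observed_mass: float
    reason: str
    stream: str
    detail: str = ""


@dataclass(frozen=True)
class ReconcileResult:
    """Accepted identifications plus a categorised exclusion log."""

    accepted: tuple[MatchResult, ...]
    exclusions: tuple[Exclusion, ...]

    @property
    def exclusion_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self.exclusions:
            counts[e.reason] = counts.get(e.reason, 0) + 1
        return counts


def reconcile_streams(
    hydrolysate_matches: Sequence[MatchResult],
    permeate_matches: Sequence[MatchResult],
    mass_window: float = 0.3,
) -> ReconcileResult:
    """Apply the stream-level exclusion rules.

    Accepted identifications are the unique matches present in the
    hydrolysate.  Logged exclusions: ambiguous hydrolysate masses,
    unmatched hydrolysate masses, and permeate masses with no hydrolysate
    counterpart within *mass_window* Da ("permeate-only") - a peptide
    cannot appear downstream of a membrane if it was not in the feed.
    Both lists must come from the same pool and tolerance.
    """
    accepted = []
    exclusions = []
    hydro_masses = sorted(m.observed_mass for m in hydrolysate_matches)

    for m in hydrolysate_matches:
        if m.status == "unique":
            accepted.append(m)
        elif m.status == "ambiguous":
            exclusions.append(
                Exclusion(
                    m.observed_mass,
                    EXCLUSION_AMBIGUOUS,
                    "hydrolysate",
                    detail=",".join(m.distinct_sequences),
                )
            )
        else:
            exclusions.append(
                Exclusion(m.observed_mass, EXCLUSION_UNMATCHED, "hydrolysate")
            )

    arr = np.asarray(hydro_masses, dtype=float)
    for m in permeate_matches:
        if arr.size and np.min(np.abs(arr - m.observed_mass)) <= mass_window:
            continue  # present in the feed; its fate is decided there
        exclusions.append(
            Exclusion(
                m.observed_mass,
                EXCLUSION_PERMEATE_ONLY,
                "permeate",
                detail=";".join(m.distinct_sequences),
            )
        )
    return ReconcileResult(accepted=tuple(accepted), exclusions=tuple(exclusions))
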