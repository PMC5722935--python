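"""Peptide mass computation.

Monoisotopic and average masses come from the pyteomics residue/atomic mass
tables (>= 4 decimal places internally).  Two charge forms are exposed and
all conversions are explicit: ``neutral`` is the uncharged molecule M,
``protonated`` the singly protonated species [M+H]+ (M plus one proton).
Reference peak-list masses throughout the package are [M+H]+ monoisotopic.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from pyteomics import mass as _pmass

from .digestion import TheoreticalPeptide
from .sequences import ProteinSequence, validate_residues

#: Mass of a proton, Da (CODATA).
PROTON = 1.00727646688

MASS_KINDS = ("monoisotopic", "average")
CHARGE_FORMS = ("neutral", "protonated")


def peptide_mass(
    sequence: str,
    kind: str = "monoisotopic",
    charge_form: str = "neutral",
) -> float:
    """Mass of a free peptide in Da.

    Sum of residue masses plus one water, plus one proton for the
    ``protonated`` ([M+H]+) form.
    """
    validate_residues(sequence)
    if kind not in MASS_KINDS:
        raise ValueError(f"kind must be one of {MASS_KINDS}")
    if charge_form not in CHARGE_FORMS:
        raise ValueError(f"charge_form must be one of {CHARGE_FORMS}")
    m = _pmass.calculate_mass(sequence=sequence, average=(kind == "average"))
    if charge_form == "protonated":
        m += PROTON
    return float(m)


def residue_prefix_masses(parent: ProteinSequence, kind: str = "monoisotopic") -> np.ndarray:
    """Cumulative residue masses of *parent*; prefix[i] sums residues 1..i.

    Lets any substring mass be formed as a difference plus water, which is
    how large theoretical pools (e.g. non-specific digests) are annotated
    without quadratic cost.
    """
    aa = _pmass.std_aa_mass if kind == "monoisotopic" else None
    if kind == "average":
        aa = {k: _pmass.calculate_mass(parsed_sequence=[k], average=True)
              for k in set(parent.residues)}
    masses = np.array([aa[r] for r in parent.residues])
    return np.concatenate([[0.0], np.cumsum(masses)])


def pool_masses(
    pool: Sequence[TheoreticalPeptide],
    parent: ProteinSequence | None = None,
    kind: str = "monoisotopic",
    charge_form: str = "protonated",
) -> np.ndarray:
    """Masses for a pool of theoretical peptides.

    With *parent* given (and every pool member carrying coordinates in it),
    masses come from prefix sums in O(n); otherwise each distinct sequence
    is computed once.
    """
    water = _pmass.calculate_mass(formula="H2O", average=(kind == "average"))
    offset = water + (PROTON if charge_form == "protonated" else 0.0)
    if parent is not None:
        prefix = residue_prefix_masses(parent, kind=kind)
        return np.array([prefix[p.end] - prefix[p.start - 1] + offset for p in pool])
    cache: dict[str, float] = {}
    out = np.empty(len(pool))
    for i, p in enumerate(pool):
        m = cache.get(p.sequence)
        if m is None:
            m = cache[p.sequence] = peptide_mass(p.sequence, kind=kind, charge_form=charge_form)
        out[i] = m
    return out
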