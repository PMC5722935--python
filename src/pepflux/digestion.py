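"""Rule-based in-silico proteolysis.

Locates cleavable peptide bonds under a :class:`~pepflux.rules.CleavageRuleSet`,
derives the theoretical maximum degree of hydrolysis (DH_max, the percentage
of bonds the enzyme could ever cleave), and enumerates candidate peptides in
three specificity modes:

* ``specific`` - fragments bounded by cleavage sites or chain termini, with
  at most ``max_missed`` internal (missed) sites;
* ``semi-specific`` - substrings with at least one end on a cleavage
  boundary and at most ``max_missed`` internal sites;
* ``non-specific`` - every substring of at least ``min_length`` residues
  (guarded by a configurable parent-length cap).

Bond *i* (1-based) joins residues *i* and *i+1*; peptide coordinates are
1-based inclusive.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

from .rules import CleavageRuleSet
from .sequences import ProteinSequence

TERMINUS = "-"

SPECIFICITY_MODES = ("specific", "semi-specific", "non-specific")


@dataclass(frozen=True)
class CleavageMap:
    """Bond-indexed cleavability of a sequence under one rule set."""

    protein: ProteinSequence
    sites: frozenset[int]
    rule_set_name: str = ""

    def __post_init__(self) -> None:
        bad = [b for b in self.sites if not 1 <= b <= self.protein.n_bonds]
        if bad:
            raise ValueError(f"bond indices out of range [1, {self.protein.n_bonds}]: {sorted(bad)}")

    @property
    def n_bonds(self) -> int:
        return self.protein.n_bonds

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def dh_max(self) -> float:
        """Theoretical maximum degree of hydrolysis, percent."""
        return max_degree_of_hydrolysis(self)


@dataclass(frozen=True)
class TheoreticalPeptide:
    """A candidate peptide from in-silico digestion.

    ``start``/``end`` are 1-based inclusive coordinates in the parent;
    flanking residues are single letters, or ``"-"`` at a chain terminus.
    """

    sequence: str
    start: int
    end: int
    preceding: str
    following: str
    specificity: str
    missed_cleavages: int = 0

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad coordinates [{self.start}, {self.end}]")
        if self.specificity not in SPECIFICITY_MODES:
            raise ValueError(f"specificity must be one of {SPECIFICITY_MODES}")

    @property
    def flanked(self) -> str:
        """Reference-table notation, e.g. ``(L)/IAF/(S)``."""
        return f"({self.preceding})/{self.sequence}/({self.following})"


def find_cleavage_sites(
    protein: ProteinSequence, rule_set: CleavageRuleSet
) -> CleavageMap:
    """Locate all cleavable bonds of *protein* under *rule_set*.

    A bond is cleavable when at least one license rule matches its context
    window and no veto rule does.  Deterministic and idempotent.
    """
    sites = set()
    for bond in range(1, protein.n_bonds + 1):
        def residue_at(offset: int, _bond: int = bond) -> str | None:
            return protein.residue(_bond + offset)

        if not any(r.matches(residue_at) for r in rule_set.licenses):
            continue
        if any(r.matches(residue_at) for r in rule_set.vetoes):
            continue
        sites.add(bond)
    return CleavageMap(protein=protein, sites=frozenset(sites), rule_set_name=rule_set.name)


def max_degree_of_hydrolysis(cmap: CleavageMap) -> float:
    """DH_max(%) = 100 * |cleavable bonds| / n_bonds, unrounded."""
    if cmap.n_bonds == 0:
        raise ValueError("sequence has no peptide bonds; DH_max undefined")
    return 100.0 * cmap.n_sites / cmap.n_bonds


def _flanks(protein: ProteinSequence, start: int, end: int) -> tuple[str, str]:
    pre = protein.residue(start - 1) or TERMINUS
    post = protein.residue(end + 1) or TERMINUS
    return pre, post


def enumerate_peptides(
    protein: ProteinSequence,
    cmap: CleavageMap,
    min_length: int = 3,
    mode: str = "specific",
    max_missed: int = 0,
    nonspecific_cap: int = 1000,
) -> list[TheoreticalPeptide]:
    """Enumerate candidate peptides of *protein* given its cleavage map.

    Output is duplicate-free on (start, end) and sorted by start then end.
    Non-specific enumeration refuses parents longer than *nonspecific_cap*
    residues (quadratically many substrings).
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    if mode not in SPECIFICITY_MODES:
        raise ValueError(f"mode must be one of {SPECIFICITY_MODES}")

    seq = protein.residues
    n = len(seq)
    sites = sorted(cmap.sites)

    out: list[TheoreticalPeptide] = []

    if mode == "specific":
        boundaries = [0] + sites + [n]
        for i, left in enumerate(boundaries[:-1]):
            # at most max_missed internal sites => at most max_missed+1 fragments ahead
            for j in range(i + 1, min(i + max_missed + 2, len(boundaries))):
                right = boundaries[j]
                if right - left < min_length:
                    continue
                start, end = left + 1, right
                pre, post = _flanks(protein, start, end)
                out.append(
                    TheoreticalPeptide(
                        sequence=seq[left:right],
                        start=start,
                        end=end,
                        preceding=pre,
                        following=post,
                        specificity="specific",
                        missed_cleavages=j - i - 1,
                    )
                )
        out.sort(key=lambda p: (p.start, p.end))
        return out

    if mode == "non-specific" and n > nonspecific_cap:
        raise ValueError(
            f"non-specific enumeration of a {n}-residue parent would generate "
            f"~{n * n // 2} substrings; raise nonspecific_cap (now {nonspecific_cap}) "
            "explicitly if this is intended"
        )

    boundary_set = {0, n, *sites}
    # prefix[i] = number of sites <= i, for internal-site counting
    for start in range(1, n + 1):
        for end in range(start + min_length - 1, n + 1):
            left, right = start - 1, end
            if mode == "semi-specific":
                if left not in boundary_set and right not in boundary_set:
                    continue
            lo = bisect.bisect_right(sites, left)
            hi = bisect.bisect_left(sites, right)
            missed = hi - lo
            if mode == "semi-specific" and missed > max_missed:
                continue
            pre, post = _flanks(protein, start, end)
            out.append(
                TheoreticalPeptide(
                    sequence=seq[left:right],
                    start=start,
                    end=end,
                    preceding=pre,
                    following=post,
                    specificity=mode,
                    missed_cleavages=missed,
                )
            )
    out.sort(key=lambda p: (p.start, p.end))
    return out
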