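"""Rule-based digestion: cleavage-site location, DH_max, peptide enumeration.

The independent oracles here are (a) hand application of the pepsin rule
table bond by bond on short sequences, (b) a brute-force enumerator over
boundary pairs / substrings, and (c) the pyteomics regex-based cleavage
rules for the bulk of the chain (their lookaround patterns require a full
context window, so the comparison excludes bonds within two residues of a
terminus, where the semantics legitimately differ).
"""

import re

import pytest
from hypothesis import given, settings, strategies as st
from pyteomics import parser as pyt_parser

from pepflux import (
    ProteinSequence,
    enumerate_peptides,
    find_cleavage_sites,
    max_degree_of_hydrolysis,
)
from pepflux.digestion import CleavageMap
from pepflux.rules import RuleError, load_rule_set
from pepflux.sequences import SequenceError

AA = "ACDEFGHIKLMNPQRSTVWY"

random_protein = st.text(alphabet=AA, min_size=2, max_size=30).map(
    lambda s: ProteinSequence("h", s)
)


def brute_force_sites_ph2(seq: str) -> set[int]:
    """Direct transliteration of the pepsin pH>2 rule table, evaluated
    independently per bond with permissive termini."""
    n = len(seq)
    sites = set()
    for b in range(1, n):
        def res(i):
            return seq[i - 1] if 1 <= i <= n else None
        p3, p2, p1, p1p, p2p = res(b - 2), res(b - 1), res(b), res(b + 1), res(b + 2)
        lic = (p1 in "FLWY") or (p1p in "FLWY" and p1 != "R")
        veto = (p3 in "HKR" if p3 else False) or (p2 == "P") or (p2p == "P")
        if lic and not veto:
            sites.add(b)
    return sites


class TestFindCleavageSites:
    def test_bsa_calibration(self, bsa, bsa_map):
        """The pH>2 pepsin variant reproduces the expected 147 cleavable
        bonds over the mature chain's 582 peptide bonds."""
        assert bsa.n_bonds == 582
        assert bsa_map.n_sites == 147

    def test_polyglycine_has_no_sites(self, pepsin, protein_factory):
        cmap = find_cleavage_sites(protein_factory("GGGGG"), pepsin)
        assert cmap.sites == frozenset()

    def test_aafaa_hand_derived(self, pepsin, protein_factory):
        # bond-by-bond: bond 2 licensed by P1'=F, bond 3 by P1=F; no vetoes
        cmap = find_cleavage_sites(protein_factory("AAFAA"), pepsin)
        assert cmap.sites == frozenset({2, 3})

    def test_idempotent_and_in_range(self, bsa, pepsin, bsa_map):
        again = find_cleavage_sites(bsa, pepsin)
        assert again.sites == bsa_map.sites
        assert all(1 <= b <= bsa.n_bonds for b in bsa_map.sites)

    @given(random_protein)
    @settings(max_examples=150, deadline=None)
    def test_matches_independent_rule_transliteration(self, protein):
        rules = load_rule_set("pepsin-ph2")
        cmap = find_cleavage_sites(protein, rules)
        assert cmap.sites == frozenset(brute_force_sites_ph2(protein.residues))

    def test_matches_pyteomics_away_from_termini(self, bsa, bsa_map):
        """Interior bonds agree with the pyteomics regex rules (which block
        cleavage when the context window is truncated by a terminus)."""
        rule = pyt_parser.expasy_rules["pepsin ph2.0"]
        regex_sites = {
            m.end() for m in re.finditer(rule, bsa.residues)
            if 0 < m.end() < len(bsa.residues)
        }
        interior = set(range(3, bsa.n_bonds - 1))
        assert bsa_map.sites & interior == regex_sites & interior

    def test_unknown_residue_names_position(self, pepsin):
        with pytest.raises(SequenceError, match="position 3"):
            find_cleavage_sites(ProteinSequence("bad", "AAXAA"), pepsin)

    def test_rule_set_without_licenses_rejected(self):
        from pepflux.rules import rule_set_from_dict

        with pytest.raises(RuleError):
            rule_set_from_dict(
                {"enzyme": "x", "rules": [
                    {"action": "veto", "where": {"P1": {"in": ["P"]}}}]}
            )


class TestDhMax:
    def test_bsa_value(self, bsa_map):
        assert max_degree_of_hydrolysis(bsa_map) == pytest.approx(
            100 * 147 / 582, abs=1e-12
        )
        assert round(bsa_map.dh_max, 2) == 25.26

    @pytest.mark.parametrize(
        "n_sites, n_residues, expected",
        [(0, 11, 0.0), (10, 11, 100.0)],
    )
    def test_limits(self, protein_factory, n_sites, n_residues, expected):
        protein = protein_factory("A" * n_residues)
        cmap = CleavageMap(protein, frozenset(range(1, n_sites + 1)))
        assert max_degree_of_hydrolysis(cmap) == pytest.approx(expected)

    def test_out_of_range_bond_rejected(self, protein_factory):
        with pytest.raises(ValueError):
            CleavageMap(protein_factory("AAA"), frozenset({5}))


def brute_force_specific(seq: str, sites: set[int], min_length: int, max_missed: int):
    """All (start, end) windows between boundaries, via a double loop."""
    bounds = sorted({0, len(seq), *sites})
    out = set()
    for i, a in enumerate(bounds):
        for b in bounds[i + 1:]:
            internal = sum(1 for s in sites if a < s < b)
            if internal <= max_missed and b - a >= min_length:
                out.add((a + 1, b))
    return out


class TestEnumeratePeptides:
    def test_single_cut_partitions(self, protein_factory):
        protein = protein_factory("AAFAA")
        cmap = CleavageMap(protein, frozenset({3}))
        peptides = enumerate_peptides(protein, cmap, min_length=1, max_missed=0)
        assert {p.sequence for p in peptides} == {"AAF", "AA"}
        assert [(p.start, p.end) for p in peptides] == [(1, 3), (4, 5)]
        assert peptides[0].preceding == "-" and peptides[0].following == "A"

    def test_nonspecific_counting(self, protein_factory):
        protein = protein_factory("AAFAA")
        cmap = CleavageMap(protein, frozenset())
        peptides = enumerate_peptides(protein, cmap, min_length=3, mode="non-specific")
        assert len(peptides) == 6  # sum over L=3..5 of (5-L+1)
        assert len({(p.start, p.end) for p in peptides}) == 6

    def test_nonspecific_cap_refuses(self, protein_factory):
        protein = protein_factory("A" * 50)
        cmap = CleavageMap(protein, frozenset())
        with pytest.raises(ValueError, match="nonspecific_cap"):
            enumerate_peptides(protein, cmap, mode="non-specific", nonspecific_cap=30)

    @given(
        st.text(alphabet=AA, min_size=2, max_size=30),
        st.integers(min_value=0, max_value=3),
        st.integers(min_value=1, max_value=4),
    )
    @settings(max_examples=100, deadline=None)
    def test_specific_equals_brute_force(self, residues, max_missed, min_length):
        protein = ProteinSequence("h", residues)
        cmap = find_cleavage_sites(protein, load_rule_set("pepsin-ph2"))
        got = {
            (p.start, p.end)
            for p in enumerate_peptides(
                protein, cmap, min_length=min_length, max_missed=max_missed
            )
        }
        assert got == brute_force_specific(
            residues, set(cmap.sites), min_length, max_missed
        )

    def test_max_missed_all_sites_gives_all_boundary_pairs(self, protein_factory):
        protein = protein_factory("LALALALALA")
        cmap = find_cleavage_sites(protein, load_rule_set("pepsin-ph2"))
        all_pairs = enumerate_peptides(
            protein, cmap, min_length=1, max_missed=len(cmap.sites)
        )
        assert {(p.start, p.end) for p in all_pairs} == brute_force_specific(
            protein.residues, set(cmap.sites), 1, len(cmap.sites)
        )

    def test_zero_missed_fragments_tile_parent(self, bsa, bsa_map):
        frags = enumerate_peptides(bsa, bsa_map, min_length=1, max_missed=0)
        assert "".join(p.sequence for p in frags) == bsa.residues

    def test_bsa_one_missed_matches_brute_force_count(self, bsa, bsa_map):
        peptides = enumerate_peptides(bsa, bsa_map, min_length=3, max_missed=1)
        expected = brute_force_specific(bsa.residues, set(bsa_map.sites), 3, 1)
        assert {(p.start, p.end) for p in peptides} == expected

    def test_semi_specific_requires_one_boundary(self, protein_factory):
        protein = protein_factory("AAFAA")
        cmap = CleavageMap(protein, frozenset({3}))
        semi = enumerate_peptides(
            protein, cmap, min_length=2, mode="semi-specific", max_missed=0
        )
        boundaries = {0, 3, 5}
        assert semi
        for p in semi:
            assert p.start - 1 in boundaries or p.end in boundaries
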