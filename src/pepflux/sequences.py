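"""Protein substrate handling.

The package's bundled substrate is the mature bovine serum albumin (BSA)
chain, UniProt P02769 residues 25-607 (precursor minus the 18-residue
signal peptide and the 6-residue propeptide): 583 residues, hence 582
peptide bonds.  The bundled FASTA is a synthetic reconstruction of that
chain assembled from the published sequence literature rather than a
verbatim database export; it reproduces the 582-bond arithmetic and the
flanking contexts of the peptic peptides it is used with.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from Bio import SeqIO

#: The 20 standard amino acids, one-letter code.
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


class SequenceError(ValueError):
    """Raised for sequences that are empty or contain unknown residues."""


def validate_residues(residues: str) -> None:
    """Check that *residues* uses only the 20 standard letters.

    Raises :class:`SequenceError` naming the first offending position.
    """
    if not residues:
        raise SequenceError("empty sequence")
    for pos, letter in enumerate(residues, start=1):
        if letter not in STANDARD_RESIDUES:
            raise SequenceError(
                f"unknown residue {letter!r} at position {pos}; only the 20 "
                "standard one-letter codes are accepted"
            )


@dataclass(frozen=True)
class ProteinSequence:
    """A substrate polypeptide with provenance.

    Parameters
    ----------
    identifier : str
        Record name, e.g. a FASTA header token.
    residues : str
        Uppercase one-letter sequence; standard residues only, length >= 2.
    provenance : str
        Free-text origin note (accession, chain coordinates, ...).
    """

    identifier: str
    residues: str
    provenance: str = ""

    def __post_init__(self) -> None:
        validate_residues(self.residues)
        if len(self.residues) < 2:
            raise SequenceError("a substrate needs at least 2 residues (1 bond)")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def n_bonds(self) -> int:
        """Number of peptide bonds (length - 1)."""
        return len(self.residues) - 1

    def residue(self, position: int) -> str | None:
        """1-based residue lookup; ``None`` beyond the chain ends."""
        if 1 <= position <= len(self.residues):
            return self.residues[position - 1]
        return None


def read_fasta(path: str | Path, identifier: str | None = None) -> ProteinSequence:
    """Read a substrate from a FASTA file.

    The first record is used unless *identifier* names a specific one.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"no FASTA records in {path}")
    if identifier is not None:
        by_id = {rec.id: rec for rec in records}
        if identifier not in by_id:
            raise SequenceError(f"no record {identifier!r} in {path}")
        rec = by_id[identifier]
    else:
        rec = records[0]
    return ProteinSequence(
        identifier=rec.id,
        residues=str(rec.seq).upper(),
        provenance=f"read from {Path(path).name}: {rec.description}",
    )


def mature_bsa() -> ProteinSequence:
    """The bundled mature BSA chain (synthetic reconstruction of P02769 25-607)."""
    ref = resources.files("pepflux.data").joinpath("bsa_mature.fasta")
    with resources.as_file(ref) as path:
        seq = read_fasta(path)
    return ProteinSequence(
        identifier="BSA_mature",
        residues=seq.residues,
        provenance="UniProt P02769 mature chain 25-607 (synthetic reconstruction)",
    )
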