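"""Protein-mass arithmetic and crystallographic cell utilities.

Average-mass peptide sums (for reconciling an ESI-MS measured subunit
mass with a predicted mass minus a proteolytically removed C-terminal
peptide) and the Matthews-coefficient / solvent-content arithmetic for
a hexagonal crystal cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

__all__ = [
    "PeptideSequence",
    "CellStats",
    "AVERAGE_RESIDUE_MASS",
    "MONOISOTOPIC_RESIDUE_MASS",
    "WATER_MASS_AVERAGE",
    "residue_mass_sum",
    "peptide_mass",
    "truncation_mass",
    "hexagonal_cell_volume",
    "matthews_coefficient",
    "matthews_solvent_fraction",
]

# IUPAC average residue masses (amino acid minus water), Da
AVERAGE_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

# Monoisotopic residue masses, Da
MONOISOTOPIC_RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276, "V": 99.06841,
    "T": 101.04768, "C": 103.00919, "L": 113.08406, "I": 113.08406,
    "N": 114.04293, "D": 115.02694, "Q": 128.05858, "K": 128.09496,
    "E": 129.04259, "M": 131.04049, "H": 137.05891, "F": 147.06841,
    "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

WATER_MASS_AVERAGE = 18.0153
WATER_MASS_MONOISOTOPIC = 18.01056

#: Reciprocal of (partial specific volume 0.74 cm^3/g expressed in
#: A^3/Da): the classical zero-solvent limit of the Matthews coefficient.
_VM_PROTEIN = 1.23


@dataclass(frozen=True)
class PeptideSequence:
    """A peptide as a one-letter amino-acid string (20 canonical letters)."""

    residues: str

    def __post_init__(self) -> None:
        for ch in self.residues:
            if ch not in AVERAGE_RESIDUE_MASS:
                raise ValueError(f"unknown amino-acid letter {ch!r}")

    def __len__(self) -> int:
        return len(self.residues)

    def __add__(self, other: "PeptideSequence") -> "PeptideSequence":
        return PeptideSequence(self.residues + other.residues)


@dataclass(frozen=True)
class CellStats:
    """Hexagonal cell dimensions and derived packing statistics."""

    a: float
    b: float
    c: float
    space_group_z: int
    vm: float
    solvent_fraction: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        if self.vm <= 0:
            raise ValueError("Matthews coefficient must be positive")
        if not 0.0 <= self.solvent_fraction < 1.0:
            raise ValueError("solvent_fraction must lie in [0, 1)")


def residue_mass_sum(seq: PeptideSequence, monoisotopic: bool = False) -> float:
    """Sum of residue (amino acid minus water) masses in Da.

    Average masses by default — the convention of predicted denatured
    protein masses; monoisotopic behind the flag.
    """
    table = MONOISOTOPIC_RESIDUE_MASS if monoisotopic else AVERAGE_RESIDUE_MASS
    return sum(table[ch] for ch in seq.residues)


def peptide_mass(seq: PeptideSequence, monoisotopic: bool = False) -> float:
    """Free-peptide mass: residue sum plus one water."""
    water = WATER_MASS_MONOISOTOPIC if monoisotopic else WATER_MASS_AVERAGE
    return residue_mass_sum(seq, monoisotopic) + water


def truncation_mass(full_mass: float, removed: PeptideSequence, monoisotopic: bool = False) -> float:
    """Predicted mass of a chain after proteolytic removal of a terminal
    peptide: ``full_mass`` minus the residue-mass sum of ``removed``
    (the cleaved peptide carries the water away with it)."""
    loss = residue_mass_sum(removed, monoisotopic)
    if loss >= full_mass:
        raise ValueError("removed peptide is heavier than the full chain")
    return full_mass - loss


def hexagonal_cell_volume(a: float, c: float) -> float:
    """Volume of a hexagonal unit cell: ``a^2 * c * sqrt(3)/2`` (A^3)."""
    if a <= 0 or c <= 0:
        raise ValueError("cell lengths must be positive")
    return a * a * c * sqrt(3.0) / 2.0


def matthews_coefficient(cell_volume: float, z: int, mass: float) -> float:
    """Matthews coefficient V_m = cell volume / (Z * mass), A^3/Da.

    ``z`` is the number of protein molecules in the unit cell
    (symmetry operators times molecules per asymmetric unit).
    """
    if cell_volume <= 0 or z <= 0:
        raise ValueError("cell volume and z must be positive")
    if mass <= 0:
        raise ValueError("mass must be positive")
    return cell_volume / (z * mass)


def matthews_solvent_fraction(vm: float) -> float:
    """Solvent content (percent) from the Matthews coefficient.

    ``100 * (1 - 1.23 / vm)``, the classical estimate with protein
    partial specific volume 0.74 cm^3/g. ``vm`` below 1.23 A^3/Da would
    mean negative solvent and is rejected.
    """
    if vm < _VM_PROTEIN:
        raise ValueError(
            f"V_m = {vm} A^3/Da is below the protein-only limit {_VM_PROTEIN}"
        )
    return 100.0 * (1.0 - _VM_PROTEIN / vm)
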