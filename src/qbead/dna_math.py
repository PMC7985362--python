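"""Molecular arithmetic for DNA-coated bead samples.

Links the quantities a bead-based impedance assay works in: fragment
length (bp), mean DNA copies per bead, per-bead mass, and the total mass
and molar amount carried by an aliquot of beads.  Double-stranded DNA is
assigned the standard average molar mass of 650 g/mol per base pair;
sequence composition and the biotin label are neglected.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.constants import Avogadro

#: Average molar mass of one base pair of double-stranded DNA, g/mol.
BP_MOLAR_MASS = 650.0

NG_PER_G = 1e9
FG_PER_G = 1e15
FMOL_PER_MOL = 1e15


@dataclass(frozen=True)
class SampleSpec:
    """Description of one bead population.

    Parameters
    ----------
    label:
        Free-text sample identifier.
    dna_length_bp:
        Fragment length in base pairs; 0 only for DNA-free beads.
    copies_per_bead:
        Mean number of DNA molecules bound per bead (population average).
        0 marks a negative control (bare streptavidin beads).
    n_beads:
        Number of beads in the measured aliquot.
    """

    label: str
    dna_length_bp: int
    copies_per_bead: float
    n_beads: int

    def __post_init__(self) -> None:
        if self.dna_length_bp < 0:
            raise ValueError("dna_length_bp must be >= 0")
        if self.copies_per_bead < 0:
            raise ValueError("copies_per_bead must be >= 0")
        if self.n_beads < 0:
            raise ValueError("n_beads must be >= 0")
        if self.dna_length_bp == 0 and self.copies_per_bead > 0:
            raise ValueError("dna_length_bp may be 0 only for DNA-free beads")

    @property
    def is_control(self) -> bool:
        """True for a DNA-free (bare bead) negative control."""
        return self.copies_per_bead == 0

    @property
    def mass_per_bead(self) -> float:
        """Mean DNA mass per bead in grams."""
        return per_bead_mass(self.copies_per_bead, self.dna_length_bp)


@dataclass(frozen=True)
class DNAQuantity:
    """DNA content of a bead aliquot, in SI units.

    ``total_mass = mass_per_bead * n_beads`` and
    ``total_moles = copies_per_bead * n_beads / N_A`` by construction.
    """

    mass_per_bead: float  # grams
    total_mass: float  # grams
    total_moles: float  # moles

    def __post_init__(self) -> None:
        if min(self.mass_per_bead, self.total_mass, self.total_moles) < 0:
            raise ValueError("DNA quantities must be non-negative")

    @property
    def mass_per_bead_ng(self) -> float:
        return self.mass_per_bead * NG_PER_G

    @property
    def mass_per_bead_fg(self) -> float:
        return self.mass_per_bead * FG_PER_G

    @property
    def total_mass_ng(self) -> float:
        return self.total_mass * NG_PER_G

    @property
    def total_fmol(self) -> float:
        return self.total_moles * FMOL_PER_MOL


def molecule_molar_mass(dna_length_bp: float) -> float:
    """Molar mass (g/mol) of a double-stranded fragment of given length."""
    if dna_length_bp < 0:
        raise ValueError("dna_length_bp must be >= 0")
    return dna_length_bp * BP_MOLAR_MASS


def per_bead_mass(copies_per_bead: float, dna_length_bp: float) -> float:
    """Mean DNA mass per bead, in grams.

    ``copies_per_bead * M(L) / N_A`` — exactly linear in both arguments.
    """
    if copies_per_bead < 0:
        raise ValueError("copies_per_bead must be >= 0")
    return copies_per_bead * molecule_molar_mass(dna_length_bp) / Avogadro


def aliquot_quantity(spec: SampleSpec) -> DNAQuantity:
    """Total DNA mass and molar amount in an aliquot of ``spec.n_beads`` beads.

    An empty aliquot (``n_beads == 0``) is a degenerate but valid input and
    returns all-zero quantities.
    """
    m_bead = per_bead_mass(spec.copies_per_bead, spec.dna_length_bp)
    total_mass = m_bead * spec.n_beads
    total_moles = spec.copies_per_bead * spec.n_beads / Avogadro
    return DNAQuantity(m_bead, total_mass, total_moles)


def copies_from_mass(total_mass: float, dna_length_bp: float, n_beads: int) -> float:
    """Invert :func:`aliquot_quantity`'s mass path to copies per bead.

    Exact inverse up to floating-point round-off (relative error < 1e-9).
    """
    if total_mass < 0:
        raise ValueError("total_mass must be >= 0")
    if dna_length_bp <= 0:
        raise ValueError("dna_length_bp must be > 0")
    if n_beads <= 0:
        raise ValueError("n_beads must be > 0")
    return total_mass * Avogadro / (molecule_molar_mass(dna_length_bp) * n_beads)
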