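"""Molecular structure identity, mass, and similarity primitives.

A :class:`Molecule` is the unit of chemical identity throughout the
package: a canonical SMILES, a standard InChIKey, a monoisotopic mass and
a circular substructure fingerprint.  Structure identity comparisons use
the first 14 InChIKey characters (the 2D-connectivity block), so
stereoisomers and salt/protonation variants compare equal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from rdkit import Chem, RDLogger
from rdkit.Chem import DataStructs, Descriptors, inchi, rdFingerprintGenerator

from .errors import FingerprintMismatchError, StructureParseError, ValenceError

RDLogger.DisableLog("rdApp.*")

#: Mass of a proton in Da, used for [M+H]+ / [M-H]- arithmetic.
PROTON_MASS = 1.00728

#: Monoisotopic mass of a hydrogen atom in Da.
HYDROGEN_MASS = 1.007825032

FINGERPRINT_RADIUS = 2
FINGERPRINT_NBITS = 2048

_FP_GEN = rdFingerprintGenerator.GetMorganGenerator(
    radius=FINGERPRINT_RADIUS, fpSize=FINGERPRINT_NBITS
)


@dataclass(frozen=True)
class Molecule:
    """Canonical structure with InChIKey, monoisotopic mass and fingerprint."""

    structure: str
    inchikey: str
    monoisotopic_mass: float
    fingerprint: object = field(repr=False, compare=False, hash=False, default=None)
    fingerprint_params: tuple = field(
        compare=False, hash=False, default=(FINGERPRINT_RADIUS, FINGERPRINT_NBITS)
    )

    @property
    def inchikey14(self) -> str:
        """First InChIKey block: 14 characters encoding 2D connectivity."""
        return self.inchikey[:14]

    def to_mol(self) -> Chem.Mol:
        """Parse the canonical SMILES back into an RDKit molecule."""
        mol = Chem.MolFromSmiles(self.structure)
        if mol is None:  # pragma: no cover - canonical SMILES always parse
            raise StructureParseError(self.structure)
        return mol

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Molecule):
            return NotImplemented
        return self.inchikey == other.inchikey

    def __hash__(self) -> int:
        return hash(self.inchikey)


def mol_from_smiles(structure_text: str) -> Chem.Mol:
    """Parse SMILES, distinguishing parse failures from valence violations."""
    if not isinstance(structure_text, str) or not structure_text.strip():
        raise StructureParseError(str(structure_text), "empty input")
    mol = Chem.MolFromSmiles(structure_text, sanitize=False)
    if mol is None:
        raise StructureParseError(structure_text)
    try:
        Chem.SanitizeMol(mol)
    except Chem.AtomValenceException as exc:
        raise ValenceError(structure_text, str(exc)) from exc
    except Chem.KekulizeException as exc:
        raise StructureParseError(structure_text, f"kekulization failed: {exc}") from exc
    except Exception as exc:  # other sanitization problems
        raise StructureParseError(structure_text, str(exc)) from exc
    return mol


def from_mol(mol: Chem.Mol) -> Molecule:
    """Build a :class:`Molecule` from a sanitized RDKit molecule."""
    canonical = Chem.MolToSmiles(mol)
    # re-parse so every downstream atom index refers to canonical order
    canonical_mol = Chem.MolFromSmiles(canonical)
    if canonical_mol is None:  # pragma: no cover
        raise StructureParseError(canonical, "canonical SMILES failed to re-parse")
    key = inchi.MolToInchiKey(canonical_mol)
    if not key:
        raise StructureParseError(canonical, "InChIKey generation failed")
    return Molecule(
        structure=canonical,
        inchikey=key,
        monoisotopic_mass=Descriptors.ExactMolWt(canonical_mol),
        fingerprint=_FP_GEN.GetFingerprint(canonical_mol),
    )


def canonicalize(structure_text: str) -> Molecule:
    """Canonicalize a SMILES string into a fully populated :class:`Molecule`.

    Raises
    ------
    StructureParseError
        If the text does not parse as a molecule.
    ValenceError
        If the structure violates standard valence rules.
    """
    return from_mol(mol_from_smiles(structure_text))


def from_inchi(inchi_text: str) -> Molecule:
    """Build a :class:`Molecule` from a standard InChI string."""
    mol = inchi.MolFromInchi(inchi_text)
    if mol is None:
        raise StructureParseError(inchi_text, "invalid InChI")
    return from_mol(mol)


def inchikey14_match(a: Molecule, b: Molecule) -> bool:
    """True iff the first 14 InChIKey characters agree (2D identity)."""
    return a.inchikey14 == b.inchikey14


def tanimoto(a: Molecule, b: Molecule) -> float:
    """Tanimoto similarity of the two molecules' substructure fingerprints."""
    if a.fingerprint_params != b.fingerprint_params:
        raise FingerprintMismatchError(
            f"fingerprint parameters differ: {a.fingerprint_params} vs {b.fingerprint_params}"
        )
    return DataStructs.TanimotoSimilarity(a.fingerprint, b.fingerprint)
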