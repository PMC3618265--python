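"""Hashed linear-path molecular fingerprints from SMILES.

Drugs are represented by 1024-bit topological fingerprints: every linear
atom-bond path of 2-7 atoms (1-6 bonds) is canonicalized and hashed into
a fixed-length bit array.  RDKit's path fingerprint with branched paths
disabled provides the enumeration and hashing; the exact bit positions
are a property of the toolkit's hash, so downstream code relies only on
determinism, atom-order invariance and Tanimoto similarity, never on
specific indices.  The generating convention (toolkit, parameters) is
recorded in :data:`FINGERPRINT_METADATA`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem, rdBase, RDLogger

RDLogger.DisableLog("rdApp.error")

N_FINGERPRINT_BITS = 1024
MIN_PATH_ATOMS = 2
MAX_PATH_ATOMS = 7

FINGERPRINT_METADATA = {
    "toolkit": f"rdkit {rdBase.rdkitVersion}",
    "kind": "linear-path (RDKFingerprint, branchedPaths=False)",
    "nbits": N_FINGERPRINT_BITS,
    "path_atoms": (MIN_PATH_ATOMS, MAX_PATH_ATOMS),
}


class SmilesParseError(ValueError):
    """The SMILES string could not be parsed into a molecule."""


@dataclass(frozen=True)
class DrugRecord:
    id: str
    smiles: str
    mol: Chem.Mol

    def __post_init__(self) -> None:
        if self.mol is None:
            raise SmilesParseError(f"unparsable SMILES: {self.smiles!r}")


def parse_molecule(smiles: str, id: str = "") -> DrugRecord:
    """Parse a SMILES string, rejecting unparsable input.

    Aromatic and isomeric SMILES are accepted; RDKit's sanitization
    (valence check, aromaticity perception) applies.
    """
    if not smiles or not smiles.strip():
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparsable SMILES: {smiles!r}")
    return DrugRecord(id or smiles, smiles, mol)


def path_fingerprint(
    drug: DrugRecord | str,
    nbits: int = N_FINGERPRINT_BITS,
    min_path_atoms: int = MIN_PATH_ATOMS,
    max_path_atoms: int = MAX_PATH_ATOMS,
    use_bond_order: bool = True,
) -> np.ndarray:
    """Hashed linear-path fingerprint as a uint8 0/1 vector of ``nbits``.

    Paths are linear walks of ``min_path_atoms``..``max_path_atoms``
    atoms without atom revisits; each canonical path hashes to a small
    set of bit positions.  The result is deterministic and invariant to
    the atom ordering of the input SMILES.  A molecule with fewer than
    ``min_path_atoms`` atoms (no qualifying path) maps to the zero
    vector.  ``use_bond_order=False`` ignores bond orders (and hence
    aromaticity) in path canonicalization.
    """
    if nbits <= 0:
        raise ValueError("nbits must be positive")
    if min_path_atoms > max_path_atoms or min_path_atoms < 2:
        raise ValueError("need 2 <= min_path_atoms <= max_path_atoms")
    if isinstance(drug, str):
        drug = parse_molecule(drug)
    bv = Chem.RDKFingerprint(
        drug.mol,
        minPath=min_path_atoms - 1,  # RDKit counts bonds, not atoms
        maxPath=max_path_atoms - 1,
        fpSize=nbits,
        branchedPaths=False,
        useBondOrder=use_bond_order,
    )
    arr = np.zeros(nbits, dtype=np.uint8)
    arr[list(bv.GetOnBits())] = 1
    return arr


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto (Jaccard) similarity |a&b| / |a|b|; 1.0 if both empty."""
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    a = a.astype(bool)
    b = b.astype(bool)
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        return 1.0
    return int(np.logical_and(a, b).sum()) / union
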