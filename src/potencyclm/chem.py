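"""Shared RDKit helpers: one canonicalization dialect for the whole package.

Every identity comparison in the pipeline (duplicate detection, core grouping,
exact-match evaluation) goes through :func:`canonical_smiles`, so a single
SMILES writer configuration is fixed here. Stereochemistry is retained.
"""

from __future__ import annotations

import logging

from rdkit import Chem, RDLogger

log = logging.getLogger(__name__)

# RDKit warns loudly on every unparsable string; the pipeline logs those itself.
RDLogger.DisableLog("rdApp.error")


def mol_from_smiles(smiles: str) -> Chem.Mol | None:
    """Parse a SMILES string, returning None (not raising) on failure."""
    if not isinstance(smiles, str) or not smiles:
        return None
    return Chem.MolFromSmiles(smiles)


def canonical_smiles(smiles: str) -> str | None:
    """Canonical isomeric SMILES under the repo-wide dialect, or None."""
    mol = mol_from_smiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol, isomericSmiles=True)


def heavy_atom_count(mol: Chem.Mol) -> int:
    """Number of non-hydrogen, non-dummy atoms."""
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)
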