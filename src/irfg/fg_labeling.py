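"""SMILES -> 17-bit functional-group label vectors via SMARTS matching.

A label vector ``y`` has ``y[i] = 1`` iff the molecule contains at least one
match of catalog pattern ``i``. Only presence/absence is recorded, never
match counts. Labels are invariant under SMILES rewriting because matching
operates on the parsed molecule, not the string.
"""

from __future__ import annotations

import numpy as np
from rdkit import Chem

from .catalog import DEFAULT_CATALOG, FunctionalGroupCatalog
from .errors import SmilesParseError

__all__ = ["canonicalize_smiles", "label_functional_groups", "labels_to_names"]


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"could not parse SMILES: {smiles!r}")
    return mol


def canonicalize_smiles(smiles: str) -> str:
    """Return the canonical form of *smiles* (idempotent).

    Raises
    ------
    SmilesParseError
        If the string is not valid SMILES.
    """
    return Chem.MolToSmiles(_mol_from_smiles(smiles))


def label_functional_groups(
    smiles: str, catalog: FunctionalGroupCatalog = DEFAULT_CATALOG
) -> np.ndarray:
    """Binary vector over the catalog: 1 = group present, 0 = absent."""
    mol = _mol_from_smiles(smiles)
    return np.array(
        [1 if mol.HasSubstructMatch(q) else 0 for q in catalog.queries()],
        dtype=np.int8,
    )


def labels_to_names(
    labels: np.ndarray, catalog: FunctionalGroupCatalog = DEFAULT_CATALOG
) -> list[str]:
    """Names of the groups whose bit is set, in catalog order."""
    return [name for name, bit in zip(catalog.names, labels) if bit]
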