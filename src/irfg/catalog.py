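"""The pinned 17-entry functional-group catalog.

Each functional group is defined by a SMARTS substructure query. The order of
the entries is fixed and every label vector in the package is aligned to it.
The ether pattern carries ``!$(C=O)`` guards on both oxygen neighbours so that
ester linkages (where one flanking carbon is a carbonyl carbon) are not
counted as ethers; without the guards every ester would also be labelled as
an ether.

The catalog is versioned through a content hash (see :func:`catalog_hash`):
model checkpoints record the hash of the catalog they were trained under and
refuse to load against a different one.

Notes on individual patterns
----------------------------
* ``alkane`` requires an sp3 carbon whose neighbours are all carbon or
  hydrogen, so a methoxy CH3 is *not* an alkane (it is still a methyl).
* ``alkyl halides`` matches a halogen on *any* carbon, including aromatic
  carbons (aryl fluorides count) and carbonyl carbons (so acyl halides also
  set this bit).
* ``amines`` excludes amide nitrogens and nitro groups.
* ``alcohols`` covers hydroxyls on any non-carbonyl carbon, i.e. phenols
  count as alcohols while carboxylic acids do not.
* ``nitro`` accepts both the hypervalent and the charge-separated depiction.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

from rdkit import Chem

#: Ordered (name, SMARTS) pairs. Do not reorder: label vectors index into this.
CATALOG_ENTRIES: tuple[tuple[str, str], ...] = (
    ("alkane", "[CX4;!$([CX4][!#6;!#1])]"),
    ("methyl", "[CX4H3]"),
    ("alkene", "[CX3]=[CX3]"),
    ("alkyne", "[CX2]#[CX2]"),
    ("alcohols", "[OX2H][#6;!$([#6]=O)]"),
    ("amines", "[NX3;!$(NC=[O,S]);!$([NX3]=O)]"),
    ("nitriles", "[NX1]#[CX2]"),
    ("aromatics", "[a]"),
    ("alkyl halides", "[#6][F,Cl,Br,I]"),
    ("esters", "[#6][CX3](=[OX1])[OX2H0][#6]"),
    ("ketones", "[#6][CX3](=[OX1])[#6]"),
    ("aldehydes", "[CX3H1](=[OX1])[#6]"),
    ("carboxylic acids", "[CX3](=[OX1])[OX2H1]"),
    ("ether", "[OD2]([#6;!$(C=O)])([#6;!$(C=O)])"),
    ("acyl halides", "[CX3](=[OX1])[F,Cl,Br,I]"),
    ("amides", "[NX3][CX3](=[OX1])"),
    ("nitro", "[$([NX3](=O)=O),$([NX3+](=[OX1])[O-])]"),
)

#: Group names in catalog order.
GROUP_NAMES: tuple[str, ...] = tuple(name for name, _ in CATALOG_ENTRIES)

N_GROUPS: int = len(CATALOG_ENTRIES)


@dataclass(frozen=True)
class FunctionalGroupCatalog:
    """An ordered set of named SMARTS queries defining the label space."""

    entries: tuple[tuple[str, str], ...] = CATALOG_ENTRIES
    _queries: tuple = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if len(self.entries) != N_GROUPS:
            raise ValueError(f"catalog must have {N_GROUPS} entries")
        queries = []
        for name, smarts in self.entries:
            q = Chem.MolFromSmarts(smarts)
            if q is None:
                raise ValueError(f"invalid SMARTS for {name!r}: {smarts}")
            queries.append(q)
        object.__setattr__(self, "_queries", tuple(queries))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.entries)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown functional group {name!r}") from None

    def queries(self):
        """Compiled RDKit query molecules, in catalog order."""
        return self._queries

    def to_table(self) -> str:
        """Plain-text (name<TAB>pattern) dump for audit trails."""
        return "\n".join(f"{n}\t{s}" for n, s in self.entries) + "\n"


DEFAULT_CATALOG = FunctionalGroupCatalog()


def catalog_hash(catalog: FunctionalGroupCatalog = DEFAULT_CATALOG) -> str:
    """SHA-256 over the ordered name/pattern pairs; pins catalog identity."""
    h = hashlib.sha256()
    for name, smarts in catalog.entries:
        h.update(name.encode())
        h.update(b"\x00")
        h.update(smarts.encode())
        h.update(b"\x00")
    return h.hexdigest()
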