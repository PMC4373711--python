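"""Residue-specific heavy-atom type registry.

Every heavy (non-hydrogen) atom of the 20 standard amino acids gets its own
type index: the same atom label in different residues is a different type
(an ALA CB is chemically distinct from a SER CB).  Enumerating all PDB v3
heavy-atom names over the 20 residues yields exactly 167 types, the pair
alphabet of the statistical potential.

Selenomethionine (MSE) is remapped onto MET (SE -> SD) before lookup, since
it is ubiquitous in X-ray structures and chemically a methionine.  Terminal
OXT, hydrogens/deuteriums and any other nonstandard residue or atom are not
in the registry; ``type_of`` returns ``None`` for them and callers report
them as skip counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

BACKBONE = ("N", "CA", "C", "O")

# Side-chain heavy atoms, PDB v3 naming, in conventional order.
SIDE_CHAINS: dict[str, tuple[str, ...]] = {
    "ALA": ("CB",),
    "ARG": ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "ASN": ("CB", "CG", "OD1", "ND2"),
    "ASP": ("CB", "CG", "OD1", "OD2"),
    "CYS": ("CB", "SG"),
    "GLN": ("CB", "CG", "CD", "OE1", "NE2"),
    "GLU": ("CB", "CG", "CD", "OE1", "OE2"),
    "GLY": (),
    "HIS": ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "LYS": ("CB", "CG", "CD", "CE", "NZ"),
    "MET": ("CB", "CG", "SD", "CE"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": ("CB", "CG", "CD"),
    "SER": ("CB", "OG"),
    "THR": ("CB", "OG1", "CG2"),
    "TRP": ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "VAL": ("CB", "CG1", "CG2"),
}

STANDARD_RESIDUES = tuple(sorted(SIDE_CHAINS))

REGISTRY_VERSION = "starpot-167-v1"


@dataclass(frozen=True)
class AtomTypeRegistry:
    """Closed, ordered mapping (residue, atom) -> dense type index.

    Indices are assigned residue-alphabetically, backbone (N, CA, C, O)
    before side chain, and are stable across runs.
    """

    entries: tuple[tuple[str, str], ...]
    version: str = REGISTRY_VERSION
    _index: dict[tuple[str, str], int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_index", {pair: i for i, pair in enumerate(self.entries)}
        )

    @property
    def size(self) -> int:
        return len(self.entries)

    def registry_size(self) -> int:
        """Number of atom types in the registry (167 for the default)."""
        return len(self.entries)

    def type_of(self, residue_name: str, atom_name: str) -> Optional[int]:
        """Type index of (residue, atom), or ``None`` if not a registry type.

        Expects uppercase, whitespace-stripped names.  MSE is treated as MET
        with its SE selenium standing in for SD.  Unknown pairs (hydrogens,
        OXT, nonstandard residues, ligand atoms) return ``None``: this is a
        normal outcome, not an error.
        """
        if residue_name == "MSE":
            residue_name = "MET"
            if atom_name == "SE":
                atom_name = "SD"
        return self._index.get((residue_name, atom_name))

    def label(self, index: int) -> str:
        """Human-readable ``RES:ATOM`` label of a type index."""
        res, atom = self.entries[index]
        return f"{res}:{atom}"

    def index_of_label(self, label: str) -> int:
        res, atom = label.split(":")
        idx = self._index.get((res, atom))
        if idx is None:
            raise KeyError(label)
        return idx

    def to_tsv(self) -> str:
        """Audit table: one row per type, ``residue\\tatom\\tindex``."""
        lines = ["residue\tatom\tindex"]
        lines += [f"{res}\t{atom}\t{i}" for i, (res, atom) in enumerate(self.entries)]
        return "\n".join(lines) + "\n"


def _build_entries() -> tuple[tuple[str, str], ...]:
    entries: list[tuple[str, str]] = []
    for res in STANDARD_RESIDUES:
        for atom in BACKBONE + SIDE_CHAINS[res]:
            entries.append((res, atom))
    return tuple(entries)


_DEFAULT = AtomTypeRegistry(entries=_build_entries())


def default_registry() -> AtomTypeRegistry:
    """The canonical 167-type registry."""
    return _DEFAULT
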