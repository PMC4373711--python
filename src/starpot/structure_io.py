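"""PDB structure reading and atom typing.

Parsing is delegated to gemmi; this module applies the policies the scoring
pipeline needs — model selection, chain selection, altloc resolution,
hydrogen/water/HETATM removal (MSE excepted) — and emits plain records the
rest of the package consumes.
"""

from __future__ import annotations

import math
import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import gemmi

from .atom_typing import AtomTypeRegistry, default_registry
from .errors import EmptySelectionError, InputError

WATER_NAMES = {"HOH", "DOD", "WAT"}


@dataclass(frozen=True)
class AtomRecord:
    """One retained heavy atom after altloc resolution."""

    chain_id: str
    residue_name: str
    residue_seq: int
    insertion_code: str
    atom_name: str
    altloc: str
    occupancy: float
    coords: tuple[float, float, float]

    @property
    def residue_key(self) -> tuple[str, str]:
        return (self.chain_id, f"{self.residue_seq}{self.insertion_code}")


@dataclass
class StructureModel:
    """Heavy atoms of one coordinate model of one or more chains."""

    source_id: str
    atoms: list[AtomRecord]
    resolution: Optional[float] = None
    model_number: int = 1

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def n_residues(self) -> int:
        return len({a.residue_key for a in self.atoms})

    def sequence(self) -> str:
        """One-letter sequence from coordinates, chain/residue order preserved.

        Nonstandard residues become ``X``.
        """
        seen: dict[tuple[str, str], str] = {}
        for a in self.atoms:
            if a.residue_key not in seen:
                seen[a.residue_key] = THREE_TO_ONE.get(a.residue_name, "X")
        return "".join(seen.values())


@dataclass(frozen=True)
class TypedAtom:
    """An atom that carries a registry type index."""

    type_index: int
    coords: tuple[float, float, float]
    residue_key: tuple[str, str]


THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",
}


def _is_hydrogen(atom: gemmi.Atom) -> bool:
    if atom.element.is_hydrogen:
        return True
    name = atom.name.strip()
    return name.startswith(("H", "D")) and atom.element.name in ("H", "D", "X")


def read_structure(
    source: Union[str, os.PathLike],
    model_policy: Union[str, int] = "first",
    chain_selection: Union[str, Iterable[str]] = "all",
    altloc_policy: str = "highest_occupancy",
) -> StructureModel:
    """Read a PDB file (path or PDB-format text) into a :class:`StructureModel`.

    Parameters
    ----------
    source:
        Path to a PDB file, or the PDB text itself (detected by the absence
        of the string from the filesystem and presence of newlines).
    model_policy:
        ``"first"`` (default) keeps the first coordinate model; an integer
        selects a 1-based model number.
    chain_selection:
        ``"all"`` or an iterable of chain identifiers to retain.
    altloc_policy:
        ``"highest_occupancy"``: among alternate conformers of one atom keep
        the highest-occupancy one, ties broken by alphabetical altloc id.

    Hydrogens, waters and HETATM residues other than MSE are removed.
    Raises :class:`InputError` for unparseable input or a missing model and
    :class:`EmptySelectionError` when nothing survives the selection.
    """
    if altloc_policy != "highest_occupancy":
        raise InputError(f"unknown altloc policy: {altloc_policy!r}")

    text_input = isinstance(source, str) and "\n" in source
    try:
        if text_input:
            st = gemmi.read_pdb_string(source)
            source_id = st.name or "pdb-string"
        else:
            st = gemmi.read_pdb(str(source))
            source_id = st.name or os.path.splitext(os.path.basename(str(source)))[0]
    except (RuntimeError, ValueError, OSError) as exc:
        raise InputError(f"cannot read PDB input: {exc}") from exc
    if len(st) == 0:
        raise InputError("no coordinate models in input")

    if model_policy == "first":
        model = st[0]
    else:
        try:
            wanted = int(model_policy)
        except (TypeError, ValueError):
            raise InputError(f"bad model policy: {model_policy!r}")
        model = None
        for m in st:
            if m.num == wanted:
                model = m
                break
        if model is None:
            raise InputError(f"model {wanted} not present")

    if chain_selection == "all":
        wanted_chains: Optional[set[str]] = None
    else:
        wanted_chains = {str(c) for c in chain_selection}
        available = {ch.name for ch in model}
        missing = wanted_chains - available
        if missing:
            raise EmptySelectionError(
                f"chain(s) {sorted(missing)} not in structure; "
                f"available: {sorted(available)}"
            )

    # candidates[(chain, seq+icode, atom_name)] -> list of (occ, altloc, record)
    candidates: dict[tuple, list[tuple[float, str, AtomRecord]]] = {}
    order: list[tuple] = []
    for chain in model:
        if wanted_chains is not None and chain.name not in wanted_chains:
            continue
        for res in chain:
            name = res.name.strip().upper()
            if name in WATER_NAMES:
                continue
            if res.het_flag == "H" and name != "MSE":
                continue
            for atom in res:
                if _is_hydrogen(atom):
                    continue
                pos = atom.pos
                if not all(math.isfinite(v) for v in (pos.x, pos.y, pos.z)):
                    raise InputError(
                        f"non-finite coordinates at {chain.name}/{res.seqid.num}/{atom.name}"
                    )
                icode = res.seqid.icode.strip()
                rec = AtomRecord(
                    chain_id=chain.name,
                    residue_name=name,
                    residue_seq=res.seqid.num,
                    insertion_code=icode,
                    atom_name=atom.name.strip().upper(),
                    altloc=atom.altloc.strip(),
                    occupancy=float(atom.occ),
                    coords=(pos.x, pos.y, pos.z),
                )
                key = (rec.chain_id, rec.residue_seq, icode, rec.atom_name)
                if key not in candidates:
                    candidates[key] = []
                    order.append(key)
                candidates[key].append((rec.occupancy, rec.altloc, rec))

    atoms: list[AtomRecord] = []
    for key in order:
        group = candidates[key]
        # highest occupancy wins; ties -> alphabetically first altloc id
        best = min(group, key=lambda t: (-t[0], t[1]))
        atoms.append(best[2])

    if not atoms:
        sel = "all chains" if wanted_chains is None else f"chain(s) {sorted(wanted_chains)}"
        raise EmptySelectionError(f"no heavy protein atoms left after selecting {sel}")

    resolution = float(st.resolution) if st.resolution and st.resolution > 0 else None
    return StructureModel(
        source_id=source_id,
        atoms=atoms,
        resolution=resolution,
        model_number=model.num,
    )


@dataclass
class SkipReport:
    """Counts of atoms that could not be typed, by reason."""

    unknown_residue: int = 0
    unknown_atom: int = 0
    oxt: int = 0
    by_residue: Counter = field(default_factory=Counter)

    @property
    def total(self) -> int:
        return self.unknown_residue + self.unknown_atom + self.oxt


def typed_atoms(
    model: StructureModel,
    registry: Optional[AtomTypeRegistry] = None,
) -> tuple[list[TypedAtom], SkipReport]:
    """Assign registry types to every atom of ``model``.

    Returns the typed atoms (input order preserved) and a skip report;
    ``len(typed) + report.total == model.n_atoms`` always holds.
    """
    if registry is None:
        registry = default_registry()
    typed: list[TypedAtom] = []
    report = SkipReport()
    from .atom_typing import SIDE_CHAINS  # standard residue set

    for a in model.atoms:
        idx = registry.type_of(a.residue_name, a.atom_name)
        if idx is not None:
            typed.append(TypedAtom(type_index=idx, coords=a.coords, residue_key=a.residue_key))
            continue
        if a.atom_name == "OXT":
            report.oxt += 1
        elif a.residue_name in SIDE_CHAINS or a.residue_name == "MSE":
            report.unknown_atom += 1
        else:
            report.unknown_residue += 1
            report.by_residue[a.residue_name] += 1
    return typed, report
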