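"""Deterministic synthetic structures: helices, repeat arrays, decoys.

Everything here exists so the potential pipeline can be exercised without
downloading real structures.  Models are poly-alanine (N, CA, C, O, CB per
residue), so every atom is in the type registry by construction.  Backbones
are built from ideal internal coordinates (bond lengths/angles and the
classic α-helical dihedrals φ=-57°, ψ=-47°), which yields the canonical
helix geometry: ~1.5 Å rise and ~100° twist per residue, consecutive CA-CA
distances of ~3.8 Å.

Repeat arrays mimic the architecture of α-helical repeat proteins (TPR/AR):
a two-helix unit stacked n times by a fixed screw transform (~10.5 Å
translation, ~24° rotation about the array axis), giving an elongated
super-helical solenoid.  The geometry is a documented testing constant, not
a fit to any natural repeat family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .curation import LibraryEntry
from .errors import InputError
from .structure_io import AtomRecord, StructureModel

# ideal backbone internal coordinates (Å, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.521
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5
ANGLE_C_CA_CB = 110.1
IMPROPER_N_C_CA_CB = -122.6  # L-amino-acid chirality
OMEGA = 180.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic generator; a fixed seed gives identical output.

    helix_phi/helix_psi are the backbone dihedrals in degrees (defaults are
    the ideal α-helix and imply rise ≈ 1.5 Å and twist ≈ 100° per residue).
    The stacking transform turns two-helix units into a solenoid.
    """

    seed: int = 0
    residues_per_helix: int = 10
    helix_phi: float = -57.0
    helix_psi: float = -47.0
    helix_separation: float = 10.0  # Å between the two helices of a unit
    stack_translation: float = 10.5  # Å per repeat along the array axis
    stack_rotation_deg: float = 24.0  # ° per repeat about the array axis
    jitter_sigma: float = 2.0  # Å, decoy coordinate noise


def _place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, torsion_deg: float,
) -> np.ndarray:
    """Position atom d given atoms a-b-c, |cd|, angle(b,c,d), torsion(a,b,c,d)."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(torsion),
            bond * math.sin(angle) * math.sin(torsion),
        ]
    )
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def _helix_coords(n_residues: int, phi: float, psi: float) -> list[dict[str, np.ndarray]]:
    """Backbone + CB + O coordinates of an ideal poly-alanine helix."""
    residues: list[dict[str, np.ndarray]] = []
    # bootstrap the first N-CA-C in a canonical frame
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    angle = math.radians(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-math.cos(angle), math.sin(angle), 0.0])
    residues.append({"N": n0, "CA": ca0, "C": c0})
    for _ in range(1, n_residues):
        prev = residues[-1]
        n = _place_atom(prev["N"], prev["CA"], prev["C"], BOND_C_N, ANGLE_CA_C_N, psi)
        ca = _place_atom(prev["CA"], prev["C"], n, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        c = _place_atom(prev["C"], n, ca, BOND_CA_C, ANGLE_N_CA_C, phi)
        residues.append({"N": n, "CA": ca, "C": c})
    for res in residues:
        # carbonyl O anti to the next amide N: torsion N-CA-C-O = psi + 180
        res["O"] = _place_atom(res["N"], res["CA"], res["C"], BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
        res["CB"] = _place_atom(res["N"], res["C"], res["CA"], BOND_CA_CB, ANGLE_C_CA_CB, IMPROPER_N_C_CA_CB)
    return residues


def _principal_axis_frame(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation aligning the dominant axis of ``coords`` with z, and centroid."""
    center = coords.mean(axis=0)
    u, s, vt = np.linalg.svd(coords - center, full_matrices=False)
    axis = vt[0]
    # orient the axis consistently (from first to last atom)
    if np.dot(coords[-1] - coords[0], axis) < 0:
        axis = -axis
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    c = float(np.dot(axis, z))
    if np.linalg.norm(v) < 1e-12:
        rot = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))
    return rot, center


_ALA_ORDER = ("N", "CA", "C", "O", "CB")


def _model_from_residue_coords(
    residue_coords: list[dict[str, np.ndarray]],
    source_id: str,
) -> StructureModel:
    atoms = []
    for i, res in enumerate(residue_coords, start=1):
        for name in _ALA_ORDER:
            xyz = res[name]
            atoms.append(
                AtomRecord(
                    chain_id="A",
                    residue_name="ALA",
                    residue_seq=i,
                    insertion_code="",
                    atom_name=name,
                    altloc="",
                    occupancy=1.0,
                    coords=(float(xyz[0]), float(xyz[1]), float(xyz[2])),
                )
            )
    return StructureModel(source_id=source_id, atoms=atoms, resolution=None)


def ideal_helix(n_residues: int, config: Optional[GeneratorConfig] = None) -> StructureModel:
    """Ideal poly-alanine α-helix with all 5 heavy atoms per residue."""
    if n_residues < 3:
        raise InputError("a helix needs at least 3 residues")
    cfg = config or GeneratorConfig()
    res = _helix_coords(n_residues, cfg.helix_phi, cfg.helix_psi)
    # center on the helix axis, axis along z, for composability
    ca = np.array([r["CA"] for r in res])
    rot, center = _principal_axis_frame(ca)
    for r in res:
        for k in r:
            r[k] = rot @ (r[k] - center)
    return _model_from_residue_coords(res, f"helix{n_residues}")


def _unit_residue_coords(cfg: GeneratorConfig) -> list[dict[str, np.ndarray]]:
    """Two antiparallel helices side by side: one repeat unit."""
    res_a = _helix_coords(cfg.residues_per_helix, cfg.helix_phi, cfg.helix_psi)
    ca = np.array([r["CA"] for r in res_a])
    rot, center = _principal_axis_frame(ca)
    half = cfg.helix_separation / 2.0
    unit: list[dict[str, np.ndarray]] = []
    for r in res_a:
        unit.append({k: rot @ (v - center) + np.array([-half, 0.0, 0.0]) for k, v in r.items()})
    flip = np.diag([1.0, -1.0, -1.0])  # 180° about x: antiparallel partner
    for r in res_a:
        unit.append({k: flip @ (rot @ (v - center)) + np.array([half, 0.0, 0.0]) for k, v in r.items()})
    return unit


def repeat_array(n_repeats: int, config: Optional[GeneratorConfig] = None) -> StructureModel:
    """Solenoid of ``n_repeats`` two-helix units related by a screw transform."""
    if n_repeats < 1:
        raise InputError("need at least one repeat")
    cfg = config or GeneratorConfig()
    unit = _unit_residue_coords(cfg)
    theta = math.radians(cfg.stack_rotation_deg)
    # screw axis = y: rotate in the x-z plane, translate along y
    rot_y = np.array(
        [
            [math.cos(theta), 0.0, math.sin(theta)],
            [0.0, 1.0, 0.0],
            [-math.sin(theta), 0.0, math.cos(theta)],
        ]
    )
    all_res: list[dict[str, np.ndarray]] = []
    rot_k = np.eye(3)
    for k in range(n_repeats):
        shift = np.array([0.0, k * cfg.stack_translation, 0.0])
        for r in unit:
            all_res.append({name: rot_k @ xyz + shift for name, xyz in r.items()})
        rot_k = rot_y @ rot_k
    return _model_from_residue_coords(all_res, f"array{n_repeats}")


def perturb_decoy(
    model: StructureModel, sigma: float, seed: int
) -> StructureModel:
    """Decoy: every coordinate displaced by N(0, sigma²) noise (seeded)."""
    if sigma < 0:
        raise InputError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=(len(model.atoms), 3)) if sigma > 0 else np.zeros((len(model.atoms), 3))
    atoms = [
        replace(
            a,
            coords=(a.coords[0] + dx, a.coords[1] + dy, a.coords[2] + dz),
        )
        for a, (dx, dy, dz) in zip(model.atoms, noise)
    ]
    return StructureModel(
        source_id=f"{model.source_id}_decoy{seed}",
        atoms=atoms,
        resolution=model.resolution,
        model_number=model.model_number,
    )


def toy_library(
    n_structures: int, config: Optional[GeneratorConfig] = None
) -> list[tuple[LibraryEntry, StructureModel]]:
    """Deterministic panel of repeat arrays with varied repeat counts.

    Repeat counts cycle 2..6 and the stacking geometry is jittered slightly
    (±1° rotation, ±0.3 Å translation) so entries are distinct but all
    share the same fold.  Entry metadata mimics an X-ray manifest.
    """
    if n_structures < 1:
        raise InputError("need at least one structure")
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    out: list[tuple[LibraryEntry, StructureModel]] = []
    for i in range(n_structures):
        n_rep = 2 + i % 5
        local = replace(
            cfg,
            stack_rotation_deg=cfg.stack_rotation_deg + rng.uniform(-1.0, 1.0),
            stack_translation=cfg.stack_translation + rng.uniform(-0.3, 0.3),
        )
        model = repeat_array(n_rep, local)
        entry_id = f"SYN{i:04d}:A"
        model.source_id = entry_id
        entry = LibraryEntry(
            entry_id=entry_id,
            sequence=model.sequence(),
            resolution=1.5,
            method="synthetic",
        )
        out.append((entry, model))
    return out


# ---------------------------------------------------------------------------
# PDB output

def model_to_pdb(model: StructureModel) -> str:
    """Serialize a model as minimal fixed-column PDB text."""
    lines = []
    for serial, a in enumerate(model.atoms, start=1):
        name = a.atom_name
        # column-13 convention: 1-letter elements start at column 14
        name_field = f" {name:<3s}" if len(name) < 4 else name
        x, y, z = a.coords
        element = name[0]
        lines.append(
            f"ATOM  {serial:5d} {name_field}{'':1s}{a.residue_name:>3s} "
            f"{a.chain_id:1s}{a.residue_seq:4d}{a.insertion_code or ' ':1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
            f"          {element:>2s}  "
        )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_fixture_directory(
    out_dir,
    n_structures: int = 5,
    config: Optional[GeneratorConfig] = None,
) -> Path:
    """Write a self-contained fixture set: PDB files + manifest TSV.

    Returns the manifest path.  Scores are not included here; the CLI's
    fixture command adds an expected-score table computed from the panel.
    """
    from .curation import write_manifest

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for entry, model in toy_library(n_structures, config):
        fname = entry.entry_id.split(":")[0] + ".pdb"
        (out / fname).write_text(model_to_pdb(model))
        rows.append(
            {
                "entry_id": entry.entry_id,
                "path": fname,
                "chain": "A",
                "resolution": entry.resolution,
                "method": entry.method,
            }
        )
    manifest = out / "manifest.tsv"
    write_manifest(rows, manifest)
    return manifest
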