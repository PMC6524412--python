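"""Protein-ligand complex structures and geometric bookkeeping.

A :class:`ComplexStructure` holds the atoms of one protein-ligand complex,
with every atom assigned a *role* (``protein``, ``ligand``, ``metal`` or
``water``).  On top of it this module provides the geometric primitives the
fingerprinting pipeline needs:

* reading and writing TRIPOS mol2 complexes (the pipeline's working format)
  and reading PDB files,
* binding-site extraction -- all residues with any atom within a distance
  cutoff (default 6 Angstrom) of any ligand atom,
* paired-coordinate RMSD between a docked and a native pose,
* receptor selection for cross docking: the candidate structure with the
  smallest average RMSD over its re-docked ligands.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "AtomRecord",
    "ComplexStructure",
    "BindingSite",
    "RmsdTable",
    "Mol2FormatError",
    "read_complex",
    "read_mol2",
    "read_pdb",
    "write_mol2",
    "extract_binding_site",
    "pose_rmsd",
    "select_receptor",
]

#: three-letter codes treated as protein residues
AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR "
    "TRP TYR VAL SEC PYL MSE HID HIE HIP CYX".split()
)
WATER_RESIDUES = frozenset({"HOH", "WAT", "H2O", "DOD", "TIP3"})
#: residue names of common monatomic metal ions (PDB / mol2 conventions)
METAL_RESIDUES = frozenset(
    "ZN MG MN FE CU NI CO NA K CA CD HG LI CS SR BA AL".split()
)
METAL_ELEMENTS = frozenset(
    "ZN MG MN FE CU NI CO NA K CA CD HG LI CS SR BA AL".split()
)


class Mol2FormatError(ValueError):
    """Raised when a mol2 file cannot be parsed; names the offending line."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom with the annotations the interaction rules consume."""

    atom_id: int
    element: str
    position: tuple[float, float, float]
    formal_charge: int = 0
    is_aromatic: bool = False
    residue_name: str = "UNK"
    residue_id: int = 1
    chain_id: str = "A"
    role: str = "protein"  # protein | ligand | metal | water
    name: str = ""

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.atom_id}: position must be 3 finite floats")
        object.__setattr__(self, "position", (float(pos[0]), float(pos[1]), float(pos[2])))
        if not self.element or not self.element[0].isalpha():
            raise ValueError(f"atom {self.atom_id}: invalid element {self.element!r}")
        if self.role not in ("protein", "ligand", "metal", "water"):
            raise ValueError(f"atom {self.atom_id}: unknown role {self.role!r}")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)

    @property
    def residue_key(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_id)


@dataclass
class ComplexStructure:
    """Atoms of one complex, with optional explicit covalent bonds.

    Bonds are stored as pairs of ``atom_id``; when absent, consumers fall
    back to a covalent distance guess (see :mod:`tifpscreen.interactions`).
    """

    structure_id: str
    atoms: list[AtomRecord]
    target_id: str = ""
    bonds: Optional[list[tuple[int, int]]] = None

    def __post_init__(self) -> None:
        ids = [a.atom_id for a in self.atoms]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate atom_id in structure")

    def atoms_with_role(self, role: str) -> list[AtomRecord]:
        return [a for a in self.atoms if a.role == role]

    @property
    def protein_atoms(self) -> list[AtomRecord]:
        return self.atoms_with_role("protein")

    @property
    def ligand_atoms(self) -> list[AtomRecord]:
        return self.atoms_with_role("ligand")

    @property
    def metal_atoms(self) -> list[AtomRecord]:
        return self.atoms_with_role("metal")

    def coords(self, atoms: Optional[Sequence[AtomRecord]] = None) -> np.ndarray:
        atoms = self.atoms if atoms is None else atoms
        if not atoms:
            return np.zeros((0, 3))
        return np.stack([a.xyz for a in atoms])


@dataclass
class BindingSite:
    """Residues of the receptor within ``cutoff`` of the ligand.

    Whole residues are kept: if any atom of a residue is within the cutoff
    of any ligand atom, every atom of that residue belongs to the site.
    Metal ions within the cutoff are retained alongside protein residues so
    metal complexation remains detectable.
    """

    residue_keys: frozenset[tuple[str, int]]
    atoms: list[AtomRecord]
    cutoff: float


# ---------------------------------------------------------------------------
# mol2 I/O


def _classify_atom(residue_name: str, element: str) -> str:
    res = residue_name.upper()
    if res in WATER_RESIDUES:
        return "water"
    if res in METAL_RESIDUES and element.upper() in METAL_ELEMENTS:
        return "metal"
    if res in AMINO_ACIDS:
        return "protein"
    return "ligand"


_SUBST_RE = re.compile(r"^([A-Za-z][A-Za-z0-9'*]*?)(\d*)$")


def _split_subst_name(subst: str) -> tuple[str, Optional[int]]:
    m = _SUBST_RE.match(subst)
    if not m:
        return subst, None
    name, num = m.groups()
    return name, (int(num) if num else None)


def read_mol2(path: str | Path) -> ComplexStructure:
    """Parse a (possibly multi-``@<TRIPOS>MOLECULE``) mol2 complex file.

    Roles: a molecule block whose name contains ``ligand`` forces role
    ``ligand`` for its atoms; otherwise each atom is classified from its
    substructure (residue) name -- amino acids are protein, HOH water,
    monatomic metal residues metal, anything else ligand.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    atoms: list[AtomRecord] = []
    bonds: list[tuple[int, int]] = []
    mol_name = ""
    block_names: list[str] = []
    section = None
    expect_name = False
    block_atom_ids: list[int] = []  # local index -> global atom_id, per block
    saw_atom_section = False
    next_id = 1
    force_role: Optional[str] = None

    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("@<TRIPOS>"):
            section = line[9:].strip().upper()
            if section == "MOLECULE":
                expect_name = True
                block_atom_ids = []
            continue
        if expect_name:
            mol_name = line
            block_names.append(mol_name)
            low = mol_name.lower()
            if "ligand" in low:
                force_role = "ligand"
            elif any(k in low for k in ("protein", "receptor", "site")):
                force_role = None  # classified per residue (metals stay metal)
            else:
                force_role = None
            expect_name = False
            continue
        if section == "ATOM":
            saw_atom_section = True
            tok = line.split()
            if len(tok) < 6:
                raise Mol2FormatError(f"{path}:{lineno}: malformed ATOM line: {raw!r}")
            try:
                local_id = int(tok[0])
                name = tok[1]
                x, y, z = (float(tok[2]), float(tok[3]), float(tok[4]))
                sybyl = tok[5]
                subst_id = int(tok[6]) if len(tok) > 6 else 1
                subst_name = tok[7] if len(tok) > 7 else "UNK"
                charge = float(tok[8]) if len(tok) > 8 else 0.0
            except ValueError as exc:
                raise Mol2FormatError(f"{path}:{lineno}: {exc}") from None
            element = sybyl.split(".")[0].capitalize()
            aromatic = sybyl.lower().endswith(".ar")
            formal = int(round(charge)) if abs(charge - round(charge)) < 1e-3 else 0
            res_name, res_num = _split_subst_name(subst_name)
            role = force_role or _classify_atom(res_name, element)
            atoms.append(
                AtomRecord(
                    atom_id=next_id,
                    element=element,
                    position=(x, y, z),
                    formal_charge=formal,
                    is_aromatic=aromatic,
                    residue_name=res_name or "UNK",
                    residue_id=res_num if res_num is not None else subst_id,
                    chain_id="A",
                    role=role,
                    name=name,
                )
            )
            block_atom_ids.append(next_id)
            next_id += 1
        elif section == "BOND":
            tok = line.split()
            if len(tok) < 3:
                raise Mol2FormatError(f"{path}:{lineno}: malformed BOND line: {raw!r}")
            try:
                i, j = int(tok[1]), int(tok[2])
            except ValueError as exc:
                raise Mol2FormatError(f"{path}:{lineno}: {exc}") from None
            if not (1 <= i <= len(block_atom_ids) and 1 <= j <= len(block_atom_ids)):
                raise Mol2FormatError(f"{path}:{lineno}: bond references unknown atom")
            bonds.append((block_atom_ids[i - 1], block_atom_ids[j - 1]))

    if not saw_atom_section:
        raise Mol2FormatError(f"{path}: no @<TRIPOS>ATOM section")
    if not atoms:
        raise Mol2FormatError(f"{path}: structure contains zero atoms")
    return ComplexStructure(
        structure_id=block_names[0] if block_names else path.stem,
        atoms=atoms,
        bonds=bonds or None,
    )


def _sybyl_type(atom: AtomRecord) -> str:
    return f"{atom.element}.ar" if atom.is_aromatic else atom.element


def write_mol2(complex_: ComplexStructure, path: str | Path) -> None:
    """Write a complex as mol2 with one MOLECULE block per role group.

    Protein, metal and water atoms go into a ``protein`` block (roles are
    recoverable from residue names on re-read); ligand atoms into a
    ``ligand`` block.  Coordinates are written to 4 decimals, the formal
    charge occupies the charge column.
    """
    path = Path(path)
    groups = [
        ("protein", [a for a in complex_.atoms if a.role in ("protein", "metal", "water")]),
        ("ligand", complex_.ligand_atoms),
    ]
    bondset = complex_.bonds or []
    out: list[str] = []
    for block_name, group in groups:
        if not group:
            continue
        local = {a.atom_id: i + 1 for i, a in enumerate(group)}
        group_bonds = [(i, j) for (i, j) in bondset if i in local and j in local]
        out.append("@<TRIPOS>MOLECULE")
        out.append(f"{complex_.structure_id}_{block_name}" if block_name != "ligand" else "ligand")
        out.append(f"{len(group)} {len(group_bonds)} 0 0 0")
        out.append("SMALL" if block_name == "ligand" else "PROTEIN")
        out.append("USER_CHARGES")
        out.append("@<TRIPOS>ATOM")
        for a in group:
            nm = a.name or a.element
            out.append(
                f"{local[a.atom_id]:>5} {nm:<4} "
                f"{a.position[0]:>10.4f} {a.position[1]:>10.4f} {a.position[2]:>10.4f} "
                f"{_sybyl_type(a):<6} {a.residue_id:>4} "
                f"{a.residue_name}{a.residue_id} {float(a.formal_charge):>8.4f}"
            )
        if group_bonds:
            out.append("@<TRIPOS>BOND")
            for k, (i, j) in enumerate(group_bonds, start=1):
                out.append(f"{k:>5} {local[i]:>5} {local[j]:>5} 1")
    path.write_text("\n".join(out) + "\n")


def read_pdb(
    path: str | Path,
    ion_residues: Iterable[str] = METAL_RESIDUES,
) -> ComplexStructure:
    """Read a PDB file via biotite.

    ATOM records become protein atoms; HETATM records are water (HOH/WAT),
    metal (configurable monatomic-ion residue list) or ligand.  PDB carries
    no aromaticity; ring perception falls to the interaction module.
    """
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    pdb = PDBFile.read(str(path))
    try:
        arr = pdb.get_structure(model=1, extra_fields=["charge"])
    except Exception as exc:  # biotite raises on files without coordinates
        raise ValueError(f"{path}: cannot parse PDB: {exc}") from None
    if arr.array_length() == 0:
        raise ValueError(f"{path}: structure contains zero atoms")
    ions = frozenset(r.upper() for r in ion_residues)
    atoms = []
    for i in range(arr.array_length()):
        res_name = str(arr.res_name[i]).upper()
        element = str(arr.element[i]).capitalize()
        if not arr.hetero[i]:
            role = "protein"
        elif res_name in WATER_RESIDUES:
            role = "water"
        elif res_name in ions and element.upper() in METAL_ELEMENTS:
            role = "metal"
        else:
            role = "ligand"
        charge = int(arr.charge[i]) if "charge" in arr.get_annotation_categories() else 0
        atoms.append(
            AtomRecord(
                atom_id=i + 1,
                element=element,
                position=tuple(float(v) for v in arr.coord[i]),
                formal_charge=charge,
                is_aromatic=False,
                residue_name=res_name,
                residue_id=int(arr.res_id[i]),
                chain_id=str(arr.chain_id[i]) or "A",
                role=role,
                name=str(arr.atom_name[i]),
            )
        )
    return ComplexStructure(structure_id=path.stem, atoms=atoms)


def read_complex(path: str | Path, format: Optional[str] = None) -> ComplexStructure:
    """Read a complex from mol2 or PDB; the format defaults to the suffix."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "mol2":
        return read_mol2(path)
    if fmt in ("pdb", "ent"):
        return read_pdb(path)
    raise ValueError(f"unsupported structure format: {fmt!r}")


# ---------------------------------------------------------------------------
# geometry


def extract_binding_site(complex_: ComplexStructure, cutoff: float = 6.0) -> BindingSite:
    """All receptor residues with any atom within ``cutoff`` of any ligand atom.

    The membership test is any-atom / any-atom Euclidean distance; included
    residues are kept whole.  Metal ions inside the cutoff are part of the
    site.  Raises if the complex has no ligand atoms.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    ligand = complex_.ligand_atoms
    if not ligand:
        raise ValueError("complex has no ligand atoms")
    receptor = [a for a in complex_.atoms if a.role in ("protein", "metal")]
    if not receptor:
        raise ValueError("complex has no protein atoms")
    lig_xyz = np.stack([a.xyz for a in ligand])
    rec_xyz = np.stack([a.xyz for a in receptor])
    dmin = cdist(rec_xyz, lig_xyz).min(axis=1)
    keys = {receptor[i].residue_key for i in np.nonzero(dmin <= cutoff)[0]}
    site_atoms = [a for a in receptor if a.residue_key in keys]
    return BindingSite(residue_keys=frozenset(keys), atoms=site_atoms, cutoff=cutoff)


def pose_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Paired-atom RMSD between two poses in a common frame.

    No re-superposition and no graph-symmetry correction: index i of
    ``coords_a`` is assumed to correspond to index i of ``coords_b``
    (docked vs. native pose of the same molecule in the receptor frame).
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3 or b.shape != a.shape:
        raise ValueError(f"coordinate arrays must both be (n, 3); got {a.shape} and {b.shape}")
    if a.shape[0] == 0:
        raise ValueError("empty coordinate arrays")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


@dataclass
class RmsdTable:
    """Cross-docking RMSDs: (candidate structure, ligand) -> RMSD or None.

    ``None`` marks a failed docking.  By default failed entries are skipped
    when averaging; pass ``on_missing=<penalty>`` to count them at a fixed
    penalty RMSD instead.
    """

    entries: dict[tuple[str, str], Optional[float]] = field(default_factory=dict)

    def add(self, structure_id: str, ligand_id: str, rmsd: Optional[float]) -> None:
        if rmsd is not None and rmsd < 0:
            raise ValueError("RMSD must be non-negative")
        self.entries[(structure_id, ligand_id)] = rmsd

    def candidates(self) -> list[str]:
        return sorted({s for (s, _l) in self.entries})

    def mean_rmsd(self, structure_id: str, on_missing: Optional[float] = None) -> float:
        vals = [
            (v if v is not None else on_missing)
            for (s, _l), v in self.entries.items()
            if s == structure_id
        ]
        vals = [v for v in vals if v is not None]
        if not vals:
            raise ValueError(f"candidate {structure_id!r} has no usable RMSD entries")
        return float(np.mean(vals))


def select_receptor(table: RmsdTable, on_missing: Optional[float] = None) -> str:
    """Pick the candidate structure with the smallest average ligand RMSD.

    Exact mean ties break toward the lexicographically smallest structure id.
    """
    cands = table.candidates()
    if not cands:
        raise ValueError("empty RMSD table")
    means = {c: table.mean_rmsd(c, on_missing=on_missing) for c in cands}
    return min(cands, key=lambda c: (means[c], c))
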