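"""Geometric detection of protein-ligand interactions.

Five interaction classes are recognised between a binding site and a
ligand -- hydrophobic contacts, aromatic (ring-ring) interactions, hydrogen
bonds, ionic interactions and metal complexation -- and each detected
instance is abstracted into a single typed 3D point (a *pseudoatom*).
Hydrogen bonds are split by direction (ligand donates = HBD, ligand accepts
= HBA) and ionic contacts by the sign of the ligand charge centre (ION_P /
ION_N), giving seven pseudoatom type codes in total.

All thresholds live in :class:`InteractionRules` and are plain geometry:
heavy-atom distances, a donor-H-acceptor angle when hydrogens are present,
and ring-plane angles for the aromatic classes.

Pseudoatom placement: hydrophobic, aromatic, ionic and metal records sit at
the geometric centre of the two participating centres; hydrogen-bond
records sit on the acceptor atom.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist

from .structures import AtomRecord, BindingSite, METAL_ELEMENTS

__all__ = [
    "PSEUDOATOM_TYPES",
    "InteractionRules",
    "InteractionRecord",
    "Pseudoatom",
    "detect_interactions",
    "place_pseudoatom",
    "ring_centroid_normal",
    "guess_bonds",
    "records_to_csv",
]

#: the seven pseudoatom type codes, in canonical encoding order
PSEUDOATOM_TYPES = ("HYD", "ARO", "HBD", "HBA", "ION_P", "ION_N", "MET")

#: mapping used when collapsing the directional codes back to five classes
FIVE_CLASS_COLLAPSE = {
    "HBD": "HB", "HBA": "HB", "ION_P": "ION", "ION_N": "ION",
    "HYD": "HYD", "ARO": "ARO", "MET": "MET",
}


@dataclass(frozen=True)
class InteractionRules:
    """Geometric thresholds for the five interaction classes.

    Defaults follow common practice for interaction-fingerprint tools:
    hydrophobic contact between apolar carbons/sulfurs at <= 4.5 A;
    hydrogen bond at heavy-atom donor-acceptor distance <= 3.5 A with a
    D-H...A angle >= 120 deg when hydrogens are present (no angle test
    otherwise); ring-ring contact at centroid distance <= 5.0 A, face-to-
    face when the folded inter-plane angle is <= 30 deg or edge-to-face
    when >= 60 deg; opposite formal charges at <= 4.0 A; metal to ligand
    N/O/S at <= 2.8 A.  All values configurable.
    """

    hyd_max_dist: float = 4.5
    hb_max_dist: float = 3.5
    hb_min_angle: float = 120.0
    aro_centroid_max_dist: float = 5.0
    aro_face_angle_max: float = 30.0
    aro_edge_angle_min: float = 60.0
    ion_max_dist: float = 4.0
    metal_max_dist: float = 2.8
    bond_guess_dist: float = 1.9

    def __post_init__(self) -> None:
        for name in ("hyd_max_dist", "hb_max_dist", "aro_centroid_max_dist",
                     "ion_max_dist", "metal_max_dist", "bond_guess_dist"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("hb_min_angle", "aro_face_angle_max", "aro_edge_angle_min"):
            v = getattr(self, name)
            if not (0.0 <= v <= 180.0):
                raise ValueError(f"{name} must be in [0, 180] degrees")


@dataclass(frozen=True)
class InteractionRecord:
    """One detected interaction, abstracted to a typed point.

    ``ligand_center`` and ``protein_center`` are the two participating
    centres (atom positions or ring centroids); ``position`` is the placed
    pseudoatom.  ``geometry`` holds the measured distance and, where
    applicable, angle.
    """

    itype: str
    position: tuple[float, float, float]
    protein_atom_ids: tuple[int, ...]
    ligand_atom_ids: tuple[int, ...]
    ligand_center: tuple[float, float, float]
    protein_center: tuple[float, float, float]
    geometry: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.itype not in PSEUDOATOM_TYPES:
            raise ValueError(f"unknown interaction type {self.itype!r}")
        if not self.protein_atom_ids or not self.ligand_atom_ids:
            raise ValueError("interaction record needs atoms on both sides")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("pseudoatom position must be finite")


@dataclass(frozen=True)
class Pseudoatom:
    """A typed 3D point abstracting one interaction."""

    ptype: str
    position: tuple[float, float, float]

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


# ---------------------------------------------------------------------------
# bond graph and atom typing


def guess_bonds(atoms: Sequence[AtomRecord], max_dist: float = 1.9) -> list[tuple[int, int]]:
    """Covalent-bond guess: heavy/any atom pairs closer than ``max_dist`` A.

    Used when the input format carried no bond records (PDB, bare mol2).
    Metals are excluded -- coordination is handled by the MET rule.
    """
    idx = [a for a in atoms if a.element.upper() not in METAL_ELEMENTS or a.role != "metal"]
    if len(idx) < 2:
        return []
    xyz = np.stack([a.xyz for a in idx])
    d = cdist(xyz, xyz)
    out = []
    for i in range(len(idx)):
        for j in range(i + 1, len(idx)):
            if d[i, j] <= max_dist:
                out.append((idx[i].atom_id, idx[j].atom_id))
    return out


def _neighbor_map(atoms: Sequence[AtomRecord], bonds: Iterable[tuple[int, int]]):
    by_id = {a.atom_id: a for a in atoms}
    nbrs: dict[int, list[AtomRecord]] = {a.atom_id: [] for a in atoms}
    for i, j in bonds:
        if i in by_id and j in by_id:
            nbrs[i].append(by_id[j])
            nbrs[j].append(by_id[i])
    return nbrs


def _is_apolar(atom: AtomRecord, nbrs: dict[int, list[AtomRecord]]) -> bool:
    # Aromatic carbons are handled by the ring-ring rule, not counted as
    # individual hydrophobic contacts.
    if atom.formal_charge != 0 or atom.is_aromatic:
        return False
    neigh = {n.element.upper() for n in nbrs.get(atom.atom_id, [])}
    if atom.element.upper() == "C":
        return not (neigh & {"N", "O", "F", "P", "CL", "BR"})
    if atom.element.upper() == "S":
        return neigh <= {"C", "H", "S"}
    return False


def _donors(atoms, nbrs, structure_has_h: bool):
    """Donor heavy atoms with their attached hydrogens (may be empty)."""
    out = []
    for a in atoms:
        if a.element.upper() not in ("N", "O"):
            continue
        hs = [n for n in nbrs.get(a.atom_id, []) if n.element.upper() == "H"]
        if hs:
            out.append((a, hs))
        elif not structure_has_h and a.formal_charge >= 0:
            # heavy-atom fallback for hydrogen-free structures
            out.append((a, []))
    return out


def _acceptors(atoms):
    return [
        a for a in atoms
        if a.element.upper() in ("N", "O") and a.formal_charge <= 0
    ]


def _charge_centers(atoms, nbrs):
    """Charged atoms, with bonded same-sign partners collapsed to a centroid."""
    charged = [a for a in atoms if a.formal_charge != 0]
    g = nx.Graph()
    g.add_nodes_from(a.atom_id for a in charged)
    by_id = {a.atom_id: a for a in charged}
    for a in charged:
        for n in nbrs.get(a.atom_id, []):
            if n.atom_id in by_id and np.sign(n.formal_charge) == np.sign(a.formal_charge):
                g.add_edge(a.atom_id, n.atom_id)
    centers = []
    for comp in nx.connected_components(g):
        members = [by_id[i] for i in sorted(comp)]
        pos = np.mean([m.xyz for m in members], axis=0)
        sign = int(np.sign(sum(m.formal_charge for m in members)))
        if sign != 0:
            centers.append((tuple(float(v) for v in pos), sign, tuple(m.atom_id for m in members)))
    return centers


def _aromatic_rings(atoms, bonds):
    """Rings of 5-7 aromatic-flagged atoms from the bond graph."""
    arom = [a for a in atoms if a.is_aromatic]
    if len(arom) < 5:
        return []
    ids = {a.atom_id for a in arom}
    by_id = {a.atom_id: a for a in arom}
    g = nx.Graph()
    g.add_nodes_from(ids)
    for i, j in bonds:
        if i in ids and j in ids:
            g.add_edge(i, j)
    rings = []
    for cyc in nx.minimum_cycle_basis(g):
        if 5 <= len(cyc) <= 7:
            rings.append(tuple(sorted(cyc)))
    return [[by_id[i] for i in ring] for ring in sorted(set(rings))]


def ring_centroid_normal(ring_coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit best-fit plane normal of a ring.

    The normal is the least-squares plane normal (smallest-variance
    direction of the centred coordinates), sign-canonicalised to a positive
    z component (then y, then x, for normals lying in a coordinate plane).
    Raises for fewer than 3 atoms or collinear input.
    """
    xyz = np.asarray(ring_coords, dtype=float)
    if xyz.ndim != 2 or xyz.shape[1] != 3 or xyz.shape[0] < 3:
        raise ValueError("ring needs at least 3 points of dimension 3")
    centroid = xyz.mean(axis=0)
    centered = xyz - centroid
    _u, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-8 * max(s[0], 1e-30):
        raise ValueError("ring atoms are collinear; plane undefined")
    normal = vt[2]
    for k in (2, 1, 0):
        if abs(normal[k]) > 1e-12:
            if normal[k] < 0:
                normal = -normal
            break
    return centroid, normal / np.linalg.norm(normal)


def _plane_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    """Folded inter-plane angle in [0, 90] degrees."""
    c = abs(float(np.dot(n1, n2)))
    return float(np.degrees(np.arccos(np.clip(c, 0.0, 1.0))))


def _dha_angle(donor: AtomRecord, hydrogens: Sequence[AtomRecord], acceptor: AtomRecord) -> Optional[float]:
    """Best D-H...A angle at the hydrogen, in degrees; None without H."""
    if not hydrogens:
        return None
    best = -1.0
    for h in hydrogens:
        v1 = donor.xyz - h.xyz
        v2 = acceptor.xyz - h.xyz
        denom = np.linalg.norm(v1) * np.linalg.norm(v2)
        if denom == 0:
            continue
        ang = float(np.degrees(np.arccos(np.clip(np.dot(v1, v2) / denom, -1.0, 1.0))))
        best = max(best, ang)
    return best if best >= 0 else None


# ---------------------------------------------------------------------------
# detection


def _midpoint(a, b) -> tuple[float, float, float]:
    m = (np.asarray(a, float) + np.asarray(b, float)) / 2.0
    return (float(m[0]), float(m[1]), float(m[2]))


def place_pseudoatom(rec: InteractionRecord) -> Pseudoatom:
    """Pseudoatom for one record: HB classes sit on the acceptor atom,
    every other class at the geometric centre of the two participants."""
    if rec.itype == "HBD":  # ligand donates -> acceptor is the protein atom
        pos = rec.protein_center
    elif rec.itype == "HBA":  # ligand accepts -> acceptor is the ligand atom
        pos = rec.ligand_center
    else:
        pos = _midpoint(rec.ligand_center, rec.protein_center)
    return Pseudoatom(ptype=rec.itype, position=pos)


def _make_record(itype, prot_ids, lig_ids, lig_center, prot_center, geometry):
    rec = InteractionRecord(
        itype=itype,
        position=(0.0, 0.0, 0.0),
        protein_atom_ids=tuple(prot_ids),
        ligand_atom_ids=tuple(lig_ids),
        ligand_center=tuple(float(v) for v in lig_center),
        protein_center=tuple(float(v) for v in prot_center),
        geometry=tuple(float(g) for g in geometry),
    )
    return replace(rec, position=place_pseudoatom(rec).position)


def detect_interactions(
    site: BindingSite | Sequence[AtomRecord],
    ligand: Sequence[AtomRecord],
    rules: InteractionRules = InteractionRules(),
    bonds: Optional[Iterable[tuple[int, int]]] = None,
) -> list[InteractionRecord]:
    """Detect every qualifying interaction between site and ligand.

    One record per qualifying atom pair / ring pair / charge-centre pair;
    the output is sorted canonically (type, then participant ids) so it is
    independent of input atom order.  ``bonds`` are explicit covalent
    bonds; when omitted they are guessed by distance within each side.
    """
    site_atoms = list(site.atoms) if isinstance(site, BindingSite) else list(site)
    lig_atoms = list(ligand)
    if not site_atoms or not lig_atoms:
        return []

    if bonds is None:
        bonds = guess_bonds(site_atoms, rules.bond_guess_dist) + guess_bonds(
            lig_atoms, rules.bond_guess_dist
        )
    bonds = list(bonds)
    nbrs = _neighbor_map(site_atoms + lig_atoms, bonds)
    has_h = any(a.element.upper() == "H" for a in site_atoms + lig_atoms)

    prot = [a for a in site_atoms if a.role == "protein"]
    metals = [a for a in site_atoms if a.role == "metal"]
    records: list[InteractionRecord] = []

    # hydrophobic contacts
    lig_apolar = [a for a in lig_atoms if _is_apolar(a, nbrs)]
    prot_apolar = [a for a in prot if _is_apolar(a, nbrs)]
    for la in lig_apolar:
        for pa in prot_apolar:
            d = float(np.linalg.norm(la.xyz - pa.xyz))
            if d <= rules.hyd_max_dist:
                records.append(_make_record("HYD", [pa.atom_id], [la.atom_id], la.position, pa.position, [d]))

    # hydrogen bonds, both directions
    for donor, hs in _donors(lig_atoms, nbrs, has_h):
        for acc in _acceptors(prot):
            d = float(np.linalg.norm(donor.xyz - acc.xyz))
            if d > rules.hb_max_dist:
                continue
            ang = _dha_angle(donor, hs, acc)
            if ang is not None and ang < rules.hb_min_angle:
                continue
            geom = [d] if ang is None else [d, ang]
            records.append(_make_record("HBD", [acc.atom_id], [donor.atom_id], donor.position, acc.position, geom))
    for donor, hs in _donors(prot, nbrs, has_h):
        for acc in _acceptors(lig_atoms):
            d = float(np.linalg.norm(donor.xyz - acc.xyz))
            if d > rules.hb_max_dist:
                continue
            ang = _dha_angle(donor, hs, acc)
            if ang is not None and ang < rules.hb_min_angle:
                continue
            geom = [d] if ang is None else [d, ang]
            records.append(_make_record("HBA", [donor.atom_id], [acc.atom_id], acc.position, donor.position, geom))

    # aromatic ring-ring
    lig_rings = _aromatic_rings(lig_atoms, bonds)
    prot_rings = _aromatic_rings(prot, bonds)
    for lring in lig_rings:
        lc, ln = ring_centroid_normal(np.stack([a.xyz for a in lring]))
        for pring in prot_rings:
            pc, pn = ring_centroid_normal(np.stack([a.xyz for a in pring]))
            d = float(np.linalg.norm(lc - pc))
            if d > rules.aro_centroid_max_dist:
                continue
            ang = _plane_angle(ln, pn)
            if ang <= rules.aro_face_angle_max or ang >= rules.aro_edge_angle_min:
                records.append(
                    _make_record("ARO", [a.atom_id for a in pring], [a.atom_id for a in lring], lc, pc, [d, ang])
                )

    # ionic
    for lpos, lsign, lids in _charge_centers(lig_atoms, nbrs):
        for ppos, psign, pids in _charge_centers(prot, nbrs):
            if lsign * psign >= 0:
                continue
            d = float(np.linalg.norm(np.asarray(lpos) - np.asarray(ppos)))
            if d <= rules.ion_max_dist:
                itype = "ION_P" if lsign > 0 else "ION_N"
                records.append(_make_record(itype, pids, lids, lpos, ppos, [d]))

    # metal complexation
    for m in metals:
        for la in lig_atoms:
            if la.element.upper() not in ("N", "O", "S"):
                continue
            d = float(np.linalg.norm(m.xyz - la.xyz))
            if d <= rules.metal_max_dist:
                records.append(_make_record("MET", [m.atom_id], [la.atom_id], la.position, m.position, [d]))

    records.sort(key=lambda r: (PSEUDOATOM_TYPES.index(r.itype), r.protein_atom_ids, r.ligand_atom_ids))
    return records


def records_to_csv(records: Sequence[InteractionRecord], path: str | Path) -> None:
    """Export records as CSV: type, pseudoatom xyz, participants, geometry."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["itype", "x", "y", "z", "protein_atom_ids", "ligand_atom_ids", "geometry"])
        for r in records:
            w.writerow([
                r.itype, *(f"{v:.4f}" for v in r.position),
                ";".join(map(str, r.protein_atom_ids)),
                ";".join(map(str, r.ligand_atom_ids)),
                ";".join(f"{g:.4f}" for g in r.geometry),
            ])
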