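"""Deterministic generators for toy complexes and labelled fingerprints.

Two generators make the whole pipeline testable without any external
structure or activity data:

* :func:`make_toy_complex` builds a synthetic protein-ligand complex in
  which a requested number of interactions of each class is *planted* with
  a comfortable geometric margin (at least 0.3 Angstrom / 10 degrees from
  every rule threshold), while filler atoms stay at least 1 Angstrom
  outside every rule's range.  Detection under default rules must recover
  exactly the planted records.
* :func:`make_fingerprint_dataset` emulates the screening dataset's shape:
  n samples (default 1740) at positive prevalence 446/1740 over 211
  features, positives carrying elevated activation of a set of signal
  bits, with optional label-flip noise.  The clean labels are returned
  alongside the noisy ones so recovery can be measured against the truth.

Geometry here is deliberately schematic (interaction "stations" strung out
on a line, then rigidly rotated): it exercises the detection geometry, not
protein realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .interactions import InteractionRules, Pseudoatom
from .structures import AtomRecord, ComplexStructure

__all__ = [
    "ComplexSpec",
    "PlantedInteraction",
    "FingerprintDatasetSpec",
    "FingerprintDataset",
    "make_toy_complex",
    "make_fingerprint_dataset",
]

_STATION_SPACING = 20.0  # Angstrom between planted-interaction stations
_MAX_STATIONS = 400


@dataclass(frozen=True)
class ComplexSpec:
    """Planted interaction counts plus filler atoms for one toy complex."""

    n_hyd: int = 0
    n_hbd: int = 0
    n_hba: int = 0
    n_aro: int = 0
    n_ion: int = 0
    n_met: int = 0
    decoy_atoms: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for f in ("n_hyd", "n_hbd", "n_hba", "n_aro", "n_ion", "n_met", "decoy_atoms"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")

    @property
    def n_stations(self) -> int:
        return self.n_hyd + self.n_hbd + self.n_hba + self.n_aro + self.n_ion + self.n_met


@dataclass(frozen=True)
class PlantedInteraction:
    """Ground truth for one planted interaction."""

    itype: str
    pseudoatom: Pseudoatom
    ligand_atom_ids: tuple[int, ...]
    protein_atom_ids: tuple[int, ...]


def _rotation_matrix(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


class _Builder:
    def __init__(self):
        self.atoms: list[dict] = []
        self.next_id = 1
        self.next_res = 10

    def add(self, element, pos, role, res_name, res_id=None, charge=0, aromatic=False):
        if res_id is None:
            res_id = self.next_res
        a = dict(
            atom_id=self.next_id, element=element, position=np.asarray(pos, float),
            formal_charge=charge, is_aromatic=aromatic, residue_name=res_name,
            residue_id=res_id, role=role,
        )
        self.atoms.append(a)
        self.next_id += 1
        return a["atom_id"]

    def new_residue(self) -> int:
        self.next_res += 1
        return self.next_res


def _hexagon(center: np.ndarray, normal_axis: int, radius: float = 1.39) -> list[np.ndarray]:
    """Regular hexagon around ``center`` in the plane normal to an axis."""
    axes = [i for i in range(3) if i != normal_axis]
    pts = []
    for k in range(6):
        ang = np.pi / 3 * k
        p = center.copy()
        p[axes[0]] += radius * np.cos(ang)
        p[axes[1]] += radius * np.sin(ang)
        pts.append(p)
    return pts


def make_toy_complex(
    spec: ComplexSpec,
    rules: InteractionRules = InteractionRules(),
) -> tuple[ComplexStructure, list[PlantedInteraction]]:
    """Build a complex whose detected interactions are exactly the planted ones.

    Each planted interaction occupies its own well-separated "station";
    planted geometries keep >= 0.3 Angstrom (10 degrees) of margin inside
    their rule threshold, and filler atoms stay >= 1 Angstrom outside every
    rule's range.  Byte-reproducible from ``spec.seed``.
    """
    if spec.n_stations > _MAX_STATIONS:
        raise ValueError("infeasible spec: too many planted interactions to place")
    rng = np.random.default_rng(spec.seed)
    b = _Builder()
    planted: list[PlantedInteraction] = []

    station = 0

    def sx() -> float:
        nonlocal station
        x = station * _STATION_SPACING
        station += 1
        return x

    for _ in range(spec.n_hyd):
        x = sx()
        d = rng.uniform(3.4, rules.hyd_max_dist - 0.4)
        lp = np.array([x, 0.0, 0.0])
        pp = np.array([x, d, 0.0])
        lid = b.add("C", lp, "ligand", "LIG", 1)
        pid = b.add("C", pp, "protein", "ALA", b.new_residue())
        planted.append(PlantedInteraction(
            "HYD", Pseudoatom("HYD", tuple((lp + pp) / 2)), (lid,), (pid,)))

    for _ in range(spec.n_hbd):
        x = sx()
        d = rng.uniform(2.7, rules.hb_max_dist - 0.4)
        donor = np.array([x, 0.0, 0.0])
        acceptor = np.array([x, d, 0.0])
        h = donor + np.array([0.0, 1.0, 0.0])  # on the D->A axis: angle 180 deg
        carbonyl_c = acceptor + np.array([1.23, 0.5, 0.0])
        did = b.add("N", donor, "ligand", "LIG", 1)
        b.add("H", h, "ligand", "LIG", 1)
        aid = b.add("O", acceptor, "protein", "SER", b.new_residue())
        b.add("C", carbonyl_c, "protein", "SER", b.next_res)
        planted.append(PlantedInteraction(
            "HBD", Pseudoatom("HBD", tuple(acceptor)), (did,), (aid,)))

    for _ in range(spec.n_hba):
        x = sx()
        d = rng.uniform(2.7, rules.hb_max_dist - 0.4)
        acceptor = np.array([x, 0.0, 0.0])
        donor = np.array([x, d, 0.0])
        h = donor - np.array([0.0, 1.0, 0.0])
        carbonyl_c = acceptor + np.array([1.23, -0.5, 0.0])
        aid = b.add("O", acceptor, "ligand", "LIG", 1)
        b.add("C", carbonyl_c, "ligand", "LIG", 1)
        res = b.new_residue()
        did = b.add("N", donor, "protein", "GLY", res)
        b.add("H", h, "protein", "GLY", res)
        planted.append(PlantedInteraction(
            "HBA", Pseudoatom("HBA", tuple(acceptor)), (aid,), (did,)))

    for _ in range(spec.n_aro):
        x = sx()
        d = rng.uniform(3.4, rules.aro_centroid_max_dist - 0.6)
        lc = np.array([x, 0.0, 0.0])
        pc = np.array([x, d, 0.0])
        lids = [b.add("C", p, "ligand", "LIG", 1, aromatic=True) for p in _hexagon(lc, 1)]
        res = b.new_residue()
        pids = [b.add("C", p, "protein", "PHE", res, aromatic=True) for p in _hexagon(pc, 1)]
        planted.append(PlantedInteraction(
            "ARO", Pseudoatom("ARO", tuple((lc + pc) / 2)), tuple(lids), tuple(pids)))

    for _ in range(spec.n_ion):
        x = sx()
        d = rng.uniform(3.1, rules.ion_max_dist - 0.4)
        lp = np.array([x, 0.0, 0.0])
        pp = np.array([x, d, 0.0])
        lid = b.add("N", lp, "ligand", "LIG", 1, charge=1)
        pid = b.add("O", pp, "protein", "ASP", b.new_residue(), charge=-1)
        planted.append(PlantedInteraction(
            "ION_P", Pseudoatom("ION_P", tuple((lp + pp) / 2)), (lid,), (pid,)))

    for _ in range(spec.n_met):
        x = sx()
        d = rng.uniform(2.2, rules.metal_max_dist - 0.35)
        lp = np.array([x, 0.0, 0.0])
        mp = np.array([x, d, 0.0])
        lid = b.add("O", lp, "ligand", "LIG", 1)
        mid = b.add("Zn", mp, "metal", "ZN", b.new_residue())
        planted.append(PlantedInteraction(
            "MET", Pseudoatom("MET", tuple((lp + mp) / 2)), (lid,), (mid,)))

    # filler: two well-separated clusters left of the stations, plus a
    # permanent ligand C-H pair so donor typing never falls back to the
    # hydrogen-free heuristic
    filler_center = np.array([-30.0, 0.0, 0.0])
    b.add("C", filler_center, "ligand", "LIG", 1)
    b.add("H", filler_center + np.array([1.0, 0.0, 0.0]), "ligand", "LIG", 1)
    for k in range(spec.decoy_atoms):
        jitter = rng.uniform(-0.9, 0.9, size=3)
        if k % 2 == 0:
            b.add("C", filler_center + jitter * np.array([1, 0.4, 1]), "ligand", "LIG", 1)
        else:
            b.add("C", filler_center + np.array([0.0, 6.8, 0.0]) + jitter * 0.1,
                  "protein", "GLY", b.new_residue())

    # global rigid motion so different seeds give genuinely different frames
    rot = _rotation_matrix(rng)
    shift = rng.uniform(-10.0, 10.0, size=3)

    atoms = [
        AtomRecord(
            atom_id=a["atom_id"], element=a["element"],
            position=tuple(rot @ a["position"] + shift),
            formal_charge=a["formal_charge"], is_aromatic=a["is_aromatic"],
            residue_name=a["residue_name"], residue_id=a["residue_id"],
            chain_id="A", role=a["role"],
        )
        for a in b.atoms
    ]
    planted = [
        PlantedInteraction(
            p.itype,
            Pseudoatom(p.itype, tuple(rot @ np.asarray(p.pseudoatom.position) + shift)),
            p.ligand_atom_ids,
            p.protein_atom_ids,
        )
        for p in planted
    ]
    structure = ComplexStructure(structure_id=f"toy_{spec.seed}", atoms=atoms)
    return structure, planted


# ---------------------------------------------------------------------------
# labelled fingerprint datasets


@dataclass(frozen=True)
class FingerprintDatasetSpec:
    """Shape of a synthetic labelled fingerprint dataset.

    Defaults emulate the screening corpus: 1740 samples at positive
    prevalence 446/1740 over 211 features.  Positives activate
    ``n_signal_bits`` randomly chosen bits with probability
    ``base_activation + effect`` (negatives: ``base_activation``); labels
    are then flipped at rate ``flip_noise``.
    """

    n_samples: int = 1740
    prevalence: float = 446 / 1740
    n_features: int = 211
    n_signal_bits: int = 24
    base_activation: float = 0.10
    effect: float = 0.5
    flip_noise: float = 0.0
    mode: str = "count"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must be in (0, 1)")
        if not (0.0 <= self.flip_noise < 0.5):
            raise ValueError("flip_noise must be in [0, 0.5)")
        if self.n_signal_bits > self.n_features:
            raise ValueError("n_signal_bits cannot exceed the feature count")
        if not (0.0 <= self.base_activation + self.effect <= 1.0):
            raise ValueError("base_activation + effect must be a probability")
        if self.mode not in ("count", "binary"):
            raise ValueError("mode must be 'count' or 'binary'")


@dataclass
class FingerprintDataset:
    """Generated fingerprints with noisy and clean labels."""

    X: np.ndarray
    y: np.ndarray        # labels after flip noise (what training sees)
    y_true: np.ndarray   # pre-flip labels (the planted truth)
    signal_bits: np.ndarray
    spec: FingerprintDatasetSpec


def make_fingerprint_dataset(spec: FingerprintDatasetSpec) -> FingerprintDataset:
    """Sample a labelled fingerprint dataset; reproducible from ``spec.seed``.

    The positive count equals round(prevalence * n) exactly before flip
    noise.  In count mode, activated bits carry 1 + Poisson(0.7) counts;
    in binary mode they carry 1.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    n_pos = int(round(spec.prevalence * n))
    y_true = np.zeros(n, dtype=int)
    y_true[rng.choice(n, size=n_pos, replace=False)] = 1
    signal = rng.choice(spec.n_features, size=spec.n_signal_bits, replace=False)
    p = np.full((n, spec.n_features), spec.base_activation)
    p[np.ix_(y_true == 1, signal)] = spec.base_activation + spec.effect
    active = rng.random((n, spec.n_features)) < p
    if spec.mode == "count":
        X = active * (1 + rng.poisson(0.7, size=active.shape))
    else:
        X = active.astype(int)
    flip = rng.random(n) < spec.flip_noise
    y = np.where(flip, 1 - y_true, y_true)
    return FingerprintDataset(
        X=X.astype(float), y=y, y_true=y_true,
        signal_bits=np.sort(signal), spec=spec,
    )
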