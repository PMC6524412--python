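"""End-to-end helpers: complex file -> pseudoatoms -> fingerprint table.

These wire the geometric modules together in the order the screening
workflow uses them: binding-site extraction at 6 Angstrom, interaction
detection, pseudoatom placement, triplet enumeration and vectorisation
through a feature dictionary.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .fingerprint import (
    BinScheme,
    FeatureDictionary,
    Fingerprint,
    build_dictionary,
    enumerate_triplets,
    vectorize,
)
from .interactions import InteractionRules, Pseudoatom, detect_interactions, place_pseudoatom
from .structures import ComplexStructure, extract_binding_site, read_complex

__all__ = [
    "pseudoatoms_from_complex",
    "fingerprint_complex",
    "fingerprint_directory",
    "fingerprints_to_frame",
    "frame_to_matrix",
]


def pseudoatoms_from_complex(
    complex_: ComplexStructure,
    cutoff: float = 6.0,
    rules: InteractionRules = InteractionRules(),
) -> list[Pseudoatom]:
    """Detect interactions within the 6 A binding site and place pseudoatoms."""
    site = extract_binding_site(complex_, cutoff=cutoff)
    records = detect_interactions(site, complex_.ligand_atoms, rules, bonds=complex_.bonds)
    return [place_pseudoatom(r) for r in records]


def fingerprint_complex(
    complex_: ComplexStructure,
    dictionary: FeatureDictionary,
    cutoff: float = 6.0,
    rules: InteractionRules = InteractionRules(),
    scheme: BinScheme = BinScheme(),
    mode: str = "count",
) -> Fingerprint:
    """Fingerprint one complex through an existing feature dictionary."""
    pas = pseudoatoms_from_complex(complex_, cutoff=cutoff, rules=rules)
    keys = enumerate_triplets(pas, scheme)
    return vectorize(keys, dictionary, mode=mode,
                     molecule_id=complex_.structure_id, target_id=complex_.target_id)


def fingerprint_directory(
    paths: Sequence[str | Path],
    dictionary: Optional[FeatureDictionary] = None,
    cutoff: float = 6.0,
    rules: InteractionRules = InteractionRules(),
    scheme: BinScheme = BinScheme(),
    mode: str = "count",
) -> tuple[list[Fingerprint], FeatureDictionary]:
    """Fingerprint a set of complex files.

    Without a dictionary, one is first built from the corpus itself (the
    most frequent triplet keys across all files).
    """
    complexes = [read_complex(p) for p in paths]
    key_sets = [
        enumerate_triplets(pseudoatoms_from_complex(c, cutoff, rules), scheme)
        for c in complexes
    ]
    if dictionary is None:
        dictionary = build_dictionary(key_sets, provenance=f"{len(paths)} complexes")
    fps = [
        vectorize(keys, dictionary, mode=mode, molecule_id=c.structure_id, target_id=c.target_id)
        for c, keys in zip(complexes, key_sets)
    ]
    return fps, dictionary


def fingerprints_to_frame(fps: Sequence[Fingerprint]) -> pd.DataFrame:
    """One row per molecule: id, target, then the numbered feature columns."""
    if not fps:
        raise ValueError("no fingerprints to export")
    width = len(fps[0].values)
    if any(len(f.values) != width for f in fps):
        raise ValueError("fingerprints have inconsistent lengths")
    cols = [f"f{i}" for i in range(width)]
    frame = pd.DataFrame([f.values for f in fps], columns=cols)
    frame.insert(0, "target_id", [f.target_id for f in fps])
    frame.insert(0, "molecule_id", [f.molecule_id for f in fps])
    return frame


def frame_to_matrix(frame: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Feature matrix and molecule ids from a fingerprint table."""
    feat_cols = [c for c in frame.columns if c.startswith("f")]
    return frame[feat_cols].to_numpy(dtype=float), list(frame["molecule_id"])
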