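"""Small reference data shipped with the package.

``DOT1L_PANEL`` is a published external test panel of 25 ligands reported
to bind the SAM pocket of the histone methyltransferase DOT1L, with their
measured pIC50 values (pIC50 = 9 - log10(IC50 in nM)).  It serves as a
worked example for the activity-labelling rule: every entry has pIC50 >= 5,
i.e. IC50 <= 10 uM, so the <= 10 uM rule classifies all 25 as positive.
"""

from __future__ import annotations

#: (ligand label, pIC50)
DOT1L_PANEL: tuple[tuple[str, float], ...] = (
    ("C170206_10", 5.19),
    ("C170206_15", 5.40),
    ("C170206_16", 5.08),
    ("C170206_17", 5.35),
    ("C170206_39", 5.39),
    ("C170206_6", 5.08),
    ("C170206_9", 5.33),
    ("C170214_3", 5.05),
    ("C170214_4", 8.4),
    ("C170214_5", 8.4),
    ("C170214_6", 9.82),
    ("C170214_7", 8.52),
    ("C180224_6", 5.15),
    ("C180224_7", 5.03),
    ("C180224_9", 5.01),
    ("C180722_3a", 5.82),
    ("C180722_3b", 5.36),
    ("C180722_3d", 5.97),
    ("C180722_3e", 5.97),
    ("C180722_8b", 5.11),
    ("C180722_8f", 5.22),
    ("C180722_8h", 5.24),
    ("C180722_8i", 5.1),
    ("C180722_9b", 5.06),
    ("C180722_9e", 5.45),
)


def pic50_to_nm(pic50: float) -> float:
    """IC50 in nM from a pIC50 value (inverse of 9 - log10(nM))."""
    return 10.0 ** (9.0 - pic50)
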