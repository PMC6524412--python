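"""Dataset assembly and the training/evaluation protocol.

This module holds the screening-campaign plumbing around the classifier:

* activity labelling (IC50/EC50/Ki <= 10 uM positive, > 50 uM negative,
  the gap excluded; decoys negative by construction) and the pActivity
  transform ``9 - log10(value in nM)``,
* docked-pose filtering (docking score at most -8.2 and pose centroid
  inside the reference pocket; best-scoring pose per molecule),
* the split protocol: test set drawn once at test:rest = 1:10, the
  remainder re-shuffled ten times into validation:train = 1:8,
* multi-grid hyperparameter search scored by validation PRC-AUC,
* repeated training over the ten splits with a mean +/- sd summary,
* pairwise Tanimoto similarity of molecule fingerprint bitsets for
  dataset-diversity histograms.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .metrics import enrichment_factor, prc_auc, roc_auc
from .network import MLPScreenClassifier, ModelConfig, init_model, train

__all__ = [
    "ActivityRecord",
    "PoseRecord",
    "DatasetSplit",
    "GridSpec",
    "assign_label",
    "p_activity",
    "filter_poses",
    "split_dataset",
    "grid_search",
    "repeated_training",
    "pairwise_similarity",
    "tanimoto",
]


def p_activity(value_nm: float) -> float:
    """pActivity = 9 - log10(activity in nM); 1 nM -> 9, 10 uM -> 5."""
    if value_nm <= 0:
        raise ValueError("activity value must be positive")
    return 9.0 - math.log10(value_nm)


@dataclass(frozen=True)
class ActivityRecord:
    """One measured activity; values stored in nM."""

    molecule_id: str
    target_id: str
    activity_type: str  # IC50 | EC50 | Ki
    value_nm: float

    def __post_init__(self) -> None:
        if self.activity_type not in ("IC50", "EC50", "Ki"):
            raise ValueError(f"unknown activity type {self.activity_type!r}")
        if self.value_nm <= 0:
            raise ValueError("activity value must be positive")

    @property
    def p_activity(self) -> float:
        return p_activity(self.value_nm)


def assign_label(
    rec: ActivityRecord | float,
    pos_max_um: float = 10.0,
    neg_min_um: float = 50.0,
) -> str:
    """Label an activity: <= 10 uM positive, > 50 uM negative, gap excluded."""
    value_nm = rec.value_nm if isinstance(rec, ActivityRecord) else float(rec)
    if value_nm <= 0:
        raise ValueError("activity value must be positive")
    if value_nm <= pos_max_um * 1000.0:
        return "positive"
    if value_nm > neg_min_um * 1000.0:
        return "negative"
    return "excluded"


@dataclass(frozen=True)
class PoseRecord:
    """One docked pose with its engine score (more negative = better)."""

    molecule_id: str
    target_id: str
    docking_score: float
    pose_centroid: tuple[float, float, float]
    reference_pocket_centroid: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not np.isfinite(self.docking_score):
            raise ValueError("docking score must be finite")


def filter_poses(
    poses: Sequence[PoseRecord],
    score_max: float = -8.2,
    pocket_radius: float = 8.0,
) -> list[PoseRecord]:
    """Keep poses scoring at most ``score_max`` whose centroid lies within
    ``pocket_radius`` of the reference pocket centre; at most one (the
    best-scoring) pose per molecule, input order preserved."""
    best: dict[str, PoseRecord] = {}
    order: list[str] = []
    for p in poses:
        d = float(np.linalg.norm(np.asarray(p.pose_centroid) - np.asarray(p.reference_pocket_centroid)))
        if p.docking_score > score_max or d > pocket_radius:
            continue
        if p.molecule_id not in best:
            order.append(p.molecule_id)
            best[p.molecule_id] = p
        elif p.docking_score < best[p.molecule_id].docking_score:
            best[p.molecule_id] = p
    return [best[m] for m in order]


@dataclass(frozen=True)
class DatasetSplit:
    """One train/validation/test partition of molecule ids."""

    test_ids: tuple
    valid_ids: tuple
    train_ids: tuple
    repeat_index: int
    seed: int

    def __post_init__(self) -> None:
        t, v, r = set(self.test_ids), set(self.valid_ids), set(self.train_ids)
        if t & v or t & r or v & r:
            raise ValueError("split parts must be disjoint")


def split_dataset(
    ids: Sequence,
    seed: int,
    n_repeats: int = 10,
    test_fraction: Optional[float] = None,
) -> list[DatasetSplit]:
    """The two-stage split protocol, reproducible from ``seed``.

    Stage 1 draws the test set once at test:rest = 1:10, i.e.
    ``round(n/11)`` ids (banker's rounding); pass ``test_fraction`` for a
    plain-fraction alternative.  Stage 2 re-shuffles the remainder
    ``n_repeats`` times into validation:train = 1:8
    (``round(remainder/9)`` validation ids).  The test set is identical
    across repeats; for n = 1740 the sizes are 158 / 176 / 1406.
    """
    ids = list(ids)
    n = len(ids)
    if len(set(ids)) != n:
        raise ValueError("ids must be unique")
    if n < 22:
        raise ValueError("need at least 22 ids so all parts are non-empty")
    n_test = round(n * test_fraction) if test_fraction is not None else round(n / 11)
    n_test = max(1, int(n_test))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test = [ids[i] for i in perm[:n_test]]
    rest = [ids[i] for i in perm[n_test:]]
    n_valid = max(1, round(len(rest) / 9))
    splits = []
    for rep in range(n_repeats):
        rng_rep = np.random.default_rng([seed, rep])
        order = rng_rep.permutation(len(rest))
        valid = [rest[i] for i in order[:n_valid]]
        train_ids = [rest[i] for i in order[n_valid:]]
        splits.append(
            DatasetSplit(
                test_ids=tuple(test),
                valid_ids=tuple(valid),
                train_ids=tuple(train_ids),
                repeat_index=rep,
                seed=seed,
            )
        )
    return splits


@dataclass
class GridSpec:
    """Axes of the hyperparameter grid (Cartesian product is searched)."""

    dropouts: tuple[float, ...] = (0.1, 0.2)
    learning_rates: tuple[float, ...] = (0.0001, 0.001, 0.0005, 0.00005)
    hidden_sizes: tuple[tuple[int, int], ...] = (
        (500, 100), (100, 500), (320, 640), (500, 1000),
    )

    def __post_init__(self) -> None:
        if not self.dropouts or not self.learning_rates or not self.hidden_sizes:
            raise ValueError("every grid axis must be non-empty")

    @property
    def n_combinations(self) -> int:
        return len(self.dropouts) * len(self.learning_rates) * len(self.hidden_sizes)


def _fit_eval(config: ModelConfig, x_tr, y_tr, x_va, y_va):
    net = init_model(config)
    model = train(net, (x_tr, y_tr), (x_va, y_va), config)
    p_tr = model.predict_proba(x_tr)[:, 1]
    p_va = model.predict_proba(x_va)[:, 1]

    def side(p, y):
        preds = (p >= 0.5).astype(int)
        tp = int(np.sum((y == 1) & (preds == 1)))
        fn = int(np.sum((y == 1) & (preds == 0)))
        fp = int(np.sum((y == 0) & (preds == 1)))
        return {
            "recall": tp / (tp + fn) if tp + fn else float("nan"),
            "precision": tp / (tp + fp) if tp + fp else float("nan"),
            "roc_auc": roc_auc(p, y),
            "prc_auc": prc_auc(p, y),
        }

    return model, side(p_tr, np.asarray(y_tr)), side(p_va, np.asarray(y_va))


def grid_search(
    grid: GridSpec,
    train_set: tuple[np.ndarray, np.ndarray],
    valid_set: tuple[np.ndarray, np.ndarray],
    base_config: Optional[ModelConfig] = None,
) -> tuple[pd.DataFrame, dict]:
    """Train one model per grid combination; score by validation PRC-AUC.

    Returns a result table with one row per combination (stop epoch plus
    train/valid recall, precision, ROC-AUC and PRC-AUC) and the best
    combination; PRC-AUC ties break toward lower dropout, then lower
    learning rate.
    """
    x_tr, y_tr = np.asarray(train_set[0], float), np.asarray(train_set[1], int)
    x_va, y_va = np.asarray(valid_set[0], float), np.asarray(valid_set[1], int)
    base = base_config or ModelConfig(input_dim=x_tr.shape[1])
    rows = []
    for dropout, lr, hidden in itertools.product(grid.dropouts, grid.learning_rates, grid.hidden_sizes):
        config = ModelConfig(
            input_dim=x_tr.shape[1],
            hidden_sizes=tuple(hidden),
            dropout=dropout,
            learning_rate=lr,
            weight_decay=base.weight_decay,
            activation=base.activation,
            batch_size=base.batch_size,
            max_epochs=base.max_epochs,
            patience=base.patience,
            seed=base.seed,
        )
        model, tr, va = _fit_eval(config, x_tr, y_tr, x_va, y_va)
        rows.append({
            "dropout": dropout,
            "learning_rate": lr,
            "hidden_sizes": str(list(hidden)),
            "stop_epoch": model.stopped_epoch,
            "train_recall": tr["recall"],
            "train_precision": tr["precision"],
            "train_roc_auc": tr["roc_auc"],
            "train_prc_auc": tr["prc_auc"],
            "valid_recall": va["recall"],
            "valid_precision": va["precision"],
            "valid_roc_auc": va["roc_auc"],
            "valid_prc_auc": va["prc_auc"],
        })
    results = pd.DataFrame(rows)
    ranked = results.sort_values(
        by=["valid_prc_auc", "dropout", "learning_rate"],
        ascending=[False, True, True],
        kind="stable",
    )
    best = ranked.iloc[0]
    best_combo = {
        "dropout": float(best["dropout"]),
        "learning_rate": float(best["learning_rate"]),
        "hidden_sizes": best["hidden_sizes"],
        "valid_prc_auc": float(best["valid_prc_auc"]),
    }
    return results, best_combo


def repeated_training(
    config: ModelConfig,
    splits: Sequence[DatasetSplit],
    X: np.ndarray,
    y: np.ndarray,
    ids: Sequence,
) -> tuple[pd.DataFrame, pd.DataFrame, int, list]:
    """Train one model per split; summarise validation metrics.

    Returns (per-split metrics table, mean/sd summary, index of the best
    model by validation PRC-AUC, trained models).  Metrics per split:
    recall, precision, accuracy, ROC-AUC and PRC-AUC on that split's
    validation set at threshold 0.5.
    """
    if len(splits) < 2:
        raise ValueError("need at least 2 splits for a mean/sd summary")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    pos = {mid: i for i, mid in enumerate(ids)}
    rows, models = [], []
    for split in splits:
        tr_idx = [pos[m] for m in split.train_ids]
        va_idx = [pos[m] for m in split.valid_ids]
        seed_config = ModelConfig(**{**config.__dict__, "seed": config.seed + split.repeat_index})
        net = init_model(seed_config)
        model = train(net, (X[tr_idx], y[tr_idx]), (X[va_idx], y[va_idx]), seed_config)
        p_va = model.predict_proba(X[va_idx])[:, 1]
        y_va = y[va_idx]
        preds = (p_va >= 0.5).astype(int)
        tp = int(np.sum((y_va == 1) & (preds == 1)))
        fn = int(np.sum((y_va == 1) & (preds == 0)))
        fp = int(np.sum((y_va == 0) & (preds == 1)))
        tn = int(np.sum((y_va == 0) & (preds == 0)))
        rows.append({
            "model": split.repeat_index + 1,
            "recall": tp / (tp + fn) if tp + fn else float("nan"),
            "precision": tp / (tp + fp) if tp + fp else float("nan"),
            "accuracy": (tp + tn) / len(y_va),
            "roc_auc": roc_auc(p_va, y_va),
            "prc_auc": prc_auc(p_va, y_va),
        })
        models.append(model)
    per_split = pd.DataFrame(rows)
    metric_cols = ["recall", "precision", "accuracy", "roc_auc", "prc_auc"]
    summary = pd.DataFrame({
        "mean": per_split[metric_cols].mean(),
        "sd": per_split[metric_cols].std(ddof=1),
    })
    best_index = int(per_split["prc_auc"].idxmax())
    return per_split, summary, best_index, models


# ---------------------------------------------------------------------------
# dataset diversity


def tanimoto(a: frozenset | set, b: frozenset | set) -> float:
    """Tanimoto coefficient |A & B| / |A | B| of two on-bit sets."""
    if not a or not b:
        raise ValueError("fingerprint bitsets must be non-empty")
    return len(a & b) / len(a | b)


def pairwise_similarity(
    bitsets: Sequence[set],
    n_hist_bins: int = 20,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All n(n-1)/2 pairwise Tanimoto coefficients plus a fixed-width
    histogram over [0, 1] for diversity inspection."""
    bitsets = [frozenset(b) for b in bitsets]
    if len(bitsets) < 2:
        raise ValueError("need at least two molecules")
    coeffs = np.array([
        tanimoto(a, b) for a, b in itertools.combinations(bitsets, 2)
    ])
    counts, edges = np.histogram(coeffs, bins=n_hist_bins, range=(0.0, 1.0))
    return coeffs, counts, edges


def morgan_bitsets(smiles: Sequence[str], radius: int = 2, n_bits: int = 2048) -> list[set]:
    """On-bit sets of circular (Morgan) fingerprints for a list of SMILES.

    Fingerprint generation is delegated to RDKit; molecules that fail to
    parse raise.
    """
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    out = []
    for smi in smiles:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smi!r}")
        fp = gen.GetFingerprint(mol)
        out.append(set(fp.GetOnBits()))
    return out
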