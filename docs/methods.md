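# Methods

This note documents the models and procedures implemented in `tifpscreen`,
the parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data generators do and do not
emulate.

## Problem setting

Structure-based virtual screening of inhibitors for the SAM
(S-adenosyl-L-methionine) pocket of methyltransferases suffers from weak
ranking power of generic docking scores. The package rescores docked
protein–ligand poses in two stages: (1) the pose is encoded as a fixed
211-feature *triplet interaction fingerprint* built from typed pseudoatoms,
and (2) a feedforward binary classifier maps the fingerprint to the
probability that the compound is an active for the target. Around the
scorer sits the full experimental harness: activity labelling, pose
filtering, a two-stage split protocol, multi-grid hyperparameter search,
repeated training, and screening metrics.

## Binding site and pose geometry

A binding site is the set of receptor residues with any atom within a
cutoff (default **6 Å**) of any ligand atom; included residues are kept
whole, and metal ions inside the cutoff stay in the site so metal
complexation remains detectable. Distances are Euclidean in Å throughout.

Pose RMSD is computed over stored atom-order correspondence in a common
reference frame, with no re-superposition and no graph-symmetry
correction; this matches the cross-docking use case (docked vs. native
pose of the same molecule in the same receptor frame) but will overstate
the deviation of symmetric ligands — a documented limitation. Receptor
selection for cross docking takes, per target, the candidate structure
with the smallest mean RMSD over its re-docked ligands; failed dockings
are skipped in the mean by default (a fixed penalty value is available),
and exact ties break toward the lexicographically smallest structure id.

## Interaction detection

Five interaction classes are detected between binding site and ligand,
each instance abstracted to one typed 3D point (pseudoatom). Hydrogen
bonds are split by direction and ionic contacts by ligand charge sign,
giving seven type codes: HYD, ARO, HBD, HBA, ION_P, ION_N, MET.

Default geometric rules (all configurable via `InteractionRules`):

| class | rule | default |
|---|---|---|
| hydrophobic (HYD) | apolar C/S pair distance | ≤ 4.5 Å |
| hydrogen bond (HBD/HBA) | donor–acceptor heavy distance | ≤ 3.5 Å |
|  | D–H···A angle (hydrogens present) | ≥ 120° |
| aromatic (ARO) | ring-centroid distance | ≤ 5.0 Å |
|  | folded plane angle: face ≤ 30° or edge ≥ 60° | |
| ionic (ION_P/ION_N) | opposite charge-centre distance | ≤ 4.0 Å |
| metal (MET) | metal to ligand N/O/S | ≤ 2.8 Å |

Atom typing uses element, formal charge, aromatic flag and bonded
neighbours; when the input format carries no bonds, a covalent guess at
1.9 Å is used (metals excluded — coordination is the MET rule's job).
Donors require an attached hydrogen when the structure has any hydrogens;
for hydrogen-free structures (bare PDB) detection falls back to permissive
heavy-atom typing with no angle test. Aromatic rings come from input
aromatic flags and a minimum-cycle-basis search over the bond graph
(rings of 5–7 atoms); ring planes are least-squares fits (smallest
singular vector), sign-canonicalised.

Two typing decisions matter for exactness guarantees:

* **Aromatic carbons are not hydrophobic contacts.** A stacked ring pair
  counts as one ARO record; letting its 36 carbon pairs also fire the HYD
  rule would swamp the triplet counts with redundant contacts.
* **One record per qualifying pair**, no clustering — triplet counting
  operates on the pseudoatom multiset, so clustering would change the
  statistics silently.

Pseudoatom placement: HYD/ARO/ION/MET records sit at the geometric centre
of the two participating centres; hydrogen bonds sit on the acceptor atom
(protein atom for HBD, ligand atom for HBA). The placement rule per class
is this package's documented choice among the conventions in use for
triplet pseudoatom fingerprints.

## Triplet fingerprints

Every unordered pseudoatom triple becomes a key: three (type,
opposite-side distance bin) pairs. Distances are binned half-open into
**0–4, 4–6, 6–9, 9–13, 13–17, 17+ Å** (so 4.0 Å falls in the second bin;
the half-open convention resolves the overlapping range labels). The key
is canonicalised as the minimum over all six vertex orderings of the
(type rank, bin) sequence, which guarantees permutation invariance
without geometric hashing; bins are paired to the side *opposite* each
vertex so the pairing survives vertex permutation.

A **feature dictionary** maps the most frequent keys of a training corpus
to a fixed 211-slot index (count ties break lexicographically on the key
encoding; a corpus with fewer than 211 distinct keys pads with inert
slots so vectors keep length 211). The original reference key table is
not published, so the dictionary is a first-class, serialisable artifact
built from the user's corpus — no hidden universal table is pretended.
Vectors are **counts** by default (triples are counted); a binary
presence mode is selectable since the literature also describes the
result as a bit vector. Appended descriptors (e.g. a docking score for
the hybrid fingerprint–docking model) extend the vector after position
211 and must be finite.

End-to-end fingerprints are invariant under rigid motion and atom
reordering of the complex, provided no pairwise pseudoatom distance sits
within numerical noise of a bin edge.

## Classifier

A fully connected network: input (211, or 212 with a docking score) →
hidden layers **500 × 1000** (ReLU, dropout 0.1) → 2-unit softmax;
609,002 trainable parameters at the default shape. Training minimises
softmax cross-entropy with an L2 weight-decay penalty (0.0001) using Adam
(learning rate 0.001), and early-stops when the validation **PRC-AUC**
(average precision) has not strictly improved for **15** consecutive
epochs; the parameters of the best validation epoch are returned.
PRC-AUC is the selection metric because the screening data are imbalanced
(positive prevalence ≈ 0.26), where the PR curve is more informative than
ROC.

The network and Adam are implemented directly in NumPy: the fitted state
is a plain list of arrays and the whole run (He-scaled initialisation,
shuffling, dropout masks) is bit-reproducible from one seed. Batch size
(64) and the epoch cap (200) are this package's defaults — the training
sets here are ~1,400 rows, where small batches suffice; both are
configurable and not claimed to match any external tooling. Weight decay
is applied to weights only, not biases. No class weighting or
oversampling is used; imbalance is handled solely through PRC-AUC model
selection. Decision threshold: positive iff the positive-class
probability ≥ 0.5 (boundary inclusive).

## Metrics

Recall = TP/(TP+FN), precision = TP/(TP+FP), TPR = recall,
FPR = FP/(FP+TN), accuracy = (TP+TN)/total; a zero denominator raises an
undefined-metric signal rather than silently returning 0. ROC-AUC is the
Mann–Whitney concordance probability (ties ½); PRC-AUC is step-wise
average precision, not linear PR interpolation, which is known to
over-estimate PR curves — other tooling may differ at the few-per-mil
level. The enrichment factor at fraction f ranks by descending score
(stable sort), takes the top ⌈f·N⌉, and returns hit-rate ratio
(hits/top)/(actives/N) by default; the recall-ratio convention
(hits/actives)/f is available behind a flag since published EF values do
not always state which was used.

## Experiment protocol

Activities are stored in nM; pActivity = 9 − log10(value in nM). Labels:
≤ 10 µM positive, > 50 µM negative, the gap (10, 50] µM excluded from
training; decoys are negative by construction. Docked poses are kept only
with docking score ≤ −8.2 and pose centroid within a pocket radius
(default 8 Å) of the reference pocket centre — the radius is this
package's operationalisation of "bound the intended pocket" — with at
most the best-scoring pose per molecule.

Split protocol: the test set is drawn once at test:rest = 1:10
(`round(n/11)` with banker's rounding; n = 1740 → 158); the remainder is
re-shuffled ten times into validation:train = 1:8 (`round(rest/9)`;
1582 → 176/1406). The test set is fixed across the ten repeats; repeats
differ in the validation/train shuffle and the training seed. A
plain-fraction test split is available behind a flag because the 1:10
phrasing admits a 10% reading.

Grid search trains one model per combination of the hyperparameter axes
(default grid: dropout {0.1, 0.2} × learning rate {0.0001, 0.001, 0.0005,
0.00005} × hidden sizes {[500,100], [100,500], [320,640], [500,1000]} =
32 cells), records the stop epoch and train/validation recall, precision,
ROC-AUC and PRC-AUC, and picks the best validation PRC-AUC (ties: lower
dropout, then lower learning rate). Repeated training fits one model per
split and reports per-split validation metrics with a mean ± sd summary
and the best model by validation PRC-AUC. Dataset diversity uses pairwise
Tanimoto coefficients of circular (Morgan) fingerprint bitsets; the
fingerprints themselves come from RDKit.

## Synthetic data

`make_toy_complex` strings planted interactions along well-separated
20 Å "stations", each satisfying its rule with ≥ 0.3 Å (10°) margin,
while filler atoms stay ≥ 1 Å outside every rule's range; a permanent
ligand C–H pair keeps donor typing in its hydrogen-aware mode. The whole
complex then receives a seeded random rigid motion. The guarantee —
detection recovers exactly the planted records — is what the geometric
tests rely on. The generator emulates interaction geometry only: atoms do
not form a connected molecule, the protein is not a chain, and no
docking-pose physics is present, so passing tests certify the
detection/encoding machinery, not performance on real structures.

`make_fingerprint_dataset` emulates the screening corpus's shape: 1740
samples at prevalence 446/1740 over 211 features. Positives activate 24
signal bits at probability 0.60 versus a 0.10 baseline (effect 0.5);
count mode multiplies activations by 1 + Poisson(0.7). Labels may then be
flipped at a configurable rate; the pre-flip labels are returned
alongside so that recovery can be measured against the planted truth —
training sees the noisy labels, evaluation of *recovery* uses the clean
ones (measuring against flipped held-out labels would cap ROC-AUC near
0.92 regardless of model quality). The signal model is independent-bit
Bernoulli — the simplest structure under which classifier recovery can be
stated quantitatively; real fingerprints have correlated, long-tailed
counts, so recovery here does not certify real-data accuracy.

## Problem sizes and statistical checks

The acceptance script and test suite run at these sizes: triplet oracle
over 100 random sets of up to 30 pseudoatoms; invariance over 50 toy
complexes; split fuzzing over 40 sizes in [22, 5000]; the full 32-cell
grid on a 240-sample dataset with a 6-epoch cap; classifier recovery on
the full 1740-sample shape over 5 seeds with a 40-epoch cap. The
permuted-label control permutes the early-stopping monitor labels along
with the training labels (selecting epochs against real validation
labels would leak signal into an otherwise label-free model) and
compares the **mean** held-out ROC-AUC of 5 permuted runs against
[0.4, 0.6]: a single permuted run's AUC on a 158-sample test set has a
standard deviation of ≈ 0.09, so a per-run band of that width would be
breached by chance alone in roughly one run of four.

## Known limitations

* No π–cation or halogen bonds, no water-mediated contacts — outside the
  five-class scheme.
* RMSD without symmetry correction overstates deviations of symmetric
  ligands.
* The interaction thresholds are standard-practice defaults, not fitted
  to any reference implementation; absolute fingerprint values will
  differ from other tools even on identical structures.
* mol2 formal charges are recovered from the charge column only when it
  holds near-integer values (as in prepared files and this package's own
  writer); partial-charge-only files yield neutral atoms.
* No GPU path; the NumPy implementation targets datasets of thousands of
  rows, not millions.
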