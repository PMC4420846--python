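# Methods

## Interaction fingerprints

A SIFt encodes one ligand pose against one receptor conformation as nine
bits per residue, concatenated in residue order: any contact, main-chain
contact, side-chain contact, polar, hydrophobic, H-bond acceptor, H-bond
donor, aromatic, charged. Two conventions that the surrounding literature
leaves ambiguous are fixed here explicitly:

* **Direction of H-bond bits.** `hb_donor` means the *residue* donates the
  hydrogen bond; `hb_acceptor` means the residue accepts. This follows the
  original SIFt convention.
* **Derived bits.** `any` is the OR over every detected interaction of any
  class, and `main_chain`/`side_chain` partition the residue atoms that
  participated in at least one detected interaction. An H-bond always sets
  the polar bit (a hydrogen bond is a polar interaction by definition; this
  also keeps the implication chain hb ⇒ polar ⇒ any intact when a ligand
  fluorine acts as acceptor).

### Geometric predicates and cutoffs

The interaction classes are named but not geometrically defined in the
protocol this package follows, so the cutoffs below are **this
implementation's choices**, following common practice in open
interaction-fingerprint tools. All are configurable through
`GeometryConfig`:

| class        | predicate                                                | default |
|--------------|----------------------------------------------------------|---------|
| any          | residue heavy atom – ligand heavy atom                   | ≤ 4.5 Å |
| polar        | N/O/S atom vs. N/O/S atom                                | ≤ 3.5 Å |
| hydrophobic  | C/S with no bonded N/O, both sides                       | ≤ 4.5 Å |
| H-bond       | donor–acceptor heavy-atom distance                       | ≤ 3.5 Å |
| aromatic     | ring centroid – ring centroid                            | ≤ 5.0 Å |
| charged      | atoms with opposite nonzero formal charge                | ≤ 4.0 Å |

When explicit hydrogens are present on a donor, the D–H…A angle must also
be ≥ 120°; without hydrogens the test is distance-only. This heavy-atom
fallback is deliberate: docked pose files do not reliably retain
hydrogens, and all geometry must be computable without them. Receptor atom
typing (main-chain role, donors/acceptors, hydrophobic carbons, aromatic
rings for PHE/TYR/TRP/HIS, carboxylate/ammonium charges) is table-driven
from standard residue topology; ligand typing is inferred from file
connectivity via RDKit, with implicit-valence donor inference when
hydrogens are absent.

## Profiles and the missing-pose denominator

The per-ligand profile is the position-wise mean of the binary SIFts over
the conformations of the ensemble. A compound qualifies with at least one
pose. For conformations where a compound received no pose, the default
("all models") divides by the full ensemble size, treating the missing
pose as a zero vector — so a compound docked in 3 of 5 conformations with
a bit always set scores 0.6, not 1.0. The alternate mode normalizing by
posed conformations only is provided (`denominator="posed"`) because the
source protocol is genuinely ambiguous; the default is the reading that
penalizes undockable compounds, which is the stricter and, we judge, the
intended one. Both modes are covered by tests.

Protonation-state expansion of a parent compound yields separate rows
carrying the parent's label; cross-validation groups rows by parent
compound so no parent appears in both training and held-out folds.

## Classifier

The linear soft-margin SVM is solved in the dual by libsvm (via
scikit-learn); the package treats the solver as a black box but verifies
the emitted solution against the dual feasibility conditions
Σαᵢyᵢ = 0 and 0 ≤ αᵢ ≤ C after every fit (KKT tolerance 1e-6), and the
test suite checks the achieved dual objective against an exhaustive
active-set enumeration oracle on small problems. One printed form of the
primal constraint in the source material contains a garbled extra term
("− var(αᵢ)ξᵢ"); it is implemented as the standard constraint
yᵢ(⟨w,xᵢ⟩ − b) ≥ 1 − ξᵢ.

Model selection: the C grid {0.01, 0.1, 1, 10, 100, 1000, 10000},
stratified compound-grouped 10-fold cross-validation, confusion counts
pooled over folds, MCC computed on the pooled table (stabler than the
per-fold mean for small folds, which is nevertheless reported). Ties on
the grid go to the smaller C. The MCC zero-denominator convention is 0.
AUROC is the exact Mann–Whitney pair count with ties at ½.

## The ensemble-size sweep

At each size s = 3…N the profile is rebuilt on the *prefix* of the first s
conformations in the caller's order and the full C grid re-optimized. The
prefix reading (rather than the best subset of each size) is the only
computationally plausible interpretation of "adding one-by-one" — a
best-subset reading would require 2^N evaluations. The addition order
defaults to the input manifest order; ordering by descending
per-conformation AUROC is available via `ConformationRanking.order`.
Best/worst sizes break ties toward the smaller ensemble (the cheaper
protocol). ΔMCC entries telescope exactly to mcc(N) − mcc(3) by
construction, and the suite asserts it.

## Synthetic data: what it emulates and what it does not

`simulate_fingerprints` draws the statistical structure the analysis
assumes from ensemble docking output, without doing any docking:

* **Actives** share one conserved interaction pattern of `n_signal_bits`
  positions (drawn among the six interaction-class bits, never the derived
  any/main/side bits). Per conformation, each signal bit flips with
  probability `flip_prob` — pose fluctuation.
* **Inactives and decoys** (and all non-signal positions) carry Bernoulli
  background contacts at `background_rate`.
* **Pose failures** drop whole (compound, conformation) fingerprints with
  `pose_fail_prob`; compounds losing every pose are omitted, mirroring the
  at-least-one-pose rule.
* After noise, the derived bits are recomputed (any = OR of the chunk's
  interaction bits; orphan contacts are attributed to the side chain) so
  every generated chunk satisfies the fingerprint invariants.
* **Correlated ("crystal-like") mode.** With correlation ρ, each noise
  draw is replaced by a per-compound shared draw with probability ρ,
  keeping marginal rates unchanged. At ρ = 1 every conformation repeats
  the same errors and ensemble averaging recovers nothing — the
  statistical signature of an ensemble with restricted conformational
  diversity.

Defaults: 550 actives, 601 inactives, 2526 decoys and 20 conformations
(the data shape of the motivating retrospective screen); 24 binding-site
residues (216 bits, the size of a GPCR binding-pocket neighbourhood);
3 signal bits, by analogy with the classic three-point aminergic
pharmacophore (ionic anchor, hydrogen bond, aromatic stack); flip
probability 0.3, background 0.05, pose-failure 0.1, ρ = 0. This operating
point was chosen so that small ensembles sit visibly below the noiseless
ceiling while averaging has room to help — the regime the protocol is
designed to study; the ensemble benefit and the correlated-noise penalty
are not knife-edge properties of this point (they held at every
neighbouring setting examined during design). Tests and the acceptance
script run at reduced compound counts (≈100 per class), which keeps the
full experiment under a minute per replicate.

What the generator does **not** model: real docking-score landscapes,
chemistry-dependent pose correlations between similar compounds,
class-imbalanced decoy property distributions, or any geometric coupling
between residues. Passing results therefore demonstrate that the pipeline
measures the ensemble-averaging mechanism correctly, not that any
particular receptor system will show an effect of a given magnitude.

`make_toy_complex` places atoms at textbook interaction geometries
(2.9 Å donor–acceptor, 4.0 Å hydrophobic pair, 3.8 Å ring stack, 3.8 Å
salt bridge) with residues spaced 20 Å apart, so each planted class fires
exactly the intended bits under the default cutoffs; the expected chunk
for any plan is available programmatically (`expected_bits`).

## Curation details

* Activity thresholds are strict inequalities: Ki values of exactly 100 or
  1000 nM are excluded. IC50 is halved before thresholding.
* Duplicate measurements merge by geometric mean of Ki — the natural mean
  on the log-affinity scale.
* The cluster count is ⌊0.3 n⌋ (minimum 1). Clustering is hierarchical
  average-linkage on Tanimoto distance of hashed 2D fingerprints — an open
  equivalent of the proprietary tool used in the original protocol — with
  centroids defined as minimal-mean-distance members, ties lexicographic.
* Decoy selection is a simplified DUD-style filter (MW ± 25 Da,
  logP ± 1.0, HBD/HBA ± 1, rotatable bonds ± 2 of any active; 2D Tanimoto
  < 0.6 to every active) followed by seeded uniform down-sampling; it is
  not a full DUD re-implementation.

## Numerical and degenerate-input conventions

* libsvm KKT tolerance 1e-6; dual feasibility re-checked post-hoc at 1e-6.
* Predictions at exactly zero decision value go to the positive class.
* Empty contact sets produce all-zero chunks, never errors; empty
  compound/pose inputs, single-class training sets, mismatched ensembles
  and non-finite features raise immediately.
* PDB altloc resolution: highest occupancy, ties to 'A'; insertion codes
  are rejected rather than silently reordered.
* All stochastic components (generator, folds, decoy sampling) take
  explicit integer seeds; identical seeds give bit-identical outputs.

## Known limitations

* Interaction classes beyond the nine (halogen bonds, water-mediated
  contacts, cation–π) are out of scope, as are per-atom fingerprints.
* Receptor atom typing assumes standard residue topology; nonstandard
  residues get backbone-only typing.
* The MOL2 reader accepts what RDKit parses; exotic atom-type dialects may
  need conversion upstream.
* The sweep's prefix semantics cannot discover a better non-prefix subset
  of conformations; that search is combinatorial and out of scope.
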