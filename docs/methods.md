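# Methods

This note documents the models and procedures implemented in `csmol`, the
parameters that matter, the design decisions taken where the design was
genuinely open, and what the synthetic fixtures do and do not demonstrate.

## Conformational-space similarity labels

**Ensemble schemes.** Each molecule gets two conformer ensembles. The
*global* scheme keeps conformers with strain energy (energy minus the
ensemble minimum, kcal/mol) up to 1.4806 kcal/mol per rotatable bond and
clusters at 1.0 Å heavy-atom RMSD; the *near-native* scheme uses 0.5060
kcal/mol per rotatable bond and 2.0 Å. The two per-bond constants derive
from a strain-energy survey of protein-bound ligand conformations (the
first quartile and the upper 95% confidence bound of the mean,
respectively) and are treated as fixed parameters here. For rigid molecules
the threshold uses `max(n_rotatable_bonds, 1)` so the rule never collapses
to "keep only the minimum". Rotatable bonds are single, non-ring bonds
between two non-terminal heavy atoms with amide C–N excluded.

**Backend.** Conformer generation is a contract: any callable producing
(coordinates, energy) works. The built-in backend embeds one conformer per
derived seed with ETKDGv3 and minimizes with MMFF94 (a shared seed would
reproduce the same starting geometry for every slot and collapse the
search — this is why embedding is per-conformer). The search budget
(default 50 embeddings) plays the role of a maximum step count in a
conformational search. All randomness is explicit: a seed is part of every
generation call.

**Filtering order.** Strain filtering precedes clustering. Clustering is
energy-ascending leader clustering: conformers are visited from the lowest
energy up, and each either joins an existing representative within the RMSD
cutoff or becomes a new representative. Representatives are therefore the
lowest-energy members of their clusters and are pairwise separated beyond
the cutoff. RMSD is heavy-atom Kabsch superposition without
graph-automorphism symmetry correction — a known limitation for highly
symmetric molecules, where the reported RMSD can overestimate the true
minimum.

**Conformer-pair scorer.** The proprietary 3D aligner the descriptor scheme
was originally built around is replaced by a pluggable interface; any map
from ordered conformer pairs to [0, 1] is admissible. The built-in scorer is
`shape × coverage`:

- *shape* = 1 / (1 + mean |Δm|) over 12 rotation/translation-invariant
  distance moments (mean, standard deviation, cube-root third central
  moment of atom distances to 4 reference points: centroid,
  closest-to-centroid, farthest-from-centroid, farthest-from-that),
  in the spirit of ultrafast shape recognition;
- *coverage* = the fraction of the **reference** conformer's pharmacophore
  feature types (donor, acceptor, aromatic, hydrophobe, cation, anion;
  SMARTS definitions shipped as an editable YAML file) also present in the
  query. Normalizing by the reference makes the score directional, mimicking
  query-onto-reference superposition; a featureless reference scores
  coverage 1.

**Descriptor algebra.** Raw descriptors per direction are the score-matrix
max/min per scheme. Per direction: `MaxSim` = max of the four raw values,
`MaxDistance` = min, `MaxOverlap` = their mean, `MaxAggregation` = mean of
the two scheme maxima. `CrossX` averages the two directions and is exactly
swap-invariant. "Maximum of all similarities" is read per-direction (the
cross-direction average is what the Cross family contributes; maximizing
over directions first would make it redundant). The label table column
order is fixed and versioned.

## Dataset construction

Pairs are stratified in the (MCS similarity, MaxSim) plane. *Analogous*:
both coordinates at or above their thresholds (default 0.6). The
*dense*/*sparse* boundary — an elliptical bulk in the plane — is modeled by
a 2D Gaussian fitted to a calibration sample with the Mahalanobis radius
set at the 30th percentile, so roughly 30% of calibration pairs are dense.
Sampling draws pairs until the 0.30 : 0.65 : 0.05 composition is met,
emits every pair in both orders, and records the achieved composition in a
manifest (best effort when a region is unreachable). Positive enrichment
extracts pairs with MaxSim above threshold outside the analogous region;
a stricter preset (MaxSim ≥ 0.75, non-analogous) is available as a named
filter.

Scaffold splits assign whole Murcko scaffolds: a seed-shuffled greedy fill
to the 7:3 target followed by single-move/swap polishing, because scaffold
granularity can be coarse and plain greedy fill can overshoot by a whole
family. One tenth of the training molecules (again whole scaffolds) becomes
validation. Pair partitions derive from member molecules: both on the
training side → train/validation, exactly one → cross, none → test.
SMILES randomization re-emits a molecule under a random atom order with
probability 0.9 (augmentation for sequence-based consumers; identity is
preserved under re-canonicalization).

## Encoder, heads, and training

**Featurization.** Nodes: one-hot atom type over {C, N, O, S, P, F, Cl,
Br, I, B, Si, Se} with an explicit unknown slot, hybridization, formal
charge, chiral tag, plus in-ring and aromatic flags (30 dims). Edges: bond
type one-hot (5 dims).

**Encoder.** Each of `n_layers` rounds sends, along every directed bond,
`LeakyReLU(W_m [h_neighbor ; e_bond])`, sums incoming messages, and updates
`h ← LeakyReLU(W_s h + messages)`. Readout is a per-node two-layer MLP
followed by the arithmetic mean over nodes, so encodings are invariant to
atom numbering by construction. Reference configuration: 4 layers,
2048-dim nodes; the desk-scale preset (used everywhere in the tests and
the acceptance run) is 2 layers, 64 dims.

**Projection heads.** One head per target descriptor ({MaxSim, MaxDistance,
MaxOverlap, MaxAggregation, CrossSim, CrossDistance, CrossOverlap,
CrossAggregation, MCS} by default). A head consumes the ordered
concatenation of two encodings: expand to 5× the concatenated width →
batch normalization → condense (1024 at reference scale, 256 at desk
scale) → shrinking linear cascade (1024→512→256→128 reference,
256→128→64 desk) → one sigmoid unit, LeakyReLU between all linear layers.
The 5× expansion applies to the concatenated input, since that is what the
head consumes. An ablation flag replaces the rectifier with a direct
reduction to 256 → batch norm → LeakyReLU → 1. Weights are
Kaiming-uniform; batch norm uses running statistics at inference.

**Training.** Weighted MSE summed over heads (uniform head and sample
weights by default; an optional positive-emphasis scheme up-weights pairs
with MaxSim > 0.6). AdamW at lr 1e-4 with batch 512 at reference scale;
linear warmup from 0.1×lr over 30 000 steps, then a periodic cosine
oscillating between 0.5×lr and lr with a 10 000-step period (oscillation
between bounds, not restart-at-peak — the other convention is config).
Validation (mean Spearman across enabled heads) every 500 steps; early
stopping after 50 validations without improvement; the best-validation
parameters are what training returns. A max-steps cap is added so short
runs terminate. Desk-scale preset: lr 1e-3, batch 128, warmup 200, period
500, validate every 100, patience 10, cap 2000 steps — chosen to make a
single-CPU run complete in minutes while leaving the schedule's structure
(warmup fraction, period, patience-to-validation ratio) intact.

The neural stack runs on a small in-package reverse-mode autodiff core
(`csmol._autograd`): float64 NumPy tensors, segment operations for graph
aggregation, batch normalization differentiated through the batch
statistics, and AdamW with decoupled weight decay. Gradients are verified
against numerical differentiation in development.

## Evaluation

**Similarity metrics.** Cosine and Pearson over encodings, with explicit
errors for degenerate inputs (zero or constant vectors). Screening scores
each library molecule as the max over references of the chosen metric (a
trained head can serve as the metric), ranks by descending score with ties
broken by stable molecule-id order (recorded — early-recognition metrics
are rank-sensitive), and reports BEDROC, AUROC, and EF.

**BEDROC** follows Truchon–Bayly: the robust initial enhancement normalized
by its analytic extremes, so the best possible ranking scores exactly 1 and
the worst exactly 0; α defaults to 160.9, weighting roughly the top 1%.
EF at fraction f is the active rate in the top ⌈fN⌉ over the base rate.

**Target identification** scores each target by its best-matching ligand
and treats each target as one observation for AUROC/BEDROC. The benchmark
curation filter chain keeps query ligands with > 300 activity entries and
≥ 12 heavy atoms, drops links weaker than 10 µM (all affinities normalized
to nM internally), drops library ligands with MCS similarity > 0.5 to the
query (so no trivially similar structure remains), and marks queries that
still cover > 70 targets as the refined subset; stage counts go into a
manifest.

**Property decoder.** Mirrors the projection head with single-molecule
input. Classification optimizes (BCE + MSE)/2 on sigmoid outputs and
validates with AUPRC when positives:negatives exceeds 3 or falls below 1/3
(strict inequalities; the boundary goes to AUROC), AUROC otherwise;
regression optimizes MSE and validates with Spearman. Size presets scale
lr/batch/epochs with dataset size (threshold 5000 rows by default). Only
this decoder supports fine-tuning the encoder.

## Synthetic fixtures — what they show and what they do not

The fixture grammar combines 12 drug-like ring systems with 20 substituents
(one or two attachment points), giving several hundred valid unique
molecules across ~11 Murcko scaffolds, all ≤ ~30 heavy atoms. The
acceptance experiments use a 500-molecule world.

Surrogate labels replace the minutes-per-pair 3D pipeline for
training-recovery experiments: a fixed random projection of path-based
fingerprints, squashed through tanh, scored by cosine and mapped to [0, 1].
The projection seed is an internal constant, so the noise-free kernel is
identical across user seeds; only the bounded label noise (±0.02) varies.
Raw directional values are constructed from the kernel so every ordering
constraint holds, and the advanced columns are computed with the real
descriptor algebra — the tables satisfy the descriptor invariants exactly.

The planted screening benchmark draws references from the largest scaffold
family and labels as actives the pool molecules nearest the references
under the same fingerprint-derived kernel that generates the labels. A
perfect label model therefore scores BEDROC 1 by construction, and the
zero-shot screening check measures how much of the label geometry the
trained encoder actually recovered. At α = 160.9 on a ~500-molecule
library, the random-ranking BEDROC null has a standard deviation near 0.1,
so clearing the 5σ bar requires genuinely strong early recognition
(BEDROC ≳ 0.55).

Desk-scale problem sizes used by the tests and the acceptance script:
500-molecule world, 2000 surrogate-label pairs, 64-dim/2-layer encoder
trained 2000 steps (batch 128, MaxSim head), 40 planted actives with 4
references, 10 000 sampled pairs for composition, 20-molecule ensembles at
budget 20, 10 self-pairs through the full 3D pipeline.

Passing these tests shows the machinery is correct and that the training
loop recovers a smooth structure-derived similarity signal at small scale.
It does not show that descriptors from the built-in scorer match any
proprietary aligner's values, nor how the encoder performs on real
screening decks — fixture molecules are small, the chemistry space is
narrow, and the planted signal is by construction recoverable.

## Numerical choices and degenerate inputs

- Multi-fragment SMILES are rejected (salt stripping is upstream), single
  heavy atoms make MCS similarity undefined (explicit error), conformers
  with < 3 atoms make shape moments undefined (explicit error).
- MCS search is exact up to a configurable timeout (default 10 s); on
  timeout the best substructure found is returned and flagged
  (`exhausted=False`). Atom matching is element-agnostic; bond matching
  ignores order but respects ring membership (both configurable).
- Zero-conformer ensembles, empty graphs, missing label columns, unknown
  fingerprints/metrics, and non-finite training losses raise immediately
  with context rather than propagating NaNs.
- All stochastic entry points take explicit seeds; derived seeds stay below
  2³¹.

## Known limitations

- The built-in conformer-pair scorer is a coarse stand-in for a true
  superposition-based aligner; its absolute values are not comparable to
  published alignment scores, only its contract (directional, [0, 1],
  identity = 1) is.
- MMFF94 energies are a generic force field; strain thresholds calibrated
  for another energy model are applied unchanged.
- RMSD ignores graph automorphisms, over-separating symmetric molecules.
- The desk-scale encoder (64 dims) is far below the reference
  configuration (2048 dims); results at desk scale demonstrate mechanism,
  not capacity.
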