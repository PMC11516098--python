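# csmol

Conformational-space similarity (CSS) descriptors, contrastive graph
encoders, and ligand-based virtual screening for small drug-like molecules.

## The problem

Two molecules can look alike on paper yet occupy very different regions of
3D shape/pharmacophore space — and vice versa: scaffold hopping lives in the
gap between 2D and 3D similarity. Single-conformer 3D comparison underrates
flexible molecules, whose bound conformation is rarely the minimum-energy
one. `csmol` works with the whole *conformational space* of each molecule
instead:

1. **CSS labels.** For a molecule pair (A, B), conformer ensembles are
   generated under two regimes — a *global* ensemble (strain threshold
   1.4806 kcal/mol per rotatable bond, 1 Å RMSD clustering) and a
   *near-native* ensemble (0.5060 kcal/mol per rotatable bond, 2 Å) — and
   every query conformer is scored against every reference conformer with a
   directional shape/pharmacophore scorer. The score matrices reduce to raw
   descriptors (`Global_MAX/MIN`, `Near_MAX/MIN` per direction) and to the
   advanced family:

   - `MaxSim` = max of the four raw values (per direction),
     `MaxDistance` = min,
   - `MaxOverlap` = (`MaxSim` + `MaxDistance`) / 2,
   - `MaxAggregation` = (`Global_MAX` + `Near_MAX`) / 2,
   - `CrossX` = (X(A→B) + X(B→A)) / 2 — symmetric under pair swap.

   2D structural overlap is measured by element-agnostic
   maximum-common-substructure similarity,
   `sim = N_bonds(MCS) / min(N_bonds(A), N_bonds(B))`.

2. **Contrastive encoder.** A Weisfeiler–Lehman-style message-passing
   network encodes each molecule independently; projection heads regress
   the CSS/MCS descriptors from ordered pairs of encodings (weighted MSE,
   AdamW, linear warmup from 0.1×lr, periodic cosine between 0.5×lr and lr,
   early stopping on validation Spearman). Training pairs are stratified in
   the (MCS, MaxSim) plane into dense/sparse/analogous regions sampled at
   0.30 : 0.65 : 0.05, and molecules are split by Murcko scaffold (7:3 with
   a 1/10 validation carve-out) so no scaffold leaks between train and test.

3. **Zero-shot applications.** The encodings support similarity search with
   cosine or Pearson metrics (or any trained head): virtual screening
   against reference actives (BEDROC with α = 160.9 ≈ EF1%, AUROC, EF),
   ligand-based target identification, benchmark curation filters, and a
   property decoder (QSAR/ADMET) with rule-based loss/metric selection and
   optional encoder fine-tuning.

Everything runs on synthetic fixtures generated in-process; no external
datasets are required.

## Worked example

```python
from csmol import parse_molecule, label_pairs

ibuprofen_like = parse_molecule("CC(C)Cc1ccc(C(C)C(=O)O)cc1", "A")
analog = parse_molecule("CC(C)Cc1ccc(CC(=O)O)cc1", "B")
table = label_pairs([ibuprofen_like, analog], [("A", "B")],
                    conformer_budget=20, seed=0)
print(table[["MaxSim", "MaxDistance", "MaxOverlap", "CrossSim", "MCS"]]
      .round(3).to_string(index=False))
```

prints

```
 MaxSim  MaxDistance  MaxOverlap  CrossSim  MCS
   0.88        0.669       0.775      0.88  1.0
```

`MCS = 1.0` says the smaller analog is entirely contained in the larger
molecule's 2D graph (element-agnostic matching); `MaxSim = 0.88` says their
best conformer pairing is highly similar in shape and pharmacophore types,
while `MaxDistance = 0.669` bounds how dissimilar the worst pairing across
the two conformational spaces gets. `MaxOverlap` is their midpoint, and
`CrossSim` averages the two directions.

The same pipeline is scriptable from the shell:

```bash
csmol mcs --a "CCO" --b "CCC"            # 1.000000 (mcs_bonds=2)
csmol fixtures --preset library --n 100 --seed 1 --out fx/
csmol conformers --in fx/library.smi --scheme global --out ens.sdf --seed 1
csmol train --data labels.csv --out model.ckpt --seed 1
csmol encode --model model.ckpt --in fx/library.smi --out enc.csv
```

## Layout

| Module | Contents |
| --- | --- |
| `csmol.chem_graph` | SMILES parsing, graph featurization, Murcko scaffolds, element-agnostic MCS |
| `csmol.conf_ensemble` | conformer generation (ETKDG + MMFF94), strain filtering, RMSD leader clustering, SDF I/O |
| `csmol.css_labels` | directional conformer-pair scorer, raw → advanced descriptor reduction, pair labeling |
| `csmol.pair_dataset` | dense/sparse/analogous stratification, pair sampling, scaffold splits, SMILES randomization |
| `csmol.encoder_model` | WLN encoder, rectifier projection heads, checkpoints |
| `csmol.training` | weighted-MSE contrastive loop, warmup + cosine schedule, early stopping |
| `csmol.similarity_eval` | cosine/Pearson similarity, BEDROC/AUROC/EF, screening, target ID, benchmark curation, fingerprint baselines |
| `csmol.prop_decoder` | property decoder with loss/metric selection rules and encoder fine-tuning |
| `csmol.fixtures` | deterministic synthetic libraries, surrogate labels, planted benchmarks |

See `docs/methods.md` for the underlying models, parameter choices, and
known limitations.
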