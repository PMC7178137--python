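# ppisite

Prediction of protein–protein interaction sites (interface residues) from
complex structures and evolutionary-conservation features, with explicit
treatment of the class-imbalance and class-overlap problems that dominate
this task.

Interface residues are a small minority of a protein's surface. A
classifier trained naively on all surface residues learns to answer
"non-interface" almost always — high accuracy, near-zero sensitivity.
`ppisite` implements two undersampling strategies that re-balance the
training data by *removing the right negatives*, not random ones, and
evaluates the resulting gradient-boosted classifier under a 10-fold
cross-validation protocol.

## What it computes

**Geometric labeling.** Residue accessibility is computed with the
Shrake–Rupley method (probe 1.4 Å, 960 sphere points, isolated-chain
state). A residue with relative accessible surface area
RASA = ASA / maxASA(residue type) strictly above 16 % is a *surface*
residue; a surface residue within 1.2 nm (Cα–Cα by default, or minimum
carbon–carbon) of the partner chain is an *interface* residue.

**Feature encoding.** Each residue carries a 24-dimensional conservation
descriptor (20 profile frequencies + entropy, relative entropy, sequence
weight, conservation score). A surface residue is encoded by concatenating
its own descriptor with those of its 10 nearest surface neighbours
(spatial, same chain), giving 11 × 24 = 264 features.

**Re-balancing.**

- *RENN* (repeated edited nearest neighbours): iteratively delete every
  removable sample whose 3 nearest neighbours hold a majority of the
  opposite label, until a sweep deletes nothing.
- *IHT* (instance hardness threshold): score every sample by
  IH(x_i, y_i) = 1 − p(y_i | x_i, h), the complement of the probability a
  logistic-regression estimator h assigns (out-of-fold) to the sample's own
  label, then delete the hardest majority-class samples until the classes
  are 1:1.

**Classification.** An XGBoost ensemble, ŷ_i = Σ_k f_k(x_i) trained
against Obj = Σ_i l(y_i, ŷ_i) + Σ_k Ω(f_k), evaluated by 10-fold CV with
six measures: Acc, Sen, Pre, Spe, F-measure, and MCC.

## Worked example

```sh
# a synthetic two-chain complex with three known contacts
cat > spec.json <<'EOF'
{"n_residues": [8, 8], "contact_pairs": [[0, 0], [3, 4], [5, 2]]}
EOF
ppisite synth structure --spec spec.json -o complex.pdb
ppisite label --pdb complex.pdb --chain-pair A,B --cutoff-nm 1.2 \
    --rasa-threshold 0.16 --mode ca_ca -o sites.tsv
```

prints

```
16 residues: 16 surface, 6 interface -> sites.tsv
```

All 16 residues of this sparse synthetic complex are solvent-exposed
(surface), and the three requested contact pairs produce exactly three
interface residues on each chain. Downstream:

```sh
ppisite featurize --sites sites.tsv --features cons.tsv -o samples.tsv
ppisite balance --method iht --in samples.tsv --out balanced.tsv --report report.json
ppisite evaluate --in samples.tsv --cv 10 --mode strict --balance iht -o metrics.json
```

`metrics.json` holds the per-fold and pooled confusion matrices and the six
measures at full precision and 3-decimal rounding. As a library-level
illustration of the six-measure arithmetic:

```python
>>> from ppisite import ConfusionMatrix, compute_metrics
>>> compute_metrics(ConfusionMatrix(tp=1864, tn=1844, fp=454, fn=432)).as_dict(3)
{'acc': 0.807, 'sen': 0.812, 'pre': 0.804, 'spe': 0.802,
 'f_measure': 0.808, 'mcc': 0.614, 'flags': []}
```

i.e. a classifier with that confusion matrix identifies 81.2 % of true
interface residues (Sen) while keeping 80.2 % of non-interface residues
correct (Spe); the MCC of 0.614 summarises the correlation between
predicted and actual labels.

## Reconstructing a real dataset (recipe, not executed here)

The reference corpus this pipeline is designed for is built from a set of
170 transient heterocomplexes: remove antibody–antigen pairs and chains
under 50 residues, keep the chain of each pair with more interface
residues, and drop chains with ≥ 30 % sequence identity (BLASTCLUST),
leaving 91 chains with 10,455 surface residues (2,297 interface / 8,158
non-interface). Reproducing it requires PDB structures plus HSSP- and
ConSurf-derived conservation tables, none of which ship with this package;
every test and the acceptance script instead run on the synthetic module's
generators.

## Layout

- `src/ppisite/structures.py` — PDB parsing, ASA/RASA, surface + interface labels
- `src/ppisite/features.py` — feature tables, spatial windows, sample matrices
- `src/ppisite/resampling.py` — RENN and IHT (from scratch)
- `src/ppisite/classifier.py` — boosted trees, CV plans and protocols
- `src/ppisite/evaluation.py` — confusion matrices and the six measures
- `src/ppisite/synthetic.py` — structure and sample-cloud generators
- `docs/methods.md` — models, assumptions, parameter choices, limitations
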