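# pairprop

Atom-pair property descriptors for small molecules, a frequency-matched
pseudo-distance between them, and a classification stack built on top:
Gaussian kernels over an adaptive bandwidth grid, precomputed-kernel SVMs
with exhaustive (γ, C) model selection, and genetic-algorithm optimization
of the descriptor's feature weights with bagged out-of-bag fitness.

## What it computes

Every ordered pair of heavy atoms in a molecule yields a 19-feature row:

| columns | content |
|---|---|
| 1–8 | atom type of the first atom: period, main-group family, counts of single/double/triple/aromatic bonds, ring flag, shifted pKa |
| 9–16 | the same eight features for the second atom |
| 17 | common-ring flag for the pair |
| 18 | bond count of the shortest path |
| 19 | cis/trans flag (−1 / 0 / 1) from 2D geometry |

Identical rows are grouped with a frequency column (column 20, never a
feature). The distance between two molecules greedily matches each grouped
row of one molecule against the nearest remaining rows of the other,
consuming frequencies, then aggregates directed distances as
`sqrt(d_AB² + d_BA²)`. The 19 per-column weights are tied to 11 free
parameters (the same atom-type weights apply to both atoms); the shipped
defaults are the initial-weight configuration.

pKa values come from a pluggable provider (CSV `mol_id,atom_index,pka`,
0-based atom indices); atoms without an entry get feature value 0 after the
−7.0 shift. No pKa prediction is bundled. Transition-metal molecules and
multi-fragment inputs are rejected. Chirality is out of scope.

## CLI

```bash
# descriptors (TSV, one `#mol <id> <n_pairs>` header per molecule)
pairprop describe --in mols.sdf --out desc.tsv
pairprop describe --in mols.smi --format smiles --pka pka.csv --out desc.tsv

# all-pairs pseudo-distance matrix
pairprop distance --in desc.tsv --weights w.json --out dmat.tsv

# precomputed-kernel SVM over the (gamma, C) grid
pairprop train --dmat dmat.tsv --labels labels.tsv --out model.json

# train on one set, score another
pairprop predict --train train.smi --test test.smi --format smiles \
    --labels labels.tsv --out pred.json

# GA weight optimization (bagged OOB-accuracy fitness)
pairprop optimize --in train.smi --format smiles --labels labels.tsv \
    --config ga.json --seed 1 --out weights.json

# repeated 90/10 protocol on a built-in synthetic set
pairprop benchmark --rule ring-presence --n 40 --repeats 20 --seed 1
```

Labels are two-column TSV `mol_id<TAB>{0,1}`. Weight files are JSON mapping
the 11 weight names (`period`, `family`, `single_bonds`, `double_bonds`,
`triple_bonds`, `aromatic_bonds`, `atom_ring_flag`, `pka`, `pair_ring_flag`,
`path_bonds`, `cis_trans`) to non-negative reals.

## Library sketch

```python
import pairprop as pp

graphs = [pp.from_smiles(s, name) for name, s in [("pyr", "c1ccncc1"), ("eth", "CC")]]
descs = [pp.build_descriptor(g) for g in graphs]
d = pp.pseudo_distance(descs[0], descs[1], pp.WeightVector())

labeled = pp.synthetic_labeled_set(40, "ring-presence", seed=1)
result = pp.run_protocol(labeled, pp.SplitPlan(repeats=20, seed=1))
print(result.mean_auc)
```

GA defaults are the full-scale settings (population 32, 20 generations,
1000 bags); pass a smaller `GaConfig` for desk-scale runs.

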