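# dtafusion

Drug–target binding affinity (DTA) prediction that fuses **protein 3D
surface geometry and electrostatics** with the usual sequence and graph
representations through **cross multi-head attention**.

Most deep DTA models read only a SMILES string and an amino-acid sequence.
`dtafusion` additionally encodes, per protein, a compact physicochemical
vector — GRAVY hydrophobicity, molecular weight, isoelectric point, a total
electrostatic potential scalar (consumed from an external Poisson–Boltzmann
run, e.g. APBS), and a **mean surface curvature** estimated from the
structure by Delaunay tetrahedralization — and, per drug, a 16-dimensional
descriptor vector (logP, TPSA, complexity, H-bond donors/acceptors, heavy
atoms, total charge, and nine atom counts C/H/N/O/F/S/Cl/Br/I). A cross
multi-head attention block fuses each entity's descriptor vector with its
structural representation (GCN node features for drugs, transformer
sequence features for proteins); four 128-dim branch vectors are
concatenated into a 512-dim vector and passed through a 2048→768→1 fully
connected head that outputs the affinity (pKd for Davis-style data, KIBA
score for KIBA-style data).

## The curvature estimate

Given the protein's atom cloud P (all heavy atoms, or the Cα trace), the
cloud is partitioned into tetrahedra by Delaunay tetrahedralization. For a
tetrahedron with vertices p₁..p₄ (canonical ascending-index order) and edge
lengths a=|p₁−p₂|, b=|p₁−p₃|, c=|p₁−p₄|, d=|p₂−p₃|, e=|p₂−p₄|, f=|p₃−p₄|:

    V = adf + bef + cde − ae² − bd² − cf²
    R = [a²(e²+f²−d²) + b²(d²+f²−e²) + c²(d²+e²−f²)] / (16V)
    k = 1/|R|            (tetrahedra with V = 0 are skipped as invalid)
    k̄ = Σ kᵢ / N_valid

k̄ (units 1/Å) enters the protein descriptor vector. Every stage is exposed
(`tetra_quantity_V`, `circum_radius`, `mean_curvature`) and checked against
an independent loop-based oracle in the tests.

## Worked example

```python
import numpy as np
from dtafusion import (SynthSpec, gen_dataset, build_pair_dataset,
                       make_splits)
from dtafusion.presets import desk_config, desk_train_config
from dtafusion.training import train_evaluate

corpus = gen_dataset(SynthSpec(seed=101))       # 30 drugs x 25 proteins
cfg = desk_config(seed=101)                     # reduced single-CPU preset
dataset = build_pair_dataset(corpus, cfg)
split = make_splits(dataset.pairs, seed=101)    # 5:1 train/test + 5 folds
net, history, report = train_evaluate(cfg, dataset, split,
                                      desk_train_config(seed=101))
print(len(dataset.pairs), round(report.r2, 3), round(report.ci, 3),
      round(report.mse, 3))
```

prints (one ~600-pair corpus with a planted linear signal, noise sd 0.1):

```
599 0.989 0.973 0.029
```

i.e. the trained network recovers ~99% of the label variance of the
planted signal and ranks held-out pairs with concordance index 0.97; the
test MSE 0.029 approaches the 0.01 noise floor.

There is also a scikit-learn-style estimator:

```python
from dtafusion import DTARegressor
reg = DTARegressor(embed_dim=16, ffn_mult=2, max_protein_len=128,
                   dtype="float32", max_epochs=20, seed=0)
reg.fit(list(zip(drug_records, protein_records)), y)
y_hat = reg.predict(list(zip(drug_records, protein_records)))
```

and a CLI:

```bash
dtafusion gen-synth --spec spec.yaml --out data/
dtafusion featurize-protein --pdb 1abc.pdb --level all --sign abs
dtafusion train --config cfg.yaml --data data/ --out run/
dtafusion evaluate --checkpoint run/checkpoint.npz --data data/
dtafusion predict --checkpoint run/checkpoint.npz \
    --smiles-file candidates.tsv --protein target.fasta --pdb target.pdb
```

`predict` with a SMILES list emits affinity-sorted scores (ranking mode,
as used for repurposing screens).

Benchmark corpora in the public Davis/KIBA layout are read with
`load_davis` (Kd→pKd transform) and `load_kiba` (scores unchanged, optional
long-protein removal); the synthetic generator emits the same layout, so
the loaders are exercised without downloads.

A note on the cross-attention Q/K/V assignment: the source description of
this architecture assigns Q to the physicochemical matrix with K = V the
structural features in its methods text, but its Q/K/V-swap experiment
table reports the best results for a different assignment (drugs:
Q = K = graph features, V = physicochemical; proteins: Q = sequence
features, K = V = physicochemical). Both are implemented behind
`qkv_mode={"methods_text","table6_best"}`; neither is guessed to be the
intended one, and `methods_text` is the default.

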