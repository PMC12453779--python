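# Methods

## Model

`dtafusion` predicts a continuous drug–target affinity from four fused
representations per (drug, protein) pair:

1. **Drug sequence branch.** The SMILES string is tokenized character-wise
   against a frozen 62-symbol vocabulary (pad id 0, a trailing unk id),
   truncated/right-padded to length k (default 100), embedded to t dims and
   summed with a sinusoidal positional encoding indexed from position 1:
   PE(i,2j) = sin(i/10000^(2j/t)), PE(i,2j+1) = cos(i/10000^(2j/t)). The
   embedded sequence passes through the **CP-Encoder** (below); masked mean
   pooling over real tokens and a linear map give a 128-dim branch vector.
2. **Drug fusion branch.** RDKit parses the SMILES into a molecular graph
   (node order = parsed atom order; initial atom features: one-hot element
   over C/H/N/O/F/S/Cl/Br/I, degree, aromaticity flag; 11 dims). Two GCN
   layers H⁽ˡ⁺¹⁾ = ReLU(D̃^{-1/2}ÃD̃^{-1/2}H⁽ˡ⁾W⁽ˡ⁾) (Ã = A + I) with a
   residual projection of the input, out = proj(X) + GCN₂(GCN₁(X)), give
   node features. The drug's 16-dim physicochemical vector is projected to
   one t-dim token and fused with the node features by cross multi-head
   attention (4 heads), pooled, and mapped to 128 dims.
3. **Protein sequence branch.** As (1) with the 25-letter amino-acid
   vocabulary (every letter except J: the 20 standard residues, U, O and
   the ambiguity codes B/Z/X) and maximum length e (default 1000).
4. **Protein fusion branch.** The 5-dim protein physicochemical vector
   (GRAVY, molecular weight, isoelectric point, total electrostatic
   potential, mean surface curvature) is projected to one token and fused
   with the encoder output by cross multi-head attention, pooled, mapped to
   128 dims.

The four 128-dim vectors are concatenated (4 x 128 = 512) and passed
through FC(2048, ReLU) → FC(768, ReLU) → linear(1).

### CP-Encoder topology

Three pre-norm transformer encoder layers arranged as: h = E₁(X) + X (the
embedded input re-added residually), then two parallel encoders with
independent parameters whose outputs, passed through linear output
projections, are summed into the stream: out = h + P₂(E₂(h)) + P₃(E₃(h)).
The output projections make the parallel branches strictly additive:
zeroing P₂ and P₃ reduces the module to the first-encoder path plus the
input residual, which is the structural contract the tests check. With
`use_cp_encoder=False` a single plain encoder layer is used instead.
Padding positions are excluded from attention by an additive −10⁹ key mask;
for an all-pad input the uniform softmax over equally masked keys keeps the
output finite. No dropout is used: runs are bit-deterministic given (seed,
config, input), which we value more at this scale than the regularization.

### Cross-attention Q/K/V assignment

Two assignments are implemented (`qkv_mode`):

* `methods_text` (default): Q = the physicochemical token; K = V = the
  structural features (graph nodes / sequence positions). The single query
  attends over an unordered set, so the drug fusion output is invariant
  under atom permutation (tested).
* `table6_best`: drugs Q = K = graph features with V = the physicochemical
  token; proteins Q = sequence features with K = V = the physicochemical
  token. Attention requires one value row per key, so on the drug side the
  single physicochemical token is tiled across keys; the value content is
  then uniform and the branch reduces to the physicochemical projection
  passed through the output/pooling maps. We implement the assignment as
  stated rather than reinterpret it.

### Ablation switches

Each flag removes exactly its component and strictly reduces the parameter
count at the default width: `use_drug_pc`/`use_protein_pc` replace the
fusion branch by a pooled structural/sequence branch; `use_mcat` replaces
cross attention by direct concatenation + linear; `use_gnn` routes the drug
fusion branch over the sequence-encoder features instead of graph features;
`use_cp_encoder` swaps the three-encoder module for one encoder layer;
`use_curvature`/`use_potential` drop that slot from the protein descriptor
(5 → 4 dims).

## Geometry: mean surface curvature

The point cloud is every heavy atom of the first model of a PDB file
(HETATM and hydrogens excluded), or one point per residue (Cα) —
both readings of "the protein's points" are supported since the level is
genuinely ambiguous; `all_atoms` is the default. scipy's Qhull-based
Delaunay tetrahedralization partitions the cloud; degenerate (coplanar)
input raises rather than being silently jittered, with an opt-in seeded
joggle for users who want it.

For each tetrahedron the six edge lengths (a..f) are taken in the fixed
vertex-pair order a=|p₁−p₂| … f=|p₃−p₄|. The validity quantity
V = adf + bef + cde − ae² − bd² − cf² is **not symmetric under vertex
relabeling**, and Qhull's simplex vertex order is arbitrary, so the
pipeline canonicalizes p₁..p₄ to ascending input-index order; this
tie-break makes k̄ exactly invariant under rigid motions (indices do not
move) and is applied identically in the test oracles. |V| below
10⁻¹²·(mean edge)³ counts as zero — the skip rule needs a scale-aware
tolerance in floating point. The circumradius formula
R = [a²(e²+f²−d²)+b²(d²+f²−e²)+c²(d²+e²−f²)]/(16V) is used exactly as
defined; note it is a formulary definition, not the geometric circumsphere
radius (for the right-corner tetrahedron with legs 2, 3, 5 the geometric
circumradius is 3.08 while the formula gives |R| = 1.043). The Delaunay
empty-circumsphere property itself is verified in tests with the true
geometric circumcenter. R may be negative; curvature is taken as 1/|R| by
default (curvature as reciprocal of an unsigned radius), with a raw-signed
mode for exactness experiments. If every tetrahedron has V = 0 (e.g. a
single regular tetrahedron) the result is an explicit error, never a silent
zero. k̄ scales as 1/s under coordinate scaling s and is invariant under
rotations and translations; both laws are tested at 10⁻⁹ relative.

## Physicochemical descriptors

Drug vectors are ordered (logP, TPSA, complexity, HBD, HBA, heavy atoms,
total charge, counts of C,H,N,O,F,S,Cl,Br,I). The seven tabulated
descriptors come from a local CSV; **missing values become exactly 0** and
present values stay raw. Atom counts are always derived from the SMILES,
with implicit hydrogens included in the H slot (formula-style counting).
The field order itself is a package convention — any fixed order works,
determinism is what matters. Protein vectors use the Kyte–Doolittle scale
for GRAVY (letters without a scale entry are skipped), average residue
masses for molecular weight (ambiguity codes without a defined mass
contribute nothing), and Biopython's Henderson–Hasselbalch bisection for
pI. The electrostatic potential is an opaque scalar consumed from an
external Poisson–Boltzmann computation; it is never computed here, and a
missing value becomes 0, mirroring the drug rule.

## Data handling

Kd values (nM) are transformed as pKd = −log10(Kd/10⁹); KIBA scores pass
through unchanged. The KIBA long-protein filter (`max_protein_len`) is off
by default since the removal threshold used in practice is unstated; when
set, removed proteins and their pairs are logged. Splitting shuffles pairs
under a seed, holds out 1/6 as test, and partitions the rest into five
folds; the split unit is the pair.

## Training

Adam (lr 0.001, β = 0.9/0.999), MSE loss, batch size 32, up to 400 epochs
by default; the rotating validation fold selects the best-MSE parameters,
and an optional patience-based early stop is available. Internally the
estimator standardizes descriptor inputs by training-set statistics before
the projection layers — molecular weights (~10⁴ Da) would otherwise
dominate early optimization; descriptor matrices written to disk remain
raw. Divergence (non-finite loss) aborts with a diagnostic rather than
continuing.

The network and optimizer run on a small NumPy reverse-mode autodiff
engine (`dtafusion.nn`): tensors record their producing operations and a
topological backward pass accumulates gradients, with scaled-dot-product
attention implemented as a single fused tape node (the softmax weights
buffer is reused in the analytic backward). Gradients are verified against
central finite differences in the tests. Forward passes are
bit-reproducible given (seed, config, input).

## Synthetic data

The generator emulates the study's input modalities without downloads:
sequences uniform over the 25-letter alphabet, lengths 50–300; atom clouds
of three jittered points per residue on an idealized helix (radius 2.3 Å,
rise 1.5 Å, 100°/residue — non-coplanar by construction); SMILES from a
closed valence-safe fragment grammar over C/N/O/S chains, branches,
halogen terminals and one optional ring; descriptor surrogates computed
with RDKit with 10% of fields knocked out to exercise the missing→0 rule;
potentials standard-normal. Labels are planted as a linear function of
standardized selected descriptors (drug logP/TPSA/heavy-atoms, protein
GRAVY/potential/curvature; weights 0.8, −0.6, 0.5, 0.7, 0.6, −0.5) plus
Gaussian noise (sd 0.1 by default), giving ≈0.99 as the achievable R²
ceiling. Corpora are fully determined by their `SynthSpec` and are written
in the benchmark directory layout so the Davis/KIBA loaders are exercised
end to end.

What passing on this data does and does not show: the synthetic labels are
linear in observable descriptors, so learnability demonstrates that the
fusion pathways transmit and recover descriptor signal through training —
it does not demonstrate chemical realism, nonlinear binding physics, or
benchmark-level generalization, which require the real corpora and
full-scale training.

## Problem sizes and presets

`published_config` keeps the full-scale architecture constants (t = u =
128, 4 heads, FC 2048/768, k = 100, e = 1000). Synthetic-data experiments
use `desk_config` — identical topology with embedding width 16,
feed-forward multiplier 2, protein truncation at 128 tokens and float32
parameters — and `desk_train_config` (20 epochs, patience 4): sizes chosen
so one train/evaluate cycle on a ~600-pair corpus takes well under a
minute on a single CPU while leaving the planted-signal recovery margin
large (test R² ≈ 0.98 against the 0.5 acceptance bar). Training on the
real Davis/KIBA benchmarks at published scale is out of scope here: it
requires downloading the corpora and GPU-scale resources.

## Known limitations

* The curvature formulas are used as defined; they are not the geometric
  circumradius, and the V = 0 rule excludes highly symmetric tetrahedra.
* The `table6_best` drug assignment is degenerate by construction (uniform
  value content); it exists for completeness of the reported comparison.
* No dropout/weight decay; regularization at desk scale comes from early
  stopping on the validation fold.
* mmCIF structures, cold-start splits, label binarization and baseline
  model reimplementations are out of scope.
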