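# hlagcn

Structure-aware prediction of HLA–peptide binding affinity with a
graph-convolutional network, plus gradient-weighted attribution of the
prediction to individual residues and atoms.

HLA (human leukocyte antigen) molecules present short peptides to T cells;
how strongly an HLA binds a peptide (measured as IC50, nM) governs antigen
presentation and is central to vaccine and immunotherapy design. `hlagcn`
represents the two molecules at their natural resolutions — the HLA as a
residue-level graph built from its 3D structure, the peptide as an
atom-level molecular graph built from its sequence — and regresses the
log50k-transformed affinity

    y = 1 − log(IC50 nM) / log(50000)   ∈ [0, 1],

where the conventional 500 nM binder cutoff corresponds to y ≈ 0.426.
Each branch is a stack of graph convolutions
H⁽ˡ⁺¹⁾ = ReLU(D̂^−1/2 (A+I) D̂^−1/2 H⁽ˡ⁾ W⁽ˡ⁺¹⁾); the pooled branch
embeddings are concatenated into a three-layer MLP trained on mean squared
error. Predictions are explained with Grad-WAM: channel weights
w_c = Σᵢ αᵢc·ReLU(∂P/∂Tᵢc) over the last convolution's activations T give
per-node scores sᵢ = ReLU(Σ_c w_c Tᵢc), written out as CSV and as B-factor
coloring in a PDB. An occlusion oracle cross-checks the attributions, and a
substitution-scanning module scores wild-type vs mutant 9-mers across an
HLA panel with a paired t-test.

Who this is for: computational immunologists prototyping structure-based
binding predictors, and anyone who needs the full pipeline — PDB in, typed
residue interaction graph, SMILES-derived peptide graph, trained regressor,
per-residue attribution — in plain, dependency-light scientific Python.

## Worked example

Everything below runs from synthetic data generated by the package itself
(a toy helical "HLA" and a 200-peptide dataset whose affinity follows a
planted rule: 0.3 + 0.4 if peptide position 2 carries an aromatic residue,
plus noise):

```python
from hlagcn import GCNConfig, train, predict, classify_binder, gradwam_scores
from hlagcn.planted import fixture_dataset, heldout_pearson
from hlagcn.gradwam import residue_attribution

data = fixture_dataset(seed=0)                       # 200 training pairs
model = train(data.train_set, GCNConfig(seed=0))     # ~30 s on one CPU

print(f"final training MSE: {model.training_history[-1]:.4f}")
print(f"held-out Pearson r: {heldout_pearson(model, data):.3f}")

hla, pep, y = data.train_set[0]
score = predict(model, hla, pep)
print(f"peptide {data.train_records[0].peptide_seq}: "
      f"predicted score {score:.3f} ({classify_binder(score)}), measured {y:.3f}")

attr = gradwam_scores(model, hla, pep, "pep")
per_res = residue_attribution(attr, pep)
top = sorted(per_res, key=per_res.get, reverse=True)[:3]
print(f"Grad-WAM top-3 peptide positions: {top} (planted anchor: {data.rule.anchor_position})")
```

Output:

```
final training MSE: 0.0208
held-out Pearson r: 0.181
peptide WMLQEARAD: predicted score 0.353 (nonbinder), measured 0.318
Grad-WAM top-3 peptide positions: [1, 2, 3] (planted anchor: 2)
```

Reading the numbers: training converges (MSE 0.021 against a target
variance of ~0.02 + noise² = 0.0025), and the attribution places the
planted causal position (2) in its top-3 — it does so in 20 of 20 seeded
runs in the test suite. The held-out correlation is honest and low: 200
samples are too few for the network to learn the *positional* part of the
rule rather than amino-acid composition, a measured sample-complexity limit
discussed in `docs/methods.md`. The peptide here scores near the 0.3 base
rate because its position 2 (M) is not aromatic.

The same pipeline is scriptable from the shell:

```bash
hlagcn simulate --seed 7 --out sim/                      # PDB + TSV + FASTA + truth
hlagcn train --data sim/train.tsv --out model.npz
hlagcn predict --model model.npz --pdb sim/hla.pdb --peptide ASAYKWLQV
hlagcn explain --model model.npz --pdb sim/hla.pdb --peptide ASAYKWLQV \
               --branch hla --out-csv attr.csv --out-pdb colored.pdb
hlagcn evaluate --data sim/train.tsv --folds 10 --out report.json
hlagcn mutscan --model model.npz --panel-dir panel/ \
               --protein-fasta prot.fasta --subs subs.tsv --out scan.csv
```

Real data goes in through the same doors: PDB structures (optionally with an
external 8-state secondary-structure TSV), peptide FASTA, and a training TSV
of `hla_id, structure_path, peptide_seq, ic50_nM`.

## Layout

| module | contents |
|---|---|
| `hlagcn.structure_io` | PDB read/write, 8-state secondary structure (external or geometric fallback) |
| `hlagcn.hla_graph` | 43-dim residue features, peptide/H-bond/ionic/disulfide edge detectors, graph JSON |
| `hlagcn.peptide_graph` | sequence → SMILES → 22-dim atom graph (RDKit), FASTA input |
| `hlagcn.gcn_model` | IC50 transform, GCN + MLP model, Adam training, checkpoints |
| `hlagcn.gradwam` | Grad-WAM attribution, occlusion oracle, B-factor annotation |
| `hlagcn.evaluation` | Acc/Sn/Sp/MCC, ROC-AUC, k-fold cross-validation |
| `hlagcn.synthetic_fixtures` | helix generator, planted-rule affinity datasets |
| `hlagcn.planted` | recovery experiments on the planted rule |
| `hlagcn.mutation_scan` | 9-mer substitution windows, panel scan, paired t-test |
| `hlagcn.cli` | `hlagcn` command with the subcommands shown above |

`docs/methods.md` documents the model, all defaults and their rationale,
and the limits of what the synthetic validation shows.
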