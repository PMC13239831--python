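# neurofcn

Classification of brain disorders from resting-state functional connectivity,
using **multiple connection patterns** estimated from the same ROI time
series, a **multi-branch graph convolutional network**, and **node-level
Grad-CAM** to explain which regions drive the prediction.

## The problem

A resting-state fMRI session yields, per subject, a matrix of ROI time series
X ∈ R^{t×n} (t time points, n atlas regions; 232 × 116 under the AAL
parcellation). A functional connectivity network (FCN) summarizes the
statistical dependence between regional signals as a weighted graph over the
ROIs — but "dependence" is not one thing. This package estimates three
complementary patterns per subject:

- **PC (Pearson correlation)** — full correlation,
  w_ij = ⟨x_i − x̄_i, x_j − x̄_j⟩ / (‖x_i − x̄_i‖·‖x_j − x̄_j‖):
  synchronous co-fluctuation.
- **SR (sparse representation)** — each ROI's series is reconstructed from all
  others under an L1 penalty,
  min_W Σ_i ‖x_i − Σ_{j≠i} W_ij x_j‖² + λ Σ_{j≠i} |W_ij|:
  conditional, partial-correlation-like dependence (default λ = 1).
- **GCM (Granger causality mapping)** — for each ordered pair,
  G_{x→y} = ln(RSS_restricted / RSS_unrestricted) comparing an autoregression
  of y on its own lags with one augmented by lags of x; symmetrized as
  A_ij = |G_{i→j} + G_{j→i}|: directed, lagged influence.

Each estimate is canonicalized (symmetrize, absolute value, zero diagonal,
rescale to unit maximum, threshold at 0.1/0.2/0.2 for PC/SR/GCM) into a
non-negative weighted adjacency A. Node features are the rows of A (each
node's connectivity profile).

Each pattern graph feeds its own spectral GCN branch using the first-order
propagation rule H^{l+1} = σ(D̂^{−1/2}(A+I)D̂^{−1/2} H^l W^l) with two
32-unit layers, pooled by a mean‖max readout into a 64-vector. Branch
embeddings are concatenated (192-dim for three patterns) and classified by a
three-layer fully connected head [64·branches, 32, 16, 2] with dropout 0.5,
trained with Adam (lr 0.0025, weight decay 1e-5, cross-entropy, 150 epochs)
and validation-accuracy checkpointing. Grad-CAM on each branch's final
convolution layer gives per-ROI importance:
α_k = (1/n) Σ_i ∂y_c/∂H_{ik}, then S_i = ReLU(Σ_k α_k H_{ik}), normalized
per subject.

Because clinical rs-fMRI cohorts are access-restricted, the package ships a
synthetic cohort simulator (stationary VAR(1) with group-specific
contemporaneous covariance and directed lag coupling) so the entire pipeline
is testable end-to-end; see `docs/methods.md` for what the simulator does and
does not emulate.

## Worked example

```python
import numpy as np
import neurofcn as nf
from neurofcn.training import TrainConfig, cohort_graphs, train_model
from neurofcn.interpret import gradcam_node_importance, importance_report

cohort = nf.simulate_cohort(nf.default_config(seed=7))   # 20 ROIs, 30/group
graphs = cohort_graphs(cohort)                           # PC, SR, GCM per subject
model, summary = train_model(graphs, cohort.labels, ("PC", "SR", "GCM"),
                             TrainConfig(seed=7))
m = summary.runs[0]
print(f"test accuracy {m.accuracy:.3f}  precision {m.precision:.3f}  "
      f"recall {m.recall:.3f}  f1 {m.f1:.3f}  auc {m.auc:.3f}")

per_pattern = {p: [] for p in model.patterns}
for i in np.flatnonzero(cohort.labels == 1):
    maps = gradcam_node_importance(model, graphs[i], target_class=1)
    for p, imp in maps.items():
        per_pattern[p].append(imp)
report = importance_report(per_pattern, k=5)
print(report["top_k"]["GCM"].to_string(index=False))
```

Output:

```
test accuracy 1.000  precision 1.000  recall 1.000  f1 1.000  auc 1.000
roi_label  roi_index  mean_score  rank
   ROI006          6    0.870886     1
   ROI005          5    0.867631     2
   ROI007          7    0.651245     3
   ROI004          4    0.624211     4
   ROI015         15    0.086408     5
```

The simulated case group carries a directed lag chain over ROIs 4–7; the GCM
branch's Grad-CAM map ranks exactly those four regions on top, while the PC
and SR branches (not shown) instead highlight the ROIs that differ in
contemporaneous coupling — the patterns are discriminative for different,
complementary reasons.

## Command line

```bash
neurofcn run      --seed 1 --out runs/demo            # simulate → … → explain
neurofcn ablate   --seed 1 --out runs/demo            # all 7 pattern subsets
neurofcn cv       --seed 1 --out runs/demo --k 5
neurofcn sweep    --seed 1 --out runs/demo --param threshold --pattern gcm \
                  --grid 0.1,0.2,0.5,1.0
neurofcn validate runs/demo/cohort
```

Every command takes `--seed`, `--config` (strict-validated YAML), `--out` and
`--log-level`; a run directory contains the resolved config, a manifest with
config hash and timings, metrics as JSON, and tables as TSV.

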