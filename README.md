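# cpifuse

Compound–protein binding-affinity prediction with a nested cross-attention
network, plus the benchmark machinery around it: cold-split protocols,
similarity filtering, regression and virtual-screening metrics, and a
synthetic interaction generator that makes the whole pipeline testable
without external downloads.

**Who it is for.**  Computational chemists and ML-for-drug-discovery
researchers who want a transparent, dependency-light reference
implementation of attention-based compound–protein interaction (CPI)
regression — the model, the split protocols that actually decide whether a
reported number means anything (novel-compound / novel-protein /
novel-pair), and the screening metrics (EF, BEDROC) — all in plain
numpy/rdkit, runnable and testable on a laptop CPU.

## The model

A compound *s* is encoded twice: as a Morgan/ECFP4 fingerprint M_s passed
through an MLP (output O_Ms), and as a directed-bond molecular graph passed
through a directed message-passing network (output O_Gs) in which hidden
states live on directed bonds,

    h⁰_vw = ReLU(W_in·[x_v, e_vw]),
    m_vw^{t+1} = Σ_{k∈N(v)\{w}} mean(x̃_v, x̃_k, h^t_kv),
    h^{t+1}_vw = ReLU(h⁰_vw + W_m·m^{t+1}_vw),

so messages never immediately backtrack along the reverse bond.  A protein
*t* is tokenized over a fixed 26-symbol vocabulary, zero-padded to length
500, and encoded by residual gated-convolution blocks
(emb_out = LN(Conv1D(emb_in) + λ·emb_in); emb_in = GLU(emb_out)), giving a
position × channel matrix Prot_t.

The two compound views are fused by cross-attention — queries from O_Ms,
keys/values from O_Gs, energies softmax(QKᵀ/√(C/d)) — refined by a stack of
latent self-attention blocks, and a final cross-attention block maps the
compound latents (queries) onto the protein positions (keys/values); the
pooled interaction vector feeds a small regression head that predicts the
affinity (pKd = −log10(Kd/1e9), Kd in nM).  Training minimizes a
density-weighted MSE (e.g. the Davis rule: weight 0.5 on targets in [0, 5],
5 outside) with the LAMB optimizer (per-layer trust ratio
r = ‖w‖/‖u + wd·w‖).  See `docs/methods.md` for the full account, including
the two stability choices (pre-projection layer norm, query-stream
residual) that keep the attention softmax from saturating.

The tensor/autodiff core, all layers and LAMB are implemented in-package on
float64 numpy; gradients are verified against finite differences in the
test suite.

## Worked example

```python
from cpifuse import generate_synthetic, train, mse, concordance_index
from cpifuse.model import AffinityModel, ModelConfig
from cpifuse.training import TrainConfig

ds = generate_synthetic(n_compounds=20, n_proteins=10, density=0.5,
                        noise_sd=0.3, seed=7, length_range=(40, 80))
model = AffinityModel(ModelConfig(fp_bits=512, fp_sizes=(128, 32),
                                  mpnn_hidden=32, max_len=100,
                                  prot_channels=16, prot_emb_dim=16,
                                  embed_dim=16, latent_blocks=1,
                                  head_hidden=16, seed=0))
history = train(model, ds, TrainConfig(epochs=30, batch_size=16,
                                       learning_rate=0.01, weight_decay=0.01,
                                       validation_fraction=0.2, patience=0,
                                       seed=0))
print(history.best_val_loss)
```

Running `python examples/03_train_and_evaluate.py` (which is exactly this
setup plus scoring) prints:

    epochs run: 30; best validation loss 0.036 at epoch 5
    all-records MSE 0.077, CI 0.816

i.e. after a 30-epoch demonstration fit the held-out loss is well below the
label variance (≈0.24 for this draw, noise variance 0.09) and the model
orders pairs far better than chance (CI 0.5 = random, 1.0 = perfect).  The other
`examples/` scripts demonstrate featurization, dataset statistics, the
cold-split protocols and the screening metrics, each printing a few
annotated numbers.

## Command line

    cpifuse simulate --compounds 20 --proteins 10 --density 0.5 --seed 7 --out data.csv
    cpifuse split --data data.csv --protocol novel_pair --seed 1 --out-dir splits/
    cpifuse train --data data.csv --epochs 50 --weight-rule none --seed 0 --out-dir run/
    cpifuse predict --data data.csv --checkpoint run/model.npz --out pred.csv
    cpifuse evaluate --predictions pred.csv
    cpifuse stats --data data.csv
    cpifuse check-split --data data.csv --assignments splits/fold0.assignments.csv --protocol novel_pair

Every command honors `--seed`, writes a JSON run manifest, and uses exit
codes 0/2/3/4 for success / usage / data / numeric errors.

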