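# scvib

Probabilistic contrastive integration of single-cell multi-omics data.

`scvib` aligns cells measured by different assays (scRNA-seq, scATAC-seq,
histone-mark profiling, ...) and in different batches, studies or species
into one shared latent space.  It addresses the three standard regimes of
multi-omics integration:

* **horizontal** — datasets share gene-centric features but contain
  different cells (batches, studies, species with homologous genes);
* **vertical** — jointly-profiled cells, where one cell carries two
  modality measurements that anchor the alignment;
* **mosaic** — a mixture of both, integrated dataset-by-dataset with
  weights inherited between stages.

It is written for computational biologists who need a desk-scale,
fully-inspectable implementation of this model family: every component is
plain numpy/scipy behind a small tape-based autodiff engine, every metric
has a brute-force oracle in the test suite, and a seeded synthetic
generator with complete ground truth makes every training mode testable
end-to-end without downloading data.

## The model

Each modality *m* owns a linear **translator** into a shared gene-centric
space (the 2000 highly-variable genes of the RNA data by default):

```
h_ng = x_nf W^(m)_fg ⊙ M_fg + b_g        (phase 1: biologically masked)
h_ng = x_nf A^(m)_fd B^(m)_dg + b_g      (phase 2: low-rank, mask lifted)
```

The binary mask `M` allows only biologically plausible feature-gene links
(e.g. ATAC peaks within ±2000 bp of a gene body); after phase-1 training
the masked weights are factored by truncated SVD (`d = 128`) and updated
freely in phase 2.  A shared 3-hidden-layer MLP **encoder** maps `h` to a
diagonal Gaussian posterior `q(z_nk | h) = N(mu, sigma²)` over the latent
cell state, with a `N(0, I)` prior; a single linear **projector**
conditioned on one-hot covariates lifts sampled latents to `y_np`, p > k.

Training minimizes a variational-information-bottleneck objective

```
L = L_DC + beta * KL(q(z|x) || N(0, I)),      beta = 0.05
```

where `L_DC` is the decoupled contrastive loss: for each cell the positive
pair is its two views — Gaussian-noise-augmented copies scored on the
projector outputs `y` in horizontal mode, the two modality encodings of the
same jointly-profiled cell scored on `z` in vertical mode — and the
normalizer sums `exp(cos/tau)` over the `2(N-1)` view-copies of *other*
cells only (the positive is excluded from the denominator).  Vertical
translators are initialized by ordinary least squares on the paired cells
instead of phase-1 training.

The package also ships the full evaluation suite (entropy mixing score,
cell-type and modality silhouette variants, local annotation enrichment
score, k-NN label transfer, NMI/ARI, weighted rank aggregation) and the
species-program machinery that clusters shared homologous genes from
`B_dg`, reconstructs per-species gene maps `w = A B`, and calls species
genes with z-scores above 2.3263 (p = 0.01, one-sided) linked to at least 5
shared genes of interest.

## Worked example

Vertical integration of synthetic jointly-profiled RNA + ATAC data with a
20% holdout, scoring cross-modal label transfer on the held-out cells:

```python
import numpy as np
from scvib import (
    SimulationConfig, simulate_multiome,
    TrainConfig, preprocess_for_integration, train_vertical, embed,
)
from scvib import evaluation as ev
from scvib.data import EmbeddingTable
import pandas as pd

datasets, truth = simulate_multiome(SimulationConfig(seed=1))
prepped, shared = preprocess_for_integration(datasets, n_hvg=150)
config = TrainConfig(mode="vertical", phase1_epochs=0, phase2_epochs=50,
                     holdout_fraction=0.2, seed=1)
state = train_vertical(prepped, config)
table = embed(prepped, state)

n = datasets[0].n_cells
hold_rna = state.holdout["s0:0:rna"]
hold_atac = state.holdout["s0:1:atac"]
ref = EmbeddingTable(z=table.z[:n], cell_ids=[f"a{i}" for i in range(n)],
                     cell_type_labels=pd.DataFrame({"cell_type": truth.cell_types}))
qry = EmbeddingTable(z=table.z[n:][hold_atac], cell_ids=[f"b{i}" for i in hold_atac],
                     cell_type_labels=pd.DataFrame({"cell_type": truth.cell_types[hold_atac]}))
res = ev.transfer_labels(ref, qry, k=1)
print(f"held-out cross-modal 1-NN accuracy: {res.accuracy:.3f}")
mix = ev.mixing_score(table.subset(np.concatenate([hold_rna, n + hold_atac])),
                      "modality", n_neighbors=50, n_samples=100, reps=20, seed=0)
print(f"held-out modality mixing entropy:  {mix.value:.3f}  (ln 2 = {np.log(2):.3f})")
```

prints

```
held-out cross-modal 1-NN accuracy: 1.000
held-out modality mixing entropy:  0.685  (ln 2 = 0.693)
```

i.e. every held-out ATAC cell lands next to an RNA cell of its true
type, and held-out neighborhoods are within 1% of the two-modality entropy
ceiling — the two assays are statistically interchangeable in the latent
space while the cell types stay separated.

A shell workflow is available through the `scvib` CLI
(`simulate`, `mask`, `preprocess`, `integrate`, `evaluate`, `programs`);
run `scvib --help`.

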