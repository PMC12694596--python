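# Methods

## Model

`scvib` embeds cells from heterogeneous single-cell assays into one latent
space using three trainable components per integration task:

1. **Modality-specific linear translators.** Each modality's native
   features (peaks, genomic bins, genes) are mapped linearly into a shared
   gene-centric space. Two parameterizations are interchanged during
   training: a *masked dense* form `h = x (W ⊙ M) + b`, where the binary
   mask `M` encodes a biological prior (a peak may load only on genes whose
   body, extended by a window, it overlaps), and a *low-rank* form
   `h = x A B + b` obtained by truncated SVD of the masked weights. The
   masked form prevents the translator from exploiting spurious
   feature-gene correlations while alignment is being established; the
   low-rank form then restores flexibility with a controlled number of
   degrees of freedom.
2. **Shared probabilistic encoder.** A fully-connected network with three
   hidden layers maps translated profiles to the mean and log-scale of a
   diagonal Gaussian posterior over the k-dimensional latent state.
   Sampling uses the reparameterization trick, so gradients flow through
   both moments. A standard-normal prior on z turns the KL term into an
   information bottleneck: the encoder may keep only the information worth
   its contrastive payoff.
3. **Shared linear projector (horizontal mode only).** Latent draws are
   concatenated with one-hot batch/species/modality covariates and mapped
   by a single linear layer — no normalization, no activation — into a
   space of dimension p > k. Because the covariates are handed to the
   projector for free, covariate-driven variation is absorbed there and z
   is left to encode cell state.

The objective is `L = L_DC + β·KL`, with the decoupled contrastive loss
`L_DC` defined over two views of every cell. For each view of cell *n* the
positive term is `−cos(v₁, v₂)/τ`; the normalizer sums `exp(cos/τ)` over
both views of the other N−1 minibatch cells — 2(N−1) negatives, with the
positive pair excluded from the denominator. In horizontal integration the
views are two noise-augmented copies evaluated on projector outputs y; in
vertical integration they are the two modality encodings of one
jointly-profiled cell evaluated directly on z.

Assumptions worth stating: translators are linear by design (that is what
makes `W`, `A·B` interpretable for gene-program analysis); the within-batch
negative pool requires minibatches drawn from a single dataset, so batches
to be integrated out must enter as separate datasets; and the method sees
no cell-type labels at any point — labels are used only by the evaluation
suite.

## Training modes

* **Horizontal** (two phases): phase 1 trains masked dense translators —
  the mask is re-applied after every optimizer step, which for a linear
  layer is identical to masking the gradients; phase 2 converts each
  translator by top-d SVD (symmetric square-root split of the singular
  values between A and B, which balances factor norms; the split does not
  affect the product) and trains A, B freely. Conversion at full rank
  reproduces the dense outputs to numerical precision, so training resumes
  continuously.
* **Vertical**: skips phase 1. The translator of the non-gene-space
  modality is initialized by ordinary least squares from its features to
  the paired cells' gene-space profiles, converted to low-rank form, and
  trained with the paired contrastive loss on z plus the KL averaged over
  both views. Cells without a visible pairing pass through the encoder in
  their own minibatches and contribute KL only — this keeps the encoder
  exposed to their input region without asserting any correspondence.
  Unit-Gaussian input augmentation is applied in vertical minibatches as
  well: all inputs are standardized, so the same noise scale is meaningful
  everywhere, and this augmentation is what makes the encoder generalize
  to cell populations that have no pairing anchors.
* **Mosaic**: an ordered list of horizontal/vertical stages. The encoder
  and projector objects carry over between stages (weights are inherited
  exactly); translators are warm-started from the modality registry when
  seen before and created fresh otherwise. The covariate vocabulary is
  frozen in order of first sight, and newly seen categories extend the
  projector input with zero-initialized rows so earlier covariates keep
  their learned effect.

Holdout: a `holdout_fraction` of cells (of joint cells in vertical mode)
is excluded from every gradient step, including the OLS initialization;
the trained/held index sets are recorded on the model state so tests can
assert the discipline directly.

## Parameters

| parameter | default | notes |
|---|---|---|
| β (bottleneck weight) | 0.05 | fixed for all integrations |
| τ (contrastive temperature) | 0.2 | free choice; sharper temperatures (0.1) overfit instance discrimination at desk scale — training cells align perfectly while held-out cells degrade |
| k (latent dim) | 32 | p defaults to k + 16 |
| d (low-rank dim) | 128 | clamped to min(f, g) with a warning |
| encoder hidden sizes | 512·256·128 | LayerNorm + ReLU between hidden layers; linear heads |
| feature dropout | 0.25 | encoder inputs, training mode only |
| log-scale clamp | [−10, 5] | numerical safety before exponentiation |
| optimizer | Adam, lr 3·10⁻³, batch 128 | chosen for the few-thousand-cell regime where 256-cell batches give too few steps per epoch |
| phase epochs | 100 / 200 | horizontal phase 1 / phase 2; vertical runs `phase2_epochs` |
| RNA normalization | CP10K → log1p → z-scale | zero-variance features fall back to scale 1 |
| ATAC | TF-IDF, IDF(p) = log((1+N)/(1+Nₚ)) + 1 | then per-peak z-scaling |
| histone marks | 10 kb midpoint bins → log1p → z-scale | bins encoded as `chrom:start-end` ids |
| HVG | 2000, dispersion = var/mean of CP10K | median rank across RNA datasets; deterministic tie-break by gene order |
| mask window | ±2000 bp around the gene body | strand ignored; gene-body anchoring (not TSS) is a declared choice — the criterion is stated for genes, and the window is configurable where TSS anchoring is wanted |
| program z threshold | 2.3263 (p = 0.01, one-sided) | ≥ 5 linked shared genes; z population = all weights of one species restricted to the shared genes of interest |
| gene clustering | cosine k-NN graph (k=15), Louvain, resolution 1.0 | seeded |

Evaluation conventions: Euclidean distance in z everywhere (cosine lives
only inside the losses); the mixing score samples 100 cells per group, 100
neighbors, 100 repetitions by default and uses Shannon entropy in natural
log (its sign is chosen so that well-mixed neighborhoods score high, as the
verbal definition of the score requires); label transfer is a k-NN majority
vote (k = 15) with ties broken by summed inverse distance; methylation
inputs are accepted as pre-standardized gene-level matrices, since no
methylation-specific preprocessing is defined.

## Synthetic study conditions

The generator draws per-type centroids at the vertices of a regular
simplex, scaled by a single `separation` knob (default 5.0 — calibrated
once so that 1-NN classification is perfect on the true latents and ≥ 0.9
on rendered RNA counts, then frozen), unit-Gaussian within-type spread
tied to `noise_scale`, and renders each modality as a linear read-out plus
batch offsets and observation noise. Count modalities pass through
softplus + Poisson so the count-based preprocessing paths are exercised on
sparse nonnegative data. All modalities observe the same cells, giving
ground-truth joint identities; `paired_fraction` and `blinded_cell_types`
control how much of that truth training may see. An optional planted
species program adds per-feature latent factors tying a block of one
modality's features to a block of shared genes, so program calling can be
validated against a known answer.

Default conditions: 5 cell types × 120 cells, RNA 150 genes + ATAC 300
peaks, 12 true latent dimensions. The spurious-alignment stress test uses
6 types × 400 cells with 3 types blinded — sized so the OLS initialization
is statistically well-posed (paired cells ≈ 4× the ATAC feature count;
under-determined regression extrapolates arbitrarily badly to blinded
populations, which would measure sample-size artifacts rather than the
method). The mosaic schedule uses 4 types × 120 cells over two stages
(2-batch horizontal RNA, then vertical RNA+ATAC). Unit tests run scaled-
down versions of the same conditions (3–4 types, 40–90 features, encoder
32·32·16) so the full suite completes in about a minute.

What the generator does *not* emulate: realistic count overdispersion
beyond Poisson, fragment-level chromatin structure, doublets or ambient
contamination, nonlinear modality relationships, and annotation noise.
Passing tests therefore demonstrate correctness of the machinery and
recovery under the model's own assumptions, not performance on real
atlases.

## Numerical choices

* All computation is float64; the autodiff engine is a minimal vectorized
  tape (matmul, broadcast arithmetic, exp/log/sqrt/tanh/relu/clip,
  reductions, concat) sized exactly to this model family.
* Cosine similarities use an ε = 10⁻¹² guard in the row normalizer.
* The DC loss is reduced to a per-cell-view mean (sum / 2N) by default for
  learning-rate stability; the raw sum is available via
  `LossConfig(reduction="sum")` and is what the closed-form checks use.
* KL is summed over latent dimensions and averaged over cells, matching
  the contrastive reduction scale.
* Minibatches with fewer than 2 cells are dropped (the contrastive
  normalizer is undefined); zero-variance features standardize to exactly
  zero; silhouette-based metrics skip cell types observed in a single
  modality, with a warning.
* SVD conversion clamps d to min(f, g); the regression initializer
  requires at least 2 paired cells and uses the holdout-excluded subset
  only.

## Known limitations

* Desk-scale by construction: dense float64 linear algebra on one CPU.
  Atlas-scale data would need minibatched sparse pipelines and hardware
  acceleration, which are out of scope.
* The blinded-type local mixing (LAES) improves non-monotonically over
  training — instance discrimination first separates near-duplicate views
  before augmentation-driven invariance folds them back together — so
  short schedules can transiently score worse than the untrained baseline
  on that one metric even while label transfer is already accurate.
* Louvain clustering of shared genes depends on the igraph RNG; labels are
  reproducible for a fixed seed but not across igraph versions.
* The translator mask is interval-overlap only; regulatory priors beyond
  proximity (Hi-C contacts, enhancer databases) would enter as externally
  constructed `MaskMatrix` objects.
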