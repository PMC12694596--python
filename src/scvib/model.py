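"""The trainable backbone: translator -> probabilistic encoder -> projector.

Each modality owns a linear *translator* into the shared gene-centric space.
Two parameterizations exist: a ``masked_dense`` form ``h = x (W o M) + b``
whose binary mask M restricts weights to biologically plausible
feature-gene links, and a ``low_rank`` form ``h = x A B + b`` obtained by
truncated SVD of the masked weights, which lifts the mask while keeping the
update space low-dimensional.  A shared 3-hidden-layer MLP *encoder* maps
translated profiles to the mean and log-scale of a diagonal Gaussian
posterior over the k-dimensional latent cell state; a single linear
*projector*, conditioned on one-hot covariates and deliberately free of any
normalization or activation, lifts latent draws into the p > k dimensional
space where the horizontal contrastive loss is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .data import MaskMatrix
from .nn import Dense, LayerNorm, Tensor, concat, dropout

__all__ = [
    "TranslatorParams",
    "EncoderParams",
    "LatentPosterior",
    "ProjectorParams",
    "translate",
    "decompose_translator",
    "encode",
    "sample_latent",
    "project",
    "init_translator_by_regression",
]

DEFAULT_LOW_RANK_DIM = 128
DEFAULT_HIDDEN_SIZES = (512, 256, 128)
DEFAULT_FEATURE_DROPOUT = 0.25
LOG_SCALE_MIN, LOG_SCALE_MAX = -10.0, 5.0


# ---------------------------------------------------------------------------
# translator
# ---------------------------------------------------------------------------


@dataclass
class TranslatorParams:
    """Per-modality translator weights.

    ``form`` is one of ``masked_dense`` (W, mask, b), ``low_rank`` (A, B, b)
    or ``identity`` (the modality's features already are the shared genes).
    """

    form: str
    modality: str = "other"
    W: Optional[Tensor] = None
    mask: Optional[MaskMatrix] = None
    A: Optional[Tensor] = None
    B: Optional[Tensor] = None
    b: Optional[Tensor] = None

    def __post_init__(self):
        if self.form not in ("masked_dense", "low_rank", "identity"):
            raise ValueError(f"unknown translator form {self.form!r}")
        if self.form == "masked_dense":
            if self.W is None or self.b is None:
                raise ValueError("masked_dense form requires W and b")
            if self.mask is not None:
                self.apply_mask()
        if self.form == "low_rank" and (self.A is None or self.B is None or self.b is None):
            raise ValueError("low_rank form requires A, B and b")

    @property
    def mask_array(self) -> Optional[np.ndarray]:
        return None if self.mask is None else self.mask.mask.astype(np.float64)

    def apply_mask(self) -> None:
        """Project W back onto the mask support (run after every optimizer step)."""
        if self.form == "masked_dense" and self.mask is not None:
            self.W.data *= self.mask_array

    def effective_weights(self) -> Optional[np.ndarray]:
        """The realized f x g linear map (W o M, or A B)."""
        if self.form == "masked_dense":
            w = self.W.data
            return w * self.mask_array if self.mask is not None else w.copy()
        if self.form == "low_rank":
            return self.A.data @ self.B.data
        return None

    @property
    def params(self) -> list[Tensor]:
        if self.form == "masked_dense":
            return [self.W, self.b]
        if self.form == "low_rank":
            return [self.A, self.B, self.b]
        return []


def new_masked_dense_translator(
    mask: MaskMatrix, modality: str, rng: np.random.Generator, init_scale: float = 0.01
) -> TranslatorParams:
    """Fresh masked-dense translator with small random weights on the mask support."""
    f, g = mask.mask.shape
    W = Tensor(rng.standard_normal((f, g)) * init_scale, requires_grad=True)
    b = Tensor(np.zeros(g), requires_grad=True)
    return TranslatorParams(form="masked_dense", modality=modality, W=W, mask=mask, b=b)


def translate(x, params: TranslatorParams):
    """Apply a translator: cells x f -> cells x g in the shared gene space.

    Accepts a numpy array (returns an array) or a :class:`~scvib.nn.Tensor`
    (returns a Tensor on the gradient tape).
    """
    as_array = not isinstance(x, Tensor)
    xt = Tensor(x) if as_array else x
    if params.form == "identity":
        out = xt
    elif params.form == "masked_dense":
        f, g = params.W.shape
        if xt.shape[1] != f:
            raise ValueError(f"input has {xt.shape[1]} features, translator expects {f}")
        W = params.W if params.mask is None else params.W * Tensor(params.mask_array)
        out = xt @ W + params.b
    else:  # low_rank
        if xt.shape[1] != params.A.shape[0]:
            raise ValueError(
                f"input has {xt.shape[1]} features, translator expects {params.A.shape[0]}"
            )
        out = (xt @ params.A) @ params.B + params.b
    return out.data if as_array else out


def decompose_translator(params: TranslatorParams, d: int = DEFAULT_LOW_RANK_DIM) -> TranslatorParams:
    """Convert a masked-dense translator to low-rank form by truncated SVD.

    The masked weight matrix ``W o M`` is factored as ``A B`` with
    ``A = U_d sqrt(S_d)`` and ``B = sqrt(S_d) V_d^T`` (the symmetric
    square-root split, which balances the factor norms); the bias carries
    over unchanged.  ``d`` is clamped to min(f, g) with a warning.
    """
    if params.form != "masked_dense":
        raise ValueError("decompose_translator expects a masked_dense translator")
    M = params.effective_weights()
    f, g = M.shape
    if d > min(f, g):
        warnings.warn(f"d={d} exceeds min(f, g)={min(f, g)}; clamping")
        d = min(f, g)
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    root = np.sqrt(s[:d])
    A = U[:, :d] * root
    B = root[:, None] * Vt[:d]
    return TranslatorParams(
        form="low_rank",
        modality=params.modality,
        A=Tensor(A, requires_grad=True),
        B=Tensor(B, requires_grad=True),
        b=Tensor(params.b.data.copy(), requires_grad=True),
    )


# ---------------------------------------------------------------------------
# encoder
# ---------------------------------------------------------------------------


class EncoderParams:
    """Shared probabilistic encoder: g inputs -> (mu, log-scale) in R^{2k}.

    Three hidden layers (default 512-256-128) with layer normalization and
    ReLU between them; the output head is linear.  A `feature_dropout_rate`
    fraction of input features is dropped during training only, acting as an
    additional augmentation of the translated profiles.
    """

    def __init__(
        self,
        n_inputs: int,
        k: int,
        rng: np.random.Generator,
        hidden_sizes: Sequence[int] = DEFAULT_HIDDEN_SIZES,
        feature_dropout_rate: float = DEFAULT_FEATURE_DROPOUT,
    ):
        if len(hidden_sizes) != 3:
            raise ValueError("encoder uses exactly 3 hidden layers")
        if not (0 <= feature_dropout_rate < 1):
            raise ValueError("feature_dropout_rate must be in [0, 1)")
        self.n_inputs = n_inputs
        self.k = k
        self.hidden_sizes = tuple(hidden_sizes)
        self.feature_dropout_rate = feature_dropout_rate
        self.layers: list[Dense] = []
        self.norms: list[LayerNorm] = []
        prev = n_inputs
        for h in hidden_sizes:
            self.layers.append(Dense(prev, h, rng))
            self.norms.append(LayerNorm(h))
            prev = h
        self.head = Dense(prev, 2 * k, rng)

    @property
    def params(self) -> list[Tensor]:
        out: list[Tensor] = []
        for lyr, ln in zip(self.layers, self.norms):
            out += lyr.params + ln.params
        out += self.head.params
        return out


@dataclass
class LatentPosterior:
    """Per-cell diagonal Gaussian posterior in the shared latent space."""

    mu: Tensor
    sigma: Tensor

    def __post_init__(self):
        if not isinstance(self.mu, Tensor):
            self.mu = Tensor(self.mu)
        if not isinstance(self.sigma, Tensor):
            self.sigma = Tensor(self.sigma)
        if self.mu.shape != self.sigma.shape:
            raise ValueError("mu and sigma must have the same shape")
        if not np.all(np.isfinite(self.sigma.data)) or np.any(self.sigma.data <= 0):
            raise ValueError("sigma must be strictly positive and finite")

    @property
    def mean(self) -> np.ndarray:
        return self.mu.data

    @property
    def scale(self) -> np.ndarray:
        return self.sigma.data

    @property
    def n_cells(self) -> int:
        return self.mu.shape[0]

    @property
    def k(self) -> int:
        return self.mu.shape[1]


def encode(
    h,
    params: EncoderParams,
    training: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> LatentPosterior:
    """Run the shared encoder on translated profiles.

    In training mode, feature dropout is applied to the inputs using `rng`
    (required); in eval mode the encoder is a pure deterministic function.
    The log-scale head is clamped to [-10, 5] before exponentiation for
    numerical safety.
    """
    xt = h if isinstance(h, Tensor) else Tensor(h)
    if not np.all(np.isfinite(xt.data)):
        raise ValueError("encoder input contains non-finite values")
    if training:
        if rng is None:
            raise ValueError("training-mode encoding requires an rng for dropout")
        xt = dropout(xt, params.feature_dropout_rate, rng)
    for lyr, ln in zip(params.layers, params.norms):
        xt = ln(lyr(xt)).relu()
    out = params.head(xt)
    k = params.k
    # split the 2k head into mean and log-scale halves (selection matrices
    # keep the gradient tape simple)
    mu = out @ Tensor(np.vstack([np.eye(k), np.zeros((k, k))]))
    log_scale = out @ Tensor(np.vstack([np.zeros((k, k)), np.eye(k)]))
    sigma = log_scale.clip(LOG_SCALE_MIN, LOG_SCALE_MAX).exp()
    return LatentPosterior(mu=mu, sigma=sigma)


def sample_latent(post: LatentPosterior, seed: int | np.random.Generator) -> Tensor:
    """Reparameterized draw z = mu + sigma * eps with eps ~ N(0, I).

    Gradients flow through mu and sigma; the noise is a constant drawn from
    `seed` (an int or a Generator), so fixed seeds give identical draws.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eps = rng.standard_normal(post.mu.shape)
    return post.mu + post.sigma * Tensor(eps)


# ---------------------------------------------------------------------------
# projector
# ---------------------------------------------------------------------------


class ProjectorParams:
    """Single linear map from [z ; one-hot covariates] to R^p, p > k.

    No batch normalization and no activation, by construction: the
    projector's only job is to absorb covariate-driven variation so that
    the latent z can stay biological.
    """

    def __init__(
        self,
        k: int,
        n_covariates: int,
        p: int,
        rng: np.random.Generator,
        vocab: Optional[dict] = None,
    ):
        if p <= k:
            raise ValueError(f"projection dimension p={p} must exceed k={k}")
        self.k = k
        self.n_covariates = n_covariates
        self.p = p
        self.linear = Dense(k + n_covariates, p, rng)
        # vocab: covariate column -> ordered category list (fixed at first sight)
        self.vocab = vocab or {}

    def extend_covariates(self, n_new: int) -> None:
        """Append zero-initialized input rows for newly seen covariate categories."""
        if n_new <= 0:
            return
        W = self.linear.W.data
        self.linear.W = Tensor(
            np.vstack([W, np.zeros((n_new, W.shape[1]))]), requires_grad=True
        )
        self.n_covariates += n_new

    @property
    def params(self) -> list[Tensor]:
        return self.linear.params


def one_hot_covariates(covariates, vocab: dict) -> np.ndarray:
    """Encode a per-cell covariate table against a frozen vocabulary.

    `vocab` maps column name -> ordered category list.  An unseen category
    raises a ValueError naming it.
    """
    import pandas as pd

    df = pd.DataFrame(covariates)
    blocks = []
    for col, cats in vocab.items():
        if col not in df.columns:
            raise ValueError(f"covariate column {col!r} missing")
        index = {c: i for i, c in enumerate(cats)}
        block = np.zeros((len(df), len(cats)))
        for row, val in enumerate(df[col].astype(str)):
            if val not in index:
                raise ValueError(
                    f"unseen covariate category {val!r} in column {col!r}"
                )
            block[row, index[val]] = 1.0
        blocks.append(block)
    if not blocks:
        return np.zeros((len(df), 0))
    return np.concatenate(blocks, axis=1)


def project(z, covariates, params: ProjectorParams):
    """Project latent draws conditioned on covariates: y = P [z ; C].

    `covariates` may be a ready one-hot ndarray, or a per-cell table that is
    encoded against ``params.vocab`` (raising on unseen categories).
    """
    as_array = not isinstance(z, Tensor)
    zt = Tensor(z) if as_array else z
    if isinstance(covariates, np.ndarray) and covariates.dtype != object:
        C = covariates.astype(np.float64)
    else:
        C = one_hot_covariates(covariates, params.vocab)
    if C.shape[1] != params.n_covariates:
        raise ValueError(
            f"covariate one-hot width {C.shape[1]} != projector width {params.n_covariates}"
        )
    y = params.linear(concat([zt, Tensor(C)], axis=1))
    return y.data if as_array else y


# ---------------------------------------------------------------------------
# regression initialization (vertical integration)
# ---------------------------------------------------------------------------


def init_translator_by_regression(
    x_other: np.ndarray, x_target: np.ndarray, modality: str = "other"
) -> TranslatorParams:
    """Initialize a vertical translator by per-feature ordinary least squares.

    Fits ``x_target ~ x_other W + b`` over jointly-profiled (row-aligned)
    cells, minimizing squared error; the fit supplies the starting weights
    for the low-rank vertical translator.
    """
    from sklearn.linear_model import LinearRegression

    x_other = np.asarray(x_other, dtype=np.float64)
    x_target = np.asarray(x_target, dtype=np.float64)
    if x_other.shape[0] != x_target.shape[0]:
        raise ValueError(
            f"paired row counts differ: {x_other.shape[0]} vs {x_target.shape[0]}"
        )
    if x_other.shape[0] < 2:
        raise ValueError("regression initialization needs at least 2 paired cells")
    reg = LinearRegression().fit(x_other, x_target)
    W = np.asarray(reg.coef_, dtype=np.float64).T  # f x g
    b = np.asarray(reg.intercept_, dtype=np.float64).reshape(-1)
    return TranslatorParams(
        form="masked_dense",
        modality=modality,
        W=Tensor(W, requires_grad=True),
        mask=None,
        b=Tensor(b, requires_grad=True),
    )
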