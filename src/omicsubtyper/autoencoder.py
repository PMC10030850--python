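"""Under-complete autoencoder integration of the multi-omics stack.

The encoder compresses the stacked matrix to a low-dimensional latent
representation through ReLU hidden layers; training minimizes mean-squared
reconstruction error with Adam, mini-batches, and early stopping on a
held-out validation split. A PCA baseline on standardized features is
provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .nn import MLP
from .types import LatentMatrix, MultiOmicsStack


@dataclass
class AEArchitecture:
    """Symmetric encoder/decoder; the decoder mirrors ``encoder_widths``."""

    encoder_widths: list[int] = field(default_factory=lambda: [2000, 1000, 500])
    latent_width: int = 100

    def __post_init__(self) -> None:
        if any(w < 1 for w in self.encoder_widths) or self.latent_width < 1:
            raise ValueError("all widths must be >= 1")

    def full_widths(self, input_width: int) -> list[int]:
        if self.latent_width >= input_width:
            raise ValueError(
                f"latent width {self.latent_width} must be smaller than "
                f"input width {input_width} (under-complete autoencoder)"
            )
        enc = list(self.encoder_widths)
        return [input_width, *enc, self.latent_width, *reversed(enc), input_width]

    @property
    def n_encoder_layers(self) -> int:
        return len(self.encoder_widths) + 1  # hidden layers + bottleneck


@dataclass
class AETrainConfig:
    max_epochs: int = 100
    patience: int = 5
    batch_size: int = 24
    val_fraction: float = 0.10
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must lie in (0, 1)")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")


@dataclass
class TrainedEncoder:
    architecture: AEArchitecture
    model: MLP
    loss_history: list[tuple[float, float]]  # (train, val) per completed epoch
    input_feature_ids: list[str]

    @property
    def final_train_loss(self) -> float:
        return self.loss_history[-1][0]

    @property
    def final_val_loss(self) -> float:
        return self.loss_history[-1][1]


def split_train_val(stack: MultiOmicsStack, val_fraction: float, seed: int):
    """Disjoint, exhaustive row partition; validation size round(n*f), min 1."""
    n = stack.n_samples
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    n_val = max(1, int(round(n * val_fraction)))
    if n_val >= n:
        n_val = n - 1
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return np.sort(perm[n_val:]), np.sort(perm[:n_val])


def epochs_before_stop(val_losses, patience: int) -> int:
    """Number of completed epochs under the early-stopping rule: halt once the
    validation loss shows no strict improvement over the best seen for
    ``patience`` consecutive epochs. Returns len(val_losses) if never halted."""
    best = np.inf
    stall = 0
    for epoch, v in enumerate(val_losses, start=1):
        if v < best:
            best = v
            stall = 0
        else:
            stall += 1
            if stall >= patience:
                return epoch
    return len(val_losses)


def train_autoencoder(
    stack: MultiOmicsStack, arch: AEArchitecture, cfg: AETrainConfig
) -> TrainedEncoder:
    """Train to reconstruct the stack; early-stop when validation MSE shows no
    strict improvement over the best seen for ``patience`` consecutive epochs.
    Best-epoch weights are restored."""
    x = stack.values
    if np.isnan(x).any():
        raise ValueError("stack contains missing values")
    widths = arch.full_widths(x.shape[1])
    train_idx, val_idx = split_train_val(stack, cfg.val_fraction, cfg.seed)
    x_train, x_val = x[train_idx], x[val_idx]

    rng = np.random.default_rng(cfg.seed)
    model = MLP(widths=widths, output="linear")
    model.initialize(rng)

    history: list[tuple[float, float]] = []
    best_val = np.inf
    best_weights = model.get_weights()
    stall = 0
    for epoch in range(cfg.max_epochs):
        try:
            model.train_epoch(x_train, x_train, cfg.batch_size, cfg.learning_rate, rng)
        except FloatingPointError as exc:
            raise FloatingPointError(f"non-finite loss at epoch {epoch + 1}") from exc
        train_loss = model.evaluate(x_train, x_train)
        val_loss = model.evaluate(x_val, x_val)
        if not (np.isfinite(train_loss) and np.isfinite(val_loss)):
            raise FloatingPointError(f"non-finite loss at epoch {epoch + 1}")
        history.append((train_loss, val_loss))
        if val_loss < best_val:
            best_val = val_loss
            best_weights = model.get_weights()
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break
    model.set_weights(best_weights)
    return TrainedEncoder(
        architecture=arch,
        model=model,
        loss_history=history,
        input_feature_ids=list(stack.feature_ids),
    )


def select_architecture(candidates):
    """Pick the candidate with the smallest |final train loss - final val loss|.

    ``candidates`` is a list of (AEArchitecture, loss_history) pairs where each
    history is a non-empty list of (train, val) tuples. Ties go to the first
    listed candidate.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    best_arch, best_gap = None, np.inf
    for arch, history in candidates:
        if not history:
            raise ValueError("candidate has an empty loss history")
        train, val = history[-1]
        gap = abs(train - val)
        if gap < best_gap:
            best_arch, best_gap = arch, gap
    return best_arch


def encode(enc: TrainedEncoder, stack: MultiOmicsStack) -> LatentMatrix:
    """Bottleneck activations for every sample in the stack."""
    if list(stack.feature_ids) != list(enc.input_feature_ids):
        missing = set(enc.input_feature_ids) - set(stack.feature_ids)
        extra = set(stack.feature_ids) - set(enc.input_feature_ids)
        raise ValueError(
            "stack columns do not match the trained encoder's inputs: "
            f"missing={sorted(missing)[:5]}, unexpected={sorted(extra)[:5]}"
        )
    z = enc.model.hidden(stack.values, enc.architecture.n_encoder_layers)
    return LatentMatrix(sample_ids=list(stack.sample_ids), values=z)


def pca_reduce(stack: MultiOmicsStack, n_components: int) -> LatentMatrix:
    """Top principal-component scores of the per-feature standardized stack.

    Zero-variance features are treated as all-zero after standardization.
    """
    x = stack.values
    n, p = x.shape
    if n_components > min(n - 1, p):
        raise ValueError(f"n_components must be <= min(n-1, p) = {min(n - 1, p)}")
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    safe = np.where(sd == 0, 1.0, sd)
    z = (x - mu) / safe
    z[:, sd == 0] = 0.0
    scores = PCA(n_components=n_components, svd_solver="full").fit_transform(z)
    return LatentMatrix(sample_ids=list(stack.sample_ids), values=scores)
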