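"""Self-supervised per-volume training and full-grid inference.

One model is trained per target volume: the network regresses the noisy target
intensity from each voxel's descriptor under a mean-squared-error loss,

    L = (1/|Ω|) Σ_p (I_noisy(p) − g_θ(f(p)))²,

using the noisy image itself as supervision.  Because the band-limited encoding
cannot express frequencies past its cutoff and the prior patches carry noise
that is independent of the target's, the fit converges to the correlated signal
component rather than the noise.

Training details: Adam (β₁ = 0.9, β₂ = 0.999), initial learning rate 4e-4
annealed to zero by a cosine schedule over the total number of steps, 20
epochs, seed-shuffled full passes over all voxels in mini-batches of 4096.
Intensities are normalised per volume by the 99th percentile before training
and the denoised output is rescaled back to the original units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .descriptor import PriorStack, build_descriptor_matrix, descriptor_length
from .encoding import EncodingConfig
from .model import MLPModel
from .volume import GridSpec, Volume3D

__all__ = ["TrainingConfig", "DenoiseResult", "compute_loss", "fit",
           "denoise_volume", "denoise_series"]


@dataclass(frozen=True)
class TrainingConfig:
    """Optimisation and normalisation settings for one per-volume fit."""

    learning_rate: float = 4e-4
    epochs: int = 20
    batch_voxels: int = 4096
    seed: int = 0
    cosine_schedule: bool = True
    normalization_percentile: float = 99.0
    hidden_dim: int = 1024
    depth: int = 4
    patch_size: int = 3

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_voxels < 1:
            raise ValueError("batch_voxels must be >= 1")
        if not (0.0 < self.normalization_percentile <= 100.0):
            raise ValueError("normalization_percentile must be in (0, 100]")


@dataclass
class DenoiseResult:
    """Outcome of one per-volume fit."""

    denoised: Volume3D
    final_loss: float
    epochs_run: int
    config_echo: TrainingConfig
    target_scale: float = 1.0
    prior_scales: list[float] = field(default_factory=list)
    epoch_losses: list[float] = field(default_factory=list)


class _Adam:
    """Adam optimiser over a list of parameter arrays (in-place updates)."""

    def __init__(self, params, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads, lr):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g = g.astype(p.dtype, copy=False)
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def compute_loss(model: MLPModel, target: Volume3D, descriptors: np.ndarray,
                 indices: np.ndarray) -> float:
    """Mean squared residual between target intensities and model predictions.

    ``indices`` is an (n, 3) array of voxel indices selecting the supervision
    values from ``target``; ``descriptors`` the matching (n, D) batch.
    """
    descriptors = np.asarray(descriptors)
    indices = np.asarray(indices)
    if descriptors.ndim != 2 or descriptors.shape[0] == 0:
        raise ValueError("descriptor batch must be non-empty and 2-D")
    if indices.shape != (descriptors.shape[0], 3):
        raise ValueError("indices must be (n, 3) matching the descriptor batch")
    y = target.data[indices[:, 0], indices[:, 1], indices[:, 2]]
    pred = model.forward(descriptors).astype(np.float64)
    return float(np.mean((y - pred) ** 2))


def _percentile_scale(data: np.ndarray, q: float) -> float:
    s = float(np.percentile(np.abs(data), q))
    return s if s > 0 else 1.0


def _learning_rate(cfg: TrainingConfig, step: int, total_steps: int) -> float:
    if not cfg.cosine_schedule or total_steps <= 0:
        return cfg.learning_rate
    return cfg.learning_rate * 0.5 * (1.0 + math.cos(math.pi * step / total_steps))


def _mean_loss_full(model, X, y, batch):
    total = 0.0
    n = X.shape[0]
    for lo in range(0, n, batch):
        pred = model.forward(X[lo:lo + batch]).astype(np.float64)
        r = pred - y[lo:lo + batch]
        total += float(r @ r)
    return total / n


def fit(
    target: Volume3D,
    priors: PriorStack,
    enc_cfg: EncodingConfig | None = None,
    train_cfg: TrainingConfig | None = None,
) -> tuple[MLPModel, DenoiseResult]:
    """Train a dedicated model on one noisy target volume and denoise it.

    One epoch is a full seed-shuffled pass over every voxel of the target grid.
    The target and each prior volume are independently normalised by their own
    ``normalization_percentile`` value before training; the returned volume is
    rescaled to the target's original units.
    """
    enc_cfg = enc_cfg or EncodingConfig()
    cfg = train_cfg or TrainingConfig()
    priors.check_grid(target.grid)

    scale_t = _percentile_scale(target.data, cfg.normalization_percentile)
    prior_scales = [
        _percentile_scale(v.data, cfg.normalization_percentile)
        for v in priors.ordered_volumes()
    ]

    X = build_descriptor_matrix(target.grid, enc_cfg, priors, cfg.patch_size,
                                prior_scales=prior_scales, dtype=np.float32)
    y = (target.data.reshape(-1) / scale_t).astype(np.float64)
    n = X.shape[0]

    model = MLPModel(X.shape[1], cfg.hidden_dim, cfg.depth, seed=cfg.seed,
                     dtype=np.float32)
    opt = _Adam(model.parameters())
    rng = np.random.default_rng(cfg.seed)
    batch = min(cfg.batch_voxels, n)
    n_batches = (n + batch - 1) // batch
    total_steps = cfg.epochs * n_batches

    epoch_losses: list[float] = []
    y32 = y.astype(np.float32)
    step = 0
    for _ in range(cfg.epochs):
        perm = rng.permutation(n)
        acc = 0.0
        for lo in range(0, n, batch):
            sel = perm[lo:lo + batch]
            loss, gW, gb = model.forward_backward(X[sel], y32[sel])
            grads = []
            for w, b in zip(gW, gb):
                grads.extend([w, b])
            opt.step(grads, _learning_rate(cfg, step, total_steps))
            step += 1
            acc += loss * len(sel)
        epoch_losses.append(acc / n)

    if cfg.epochs == 0:
        final_loss = _mean_loss_full(model, X, y, batch)
    else:
        final_loss = epoch_losses[-1]

    pred = np.empty(n, dtype=np.float64)
    for lo in range(0, n, batch):
        pred[lo:lo + batch] = model.forward(X[lo:lo + batch])
    denoised = Volume3D(target.grid, (pred * scale_t).reshape(target.grid.shape),
                        role="denoised", meta=target.meta)
    result = DenoiseResult(denoised=denoised, final_loss=final_loss,
                           epochs_run=cfg.epochs, config_echo=cfg,
                           target_scale=scale_t, prior_scales=prior_scales,
                           epoch_losses=epoch_losses)
    return model, result


def denoise_volume(
    model: MLPModel,
    grid: GridSpec,
    priors: PriorStack,
    enc_cfg: EncodingConfig | None = None,
    patch_size: int = 3,
    prior_scales: list[float] | None = None,
    output_scale: float = 1.0,
    batch_voxels: int = 4096,
) -> Volume3D:
    """Evaluate a trained model at every voxel of ``grid``.

    ``prior_scales``/``output_scale`` must match the normalisation used when
    the model was trained (both are recorded on the :class:`DenoiseResult`).
    Deterministic given the model parameters; the evaluation is tiled in
    batches purely for memory, the result does not depend on the tiling.
    """
    expected = descriptor_length(enc_cfg or EncodingConfig(), priors.n_priors, patch_size)
    if model.input_dim != expected:
        raise ValueError(
            f"model input_dim {model.input_dim} != descriptor length {expected}"
        )
    X = build_descriptor_matrix(grid, enc_cfg or EncodingConfig(), priors, patch_size,
                                prior_scales=prior_scales, dtype=np.float32)
    n = X.shape[0]
    pred = np.empty(n, dtype=np.float64)
    for lo in range(0, n, batch_voxels):
        pred[lo:lo + batch_voxels] = model.forward(X[lo:lo + batch_voxels])
    return Volume3D(grid, (pred * output_scale).reshape(grid.shape), role="denoised")


def denoise_series(
    volumes: list[tuple[float, Volume3D]],
    anatomical: list[tuple[str, Volume3D]] | None = None,
    enc_cfg: EncodingConfig | None = None,
    train_cfg: TrainingConfig | None = None,
) -> list[DenoiseResult]:
    """Denoise every b-value volume, each with all the others as priors.

    For each target b-value an independent model is trained with the remaining
    b-value volumes plus any anatomical volumes as its prior stack.  Per-target
    seeds are derived from the configured seed and the rank of the target
    b-value, so results do not depend on the order volumes are listed in.
    """
    if not volumes:
        raise ValueError("need at least one volume")
    bs = [float(b) for b, _ in volumes]
    if len(set(bs)) != len(bs):
        raise ValueError(f"duplicate b-values in series: {sorted(bs)}")
    anatomical = anatomical or []
    cfg = train_cfg or TrainingConfig()
    rank = {b: r for r, b in enumerate(sorted(bs))}
    results = []
    for b_t, vol in volumes:
        others = [(float(b), v) for b, v in volumes if float(b) != float(b_t)]
        priors = PriorStack(dwi=others, anatomical=list(anatomical), target_b=float(b_t))
        cfg_t = replace(cfg, seed=(cfg.seed + 9973 * rank[float(b_t)]) % (2**31 - 1))
        _, res = fit(vol, priors, enc_cfg, cfg_t)
        results.append(res)
    return results
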