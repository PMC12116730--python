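"""Two-phase transfer training and the user-facing Model/Results objects.

The training procedure has two phases.  Phase 1 ("pretrain") fits the CNN
trunk plus a linear head to the *source* corpus (natural-image-like textures
with MOS-style scores) under an L2 loss summed per minibatch.  Phase 2
("finetune") drops the pre-train head, assembles the hybrid model — the
pre-trained trunk, a freshly initialized connector, and a freshly initialized
windowed transformer with MK-CA fusion — and fits it to the *target* (CT-like)
corpus with the same optimizer family and loss.  Optionally the trunk is
frozen during phase 2, which leaves its parameters bit-identical.

Optimization is Adam with a cosine-annealed learning rate (initial value at
epoch 0, floor at the final epoch).  All randomness (init, batch order) flows
from integer seeds, so identical seeds reproduce identical checkpoints.

The object layer follows the fit/results convention of statistical modelling
libraries: :class:`QualityTransferModel` holds the data and architecture,
``fit()`` runs both phases and returns :class:`TransferFitResults` carrying
the fitted parameters, loss histories, held-out metrics, ``predict`` and a
``summary()`` table.
"""

from __future__ import annotations

import copy
import hashlib
from dataclasses import dataclass, field, replace

import autograd.numpy as anp
import numpy as np
from autograd import value_and_grad
from autograd.misc import flatten

from . import metrics as _metrics
from .backbone import (
    BackboneConfig,
    ConnectorConfig,
    TINY_BACKBONE,
    cnn_forward,
    hybrid_forward,
    init_backbone_params,
    init_connector_params,
    pretrain_forward,
)
from .corpus import CT_IQA_RANGE, CorpusManifest, ScoreRange
from .swin import StageSchedule, TINY_SCHEDULE, init_swin_params

__all__ = [
    "TrainConfig",
    "TrainState",
    "ModelSpec",
    "QualityTransferModel",
    "TransferFitResults",
    "preprocess",
    "l2_minibatch_loss",
    "cosine_lr",
    "run_pretrain",
    "run_finetune",
    "assemble_hybrid",
    "predict_scores",
    "params_hash",
    "ablation_combination_grid",
    "ablation_pretraining_grid",
    "tiny_model_spec",
]


# ---------------------------------------------------------------------------
# primitives


def preprocess(image: np.ndarray, target_size: int) -> np.ndarray:
    """Min-max normalize to [0,1]; bilinear-resize only if sizes differ.

    A constant image maps to all zeros (degenerate min = max case).
    """
    img = np.asarray(image, dtype=np.float64)
    if img.size == 0:
        raise ValueError("empty image")
    lo, hi = img.min(), img.max()
    img = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    if img.shape != (target_size, target_size):
        from skimage.transform import resize

        img = resize(img, (target_size, target_size), order=1, mode="reflect",
                     anti_aliasing=img.shape[0] > target_size)
        img = np.clip(img, 0.0, 1.0)
    return img


def l2_minibatch_loss(y, y_hat, reduction: str = "sum"):
    """Sum (default) or mean of squared prediction errors over a minibatch."""
    if anp.shape(y) != anp.shape(y_hat):
        raise ValueError(f"length mismatch: {anp.shape(y)} vs {anp.shape(y_hat)}")
    if reduction not in ("sum", "mean"):
        raise ValueError("reduction must be 'sum' or 'mean'")
    sq = (y - y_hat) ** 2
    return anp.sum(sq) if reduction == "sum" else anp.mean(sq)


def cosine_lr(epoch: int, total_epochs: int, lr0: float, lr_floor: float = 0.0) -> float:
    """Cosine annealing: lr0 at epoch 0, lr_floor at the final epoch."""
    if total_epochs <= 1:
        return lr0
    t = epoch / (total_epochs - 1)
    return lr_floor + 0.5 * (lr0 - lr_floor) * (1.0 + np.cos(np.pi * t))


def tree_map(f, tree):
    if isinstance(tree, dict):
        return {k: tree_map(f, v) for k, v in tree.items()}
    if isinstance(tree, (list, tuple)):
        return type(tree)(tree_map(f, v) for v in tree)
    return f(tree)


def params_hash(params) -> str:
    flat, _ = flatten(params)
    return hashlib.sha256(np.ascontiguousarray(flat).tobytes()).hexdigest()


class _Adam:
    """Standard Adam on the flattened parameter vector."""

    def __init__(self, n: int, beta1=0.9, beta2=0.999, eps=1e-8):
        self.m = np.zeros(n)
        self.v = np.zeros(n)
        self.t = 0
        self.beta1, self.beta2, self.eps = beta1, beta2, eps

    def step(self, flat_params, flat_grad, lr):
        self.t += 1
        self.m = self.beta1 * self.m + (1 - self.beta1) * flat_grad
        self.v = self.beta2 * self.v + (1 - self.beta2) * flat_grad**2
        mh = self.m / (1 - self.beta1**self.t)
        vh = self.v / (1 - self.beta2**self.t)
        return flat_params - lr * mh / (np.sqrt(vh) + self.eps)


# ---------------------------------------------------------------------------
# configs and state


@dataclass(frozen=True)
class TrainConfig:
    """One training phase: optimizer, schedule and bookkeeping knobs."""

    phase: str  # 'pretrain' | 'finetune'
    epochs: int
    batch_size: int = 4
    learning_rate: float = 1e-4
    lr_floor: float = 1e-6
    seed: int = 0
    freeze_backbone: bool = False
    grad_clip: float | None = None  # global-norm clip; off by default
    augment: bool = False  # dihedral (flip/rotate) training augmentation
    loss_reduction: str = "sum"
    score_range: ScoreRange = field(default_factory=lambda: CT_IQA_RANGE)
    deterministic: bool = True  # seeded data order (always honoured)
    select_best_val: bool = False

    def __post_init__(self) -> None:
        if self.phase not in ("pretrain", "finetune"):
            raise ValueError(f"phase must be pretrain|finetune, got {self.phase!r}")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


@dataclass
class TrainState:
    """Fitted parameters plus the full optimization trace of one phase."""

    params: dict
    phase: str
    epoch_losses: list[float]
    minibatch_losses: list[list[float]]
    lr_history: list[float]
    config: TrainConfig
    val_history: list[float] = field(default_factory=list)

    @property
    def final_loss(self) -> float:
        return self.epoch_losses[-1]


@dataclass(frozen=True)
class ModelSpec:
    """Architecture bundle: trunk, connector and transformer plans."""

    backbone: BackboneConfig = TINY_BACKBONE
    schedule: StageSchedule = TINY_SCHEDULE
    grid_side: int = 16
    clip_scores_at_inference: bool = True
    tta: bool = False  # average predictions over the 8 dihedral variants

    @property
    def connector(self) -> ConnectorConfig:
        return ConnectorConfig(self.backbone.feature_dim, self.grid_side)


def tiny_model_spec(combination: str = "mkca", kan_heads: int = 16) -> ModelSpec:
    """The desk-scale preset exercised by the test-suite: 64x64 inputs,
    feature width 32, 16x16 connector grid, two transformer stages.

    Dihedral test-time averaging is on: slice quality is invariant to
    flips and right-angle rotations, so averaging the 8 orientation
    variants reduces prediction variance at small model scale.
    """
    return ModelSpec(
        backbone=TINY_BACKBONE,
        schedule=replace(TINY_SCHEDULE, combination=combination, kan_heads=kan_heads),
        grid_side=16,
        tta=True,
    )


# ---------------------------------------------------------------------------
# data plumbing


def _stack_corpus(corpus: CorpusManifest, input_size: int):
    xs = np.stack([preprocess(r.pixels, input_size) for r in corpus.records])
    ys = np.array([r.score for r in corpus.records], dtype=np.float64)
    return xs[..., None], ys


def _iter_minibatches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def _dihedral(imgs, ks, flips):
    """Apply per-image 90-degree rotations and horizontal flips (B,H,W,1)."""
    out = []
    for im, k, f in zip(imgs, ks, flips):
        a = np.rot90(im, k=int(k), axes=(0, 1))
        if f:
            a = a[:, ::-1, :]
        out.append(a)
    return np.ascontiguousarray(np.stack(out))


def _train_loop(
    loss_fn, params, xs, ys, config: TrainConfig, grad_mask=None, val_fn=None
):
    flat, unflatten = flatten(params)
    mask_flat = None
    if grad_mask is not None:
        mask_flat, _ = flatten(grad_mask)
    opt = _Adam(flat.size)
    vg = value_and_grad(lambda p, xb, yb: loss_fn(unflatten(p), xb, yb))
    epoch_losses, minibatch_losses, lrs, val_history = [], [], [], []
    best = (-np.inf, None)
    for epoch in range(config.epochs):
        lr = cosine_lr(epoch, config.epochs, config.learning_rate, config.lr_floor)
        lrs.append(lr)
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 0xB47C, epoch])
        )
        batch_losses = []
        for bi, idx in enumerate(_iter_minibatches(len(ys), config.batch_size, rng)):
            xb, yb = xs[idx], ys[idx]
            if config.augment:
                xb = _dihedral(
                    xb, rng.integers(0, 4, len(idx)), rng.integers(0, 2, len(idx))
                )
            loss, g = vg(flat, xb, yb)
            loss = float(loss)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, minibatch {bi}"
                )
            if mask_flat is not None:
                g = g * mask_flat
            if config.grad_clip is not None:
                gn = float(np.linalg.norm(g))
                if gn > config.grad_clip:
                    g = g * (config.grad_clip / gn)
            flat = opt.step(flat, g, lr)
            batch_losses.append(loss)
        minibatch_losses.append(batch_losses)
        epoch_losses.append(float(np.mean(batch_losses)))
        if val_fn is not None:
            score = val_fn(unflatten(flat))
            val_history.append(score)
            if config.select_best_val and score > best[0]:
                best = (score, flat.copy())
    if config.select_best_val and best[1] is not None:
        flat = best[1]
    return unflatten(flat), epoch_losses, minibatch_losses, lrs, val_history


# ---------------------------------------------------------------------------
# phase runners


def _make_val_fn(corpus: CorpusManifest, input_size: int, forward):
    """Per-epoch validation score s = |r|+|rho|+|tau| on the val split
    (used for best-checkpoint selection); returns None without a val split."""
    val = corpus.subset("val")
    if len(val) < 3:
        return None
    xv, yv = _stack_corpus(val, input_size)

    def val_fn(params):
        preds = np.asarray(forward(params, xv))
        pairs = _metrics.ScorePairs(yv, preds)
        try:
            return _metrics.overall_s(
                _metrics.pearson_r(pairs),
                _metrics.spearman_rho(pairs),
                _metrics.kendall_tau(pairs),
            )
        except _metrics.UndefinedCorrelationError:
            return -np.inf

    return val_fn


def run_pretrain(
    corpus: CorpusManifest,
    config: TrainConfig,
    backbone_config: BackboneConfig = TINY_BACKBONE,
    init_params: dict | None = None,
) -> TrainState:
    """Phase 1: fit the CNN regressor to the source corpus (train split).

    Scores must already live in the shared score range (the synthetic source
    corpus emits them there; external MOS tables go through rescale_score).
    Returns the trained state; ``state.params`` holds phi plus the pre-train
    head.
    """
    train = corpus.subset("train")
    if len(train) == 0:
        raise ValueError("empty training split in source corpus")
    xs, ys = _stack_corpus(train, backbone_config.input_size)
    params = init_params if init_params is not None else init_backbone_params(
        backbone_config, np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    )

    def loss_fn(p, xb, yb):
        return l2_minibatch_loss(yb, pretrain_forward(xb, p, backbone_config),
                                 config.loss_reduction)

    val_fn = _make_val_fn(
        corpus, backbone_config.input_size,
        lambda p, xv: pretrain_forward(xv, p, backbone_config),
    ) if config.select_best_val else None
    params, el, ml, lrs, vh = _train_loop(loss_fn, params, xs, ys, config,
                                          val_fn=val_fn)
    return TrainState(params, "pretrain", el, ml, lrs, config, vh)


def assemble_hybrid(
    phi_pretrained: dict,
    spec: ModelSpec,
    rng: np.random.Generator,
) -> dict:
    """Build the hybrid parameter set: pre-trained trunk (pre-train head
    dropped), fresh connector, fresh transformer."""
    backbone = {
        k: copy.deepcopy(v) for k, v in phi_pretrained.items() if k != "pretrain_head"
    }
    if spec.grid_side % spec.schedule.patch:
        raise ValueError(
            f"connector grid {spec.grid_side} incompatible with patch "
            f"{spec.schedule.patch}"
        )
    return {
        "backbone": backbone,
        "connector": init_connector_params(spec.connector, rng),
        "swin": init_swin_params(spec.schedule, spec.grid_side, rng),
    }


def run_finetune(
    corpus: CorpusManifest,
    phi_pretrained: dict,
    config: TrainConfig,
    spec: ModelSpec = ModelSpec(),
) -> TrainState:
    """Phase 2: fit the hybrid model to the target corpus (train split).

    With ``config.freeze_backbone`` the trunk receives no updates (its
    parameters stay bit-identical); connector and transformer always train.
    """
    train = corpus.subset("train")
    if len(train) == 0:
        raise ValueError("empty training split in target corpus")
    xs, ys = _stack_corpus(train, spec.backbone.input_size)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    params = assemble_hybrid(phi_pretrained, spec, rng)

    grad_mask = None
    if config.freeze_backbone:
        grad_mask = tree_map(lambda a: np.zeros_like(np.asarray(a, dtype=float)),
                             params)
        grad_mask["connector"] = tree_map(
            lambda a: np.ones_like(np.asarray(a, dtype=float)), params["connector"]
        )
        grad_mask["swin"] = tree_map(
            lambda a: np.ones_like(np.asarray(a, dtype=float)), params["swin"]
        )

    def loss_fn(p, xb, yb):
        preds = hybrid_forward(xb, p, spec.backbone, spec.schedule, clip_range=None)
        return l2_minibatch_loss(yb, preds, config.loss_reduction)

    val_fn = _make_val_fn(
        corpus, spec.backbone.input_size,
        lambda p, xv: hybrid_forward(xv, p, spec.backbone, spec.schedule),
    ) if config.select_best_val else None
    params, el, ml, lrs, vh = _train_loop(loss_fn, params, xs, ys, config,
                                          grad_mask, val_fn)
    return TrainState(params, "finetune", el, ml, lrs, config, vh)


def predict_scores(
    images,
    params: dict,
    spec: ModelSpec,
    clip: bool | None = None,
    batch_size: int = 16,
    tta: bool | None = None,
) -> np.ndarray:
    """Score a batch of images (order-preserving, deterministic).

    With ``tta`` (default from the spec) each image is scored as the mean
    over its 8 dihedral (flip/rotation) variants.
    """
    xs = np.stack([preprocess(np.asarray(im), spec.backbone.input_size)
                   for im in images])[..., None]
    clip_range = CT_IQA_RANGE if (clip if clip is not None
                                  else spec.clip_scores_at_inference) else None
    use_tta = spec.tta if tta is None else tta
    variants = [xs]
    if use_tta:
        variants = [
            np.ascontiguousarray(
                np.rot90(xs, k=k, axes=(1, 2))[:, :, ::-1] if f
                else np.rot90(xs, k=k, axes=(1, 2))
            )
            for k in range(4) for f in (False, True)
        ]
    acc = np.zeros(len(xs))
    for var in variants:
        for start in range(0, len(var), batch_size):
            acc[start:start + batch_size] += np.asarray(
                hybrid_forward(var[start:start + batch_size], params,
                               spec.backbone, spec.schedule, clip_range=clip_range)
            )
    return acc / len(variants)


# ---------------------------------------------------------------------------
# Model / Results objects


class QualityTransferModel:
    """No-reference quality scorer fitted by natural-to-CT transfer.

    Parameters
    ----------
    source : CorpusManifest
        Phase-1 corpus (natural-image-like, scores already in the shared
        range).
    target : CorpusManifest
        Phase-2 corpus (CT-like, 0-4 scores).
    spec : ModelSpec
        Architecture bundle; defaults to the desk-scale preset.
    """

    def __init__(
        self,
        source: CorpusManifest | None,
        target: CorpusManifest,
        spec: ModelSpec | None = None,
    ):
        self.source = source
        self.target = target
        self.spec = spec or tiny_model_spec()

    @classmethod
    def from_manifests(cls, source, target, **kw):
        return cls(source, target, **kw)

    def fit(
        self,
        pretrain_config: TrainConfig | None = None,
        finetune_config: TrainConfig | None = None,
        seed: int = 0,
    ) -> "TransferFitResults":
        """Run phase 1 (if a source corpus is present) then phase 2."""
        pre_state = None
        if self.source is not None:
            pc = pretrain_config or TrainConfig("pretrain", epochs=8, seed=seed,
                                                learning_rate=1e-3)
            pre_state = run_pretrain(self.source, pc, self.spec.backbone)
            phi = pre_state.params
        else:
            phi = init_backbone_params(
                self.spec.backbone,
                np.random.default_rng(np.random.SeedSequence([seed, 1])),
            )
        fc = finetune_config or TrainConfig("finetune", epochs=30, seed=seed,
                                            learning_rate=1e-3)
        fin_state = run_finetune(self.target, phi, fc, self.spec)
        return TransferFitResults(self, pre_state, fin_state)


class TransferFitResults:
    """Outcome of a two-phase fit: parameters, traces, metrics, prediction."""

    def __init__(self, model: QualityTransferModel, pretrain_state, finetune_state):
        self.model = model
        self.pretrain_state = pretrain_state
        self.finetune_state = finetune_state
        self.params = finetune_state.params

    def predict(self, images, clip: bool | None = None) -> np.ndarray:
        return predict_scores(images, self.params, self.model.spec, clip)

    def predict_manifest(self, manifest: CorpusManifest, clip=None):
        return self.predict([r.pixels for r in manifest.records], clip)

    def evaluate(self, split: str = "test") -> _metrics.EvalReport:
        sub = self.model.target.subset(split)
        if len(sub) < 2:
            raise ValueError(f"split {split!r} has fewer than two records")
        preds = self.predict([r.pixels for r in sub.records])
        pairs = _metrics.ScorePairs(
            np.array([r.score for r in sub.records]), preds,
            [r.image_id for r in sub.records],
        )
        return _metrics.evaluate_pairs(pairs)

    def summary(self, split: str = "test") -> str:
        rep = self.evaluate(split)
        lines = [
            "Quality transfer model — fit summary",
            "=" * 44,
            f"architecture: trunk {self.model.spec.backbone.feature_dim}-d, "
            f"connector {self.model.spec.grid_side}x{self.model.spec.grid_side}, "
            f"{self.model.spec.schedule.num_stages} transformer stage(s), "
            f"fusion '{self.model.spec.schedule.combination}'",
        ]
        if self.pretrain_state is not None:
            lines.append(
                f"phase 1: {len(self.pretrain_state.epoch_losses)} epochs, "
                f"loss {self.pretrain_state.epoch_losses[0]:.3f} -> "
                f"{self.pretrain_state.final_loss:.3f}"
            )
        lines += [
            f"phase 2: {len(self.finetune_state.epoch_losses)} epochs, "
            f"loss {self.finetune_state.epoch_losses[0]:.3f} -> "
            f"{self.finetune_state.final_loss:.3f}"
            + (" (trunk frozen)" if self.finetune_state.config.freeze_backbone else ""),
            "-" * 44,
            f"held-out ({split}, n={rep.n}):",
            f"  r   = {rep.r: .4f}",
            f"  rho = {rep.rho: .4f}",
            f"  tau = {rep.tau: .4f}",
            f"  s   = {rep.s: .4f}",
            f"  R^2 = {rep.r2: .4f}",
        ]
        if rep.range_groups:
            lines.append(
                f"  group accuracy = {rep.range_groups['overall_accuracy']:.2%}"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# ablation harnesses


def ablation_combination_grid(
    modes,
    source: CorpusManifest | None,
    target: CorpusManifest,
    pretrain_config: TrainConfig,
    finetune_config: TrainConfig,
    spec: ModelSpec | None = None,
    split: str = "val",
):
    """Train one model per MLP/KAN combination mode; one metric row each."""
    import pandas as pd

    base = spec or tiny_model_spec()
    rows = []
    for mode in modes:
        m_spec = replace(base, schedule=replace(base.schedule, combination=mode))
        model = QualityTransferModel(source, target, m_spec)
        res = model.fit(pretrain_config, finetune_config,
                        seed=finetune_config.seed)
        rep = res.evaluate(split)
        rows.append({"combination": mode, **rep.summary_row()})
    return pd.DataFrame(rows)


def ablation_pretraining_grid(
    source: CorpusManifest,
    target: CorpusManifest,
    pretrain_config: TrainConfig,
    finetune_config: TrainConfig,
    spec: ModelSpec | None = None,
    split: str = "val",
):
    """Paired comparison: phase-2 training with vs. without phase-1
    pre-training of the trunk, at equal budget and seed."""
    import pandas as pd

    base = spec or tiny_model_spec()
    rows = []
    for pretrained in (False, True):
        model = QualityTransferModel(source if pretrained else None, target, base)
        res = model.fit(pretrain_config, finetune_config,
                        seed=finetune_config.seed)
        rep = res.evaluate(split)
        rows.append({"trunk_pretrained": pretrained, **rep.summary_row()})
    return pd.DataFrame(rows)
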