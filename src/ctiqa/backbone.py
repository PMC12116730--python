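"""CNN feature trunk and the connector bridging it into the transformer.

The trunk is a configurable stack of fused inverted-bottleneck convolution
blocks with squeeze-excitation (the EfficientNetV2 early-stage block style):
a 3x3 expanding convolution, channel-wise normalization and SiLU, an SE gate,
and a 1x1 projection with a residual path when shapes permit.  A final 1x1
convolution widens to ``feature_dim`` and global average pooling yields the
image feature vector.  During pre-training a single linear head on top of the
pooled features regresses the quality score; for fine-tuning that head is
dropped and the pooled features feed the connector.

The connector is deliberately small: one fully connected layer mapping the
pooled CNN features to ``grid_side**2`` values, a ReLU, and a row-major
reshape to a ``grid_side x grid_side`` single-channel map that re-enters the
transformer through its patch embedding.

Shapes are (batch, height, width, channels) throughout; single-channel
grayscale input is enforced.
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np

from .kan import silu
from .swin import StageSchedule, patch_embed, run_stages, score_head

__all__ = [
    "BackboneConfig",
    "ConnectorConfig",
    "TINY_BACKBONE",
    "PAPER_BACKBONE",
    "conv2d",
    "cnn_forward",
    "pretrain_forward",
    "connector_forward",
    "hybrid_forward",
    "init_backbone_params",
    "init_connector_params",
]


@dataclass(frozen=True)
class BackboneConfig:
    """Conv-trunk plan: per-stage (out_channels, stride, expansion ratio)."""

    stages: tuple[tuple[int, int, int], ...] = ((8, 2, 8), (16, 2, 2), (32, 2, 2))
    feature_dim: int = 32
    se_ratio: float = 0.25
    input_size: int = 64


TINY_BACKBONE = BackboneConfig()
# paper-scale preset: pooled feature width 1280 as in the full-size trunk
PAPER_BACKBONE = BackboneConfig(
    stages=((32, 2, 1), (64, 2, 4), (128, 2, 4), (256, 2, 4), (512, 2, 6)),
    feature_dim=1280,
    input_size=512,
)


@dataclass(frozen=True)
class ConnectorConfig:
    feature_dim: int = 32
    grid_side: int = 16


def conv2d(x, W, b, stride: int = 1):
    """Same-padded 2-D convolution via patch gathering (im2col).

    x: (B, H, W, Cin); W: (kh, kw, Cin, Cout).  Differentiable end to end.
    """
    B, H, Wd, Cin = anp.shape(x)
    kh, kw, _, Cout = W.shape
    ph, pw = kh // 2, kw // 2
    xp = anp.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)), mode="constant")
    Ho = (H + 2 * ph - kh) // stride + 1
    Wo = (Wd + 2 * pw - kw) // stride + 1
    idx_h = (stride * np.arange(Ho))[:, None] + np.arange(kh)  # (Ho, kh)
    idx_w = (stride * np.arange(Wo))[:, None] + np.arange(kw)  # (Wo, kw)
    xr = anp.reshape(xp[:, idx_h.ravel(), :, :], (B, Ho, kh, Wd + 2 * pw, Cin))
    xc = anp.reshape(
        xr[:, :, :, idx_w.ravel(), :], (B, Ho, kh, Wo, kw, Cin)
    )
    return anp.einsum("bhiwjc,ijco->bhwo", xc, W) + b


def _channel_norm(x, p, eps=1e-3):
    """Per-pixel normalization across channels.  The generous eps keeps
    gradients bounded when early narrow layers emit near-constant channel
    vectors (tiny variance would otherwise explode 1/sqrt(var))."""
    mu = anp.mean(x, axis=-1, keepdims=True)
    var = anp.mean((x - mu) ** 2, axis=-1, keepdims=True)
    return (x - mu) / anp.sqrt(var + eps) * p["g"] + p["b"]


def _se_gate(x, p, eps=1e-12):
    # squeeze-excitation: pooled descriptor -> bottleneck -> sigmoid gate
    s = anp.mean(x, axis=(1, 2))
    s = silu(s @ p["W1"] + p["b1"])
    g = 1.0 / (1.0 + anp.exp(-(s @ p["W2"] + p["b2"])))
    return x * g[:, None, None, :]


def _coerce_batch(image, expected_size: int | None = None):
    x = image if hasattr(image, "_value") else np.asarray(image, dtype=np.float64)
    nd = len(anp.shape(x))
    if nd == 2:
        x = anp.reshape(x, (1,) + anp.shape(x) + (1,))
    elif nd == 3:
        x = anp.reshape(x, anp.shape(x) + (1,))
    elif nd != 4:
        raise ValueError(f"expected a 2-D image or batch thereof, got ndim={nd}")
    B, H, W, C = anp.shape(x)
    if C != 1:
        raise ValueError(f"single-channel grayscale input required, got {C} channels")
    if expected_size is not None and (H != expected_size or W != expected_size):
        raise ValueError(
            f"input size {H}x{W} does not match configured {expected_size}x{expected_size}"
        )
    return x


def cnn_forward(image, params: dict, config: BackboneConfig = TINY_BACKBONE):
    """Conv-trunk features: (B, feature_dim) global-average-pooled vector."""
    x = _coerce_batch(image, config.input_size)
    for sp, (_, stride, _) in zip(params["stages"], config.stages):
        inp = x
        h = silu(_channel_norm(conv2d(x, sp["expand"]["W"], sp["expand"]["b"],
                                      stride=stride), sp["ln1"]))
        h = _se_gate(h, sp["se"])
        h = _channel_norm(
            anp.einsum("bhwc,co->bhwo", h, sp["project"]["W"]) + sp["project"]["b"],
            sp["ln2"],
        )
        if stride == 1 and anp.shape(inp)[-1] == anp.shape(h)[-1]:
            h = h + inp
        x = h
    x = silu(anp.einsum("bhwc,co->bhwo", x, params["final"]["W"]) + params["final"]["b"])
    return anp.mean(x, axis=(1, 2))


def pretrain_forward(image, params: dict, config: BackboneConfig = TINY_BACKBONE):
    """Phase-1 regressor: trunk features through the linear pre-train head."""
    feats = cnn_forward(image, params, config)
    return feats @ params["pretrain_head"]["W"] + params["pretrain_head"]["b"]


def connector_forward(feat, params: dict):
    """Affine map -> ReLU -> row-major reshape to (B, grid_side, grid_side, 1)."""
    F, G2 = params["W"].shape
    if anp.shape(feat)[-1] != F:
        raise ValueError(
            f"feature length {anp.shape(feat)[-1]} does not match connector input {F}"
        )
    gs = int(round(np.sqrt(G2)))
    h = anp.maximum(feat @ params["W"] + params["b"], 0.0)
    return anp.reshape(h, (-1, gs, gs, 1))


def hybrid_forward(
    image,
    params: dict,
    backbone_config: BackboneConfig,
    schedule: StageSchedule,
    clip_range=None,
):
    """Full inference path: CNN trunk -> connector -> transformer -> score.

    Returns one score per input image, in input order; deterministic (the
    model has no stochastic layers).
    """
    feats = cnn_forward(image, params["backbone"], backbone_config)
    grid = connector_forward(feats, params["connector"])
    tokens = patch_embed(grid, params["swin"]["patch_embed"], schedule.patch)
    pooled = run_stages(tokens, schedule, params["swin"])
    return score_head(pooled, params["swin"]["head"], clip_range)


# ---------------------------------------------------------------------------
# initialization


def _lin(rng, n_in, n_out, sd=None):
    sd = sd if sd is not None else np.sqrt(2.0 / n_in)
    return {"W": rng.normal(0.0, sd, size=(n_in, n_out)), "b": np.zeros(n_out)}


def init_backbone_params(
    config: BackboneConfig, rng: np.random.Generator
) -> dict:
    """He-style initialization of the conv trunk plus the pre-train head."""
    stages = []
    c_in = 1
    for c_out, stride, expand in config.stages:
        c_mid = c_in * expand
        se_dim = max(1, int(round(config.se_ratio * c_mid)))
        stages.append(
            {
                "expand": {
                    "W": rng.normal(
                        0.0, np.sqrt(2.0 / (9 * c_in)), size=(3, 3, c_in, c_mid)
                    ),
                    "b": np.zeros(c_mid),
                },
                "ln1": {"g": np.ones(c_mid), "b": np.zeros(c_mid)},
                "se": {
                    "W1": rng.normal(0.0, np.sqrt(2.0 / c_mid), size=(c_mid, se_dim)),
                    "b1": np.zeros(se_dim),
                    "W2": rng.normal(0.0, np.sqrt(2.0 / se_dim), size=(se_dim, c_mid)),
                    "b2": np.zeros(c_mid),
                },
                "project": _lin(rng, c_mid, c_out),
                "ln2": {"g": np.ones(c_out), "b": np.zeros(c_out)},
            }
        )
        c_in = c_out
    final = _lin(rng, c_in, config.feature_dim)
    head = _lin(rng, config.feature_dim, 1, sd=0.01)
    return {
        "stages": stages,
        "final": final,
        "pretrain_head": {"W": head["W"][:, 0], "b": 0.0},
    }


def init_connector_params(
    config: ConnectorConfig, rng: np.random.Generator
) -> dict:
    g2 = config.grid_side**2
    return {
        "W": rng.normal(0.0, np.sqrt(2.0 / config.feature_dim),
                        size=(config.feature_dim, g2)),
        "b": np.zeros(g2),
    }
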