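"""Windowed-attention transformer stages with MLP-KAN cross-attention fusion.

The backbone is a hierarchical shifted-window transformer in the SwinV2
style: attention restricted to non-overlapping local windows (alternately
cyclically shifted so information crosses window borders), scaled *cosine*
attention with a learnable per-head temperature, residual post-normalization,
and 2x2 patch merging between stages.

The departure from a standard Swin block is the feed-forward sublayer: the
usual MLP is replaced by MK-CA, a dual cross-attention fusion of two parallel
transforms of the window tokens —

    u = mlp(tokens)                (the MLP path)
    v = kan_eta(tokens)            (a KAN applied per eta-head channel slice)
    beta1 = CrossAttention(Q(u), K(v), V(v))
    beta2 = CrossAttention(Q(v), K(u), V(u))
    omega = beta1 + beta2

so each path queries the other's representation and the two attention outputs
are summed.  Ablation modes (mlp-only, kan-only, average, concat, sum, single
cross-attention either way) are selectable per model for controlled
comparisons.

Learnable parameters are nested dicts of numpy arrays (autograd-compatible);
the dataclasses below are typed views over those dicts used by the
operation-level API.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import autograd.numpy as anp
import numpy as np

from .kan import (
    HeadSplit,
    KanLayerParams,
    SplineGrid,
    init_kan_layer,
    kan_transform,
    merge_heads,
    silu,
    split_heads,
)

__all__ = [
    "StageSchedule",
    "TINY_SCHEDULE",
    "PAPER_SCHEDULE",
    "AttentionProjection",
    "MkCaParams",
    "partition_windows",
    "merge_windows",
    "shift_attention_mask",
    "cosine_window_attention",
    "cross_attention",
    "mk_ca_forward",
    "swin_kat_block",
    "patch_embed",
    "run_stages",
    "score_head",
    "init_swin_params",
    "COMBINATION_MODES",
]

COMBINATION_MODES = (
    "mlp", "kan", "average", "concat", "sum", "ca_mk", "ca_km", "mkca",
)

_LN_EPS = 1e-5
_MASK_NEG = -1e9


# ---------------------------------------------------------------------------
# schedules and parameter views


@dataclass(frozen=True)
class StageSchedule:
    """Static stage plan: patch size, window, per-stage repeats and widths.

    Stage n (0-based) runs ``repeats[n]`` blocks on a token grid downsampled
    by ``patch * 2**n`` relative to the input image, with ``base_channels *
    2**n`` channels; 2x2 patch merging sits between stages.  The effective
    window at a stage is ``min(window, grid_side)``.
    """

    patch: int = 4
    window: int = 4
    repeats: tuple[int, ...] = (2, 2)
    base_channels: int = 32
    attn_heads: int = 4
    kan_heads: int = 16
    kan_grid: SplineGrid = field(default_factory=SplineGrid)
    mlp_ratio: float = 2.0
    combination: str = "mkca"

    def __post_init__(self) -> None:
        if self.combination not in COMBINATION_MODES:
            raise ValueError(
                f"unknown combination mode {self.combination!r}; "
                f"choose from {COMBINATION_MODES}"
            )

    @property
    def num_stages(self) -> int:
        return len(self.repeats)

    def channels(self, stage: int) -> int:
        return self.base_channels * 2**stage

    def downsampling(self, stage: int) -> int:
        return self.patch * 2**stage

    @property
    def final_channels(self) -> int:
        return self.channels(self.num_stages - 1)


# a paper-scale preset mirroring SwinV2-B conventions, and the desk-scale
# default actually exercised by the test-suite
TINY_SCHEDULE = StageSchedule()
PAPER_SCHEDULE = StageSchedule(
    patch=4, window=8, repeats=(2, 2, 18, 2), base_channels=128, attn_heads=4,
)


@dataclass
class AttentionProjection:
    """Q/K/V/output projections of one attention operator."""

    W_q: np.ndarray
    b_q: np.ndarray
    W_k: np.ndarray
    b_k: np.ndarray
    W_v: np.ndarray
    b_v: np.ndarray
    W_o: np.ndarray
    b_o: np.ndarray
    heads: int
    logit_scale: np.ndarray | None = None  # per-head, cosine attention only
    rel_pos_bias: np.ndarray | None = None  # ((2w-1)^2, heads)

    @classmethod
    def from_dict(cls, d: dict, heads: int) -> "AttentionProjection":
        return cls(
            d["Wq"], d["bq"], d["Wk"], d["bk"], d["Wv"], d["bv"],
            d["Wo"], d["bo"], heads,
            d.get("logit_scale"), d.get("rpb"),
        )


@dataclass
class MkCaParams:
    """Parameters of one MK-CA sublayer (typed view over the param dict)."""

    mlp: dict  # {'W1','b1','W2','b2'}
    kan: KanLayerParams
    split: HeadSplit
    attn_1: AttentionProjection  # beta1: queries from the MLP path
    attn_2: AttentionProjection  # beta2: queries from the KAN path
    concat_proj: dict | None = None  # {'W','b'}, concat mode only

    @classmethod
    def from_dict(cls, d: dict, schedule: StageSchedule) -> "MkCaParams":
        return cls(
            mlp=d["mlp"],
            kan=KanLayerParams(d["kan"]["coeffs"], d["kan"]["base"], schedule.kan_grid),
            split=HeadSplit(schedule.kan_heads),
            attn_1=AttentionProjection.from_dict(d["ca1"], schedule.attn_heads),
            attn_2=AttentionProjection.from_dict(d["ca2"], schedule.attn_heads),
            concat_proj=d.get("concat"),
        )


# ---------------------------------------------------------------------------
# window partitioning


def partition_windows(tokens, window: int, shift: int = 0):
    """Split a (B, H, W, C) token grid into (B*nW, window^2, C) blocks.

    With ``shift`` > 0 the grid is first cyclically rolled by -shift along
    both spatial axes (shifted-window mode).  Returns the blocks plus
    metadata sufficient for exact inversion by :func:`merge_windows`.
    """
    B, H, W, C = anp.shape(tokens)
    if H % window or W % window:
        raise ValueError(
            f"grid {H}x{W} not divisible by window {window}; pad before partitioning"
        )
    if not 0 <= shift < window:
        raise ValueError(f"shift {shift} must satisfy 0 <= shift < window {window}")
    x = tokens
    if shift:
        x = anp.roll(x, (-shift, -shift), axis=(1, 2))
    nh, nw = H // window, W // window
    x = anp.reshape(x, (B, nh, window, nw, window, C))
    x = anp.transpose(x, (0, 1, 3, 2, 4, 5))
    blocks = anp.reshape(x, (B * nh * nw, window * window, C))
    meta = {"B": B, "H": H, "W": W, "window": window, "shift": shift}
    return blocks, meta


def merge_windows(blocks, meta):
    """Exact inverse of :func:`partition_windows`."""
    B, H, W, w, s = meta["B"], meta["H"], meta["W"], meta["window"], meta["shift"]
    C = anp.shape(blocks)[-1]
    nh, nw = H // w, W // w
    x = anp.reshape(blocks, (B, nh, nw, w, w, C))
    x = anp.transpose(x, (0, 1, 3, 2, 4, 5))
    x = anp.reshape(x, (B, H, W, C))
    if s:
        x = anp.roll(x, (s, s), axis=(1, 2))
    return x


def shift_attention_mask(H: int, W: int, window: int, shift: int) -> np.ndarray | None:
    """Attention mask blocking cross-region pairs under cyclic shifting.

    Tokens that originate from different pre-shift regions of the image end
    up in the same window after rolling; their attention logits receive a
    large negative bias.  Returns (nW, window^2, window^2), or None when no
    shift is applied.
    """
    if shift == 0:
        return None
    region = np.zeros((H, W))
    bounds = (slice(0, -window), slice(-window, -shift), slice(-shift, None))
    label = 0
    for hs in bounds:
        for ws in bounds:
            region[hs, ws] = label
            label += 1
    region = np.roll(region, (-shift, -shift), axis=(0, 1))
    nh, nw = H // window, W // window
    region = region.reshape(nh, window, nw, window).transpose(0, 2, 1, 3)
    region = region.reshape(nh * nw, window * window)
    same = region[:, :, None] == region[:, None, :]
    return np.where(same, 0.0, _MASK_NEG)


def relative_position_index(window: int) -> np.ndarray:
    """(w^2, w^2) index into a ((2w-1)^2,) relative-position-bias table."""
    coords = np.stack(np.meshgrid(np.arange(window), np.arange(window), indexing="ij"))
    flat = coords.reshape(2, -1)
    rel = flat[:, :, None] - flat[:, None, :] + window - 1
    return rel[0] * (2 * window - 1) + rel[1]


# ---------------------------------------------------------------------------
# attention operators


def _split_attn_heads(x, heads):
    nB, T, C = anp.shape(x)
    x = anp.reshape(x, (nB, T, heads, C // heads))
    return anp.transpose(x, (0, 2, 1, 3))  # (nB, heads, T, dh)


def _merge_attn_heads(x):
    nB, h, T, dh = anp.shape(x)
    return anp.reshape(anp.transpose(x, (0, 2, 1, 3)), (nB, T, h * dh))


def _softmax(logits):
    m = anp.max(logits, axis=-1, keepdims=True)
    e = anp.exp(logits - m)
    return e / anp.sum(e, axis=-1, keepdims=True)


def cosine_window_attention(
    block_tokens, proj: AttentionProjection, mask=None, return_weights: bool = False
):
    """Scaled cosine attention over window token blocks (nB, T, C).

    Logits are cosine similarities between queries and keys multiplied by a
    clamped learnable per-head temperature, plus a relative-position bias and
    the optional shift mask.  Softmax rows sum to one by construction.
    """
    vals = block_tokens if hasattr(block_tokens, "_value") else np.asarray(block_tokens)
    if not hasattr(block_tokens, "_value") and not np.all(np.isfinite(vals)):
        raise ValueError("non-finite attention input")
    nB, T, C = anp.shape(block_tokens)
    if C % proj.heads:
        raise ValueError(f"channels {C} not divisible by heads {proj.heads}")
    q = _split_attn_heads(block_tokens @ proj.W_q + proj.b_q, proj.heads)
    k = _split_attn_heads(block_tokens @ proj.W_k + proj.b_k, proj.heads)
    v = _split_attn_heads(block_tokens @ proj.W_v + proj.b_v, proj.heads)
    qn = q / anp.sqrt(anp.sum(q**2, axis=-1, keepdims=True) + 1e-12)
    kn = k / anp.sqrt(anp.sum(k**2, axis=-1, keepdims=True) + 1e-12)
    logits = anp.einsum("bhtd,bhsd->bhts", qn, kn)
    if proj.logit_scale is not None:
        scale = anp.exp(anp.clip(proj.logit_scale, -10.0, np.log(100.0)))
        logits = logits * anp.reshape(scale, (1, -1, 1, 1))
    if proj.rel_pos_bias is not None:
        idx = relative_position_index(int(np.sqrt(T)))
        bias = proj.rel_pos_bias[idx]  # (T, T, heads)
        logits = logits + anp.transpose(bias, (2, 0, 1))[None]
    if mask is not None:
        nW = mask.shape[0]
        lb = anp.reshape(logits, (nB // nW, nW, proj.heads, T, T))
        lb = lb + mask[None, :, None, :, :]
        logits = anp.reshape(lb, (nB, proj.heads, T, T))
    weights = _softmax(logits)
    out = _merge_attn_heads(anp.einsum("bhts,bhsd->bhtd", weights, v))
    out = out @ proj.W_o + proj.b_o
    return (out, weights) if return_weights else out


def cross_attention(
    query_seq, context_seq, proj: AttentionProjection, return_weights: bool = False
):
    """Scaled dot-product attention: queries from one sequence, keys/values
    from the other.  Output length equals the query length."""
    if anp.shape(query_seq)[-1] != anp.shape(context_seq)[-1]:
        raise ValueError(
            f"channel mismatch: query {anp.shape(query_seq)[-1]} vs "
            f"context {anp.shape(context_seq)[-1]}"
        )
    q = _split_attn_heads(query_seq @ proj.W_q + proj.b_q, proj.heads)
    k = _split_attn_heads(context_seq @ proj.W_k + proj.b_k, proj.heads)
    v = _split_attn_heads(context_seq @ proj.W_v + proj.b_v, proj.heads)
    dh = anp.shape(q)[-1]
    logits = anp.einsum("bhtd,bhsd->bhts", q, k) / np.sqrt(dh)
    weights = _softmax(logits)
    out = _merge_attn_heads(anp.einsum("bhts,bhsd->bhtd", weights, v))
    out = out @ proj.W_o + proj.b_o
    return (out, weights) if return_weights else out


# ---------------------------------------------------------------------------
# MK-CA


def _mlp_path(x, p):
    return silu(x @ p["W1"] + p["b1"]) @ p["W2"] + p["b2"]


def _kan_path(x, kan: KanLayerParams, split: HeadSplit):
    # shared KAN over eta contiguous channel slices == reshape + single apply
    shape = anp.shape(x)
    c = shape[-1]
    if c % split.heads:
        raise ValueError(f"channels {c} not divisible by head count {split.heads}")
    xh = anp.reshape(x, shape[:-1] + (split.heads, c // split.heads))
    return anp.reshape(kan_transform(xh, kan), shape)


def mk_ca_forward(tokens, params: MkCaParams, mode: str = "mkca"):
    """MK-CA sublayer on window token blocks (nB, T, C).

    In the full ``mkca`` mode the output is omega = beta1 + beta2 of the dual
    cross-attentions; the remaining modes are the ablation combinations.
    """
    if mode not in COMBINATION_MODES:
        raise ValueError(f"unknown combination mode {mode!r}")
    if mode == "mlp":
        return _mlp_path(tokens, params.mlp)
    if mode == "kan":
        return _kan_path(tokens, params.kan, params.split)
    u = _mlp_path(tokens, params.mlp)
    v = _kan_path(tokens, params.kan, params.split)
    if mode == "average":
        return 0.5 * (u + v)
    if mode == "sum":
        return u + v
    if mode == "concat":
        cp = params.concat_proj
        return anp.concatenate([u, v], axis=-1) @ cp["W"] + cp["b"]
    if mode == "ca_mk":
        return cross_attention(u, v, params.attn_1)
    if mode == "ca_km":
        return cross_attention(v, u, params.attn_2)
    beta1 = cross_attention(u, v, params.attn_1)
    beta2 = cross_attention(v, u, params.attn_2)
    return beta1 + beta2


# ---------------------------------------------------------------------------
# blocks and stages


def layer_norm(x, p):
    mu = anp.mean(x, axis=-1, keepdims=True)
    var = anp.mean((x - mu) ** 2, axis=-1, keepdims=True)
    return (x - mu) / anp.sqrt(var + _LN_EPS) * p["g"] + p["b"]


def swin_kat_block(tokens, block_params: dict, schedule: StageSchedule, shift: int):
    """One transformer block with residual post-normalization:

        y   = tokens + LN(WindowAttention(tokens))
        out = y + LN(MK-CA(y))

    Both sublayers operate on the same (possibly shifted) window partition.
    """
    B, H, W, C = anp.shape(tokens)
    w = min(schedule.window, H, W)
    s = shift if w < min(H, W) else 0  # shifting a single window is a no-op
    attn = AttentionProjection.from_dict(block_params["attn"], schedule.attn_heads)
    mask = shift_attention_mask(H, W, w, s)
    blocks, meta = partition_windows(tokens, w, s)
    a = cosine_window_attention(blocks, attn, mask)
    y = tokens + layer_norm(merge_windows(a, meta), block_params["ln1"])
    mkca = MkCaParams.from_dict(block_params["mkca"], schedule)
    yb, metb = partition_windows(y, w, s)
    m = mk_ca_forward(yb, mkca, schedule.combination)
    return y + layer_norm(merge_windows(m, metb), block_params["ln2"])


def patch_embed(grid, params: dict, patch: int):
    """Patchify a (B, G, G, c) map into tokens: linear on flattened patches
    followed by layer norm."""
    B, G, _, c = anp.shape(grid)
    if G % patch:
        raise ValueError(f"grid side {G} not divisible by patch {patch}")
    n = G // patch
    x = anp.reshape(grid, (B, n, patch, n, patch, c))
    x = anp.transpose(x, (0, 1, 3, 2, 4, 5))
    x = anp.reshape(x, (B, n, n, patch * patch * c))
    return layer_norm(x @ params["W"] + params["b"], params["ln"])


def _patch_merge(x, p):
    B, H, W, C = anp.shape(x)
    if H % 2 or W % 2:
        raise ValueError(f"patch merging requires even grid, got {H}x{W}")
    x = anp.reshape(x, (B, H // 2, 2, W // 2, 2, C))
    x = anp.transpose(x, (0, 1, 3, 2, 4, 5))
    x = anp.reshape(x, (B, H // 2, W // 2, 4 * C))
    return layer_norm(x, p["ln"]) @ p["W"] + p["b"]


def run_stages(tokens, schedule: StageSchedule, params: dict):
    """Run all stages on an embedded token grid and pool to a feature vector.

    Per stage: ``repeats[n]`` blocks with window shift alternating between 0
    and w/2; 2x2 patch merging (concatenate + linear halving) between stages;
    final layer norm then mean pooling over tokens.
    """
    x = tokens
    for n, stage in enumerate(params["stages"]):
        B, H, W, C = anp.shape(x)
        if C != schedule.channels(n):
            raise ValueError(
                f"stage {n}: expected {schedule.channels(n)} channels, got {C}"
            )
        w = min(schedule.window, H, W)
        for i, bp in enumerate(stage["blocks"]):
            shift = w // 2 if (i % 2 == 1 and w < min(H, W) and w > 1) else 0
            x = swin_kat_block(x, bp, schedule, shift)
        if "merge" in stage:
            x = _patch_merge(x, stage["merge"])
    x = layer_norm(x, params["final_ln"])
    return anp.mean(x, axis=(1, 2))


def score_head(pooled, params: dict, clip_range=None):
    """Single linear regression unit; optional clipping to the score range."""
    s = pooled @ params["W"] + params["b"]
    if clip_range is not None:
        s = anp.clip(s, clip_range.s_min, clip_range.s_max)
    return s


# ---------------------------------------------------------------------------
# initialization


def _init_linear(rng, n_in, n_out, sd=None):
    # scale-preserving init: with residual post-normalization every sublayer
    # output is renormalized to unit variance, so undersized projections
    # would dilute the input-dependent signal relative to the additive
    # stream instead of merely slowing learning
    sd = sd if sd is not None else 1.0 / np.sqrt(n_in)
    return {"W": rng.normal(0.0, sd, size=(n_in, n_out)), "b": np.zeros(n_out)}


def _init_ln(c):
    return {"g": np.ones(c), "b": np.zeros(c)}


def _init_attn(rng, c, heads, window=None, cosine=False):
    d = {}
    for name in ("q", "k", "v", "o"):
        lin = _init_linear(rng, c, c)
        d[f"W{name}"], d[f"b{name}"] = lin["W"], lin["b"]
    if cosine:
        d["logit_scale"] = np.full(heads, np.log(10.0))
        d["rpb"] = np.zeros(((2 * window - 1) ** 2, heads))
    return d


def _init_block(rng, c, window, schedule: StageSchedule):
    hidden = int(round(schedule.mlp_ratio * c))
    if c % schedule.kan_heads:
        raise ValueError(
            f"channels {c} not divisible by kan_heads {schedule.kan_heads}"
        )
    slice_dim = c // schedule.kan_heads
    kan = init_kan_layer(slice_dim, slice_dim, schedule.kan_grid, rng)
    m1, m2 = _init_linear(rng, c, hidden), _init_linear(rng, hidden, c)
    return {
        "attn": _init_attn(rng, c, schedule.attn_heads, window, cosine=True),
        "ln1": _init_ln(c),
        "ln2": _init_ln(c),
        "mkca": {
            "mlp": {"W1": m1["W"], "b1": m1["b"], "W2": m2["W"], "b2": m2["b"]},
            "kan": {"coeffs": kan.spline_coeffs, "base": kan.base_weight},
            "ca1": _init_attn(rng, c, schedule.attn_heads),
            "ca2": _init_attn(rng, c, schedule.attn_heads),
            "concat": _init_linear(rng, 2 * c, c),
        },
    }


def init_swin_params(
    schedule: StageSchedule,
    grid_side: int,
    rng: np.random.Generator,
    in_channels: int = 1,
) -> dict:
    """Initialize all transformer parameters for an input grid of
    ``grid_side x grid_side x in_channels``."""
    if grid_side % schedule.patch:
        raise ValueError(
            f"grid side {grid_side} not divisible by patch {schedule.patch}"
        )
    params: dict = {
        "patch_embed": {
            **_init_linear(
                rng, schedule.patch**2 * in_channels, schedule.base_channels
            ),
            "ln": _init_ln(schedule.base_channels),
        },
        "stages": [],
    }
    side = grid_side // schedule.patch
    for n, reps in enumerate(schedule.repeats):
        c = schedule.channels(n)
        w = min(schedule.window, side)
        if side % w:
            raise ValueError(
                f"stage {n}: token grid {side} not divisible by window {w}"
            )
        stage = {"blocks": [_init_block(rng, c, w, schedule) for _ in range(reps)]}
        if n < schedule.num_stages - 1:
            merge = _init_linear(rng, 4 * c, 2 * c)
            merge["ln"] = _init_ln(4 * c)
            stage["merge"] = merge
            if side % 2:
                raise ValueError(f"stage {n}: grid side {side} not even for merging")
            side //= 2
        params["stages"].append(stage)
    cf = schedule.final_channels
    params["final_ln"] = _init_ln(cf)
    head = _init_linear(rng, cf, 1, sd=0.02)
    params["head"] = {"W": head["W"][:, 0], "b": float(head["b"][0])}
    return params
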