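"""Spline-parameterized Kolmogorov-Arnold (KAN) layer.

A KAN layer replaces a dense layer's fixed nonlinearity with a learnable
univariate function per edge: each input coordinate u_i reaching output j is
passed through w_b[i,j] * silu(u_i) plus a B-spline expansion whose
coefficients are trained.  The spline basis is evaluated by the Cox-de Boor
recursion on a uniform knot grid extended k-fold beyond [lo, hi], giving
G + k basis functions for G intervals at order k.

Everything here is written against ``autograd.numpy`` so layers participate
in end-to-end reverse-mode differentiation during training; plain numpy
arrays pass through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np

__all__ = [
    "SplineGrid",
    "KanLayerParams",
    "HeadSplit",
    "bspline_basis",
    "kan_transform",
    "split_heads",
    "merge_heads",
    "init_kan_layer",
    "silu",
]


@dataclass(frozen=True)
class SplineGrid:
    """Uniform B-spline knot grid on [lo, hi]: G intervals, order k.

    The knot vector has G + 2k + 1 uniformly spaced knots, extending k
    intervals beyond each end so that all G + k order-k basis functions are
    well defined (and form a partition of unity) on [lo, hi].
    """

    lo: float = -1.0
    hi: float = 1.0
    intervals: int = 5
    order: int = 3

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"degenerate grid: lo={self.lo} >= hi={self.hi}")
        if self.intervals < 1:
            raise ValueError("grid needs at least one interval")
        if self.order < 0:
            raise ValueError("spline order must be >= 0")

    @property
    def n_basis(self) -> int:
        return self.intervals + self.order

    def knots(self) -> np.ndarray:
        G, k = self.intervals, self.order
        h = (self.hi - self.lo) / G
        return self.lo + h * np.arange(-k, G + k + 1)


def bspline_basis(x, grid: SplineGrid):
    """All G+k order-k B-spline basis values at ``x`` (Cox-de Boor recursion).

    ``x`` may be a scalar or an array of any shape; the basis axis is
    appended last.  Values are nonnegative everywhere and sum to one for x
    in [lo, hi].  Differentiable in x except exactly at knots.
    """
    t = grid.knots()
    k = grid.order
    xe = anp.expand_dims(anp.asarray(x, dtype=float) if not hasattr(x, "_value") else x, -1)
    # order 0: indicators over every knot interval (G + 2k of them)
    b = anp.where((xe >= t[:-1]) & (xe < t[1:]), 1.0, 0.0)
    for d in range(1, k + 1):
        left = (xe - t[: -(d + 1)]) / (t[d:-1] - t[: -(d + 1)])
        right = (t[d + 1:] - xe) / (t[d + 1:] - t[1:-d])
        b = left * b[..., :-1] + right * b[..., 1:]
    return b


def silu(x):
    return x / (1.0 + anp.exp(-x))


@dataclass
class KanLayerParams:
    """Edge-function parameters of one KAN layer.

    out_j = sum_i [ base_weight[i,j] * silu(u_i)
                    + sum_m spline_coeffs[i,j,m] * B_m(u_i) ]
    """

    spline_coeffs: np.ndarray  # (in_dim, out_dim, G + k)
    base_weight: np.ndarray  # (in_dim, out_dim)
    grid: SplineGrid

    @property
    def in_dim(self) -> int:
        return self.base_weight.shape[0]

    @property
    def out_dim(self) -> int:
        return self.base_weight.shape[1]

    def validate(self) -> None:
        if self.spline_coeffs.shape != (self.in_dim, self.out_dim, self.grid.n_basis):
            raise ValueError(
                f"spline_coeffs shape {self.spline_coeffs.shape} inconsistent with "
                f"({self.in_dim}, {self.out_dim}, {self.grid.n_basis})"
            )
        if not (np.all(np.isfinite(self.spline_coeffs)) and np.all(np.isfinite(self.base_weight))):
            raise ValueError("non-finite KAN parameters")


def init_kan_layer(
    in_dim: int,
    out_dim: int,
    grid: SplineGrid | None = None,
    rng: np.random.Generator | None = None,
    base_sd_scale: float = 1.0,
    spline_sd: float = 0.1,
) -> KanLayerParams:
    """Near-linear initialization: base path ~ N(0, scale/sqrt(in_dim)),
    spline coefficients ~ small noise so the layer starts close to its silu
    skeleton and the splines learn residual shape."""
    grid = grid or SplineGrid()
    rng = rng or np.random.default_rng(0)
    base = rng.normal(0.0, base_sd_scale / np.sqrt(in_dim), size=(in_dim, out_dim))
    coeffs = rng.normal(0.0, spline_sd, size=(in_dim, out_dim, grid.n_basis))
    return KanLayerParams(coeffs, base, grid)


def kan_transform(u, params: KanLayerParams):
    """Apply the KAN layer to ``u`` of shape (..., in_dim) -> (..., out_dim)."""
    shape = anp.shape(u)
    if shape[-1] != params.in_dim:
        raise ValueError(
            f"input dim {shape[-1]} does not match layer in_dim {params.in_dim}"
        )
    basis = bspline_basis(u, params.grid)  # (..., in, n_basis)
    out = anp.einsum("...i,io->...o", silu(u), params.base_weight)
    out = out + anp.einsum("...im,iom->...o", basis, params.spline_coeffs)
    return out


@dataclass(frozen=True)
class HeadSplit:
    """Channel split into eta parallel KAN heads."""

    heads: int = 16

    def __post_init__(self) -> None:
        if self.heads < 1:
            raise ValueError("head count must be >= 1")


def split_heads(values, split: HeadSplit):
    """Slice the channel axis into eta contiguous equal sub-arrays."""
    c = anp.shape(values)[-1]
    if c % split.heads != 0:
        raise ValueError(
            f"channel count {c} not divisible by head count {split.heads}"
        )
    step = c // split.heads
    return [values[..., i * step:(i + 1) * step] for i in range(split.heads)]


def merge_heads(slices):
    """Inverse of :func:`split_heads` (concatenate along channels)."""
    return anp.concatenate(slices, axis=-1)
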