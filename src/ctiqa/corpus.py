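"""Synthetic image-quality corpora.

Generates score-annotated grayscale corpora that mimic the structure of the
two kinds of data a natural-to-CT transfer IQA experiment needs:

* a *source* corpus of band-limited random textures standing in for natural
  photographs, distorted combinatorially (every pristine image x every
  distortion kind x every severity level), each record carrying a mean-opinion
  style score, and
* a *target* corpus of elliptical-phantom "axial slice" composites standing in
  for low-dose CT, each slice degraded by a random mixture of 1-3 distortion
  kinds, scored on the 0-4 diagnostic-quality scale.

Ground-truth scores decrease linearly with distortion severity (optionally
jittered), so rank recovery by a trained regressor is a checkable property.
All generation is deterministic given a seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "DistortionSpec",
    "ImageRecord",
    "ScoreRange",
    "CorpusManifest",
    "MixtureConfig",
    "DISTORTION_BANK",
    "generate_pristine",
    "apply_distortion",
    "assign_quality",
    "build_source_corpus",
    "build_target_corpus",
    "rescale_score",
]

MIN_IMAGE_SIZE = 16
DEFAULT_LEVELS = 5

# ---------------------------------------------------------------------------
# score ranges


@dataclass(frozen=True)
class ScoreRange:
    """Closed interval of valid quality scores for one domain."""

    s_min: float
    s_max: float

    def __post_init__(self) -> None:
        if not self.s_min < self.s_max:
            raise ValueError(
                f"score range requires s_min < s_max, got [{self.s_min}, {self.s_max}]"
            )

    @property
    def width(self) -> float:
        return self.s_max - self.s_min


NATURAL_MOS_RANGE = ScoreRange(1.0, 5.0)  # "1 for bad and 5 for excellent"
CT_IQA_RANGE = ScoreRange(0.0, 4.0)  # diagnostic 0 (bad) .. 4 (excellent)


def rescale_score(v: float, from_range: ScoreRange, to_range: ScoreRange) -> float:
    """Affinely map ``v`` from one score range onto another.

    Endpoints map to endpoints and order is preserved.  Values outside the
    source range (beyond a 1e-9 tolerance) are rejected.
    """
    if v < from_range.s_min - 1e-9 or v > from_range.s_max + 1e-9:
        raise ValueError(
            f"score {v} outside source range [{from_range.s_min}, {from_range.s_max}]"
        )
    t = (v - from_range.s_min) / from_range.width
    return float(to_range.s_min + t * to_range.width)


# ---------------------------------------------------------------------------
# distortion bank

# severity -> physical parameter maps; each strictly increasing in level.
# All kinds are designed to stay observable after the min-max normalization
# of the training protocol: purely affine intensity changes would be undone
# by it, so contrast scaling uses a nonlinear tone curve and the intensity
# shift is large enough that clipping saturates structure.
# Constants are perceptually calibrated: on reference phantoms the RMS
# departure from pristine is comparable across kinds at equal level (the way
# graded-distortion IQA benchmarks calibrate severity steps), so a level
# means a similar quality drop whichever kind produced it.
_SEVERITY_PARAMS: dict[str, Callable[[float], float]] = {
    "gaussian_noise": lambda lv: 0.04 * lv,        # additive noise sd
    "gaussian_blur": lambda lv: 1.1 * lv,          # blur kernel sd (pixels)
    "contrast_scale": lambda lv: 0.16 * lv,        # tone-curve gamma excess
    "intensity_shift": lambda lv: 0.055 * lv,      # brightness shift (clips)
    "block_average": lambda lv: 0.19 * lv,         # blend weight toward 8x8 means
}

_BLOCK_SIZE = 8  # fixed pooling block for the blockiness distortion

DISTORTION_KINDS = tuple(_SEVERITY_PARAMS)
DISTORTION_BANK = _SEVERITY_PARAMS  # public alias

# Distortion *types* extend the 5 parametric kinds with severity-profile
# variants (a per-type multiplier on the physical severity parameter), the
# way photographic IQA benchmarks enumerate many named distortions that are
# parameter variations of a few families.  5 kinds x 5 profiles = 25 types.
_VARIANT_SCALES = (1.0, 0.6, 1.4, 0.8, 1.2)


def distortion_type_bank(n_types: int) -> list[tuple[str, str, float]]:
    """First ``n_types`` entries of the (label, kind, param_scale) bank."""
    bank = [
        (kind if s == 1.0 else f"{kind}_x{s:g}", kind, s)
        for s in _VARIANT_SCALES
        for kind in DISTORTION_KINDS
    ]
    if n_types > len(bank):
        raise ValueError(
            f"n_types={n_types} exceeds the implemented distortion bank "
            f"({len(bank)} types = {len(DISTORTION_KINDS)} kinds x "
            f"{len(_VARIANT_SCALES)} severity profiles)"
        )
    return bank[:n_types]


@dataclass(frozen=True)
class DistortionSpec:
    """One graded degradation: a kind, a severity level and a noise seed.

    ``level`` may be fractional (mixture corpora draw continuous severities);
    level 0 means "no distortion" and always returns the input unchanged.
    """

    kind: str
    level: float
    seed: int = 0
    n_levels: int = DEFAULT_LEVELS
    param_scale: float = 1.0  # severity-profile variant multiplier

    def __post_init__(self) -> None:
        if self.kind not in _SEVERITY_PARAMS:
            raise ValueError(
                f"unknown distortion kind {self.kind!r}; supported: {sorted(_SEVERITY_PARAMS)}"
            )
        if not 0 <= self.level <= self.n_levels:
            raise ValueError(
                f"severity level {self.level} outside [0, {self.n_levels}]"
            )
        if self.param_scale <= 0:
            raise ValueError("param_scale must be > 0")

    @property
    def parameter(self) -> float:
        """The physical severity parameter for this kind at this level."""
        return self.param_scale * _SEVERITY_PARAMS[self.kind](self.level)


def apply_distortion(image: np.ndarray, spec: DistortionSpec) -> np.ndarray:
    """Apply one distortion to a [0,1] grayscale image; output clipped to [0,1].

    Same (kind, level, seed, image) always yields the identical output.
    """
    image = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(image)):
        raise ValueError("input image contains non-finite pixels")
    if spec.level == 0:
        return image.copy()
    p = spec.parameter
    if spec.kind == "gaussian_noise":
        rng = np.random.default_rng(spec.seed)
        out = image + rng.normal(0.0, p, size=image.shape)
    elif spec.kind == "gaussian_blur":
        # 'reflect' (half-sample symmetric) boundary keeps the mean exact
        out = ndimage.gaussian_filter(image, sigma=p, mode="reflect")
    elif spec.kind == "contrast_scale":
        # nonlinear contrast compression (gamma tone curve); unlike an affine
        # squeeze this is not undone by later min-max renormalization
        out = np.power(np.clip(image, 0.0, 1.0), 1.0 + p)
    elif spec.kind == "intensity_shift":
        rng = np.random.default_rng(spec.seed)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        out = image + sign * p
    elif spec.kind == "block_average":
        # blend toward the block-mean image: MSE grows as the square of the
        # blend weight, so severity->magnitude monotonicity is structural
        alpha = min(p, 1.0)
        out = (1.0 - alpha) * image + alpha * _block_average(image, _BLOCK_SIZE)
    else:  # pragma: no cover - guarded by DistortionSpec validation
        raise ValueError(f"unknown distortion kind {spec.kind!r}")
    return np.clip(out, 0.0, 1.0)


def _block_average(image: np.ndarray, b: int) -> np.ndarray:
    """Replace each b x b block by its mean (edge blocks use partial means)."""
    if b == 1:
        return image.copy()
    h, w = image.shape
    hp, wp = -(-h // b) * b, -(-w // b) * b
    pad = np.pad(image, ((0, hp - h), (0, wp - w)), mode="edge")
    red = pad.reshape(hp // b, b, wp // b, b).mean(axis=(1, 3))
    return np.kron(red, np.ones((b, b)))[:h, :w]


def assign_quality(
    spec: DistortionSpec,
    score_range: ScoreRange = CT_IQA_RANGE,
    jitter_sd: float = 0.1,
    seed: int | None = None,
) -> float:
    """Severity-linear ground-truth score with optional Gaussian jitter.

    score = s_max - width * level / L (+ jitter), clipped to the range.  With
    ``jitter_sd = 0`` the map is strictly decreasing in level: level 0
    (pristine) scores s_max, level L scores s_min.
    """
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    s = score_range.s_max - score_range.width * (spec.level / spec.n_levels)
    if jitter_sd > 0:
        rng = np.random.default_rng(spec.seed if seed is None else seed)
        s += rng.normal(0.0, jitter_sd)
    return float(np.clip(s, score_range.s_min, score_range.s_max))


# ---------------------------------------------------------------------------
# pristine image synthesis


def generate_pristine(
    domain: str, n: int, size: int, seed: int
) -> list[np.ndarray]:
    """Generate ``n`` pristine ``size x size`` images in [0,1].

    ``source`` images are band-limited random textures (power-law spectra of
    per-image random slope), statistically akin to natural photographs;
    ``target`` images are smoothed elliptical-phantom composites resembling
    axial body CT slices: a body outline enclosing randomly placed internal
    structures of varying attenuation.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if size < MIN_IMAGE_SIZE:
        raise ValueError(
            f"image size {size} below the supported minimum {MIN_IMAGE_SIZE}"
        )
    if domain not in ("source", "target"):
        raise ValueError(f"domain must be 'source' or 'target', got {domain!r}")
    rng = np.random.default_rng(seed)
    maker = _texture_image if domain == "source" else _phantom_image
    return [maker(size, rng) for _ in range(n)]


def _texture_image(size: int, rng: np.random.Generator) -> np.ndarray:
    """Band-limited texture: white noise shaped by a 1/f^alpha spectrum."""
    alpha = rng.uniform(1.0, 2.2)
    noise = rng.normal(size=(size, size))
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.fftfreq(size)[None, :]
    f = np.sqrt(fy**2 + fx**2)
    f[0, 0] = 1.0
    spectrum = np.fft.fft2(noise) / f**alpha
    img = np.real(np.fft.ifft2(spectrum))
    lo, hi = img.min(), img.max()
    return (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)


def _phantom_image(size: int, rng: np.random.Generator) -> np.ndarray:
    """Elliptical body phantom with internal soft-tissue-like structures.

    Variability is moderate by design: slices in a curated benchmark come
    from a limited pool of patients and one anatomical region, so content
    varies far less than the degradations applied to it.
    """
    yy, xx = np.mgrid[0:size, 0:size]
    cy, cx = size / 2 + rng.uniform(-0.02, 0.02, 2) * size
    ay = size * rng.uniform(0.38, 0.42)
    ax = size * rng.uniform(0.42, 0.46)
    theta = rng.uniform(-0.15, 0.15)
    body = _ellipse_mask(yy, xx, cy, cx, ay, ax, theta)
    img = np.where(body, 0.35, 0.02).astype(np.float64)
    # internal structures: organs / vessels / bone-like inclusions
    for _ in range(rng.integers(5, 8)):
        ecy = cy + rng.uniform(-0.5, 0.5) * ay
        ecx = cx + rng.uniform(-0.5, 0.5) * ax
        eay = size * rng.uniform(0.04, 0.12)
        eax = size * rng.uniform(0.04, 0.12)
        eth = rng.uniform(-np.pi, np.pi)
        mask = _ellipse_mask(yy, xx, ecy, ecx, eay, eax, eth) & body
        img[mask] += rng.uniform(-0.12, 0.3)
    img = ndimage.gaussian_filter(img, sigma=size / 64.0, mode="reflect")
    img += rng.normal(0.0, 0.008, size=img.shape)  # faint acquisition texture
    return np.clip(img, 0.0, 1.0)


def _ellipse_mask(yy, xx, cy, cx, ay, ax, theta) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    u = (yy - cy) * c + (xx - cx) * s
    v = -(yy - cy) * s + (xx - cx) * c
    return (u / ay) ** 2 + (v / ax) ** 2 <= 1.0


# ---------------------------------------------------------------------------
# records and manifests


@dataclass
class ImageRecord:
    """One grayscale image, its quality score and provenance."""

    image_id: str
    pixels: np.ndarray
    score: float
    domain: str
    distortions: tuple[DistortionSpec, ...] = ()
    split: str = "train"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError(f"record {self.image_id}: non-finite pixels")
        if self.split not in ("train", "val", "test"):
            raise ValueError(f"record {self.image_id}: bad split {self.split!r}")


@dataclass
class CorpusManifest:
    """A list of records plus the domain, score range and generator config."""

    records: list[ImageRecord]
    domain: str
    score_range: ScoreRange
    generator_config: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __post_init__(self) -> None:
        ids = [r.image_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate image_id in manifest")
        lo, hi = self.score_range.s_min - 1e-9, self.score_range.s_max + 1e-9
        bad = [r.image_id for r in self.records if not lo <= r.score <= hi]
        if bad:
            raise ValueError(f"scores outside declared range for: {bad[:5]}")

    def subset(self, split: str) -> "CorpusManifest":
        return CorpusManifest(
            [r for r in self.records if r.split == split],
            self.domain,
            self.score_range,
            dict(self.generator_config, subset=split),
        )

    def to_dataframe(self):
        import pandas as pd

        rows = [
            {
                "image_id": r.image_id,
                "domain": r.domain,
                "score": r.score,
                "distortion_kinds": "|".join(d.kind for d in r.distortions),
                "severity_levels": "|".join(f"{d.level:g}" for d in r.distortions),
                "split": r.split,
                "seed": r.distortions[0].seed if r.distortions else 0,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows)

    def content_hash(self) -> str:
        """SHA-256 over pixels, scores and metadata; bit-identical regeneration
        under the same seed hashes equal."""
        h = hashlib.sha256()
        for r in self.records:
            h.update(r.image_id.encode())
            h.update(np.ascontiguousarray(r.pixels).tobytes())
            h.update(np.float64(r.score).tobytes())
            h.update(r.split.encode())
            for d in r.distortions:
                h.update(f"{d.kind}:{d.level}:{d.seed}".encode())
        return h.hexdigest()


def _split_for(index: int, n_total: int, fractions=(0.7, 0.15, 0.15)) -> str:
    """Deterministic contiguous split assignment by index."""
    n_train = int(round(fractions[0] * n_total))
    n_val = int(round(fractions[1] * n_total))
    if index < n_train:
        return "train"
    if index < n_train + n_val:
        return "val"
    return "test"


def build_source_corpus(
    n_pristine: int,
    n_types: int,
    n_levels: int = DEFAULT_LEVELS,
    size: int = 64,
    seed: int = 0,
    jitter_sd: float = 0.1,
    score_range: ScoreRange = CT_IQA_RANGE,
    split_fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
) -> CorpusManifest:
    """Combinatorial source (natural-image-like) corpus.

    Every pristine texture is degraded by every requested distortion kind at
    every severity level: exactly n_pristine * n_types * n_levels records.
    Splits are assigned per pristine image so that all degraded versions of
    one image share a split.
    """
    if min(n_pristine, n_types, n_levels) < 1:
        raise ValueError("n_pristine, n_types and n_levels must all be >= 1")
    types = distortion_type_bank(n_types)
    pristine = generate_pristine("source", n_pristine, size, seed)
    seq = np.random.SeedSequence([seed, 0x5EED])
    child_seeds = seq.generate_state(n_pristine * n_types * n_levels * 2)
    records: list[ImageRecord] = []
    idx = 0
    for i, img in enumerate(pristine):
        split = _split_for(i, n_pristine, split_fractions)
        for label, kind, scale in types:
            for level in range(1, n_levels + 1):
                spec = DistortionSpec(
                    kind, float(level), int(child_seeds[idx] % 2**31), n_levels,
                    param_scale=scale,
                )
                score = assign_quality(
                    spec, score_range, jitter_sd,
                    seed=int(child_seeds[idx + 1] % 2**31),
                )
                records.append(
                    ImageRecord(
                        image_id=f"src_{i:04d}_{label}_{level}",
                        pixels=apply_distortion(img, spec),
                        score=score,
                        domain="source",
                        distortions=(spec,),
                        split=split,
                    )
                )
                idx += 2
    cfg = dict(
        kind="source",
        n_pristine=n_pristine,
        n_types=n_types,
        n_levels=n_levels,
        size=size,
        seed=seed,
        jitter_sd=jitter_sd,
        score_range=[score_range.s_min, score_range.s_max],
        split_fractions=list(split_fractions),
    )
    return CorpusManifest(records, "source", score_range, cfg)


@dataclass(frozen=True)
class MixtureConfig:
    """How target-slice degradations are mixed.

    Each slice receives ``k`` in [k_min, k_max] distinct distortion kinds.
    A target score is drawn stratified round-robin across the four unit bins
    of the 0-4 scale (so every bin is populated deterministically), per-kind
    scores scatter around it with zero mean, and severities are the linear
    inverse of the score map.  The record score is the mean of per-kind
    scores, optionally jittered.
    """

    kinds: tuple[str, ...] = DISTORTION_KINDS
    k_min: int = 2
    k_max: int = 3
    per_kind_spread: float = 0.3
    jitter_sd: float = 0.1
    n_levels: int = DEFAULT_LEVELS


def build_target_corpus(
    n_slices: int,
    size: int = 64,
    seed: int = 0,
    mixture: MixtureConfig | None = None,
    score_range: ScoreRange = CT_IQA_RANGE,
    split_fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
) -> CorpusManifest:
    """Target (CT-like) corpus: phantoms degraded by 1-3 mixed distortions."""
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    mix = mixture or MixtureConfig()
    pristine = generate_pristine("target", n_slices, size, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7A26E7]))
    n_bins = int(score_range.width)  # four unit bins on the 0-4 scale
    L = mix.n_levels
    records: list[ImageRecord] = []
    for i, img in enumerate(pristine):
        b = i % n_bins
        k = int(rng.integers(mix.k_min, mix.k_max + 1))
        if k == 1:
            s_target = rng.uniform(b, b + 1)
            per_kind = np.array([s_target])
        else:
            m = min(mix.per_kind_spread, 0.45)
            s_target = rng.uniform(b + m, b + 1 - m)
            deltas = rng.uniform(-m, m, size=k)
            per_kind = s_target + (deltas - deltas.mean())
        kinds = list(rng.choice(mix.kinds, size=k, replace=False))
        # apply in the physical acquisition order (tone scale, resolution
        # loss, reconstruction blockiness, then quantum noise) so later
        # stages never erase the perceptual trace of earlier ones
        kinds.sort(key=_CANONICAL_ORDER.index)
        specs = []
        out = img
        for kind, s_j in zip(kinds, per_kind):
            level = float(L * (1.0 - (s_j - score_range.s_min) / score_range.width))
            spec = DistortionSpec(
                kind, min(max(level, 0.0), L), int(rng.integers(2**31)), L
            )
            out = apply_distortion(out, spec)
            specs.append(spec)
        score = float(np.mean(per_kind))
        if mix.jitter_sd > 0:
            score += rng.normal(0.0, mix.jitter_sd)
        score = float(np.clip(score, score_range.s_min, score_range.s_max))
        records.append(
            ImageRecord(
                image_id=f"tgt_{i:04d}",
                pixels=out,
                score=score,
                domain="target",
                distortions=tuple(specs),
                split=_block_split(i, n_bins, split_fractions),
            )
        )
    cfg = dict(
        kind="target",
        n_slices=n_slices,
        size=size,
        seed=seed,
        mixture=asdict(mix),
        score_range=[score_range.s_min, score_range.s_max],
        split_fractions=list(split_fractions),
    )
    return CorpusManifest(records, "target", score_range, cfg)


_CANONICAL_ORDER = [
    "contrast_scale", "intensity_shift", "gaussian_blur",
    "block_average", "gaussian_noise",
]

_SPLIT_CYCLE = 20  # blocks per split-assignment cycle


def _block_split(i: int, n_bins: int, fractions) -> str:
    """Stratified split: records come in blocks of one-per-score-bin; whole
    blocks are assigned to splits on a repeating cycle so every split sees
    every score bin once it holds at least one full block."""
    pos = ((i // n_bins) % _SPLIT_CYCLE) / _SPLIT_CYCLE
    if pos < fractions[0]:
        return "train"
    if pos < fractions[0] + fractions[1]:
        return "val"
    return "test"


def severity_mse_curve(
    image: np.ndarray, kind: str, n_levels: int = DEFAULT_LEVELS, seed: int = 0
) -> np.ndarray:
    """Pixel-MSE against the pristine image at each severity level 1..L."""
    return np.array(
        [
            float(np.mean((apply_distortion(image, DistortionSpec(kind, float(l), seed, n_levels)) - image) ** 2))
            for l in range(1, n_levels + 1)
        ]
    )
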