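"""Encode intensity grids into fixed-length feature vectors.

A grid becomes an encoder-ready image by: intensity transform, per-image
max normalization to [0, 1], bilinear resize to the encoder's input side S,
then triplication of the gray channel into three identical RGB channels —
the preparation pretrained natural-image networks expect. Encoders are
pluggable: any callable taking an S x S x 3 array and returning a length-D
vector, described by an :class:`EncoderSpec`.

The built-in :func:`reference_encoder` is a deterministic stand-in for a
pretrained network: it mean-pools the first channel into P x P blocks and
applies a fixed seeded random linear projection to D dimensions, so the
whole pipeline is testable offline and bit-reproducible. Adapters for
external pretrained models (e.g. TensorFlow Hub modules) plug in through
:func:`load_external_encoder`.

Bilinear resampling uses the half-pixel-center (align-corners-false)
convention throughout.
"""

from __future__ import annotations

import importlib
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import EncoderError, OptionalDependencyError, ValidationError
from .rasterize import RasterGrid, apply_transform
from .sources import MS1, Source

__all__ = [
    "EncoderSpec",
    "EncoderInput",
    "FeatureVector",
    "bilinear_resize",
    "prepare_image",
    "ReferenceEncoder",
    "reference_encoder",
    "encode_grid",
    "load_external_encoder",
]


@dataclass(frozen=True)
class EncoderSpec:
    """Contract of an image-to-vector encoder.

    input_size: square input side S (pretrained families use e.g. 224, 299,
        331); output_dim: feature-vector length D; pixel_scaling: value
        range the encoder expects ("unit_interval" [0,1] or
        "symmetric_unit" [-1,1]).
    """

    name: str
    input_size: int
    output_dim: int
    pixel_scaling: str = "unit_interval"

    def __post_init__(self) -> None:
        if self.input_size < 8:
            raise ValidationError(f"input_size must be >= 8, got {self.input_size}")
        if self.output_dim < 1:
            raise ValidationError(f"output_dim must be >= 1, got {self.output_dim}")
        if self.pixel_scaling not in ("unit_interval", "symmetric_unit"):
            raise ValidationError(f"unknown pixel_scaling {self.pixel_scaling!r}")


@dataclass
class EncoderInput:
    """Prepared S x S x 3 image ready for an encoder."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3 or (
            self.pixels.shape[0] != self.pixels.shape[1]
        ):
            raise ValidationError(f"expected S x S x 3 pixels, got {self.pixels.shape}")


@dataclass
class FeatureVector:
    """One grid's encoding: a finite length-D vector plus provenance."""

    values: np.ndarray
    encoder_name: str
    source: Source = field(default_factory=lambda: MS1)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"non-finite encoding from {self.encoder_name!r}")

    def __len__(self) -> int:
        return len(self.values)


def bilinear_resize(image: np.ndarray, out_size: int) -> np.ndarray:
    """Bilinearly resample a 2-D image to out_size x out_size.

    Half-pixel-center convention: output pixel i samples source coordinate
    (i + 0.5) * G / S - 0.5, clamped to the image, with separable linear
    interpolation between the four neighbours.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValidationError("bilinear_resize expects a 2-D image")
    in_h, in_w = image.shape

    def axis_weights(n_in: int, n_out: int):
        coords = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
        coords = np.clip(coords, 0.0, n_in - 1.0)
        lo = np.floor(coords).astype(int)
        hi = np.minimum(lo + 1, n_in - 1)
        frac = coords - lo
        return lo, hi, frac

    r0, r1, fr = axis_weights(in_h, out_size)
    c0, c1, fc = axis_weights(in_w, out_size)
    top = image[r0][:, c0] * (1 - fc) + image[r0][:, c1] * fc
    bot = image[r1][:, c0] * (1 - fc) + image[r1][:, c1] * fc
    return top * (1 - fr[:, None]) + bot * fr[:, None]


def prepare_image(
    grid: RasterGrid, spec: EncoderSpec, transform: str = "linear_max"
) -> EncoderInput:
    """Turn a grid into the encoder's expected input.

    Steps: intensity transform, scale to [0, 1] by the per-image maximum
    (an all-zero grid stays all zero), bilinear resize to S x S, triplicate
    the gray channel; symmetric_unit then maps [0, 1] onto [-1, 1].
    """
    values = apply_transform(grid.values, transform)
    peak = float(values.max())
    if peak > 0:
        values = values / peak
    resized = bilinear_resize(values, spec.input_size)
    pixels = np.repeat(resized[:, :, None], 3, axis=2)
    if spec.pixel_scaling == "symmetric_unit":
        pixels = pixels * 2.0 - 1.0
    return EncoderInput(pixels)


class ReferenceEncoder:
    """Deterministic built-in encoder: block mean-pooling + fixed random projection.

    The first channel of the prepared image is mean-pooled into pool x pool
    blocks, flattened, and multiplied by a projection matrix drawn once from
    the seed; the same seed always yields the same projection, so encodings
    are bit-reproducible. The map is linear in the pooled image.
    """

    def __init__(
        self,
        seed: int,
        output_dim: int,
        pool: int = 32,
        input_size: int = 224,
        pixel_scaling: str = "unit_interval",
    ) -> None:
        if input_size % pool != 0:
            raise ValidationError(
                f"pool ({pool}) must divide the input size ({input_size})"
            )
        self.seed = int(seed)
        self.pool = int(pool)
        self.spec = EncoderSpec(
            name=f"reference-s{seed}-d{output_dim}-p{pool}",
            input_size=input_size,
            output_dim=output_dim,
            pixel_scaling=pixel_scaling,
        )
        rng = np.random.default_rng(self.seed)
        n_blocks = pool * pool
        self._projection = rng.standard_normal((n_blocks, output_dim)) / np.sqrt(n_blocks)

    def __call__(self, pixels: np.ndarray) -> np.ndarray:
        pixels = np.asarray(pixels, dtype=float)
        side = self.spec.input_size
        if pixels.shape != (side, side, 3):
            raise EncoderError(
                f"{self.spec.name}: expected {(side, side, 3)} input, got {pixels.shape}"
            )
        block = side // self.pool
        channel = pixels[:, :, 0]
        pooled = channel.reshape(self.pool, block, self.pool, block).mean(axis=(1, 3))
        return pooled.ravel() @ self._projection


def reference_encoder(
    seed: int, output_dim: int, pool: int = 32, input_size: int = 224
) -> ReferenceEncoder:
    """Build the deterministic reference encoder (see :class:`ReferenceEncoder`)."""
    return ReferenceEncoder(seed, output_dim, pool=pool, input_size=input_size)


def encode_grid(grid: RasterGrid, encoder, transform: str = "linear_max") -> FeatureVector:
    """Prepare a grid for ``encoder`` and return its feature vector."""
    spec: EncoderSpec = encoder.spec
    prepared = prepare_image(grid, spec, transform)
    try:
        values = np.asarray(encoder(prepared.pixels), dtype=float).ravel()
    except Exception as exc:  # noqa: BLE001 - wrap with grid provenance
        raise EncoderError(f"encoder {spec.name!r} failed on grid {grid.source}: {exc}") from exc
    if values.shape != (spec.output_dim,):
        raise EncoderError(
            f"encoder {spec.name!r} returned {values.shape[0] if values.ndim else 0} "
            f"values, declared output_dim is {spec.output_dim}"
        )
    return FeatureVector(values, spec.name, grid.source)


class _ExternalEncoder:
    """Adapter giving an arbitrary image->vector callable the encoder contract."""

    def __init__(self, fn: Callable[[np.ndarray], np.ndarray], spec: EncoderSpec):
        self.spec = spec
        self._fn = fn

    def __call__(self, pixels: np.ndarray) -> np.ndarray:
        return np.asarray(self._fn(pixels), dtype=float).ravel()


def load_external_encoder(uri: str, spec: EncoderSpec):
    """Load an external encoder behind the standard contract.

    ``python:<module>:<attribute>`` resolves an importable factory that is
    called with the spec and must return an image->vector callable — the
    hook for locally wrapped pretrained models. Any other URI is treated as
    a TensorFlow Hub handle and requires the optional ``tensorflow_hub``
    backend. The declared output_dim is validated by encoding a zero image.
    """
    if uri.startswith("python:"):
        try:
            _, module_name, attr = uri.split(":", 2)
        except ValueError as exc:
            raise ValidationError(f"malformed python encoder uri {uri!r}") from exc
        try:
            factory = getattr(importlib.import_module(module_name), attr)
        except (ImportError, AttributeError) as exc:
            raise OptionalDependencyError(f"cannot resolve encoder factory {uri!r}: {exc}") from exc
        encoder = _ExternalEncoder(factory(spec), spec)
    else:
        try:
            hub = importlib.import_module("tensorflow_hub")
        except ImportError as exc:
            raise OptionalDependencyError(
                "loading TensorFlow Hub encoders requires the optional "
                "'tensorflow_hub' backend; the built-in reference encoder "
                "needs no external dependency"
            ) from exc
        model = hub.load(uri)
        encoder = _ExternalEncoder(
            lambda px: np.asarray(model(px[None, ...])).ravel(), spec
        )

    probe = encoder(np.zeros((spec.input_size, spec.input_size, 3)))
    if probe.shape != (spec.output_dim,):
        raise ValidationError(
            f"encoder at {uri!r} produced {probe.size} values but the spec "
            f"declares output_dim={spec.output_dim}"
        )
    return encoder
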