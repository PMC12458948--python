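"""Frozen encoders mapping feature images (or raw time series) to unit-norm vectors.

Two backends are registered:

``mock_projection``
    A deterministic, download-free encoder: grayscale block-average
    downsampling to a fixed grid, flattening, multiplication by a seeded
    fixed Gaussian random matrix, then L2 normalization.  It preserves
    relative image similarity (a Johnson-Lindenstrauss-style projection of
    the blurred pixel vector) and makes the whole pipeline testable offline.

``pretrained_vl``
    The interface for a frozen pretrained vision-language image tower
    (CLIP/SigLIP family).  Loading requires locally available weights; when
    they are absent the loader raises a "weights unavailable" error and
    directs the caller to mock mode.

L2 normalization happens inside this module, so downstream cosine
similarity reduces to a dot product.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from spikesight.ephys_features import NeuronRecord
from spikesight.imaging import FeatureImage

_MOCK_GRID = 32  # downsample grid (pixels per side) for the mock backend


@dataclass(frozen=True)
class EncoderHandle:
    """A loaded frozen encoder.  ``embed`` calls never mutate weights."""

    backend_id: str
    embedding_dim: int
    deterministic: bool
    weights_ref: str | None = None
    _projection: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.embedding_dim <= 0:
            raise ValueError("embedding_dim must be positive")


@dataclass(frozen=True)
class EmbeddingVector:
    """A fixed-dimension embedding; unit L2 norm unless ``zero_norm_flag``."""

    values: np.ndarray
    source: str = "image"
    zero_norm_flag: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if not np.all(np.isfinite(v)):
            raise ValueError("embedding values must be finite")


def load_encoder(spec: str | dict) -> EncoderHandle:
    """Load a registered encoder backend.

    ``spec`` is a backend id string or a dict with keys ``backend``
    (``mock_projection`` or ``pretrained_vl``), ``dim`` and ``seed`` for the
    mock backend, or ``weights`` for the pretrained one.
    """
    if isinstance(spec, str):
        spec = {"backend": spec}
    backend = spec.get("backend")
    if backend == "mock_projection":
        dim = int(spec.get("dim", 64))
        seed = int(spec.get("seed", 0))
        if dim <= 0:
            raise ValueError("embedding_dim must be positive")
        rng = np.random.default_rng(seed)
        proj = rng.standard_normal((dim, _MOCK_GRID * _MOCK_GRID)) / np.sqrt(dim)
        return EncoderHandle(
            backend_id="mock_projection",
            embedding_dim=dim,
            deterministic=True,
            _projection=proj,
        )
    if backend == "pretrained_vl":
        weights = spec.get("weights")
        if weights is None:
            raise RuntimeError(
                "weights unavailable: no local checkpoint was provided for the "
                "pretrained_vl backend; pass weights=<path> or run with the "
                "mock_projection encoder"
            )
        raise RuntimeError(
            "weights unavailable: loading pretrained vision-language weights "
            f"from {weights!r} requires a local torch + open-clip install; "
            "run with the mock_projection encoder"
        )
    raise ValueError(f"unregistered encoder backend {backend!r}")


def _grayscale_grid(pixels: np.ndarray, grid: int = _MOCK_GRID) -> np.ndarray:
    """Block-average grayscale downsample to a grid x grid array in [0, 1]."""
    gray = pixels.astype(float).mean(axis=2) / 255.0
    h, w = gray.shape
    # crop to a multiple of the grid, then average blocks
    bh, bw = h // grid, w // grid
    if bh == 0 or bw == 0:
        raise ValueError("invalid image: smaller than the downsample grid")
    gray = gray[: bh * grid, : bw * grid]
    return gray.reshape(grid, bh, grid, bw).mean(axis=(1, 3))


def embed_image(handle: EncoderHandle, image: FeatureImage) -> EmbeddingVector:
    """Embed a feature image into a unit-norm vector."""
    if handle.backend_id != "mock_projection":
        raise RuntimeError("weights unavailable: only mock_projection can embed here")
    px = image.pixels
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError("invalid image")
    flat = _grayscale_grid(px).ravel()
    flat = flat - flat.mean()  # background-invariant contrast signal
    raw = handle._projection @ flat
    return _normalize(raw, source="image")


def embed_timeseries(record: NeuronRecord, modalities=("waveform", "isi", "acg")) -> EmbeddingVector:
    """Concatenated z-scored raw feature series baseline (no image encoder).

    Each requested modality (peak-channel waveform samples, ISI counts, ACG
    counts) is z-scored independently, concatenated, then L2-normalized.
    A zero-variance segment is replaced by zeros; if everything is zero the
    result carries ``zero_norm_flag``.
    """
    parts = []
    for m in modalities:
        if m == "waveform":
            x = np.asarray(record.template.peak_waveform, dtype=float)
        elif m == "isi":
            x = np.asarray(record.isi.counts, dtype=float)
        elif m == "acg":
            x = np.asarray(record.acg.counts, dtype=float)
        else:
            raise ValueError(f"unknown modality {m!r}")
        sd = x.std()
        parts.append((x - x.mean()) / sd if sd > 0 else np.zeros_like(x))
    raw = np.concatenate(parts)
    return _normalize(raw, source="timeseries")


def _normalize(raw: np.ndarray, source: str) -> EmbeddingVector:
    norm = np.linalg.norm(raw)
    if norm == 0:
        return EmbeddingVector(raw, source=source, zero_norm_flag=True)
    return EmbeddingVector(raw / norm, source=source)
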