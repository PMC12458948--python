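"""Byte-deterministic rendering of spike features into encoder-ready images.

Plots are rasterized directly into a uint8 pixel grid with a fixed,
anti-aliasing-free polyline rasterizer and no text or axes, so identical
(feature, config) pairs produce byte-identical images on every platform.
The default palette follows the blue/orange/green convention spike-analysis
toolkits use for waveform / ISI / ACG panels.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from spikesight.ephys_features import NeuronRecord

MODALITIES = ("waveform", "isi", "acg")

_DEFAULT_COLORS = {
    "waveform": (31, 119, 180),   # blue
    "isi": (255, 127, 14),        # orange
    "acg": (44, 160, 44),         # green
}


@dataclass(frozen=True)
class RenderConfig:
    """Rendering parameters shared by every feature image.

    ``normalization`` is either ``"minmax"`` (per-image min-max to the full
    plotting area) or ``"fixed"`` (map ``fixed_range`` to the plotting
    area, clipping outside values).  ``axes_policy`` stays ``"off"`` by
    default so images contain no text and are locale-independent.
    """

    image_size: tuple[int, int] = (224, 224)  # (height, width) px
    line_colors: dict = field(default_factory=lambda: dict(_DEFAULT_COLORS))
    background: tuple[int, int, int] = (255, 255, 255)
    axes_policy: str = "off"
    normalization: str = "minmax"
    fixed_range: tuple[float, float] = (-1.0, 1.0)
    composite_layout: tuple[str, ...] = ("waveform", "isi", "acg")
    margin_px: int = 8

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h <= 0 or w <= 0:
            raise ValueError("image_size entries must be positive")
        if self.normalization not in ("minmax", "fixed"):
            raise ValueError("normalization must be 'minmax' or 'fixed'")
        for m in self.composite_layout:
            if m not in MODALITIES:
                raise ValueError(f"unknown modality {m!r}")

    def hash(self) -> str:
        payload = repr(
            (
                self.image_size,
                sorted(self.line_colors.items()),
                self.background,
                self.axes_policy,
                self.normalization,
                self.fixed_range,
                self.composite_layout,
                self.margin_px,
            )
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass(frozen=True)
class FeatureImage:
    """A rendered feature panel: H x W x 3 uint8 pixels plus provenance."""

    pixels: np.ndarray
    modality: str
    unit_id: object
    render_config_hash: str
    flat_warning: bool = False

    def __post_init__(self) -> None:
        px = np.ascontiguousarray(self.pixels, dtype=np.uint8)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("pixels must be H x W x 3")

    def save_png(self, path) -> None:
        Image.fromarray(self.pixels, mode="RGB").save(path, format="PNG")

    @classmethod
    def load_png(cls, path, modality="waveform", unit_id=None, config_hash="") -> "FeatureImage":
        px = np.asarray(Image.open(path).convert("RGB"))
        return cls(px, modality, unit_id, config_hash)


def _feature_series(record: NeuronRecord, modality: str) -> np.ndarray:
    if modality == "waveform":
        return np.asarray(record.template.peak_waveform, dtype=float)
    if modality == "isi":
        return np.asarray(record.isi.counts, dtype=float)
    if modality == "acg":
        return np.asarray(record.acg.counts, dtype=float)
    raise ValueError(f"unknown modality {modality!r}")


def _draw_polyline(px: np.ndarray, rows: np.ndarray, cols: np.ndarray, color) -> None:
    """Connect consecutive (row, col) vertices with dense integer segments."""
    color = np.asarray(color, dtype=np.uint8)
    h, w = px.shape[:2]
    for i in range(len(rows) - 1):
        r0, c0, r1, c1 = rows[i], cols[i], rows[i + 1], cols[i + 1]
        n = int(max(abs(r1 - r0), abs(c1 - c0))) + 1
        rr = np.round(np.linspace(r0, r1, n)).astype(int)
        cc = np.round(np.linspace(c0, c1, n)).astype(int)
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        px[rr[keep], cc[keep]] = color
    if len(rows) == 1:
        r, c = int(rows[0]), int(cols[0])
        if 0 <= r < h and 0 <= c < w:
            px[r, c] = color


def render_feature(
    record: NeuronRecord, modality: str, config: RenderConfig | None = None
) -> FeatureImage:
    """Render one feature modality of a unit as a deterministic image.

    The trace spans the full plotting area (inside ``margin_px``) under the
    configured normalization; larger feature values map to higher plot
    positions, i.e. smaller raster row indices.  A flat or empty feature is
    rendered as a horizontal mid-height baseline with ``flat_warning`` set.
    """
    config = config or RenderConfig()
    series = _feature_series(record, modality)
    h, w = config.image_size
    m = config.margin_px
    px = np.empty((h, w, 3), dtype=np.uint8)
    px[:] = np.asarray(config.background, dtype=np.uint8)

    flat = False
    if series.size == 0:
        series = np.zeros(2)
    if config.normalization == "minmax":
        lo, hi = float(series.min()), float(series.max())
    else:
        lo, hi = config.fixed_range
    if hi <= lo:
        flat = True
        unit = np.full(series.size, 0.5)
    else:
        unit = np.clip((series - lo) / (hi - lo), 0.0, 1.0)

    top, bottom = m, h - 1 - m
    rows = np.round(bottom - unit * (bottom - top)).astype(int)
    if series.size == 1:
        cols = np.array([(w - 1) // 2])
        rows = rows[:1]
    else:
        cols = np.round(np.linspace(m, w - 1 - m, series.size)).astype(int)
    color = config.line_colors.get(modality, (0, 0, 0))
    _draw_polyline(px, rows, cols, color)
    return FeatureImage(px, modality, record.unit_id, config.hash(), flat_warning=flat)


def compose_panel(images: list[FeatureImage], config: RenderConfig | None = None) -> FeatureImage:
    """Concatenate feature images side by side and resize to the config size.

    All inputs must share one height.  Resizing uses box (area-average)
    resampling, which is deterministic and preserves thin polylines when
    downsizing a wide concatenated panel.
    """
    config = config or RenderConfig()
    if not images:
        raise ValueError("compose_panel needs >= 1 image")
    heights = {im.pixels.shape[0] for im in images}
    if len(heights) != 1:
        raise ValueError("layout mismatch: images have mixed heights")
    wide = np.concatenate([im.pixels for im in images], axis=1)
    h, w = config.image_size
    resized = np.asarray(
        Image.fromarray(wide, mode="RGB").resize((w, h), resample=Image.BOX)
    )
    return FeatureImage(
        resized,
        modality="+".join(im.modality for im in images),
        unit_id=images[0].unit_id,
        render_config_hash=config.hash(),
        flat_warning=any(im.flat_warning for im in images),
    )


def render_panel(
    record: NeuronRecord, config: RenderConfig | None = None
) -> FeatureImage:
    """Render the configured composite layout (default waveform+ISI+ACG)."""
    config = config or RenderConfig()
    parts = [render_feature(record, m, config) for m in config.composite_layout]
    if len(parts) == 1:
        return parts[0]
    return compose_panel(parts, config)
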