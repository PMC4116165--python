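"""Quantification of spatial expression from embryo images.

Pipeline: decompose the cell layer of an adapted morphology into quadrilateral
segments spanning the inner-to-outer boundary, average the pixel intensities
of a chosen color channel inside each segment, edit the raw trace (background
subtraction, masking of annotation artifacts, optional smoothing), and
standardize to 100 equidistant points scaled to unit maximum with the oral
pole anchored at position 50.

The morphology is assumed to be pre-adapted to the imaged embryo (from an
annotation file or from synthetic ground truth); interactive dragging of
morphology points onto the micrograph is out of scope.  Images are assumed
oriented with the oral pole to the right; pass ``flip=True`` to
:func:`standardize` to mirror a profile from an oppositely oriented image.
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np
from skimage.draw import polygon as _raster_polygon

from .morphology import Morphology, path_length, resample_path

N_STANDARD_POINTS = 100
# the oral pole maps to output segment 50 of 100 (1-based), i.e. the grid
# point centered at arc position (50 - 0.5) / 100
ORAL_POSITION = (N_STANDARD_POINTS // 2 - 0.5) / N_STANDARD_POINTS

_CHANNELS = {"R": 0, "G": 1, "B": 2, "gray": None}


class QuantificationError(ValueError):
    """Invalid decomposition, image or editing request."""


@dataclass(frozen=True)
class SegmentDecomposition:
    """Ordered quadrilateral segments spanning the cell-layer band.

    ``quads`` has shape (K, 4, 2): for segment ``i`` the corners are
    outer[i], outer[i+1], inner[i+1], inner[i].  ``positions`` are segment
    mid-arc positions in [0, 1) along the layer path; ``oral_segment`` is the
    0-based segment containing the oral pole.
    """

    quads: np.ndarray
    positions: np.ndarray
    segment_width: float
    oral_segment: int
    layer_length: float

    @property
    def n_segments(self) -> int:
        return len(self.quads)


def decompose_cell_layer(morph: Morphology, segment_width: float | None = None,
                         n_segments: int | None = None) -> SegmentDecomposition:
    """Decompose the cell layer into segments of roughly ``segment_width``
    pixels (or exactly ``n_segments`` segments).

    Inner and outer loops are resampled at equal arc spacing and paired index
    by index, so neighboring segments share an edge and their union covers
    the band.
    """
    layer_length = 0.5 * (path_length(morph.outer_loop) + path_length(morph.inner_loop))
    if n_segments is None:
        if segment_width is None or segment_width <= 0:
            raise QuantificationError("segment_width must be positive")
        if segment_width > layer_length / 2:
            raise QuantificationError("segment width exceeds half the layer length")
        n_segments = int(round(layer_length / segment_width))
    if n_segments < 8:
        raise QuantificationError("decomposition needs at least 8 segments")
    outer = resample_path(morph.outer_loop, n_segments)
    inner = resample_path(morph.inner_loop, n_segments)
    quads = np.stack([
        np.stack([outer[i], outer[i + 1], inner[i + 1], inner[i]])
        for i in range(n_segments)
    ])
    # shoelace area per quad; a zero-area band cannot hold any stain
    x, y = quads[..., 0], quads[..., 1]
    area = 0.5 * np.abs(np.sum(x * np.roll(y, -1, axis=1) - np.roll(x, -1, axis=1) * y,
                               axis=1))
    if np.mean(area) <= 1e-9:
        raise QuantificationError("degenerate (zero-area) cell layer")
    positions = (np.arange(n_segments) + 0.5) / n_segments
    oral_segment = min(int(morph.oral_fraction() * n_segments), n_segments - 1)
    return SegmentDecomposition(quads, positions,
                                segment_width or layer_length / n_segments,
                                oral_segment, layer_length)


@dataclass(frozen=True)
class RawIntensityProfile:
    """Per-segment mean channel intensity; NaN marks segments that contained
    no pixel centers (flagged missing, never silently zero)."""

    intensities: np.ndarray
    positions: np.ndarray
    channel: str
    oral_segment: int
    source: str = ""

    @property
    def n_segments(self) -> int:
        return len(self.intensities)


def _channel_plane(image: np.ndarray, channel: str) -> np.ndarray:
    if channel not in _CHANNELS:
        raise QuantificationError(f"channel must be one of {sorted(_CHANNELS)}")
    img = np.asarray(image)
    if img.dtype == np.uint8:
        img = img.astype(float) / 255.0
    else:
        img = img.astype(float)
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[2] >= 3:
        if channel == "gray":
            return img[:, :, :3].mean(axis=2)
        return img[:, :, _CHANNELS[channel]]
    raise QuantificationError(f"unsupported image shape {img.shape}")


def measure_intensity(image: np.ndarray, decomposition: SegmentDecomposition,
                      channel: str = "gray", source: str = "") -> RawIntensityProfile:
    """Mean intensity of the chosen channel over the pixels whose centers
    fall inside each segment polygon."""
    plane = _channel_plane(image, channel)
    h, w = plane.shape
    values = np.full(decomposition.n_segments, np.nan)
    for i, quad in enumerate(decomposition.quads):
        rr, cc = _raster_polygon(quad[:, 1], quad[:, 0], shape=(h, w))
        if rr.size:
            values[i] = plane[rr, cc].mean()
    return RawIntensityProfile(values, decomposition.positions.copy(), channel,
                               decomposition.oral_segment, source)


@dataclass(frozen=True)
class EditRules:
    """Rule-based replacement for the manual editing of raw traces.

    ``background_pct``: percentile of the profile subtracted as background
    (None disables); ``masks``: 0-based inclusive segment ranges replaced by
    linear interpolation from their circular neighbors (annotation artifacts,
    decomposition glitches); ``smooth_window``: odd width of an optional
    circular moving average.
    """

    background_pct: float | None = 5.0
    masks: tuple[tuple[int, int], ...] = ()
    smooth_window: int | None = None


def _interpolate_masked_circular(values: np.ndarray, masked: np.ndarray) -> np.ndarray:
    """Replace masked entries by linear interpolation on the circle."""
    n = len(values)
    if masked.all():
        raise QuantificationError("mask covers the whole profile")
    out = values.copy()
    idx = np.arange(n)
    good = ~masked
    # unwrap onto a tripled axis so interpolation wraps around the ends
    xg = np.concatenate([idx[good] - n, idx[good], idx[good] + n])
    yg = np.tile(values[good], 3)
    out[masked] = np.interp(idx[masked], xg, yg)
    return out


def edit_profile(raw: RawIntensityProfile | np.ndarray,
                 rules: EditRules = EditRules()) -> np.ndarray:
    """Apply background subtraction, masking and optional smoothing.

    Missing (NaN) segments are treated like masked ones and filled by
    interpolation.  With all rules disabled and no missing values this is the
    identity.
    """
    values = np.asarray(raw.intensities if isinstance(raw, RawIntensityProfile)
                        else raw, dtype=float).copy()
    n = len(values)
    masked = ~np.isfinite(values)
    for a, b in (rules.masks or ()):
        if not (0 <= a <= b < n):
            raise QuantificationError(f"mask range ({a}, {b}) outside profile")
        masked[a: b + 1] = True
    if masked.any():
        values = _interpolate_masked_circular(values, masked)
    if rules.background_pct is not None:
        values = np.maximum(values - np.percentile(values, rules.background_pct), 0.0)
    if rules.smooth_window:
        win = int(rules.smooth_window)
        if win < 1 or win % 2 == 0:
            raise QuantificationError("smooth_window must be odd and positive")
        kernel = np.ones(win) / win
        pad = win // 2
        values = np.convolve(np.concatenate([values[-pad:], values, values[:pad]]),
                             kernel, mode="valid")
    return values


@dataclass(frozen=True)
class StandardizedProfile:
    """100-point unit-normalized spatial expression profile.

    ``values[49]`` (1-based segment 50) sits at the oral pole; values are in
    [0, 1] with maximum exactly 1 unless the profile is identically zero.
    """

    gene: str
    stage_hours: float
    values: np.ndarray
    oral_anchor: int = N_STANDARD_POINTS // 2

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_STANDARD_POINTS,):
            raise QuantificationError(
                f"standardized profile must have {N_STANDARD_POINTS} points")
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise QuantificationError("profile values must be finite and non-negative")
        mx = v.max()
        if mx > 0 and abs(mx - 1.0) > 1e-9:
            raise QuantificationError("non-zero profile must have unit maximum")
        object.__setattr__(self, "values", v)


def standardize(edited: np.ndarray, oral_segment: int, gene: str = "",
                stage_hours: float = 0.0, flip: bool = False) -> StandardizedProfile:
    """Rotate the profile so the oral pole maps to position 50 of 100,
    interpolate at 100 equidistant points and scale to unit maximum.

    The profile is circular along the cell layer; rotation and interpolation
    are therefore periodic.  An all-zero profile is passed through without
    normalization.
    """
    values = np.asarray(edited, dtype=float)
    k = np.isfinite(values).sum()
    if k < 2:
        raise QuantificationError("standardization needs at least 2 valid segments")
    if not np.all(np.isfinite(values)):
        values = _interpolate_masked_circular(values, ~np.isfinite(values))
    n = len(values)
    positions = (np.arange(n) + 0.5) / n
    if flip:
        values = values[::-1]
        # mirroring reverses arc direction; the anchor follows
        oral_segment = n - 1 - oral_segment
    anchor_pos = (oral_segment + 0.5) / n
    shifted = np.mod(positions - anchor_pos + ORAL_POSITION, 1.0)
    order = np.argsort(shifted)
    xs, ys = shifted[order], values[order]
    # periodic linear interpolation: extend one period on both sides
    xs_ext = np.concatenate([xs - 1.0, xs, xs + 1.0])
    ys_ext = np.tile(ys, 3)
    grid = (np.arange(N_STANDARD_POINTS) + 0.5) / N_STANDARD_POINTS
    out = np.interp(grid, xs_ext, ys_ext)
    out = np.maximum(out, 0.0)
    mx = out.max()
    if mx > 0:
        out = out / mx
    return StandardizedProfile(gene, stage_hours, out)


def quantify_image(image: np.ndarray, morph: Morphology, channel: str = "gray",
                   segment_width: float | None = None, n_segments: int | None = 100,
                   rules: EditRules = EditRules(), gene: str = "",
                   stage_hours: float | None = None,
                   flip: bool = False) -> StandardizedProfile:
    """Full image-to-profile pipeline: decompose, measure, edit, standardize."""
    decomp = decompose_cell_layer(morph, segment_width, n_segments)
    raw = measure_intensity(image, decomp, channel, source=gene)
    edited = edit_profile(raw, rules)
    return standardize(edited, decomp.oral_segment, gene=gene,
                       stage_hours=morph.stage_hours if stage_hours is None else stage_hours,
                       flip=flip)
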