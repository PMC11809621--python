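"""Recover fragment data from sequence-map raster images.

Sequence-mapping software exports colour-coded bar maps: each identified
oligoribonucleotide is a solid horizontal bar, its colour encoding a
confidence band, packed into rows on a white background.  Given such a PNG
and the total sequence length, this module reverses the rendering: greyscale
conversion, white-margin cropping, row/bar detection from pixel-intensity
runs, colour-to-confidence classification against a configurable palette,
and pixel-to-nucleotide coordinate conversion.

The cropped content is assumed to span exactly the full sequence — the only
scale input is the total sequence length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .core import Fragment, FragmentSet, FragmentSource, ValidationError

__all__ = [
    "ColorConfidenceMap",
    "DEFAULT_COLOR_MAP",
    "PixelBar",
    "ExtractConfig",
    "load_image",
    "to_greyscale",
    "crop_margins",
    "detect_bars",
    "pixels_to_positions",
    "classify_color",
    "extract",
]

#: Rec. 601 luma weights for greyscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class ColorConfidenceMap:
    """Palette mapping bar colours to confidence values.

    ``entries`` is a list of ``((R, G, B), confidence)`` pairs;
    ``match_tolerance`` is the maximum Euclidean RGB distance for a bar
    colour to be assigned to an entry.
    """

    entries: tuple[tuple[tuple[int, int, int], float], ...]
    match_tolerance: float = 20.0

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValidationError("colour map has no entries")
        colours = [tuple(c) for c, _ in self.entries]
        if len(set(colours)) != len(colours):
            raise ValidationError("colour map entries must have distinct colours")
        if self.match_tolerance < 0:
            raise ValidationError("match_tolerance must be >= 0")
        object.__setattr__(
            self,
            "entries",
            tuple((tuple(int(v) for v in c), float(conf)) for c, conf in self.entries),
        )

    @property
    def confidences(self) -> tuple[float, ...]:
        return tuple(conf for _, conf in self.entries)


#: Default 4-band palette used by the fixtures renderer: saturated
#: green/yellow/orange/red for decreasing confidence.  Real exports need the
#: software's actual legend palette supplied as configuration.
DEFAULT_COLOR_MAP = ColorConfidenceMap(
    entries=(
        ((0, 170, 0), 1.0),
        ((255, 204, 0), 0.75),
        ((255, 128, 0), 0.5),
        ((220, 0, 0), 0.25),
    )
)


@dataclass(frozen=True)
class PixelBar:
    """One detected bar: a maximal horizontal run of bar pixels in a row."""

    row_index: int
    x_start: int
    x_end: int  # inclusive pixel column
    colour: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.x_start > self.x_end:
            raise ValidationError("x_start must be <= x_end")


@dataclass(frozen=True)
class ExtractConfig:
    """Thresholds for margin cropping and bar detection.

    Maps are saturated bars on white: pixels with luminance below
    ``white_threshold`` count as content for cropping; below
    ``bar_threshold`` they count as bar ink.  Anti-aliased edge pixels above
    ``bar_threshold`` are ignored, and bar colour is the per-channel median
    of the bar's ink pixels, so soft edges do not shift classification.
    """

    white_threshold: int = 250
    bar_threshold: int = 240

    def __post_init__(self) -> None:
        if not (0 < self.white_threshold <= 255):
            raise ValidationError("white_threshold must be in (0, 255]")
        if not (0 < self.bar_threshold <= 255):
            raise ValidationError("bar_threshold must be in (0, 255]")


def load_image(path: str | Path) -> np.ndarray:
    """Load a PNG as an (H, W, 3) uint8 RGB array, alpha composited over white."""
    with Image.open(path) as im:
        if im.mode == "RGBA":
            bg = Image.new("RGBA", im.size, (255, 255, 255, 255))
            im = Image.alpha_composite(bg, im)
        rgb = im.convert("RGB")
        return np.asarray(rgb, dtype=np.uint8)


def to_greyscale(img: np.ndarray) -> np.ndarray:
    """Per-pixel Rec. 601 luminance in [0, 255]; dimensions preserved."""
    arr = np.asarray(img, dtype=float)
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise ValidationError("expected an (H, W, 3) RGB array")
    return arr[:, :, :3] @ _LUMA


def crop_margins(
    grey: np.ndarray, white_threshold: int = 250
) -> tuple[np.ndarray, tuple[int, int]]:
    """Crop to the smallest box containing all content pixels.

    Content is intensity strictly below ``white_threshold``.  Returns the
    cropped matrix and ``(row_offset, col_offset)`` of its top-left corner
    so pixel coordinates remain convertible to the original image.
    """
    grey = np.asarray(grey)
    content = grey < white_threshold
    if not content.any():
        raise ValidationError("no content detected: image is entirely background")
    rows = np.flatnonzero(content.any(axis=1))
    cols = np.flatnonzero(content.any(axis=0))
    r0, r1 = int(rows[0]), int(rows[-1])
    c0, c1 = int(cols[0]), int(cols[-1])
    return grey[r0:r1 + 1, c0:c1 + 1], (r0, c0)


def _row_bands(row_has_bar: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (first, last) inclusive index pairs."""
    idx = np.flatnonzero(row_has_bar)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    return [(int(idx[s]), int(idx[e])) for s, e in zip(starts, ends)]


def detect_bars(
    img: np.ndarray,
    grey: np.ndarray,
    config: ExtractConfig = ExtractConfig(),
    row_model: tuple[int, int] | None = None,
) -> list[PixelBar]:
    """Detect fragment bars in a cropped map.

    Rows are horizontal bands whose minimum intensity falls below the bar
    threshold, separated by background-only pixel rows; ``row_model``
    (row height, gap in pixels) may force fixed-height bands instead.
    Within each band, every maximal horizontal run of bar columns becomes
    one :class:`PixelBar` carrying the per-channel median colour of its ink
    pixels.  Bars separated by even a single background column stay distinct.
    """
    grey = np.asarray(grey)
    ink = grey < config.bar_threshold
    if row_model is not None:
        height, gap = row_model
        pitch = height + gap
        bands = [
            (top, min(top + height - 1, grey.shape[0] - 1))
            for top in range(0, grey.shape[0], pitch)
        ]
        bands = [(a, b) for a, b in bands if ink[a:b + 1].any()]
    else:
        bands = _row_bands(ink.any(axis=1))
    if not bands:
        raise ValidationError("no bars found: no pixel rows below the bar threshold")

    bars: list[PixelBar] = []
    for row_index, (top, bottom) in enumerate(bands):
        band_ink = ink[top:bottom + 1]
        for c0, c1 in _row_bands(band_ink.any(axis=0)):
            mask = band_ink[:, c0:c1 + 1]
            patch = np.asarray(img)[top:bottom + 1, c0:c1 + 1, :3]
            colour = tuple(
                int(np.median(patch[:, :, ch][mask])) for ch in range(3)
            )
            bars.append(PixelBar(row_index=row_index, x_start=c0, x_end=c1,
                                 colour=colour))
    return bars


def pixels_to_positions(
    bars: list[PixelBar], content_width: int, sequence_length: int
) -> list[tuple[int, int]]:
    """Convert bar pixel extents to 1-based nucleotide intervals.

    The cropped content width maps linearly onto the full sequence:
    ``start = floor(x_start / W * L) + 1`` and
    ``end = ceil((x_end + 1) / W * L)``, clamped into ``[1, L]``.
    """
    if sequence_length < 1:
        raise ValidationError("sequence_length must be >= 1")
    if content_width < 1:
        raise ValidationError("content_width must be >= 1")
    out: list[tuple[int, int]] = []
    for bar in bars:
        # integer arithmetic: floor/ceil of exact rationals, no float round-off
        start = (bar.x_start * sequence_length) // content_width + 1
        end = -((-(bar.x_end + 1) * sequence_length) // content_width)
        start = min(max(start, 1), sequence_length)
        end = min(max(end, start), sequence_length)
        out.append((start, end))
    return out


def classify_color(
    bar: PixelBar, cmap: ColorConfidenceMap
) -> float | None:
    """Confidence of the nearest palette entry by Euclidean RGB distance.

    Ties go to the entry with the higher confidence.  Returns ``None`` (bar
    flagged as unmapped colour) when the nearest entry is farther than the
    match tolerance.
    """
    colour = np.asarray(bar.colour, dtype=float)
    best: tuple[float, float] | None = None  # (distance, -confidence)
    for entry_colour, conf in cmap.entries:
        dist = float(np.linalg.norm(colour - np.asarray(entry_colour, dtype=float)))
        key = (dist, -conf)
        if best is None or key < best:
            best = key
    assert best is not None
    if best[0] > cmap.match_tolerance:
        return None
    return -best[1]


def extract(
    img_path: str | Path,
    sequence_length: int,
    cmap: ColorConfidenceMap = DEFAULT_COLOR_MAP,
    config: ExtractConfig = ExtractConfig(),
    digest_id: str | None = None,
) -> FragmentSet:
    """Full image-to-fragments pipeline.

    Composition of load -> greyscale -> crop -> bar detection -> colour
    classification -> coordinate conversion; deterministic for a fixed input
    and configuration.  Bars whose colour matches no palette entry within
    tolerance are excluded with a warning.
    """
    img = load_image(img_path)
    grey = to_greyscale(img)
    grey_c, (r0, c0) = crop_margins(grey, config.white_threshold)
    img_c = img[r0:r0 + grey_c.shape[0], c0:c0 + grey_c.shape[1]]
    bars = detect_bars(img_c, grey_c, config)
    confidences: list[float] = []
    kept: list[PixelBar] = []
    for bar in bars:
        conf = classify_color(bar, cmap)
        if conf is None:
            warnings.warn(
                f"bar at row {bar.row_index}, columns {bar.x_start}-{bar.x_end} "
                f"has unmapped colour {bar.colour}; excluded",
                stacklevel=2,
            )
            continue
        kept.append(bar)
        confidences.append(conf)
    intervals = pixels_to_positions(kept, grey_c.shape[1], sequence_length)
    label = digest_id if digest_id is not None else Path(img_path).stem
    fragments = [
        Fragment(start=s, end=e, confidence=conf, digest_id=label,
                 source=FragmentSource.IMAGE)
        for (s, e), conf in zip(intervals, confidences)
    ]
    fragments.sort(key=lambda f: (f.start, f.end))
    return FragmentSet(digest_id=label, sequence_length=sequence_length,
                       fragments=fragments)
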