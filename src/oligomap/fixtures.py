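"""Synthetic data: random fragment sets and a bar-map image renderer.

These stand in for the two real input kinds of the pipeline — LC-MS/MS
identification tables and the colour-coded sequence-map images exported by
the analysis software — and provide exact ground truth for round-trip tests
of the image extractor.

Rendered maps are plain solid bars on white drawn without anti-aliasing, so
a render -> extract round trip is exact at sufficient resolution.  A thin
grey "sequence ruler" spanning the full content width is drawn above the
bars: its intensity (245) sits between the bar-detection threshold (240)
and the white-margin threshold (250), so it anchors the crop to the full
sequence extent — which extraction assumes — without ever being detected as
a bar.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from PIL import Image, ImageFilter

from .core import Fragment, FragmentSet, FragmentSource, ValidationError
from .digest import Oligo
from .image_extract import DEFAULT_COLOR_MAP, ColorConfidenceMap
from .visualize import pack_rows

__all__ = [
    "FixtureParams",
    "simulate_fragmentset",
    "digest_to_fragmentset",
    "length_window_model",
    "render_bpf_style",
]

#: Ruler grey level: below the white-margin threshold, above the bar threshold.
RULER_INTENSITY = 245
RULER_HEIGHT = 2


@dataclass(frozen=True)
class FixtureParams:
    """Parameters of the synthetic world.

    Defaults emulate a partial-digest identification set on a 300-nt toy
    construct: 40 fragments, 3-30 nt long (the MS-identifiable window),
    confidences on the 4-band palette, rendered at 4 px/nt.
    """

    sequence_length: int = 300
    n_fragments: int = 40
    length_distribution: tuple[int, int] = (3, 30)
    confidence_levels: tuple[float, ...] = (1.0, 0.75, 0.5, 0.25)
    seed: int = 0
    pixels_per_nucleotide: int = 4
    row_height: int = 8
    row_gap: int = 4
    margin: int = 12

    def __post_init__(self) -> None:
        lo, hi = self.length_distribution
        if not (1 <= lo <= hi <= self.sequence_length):
            raise ValidationError(
                "length_distribution must satisfy 1 <= min <= max <= sequence_length"
            )
        if self.pixels_per_nucleotide < 1:
            raise ValidationError("pixels_per_nucleotide must be >= 1")
        if not self.confidence_levels:
            raise ValidationError("confidence_levels must be non-empty")


def simulate_fragmentset(
    params: FixtureParams, digest_id: str = "sim"
) -> FragmentSet:
    """Draw a random fragment set, reproducible under the seed.

    Starts are uniform over [1, sequence_length]; lengths uniform over the
    configured range, with the end clamped to the sequence; confidences are
    drawn uniformly from the discrete levels.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_fragments
    lo, hi = params.length_distribution
    starts = rng.integers(1, params.sequence_length + 1, size=n)
    lengths = rng.integers(lo, hi + 1, size=n)
    levels = np.asarray(params.confidence_levels, dtype=float)
    confs = levels[rng.integers(0, len(levels), size=n)]
    fragments = [
        Fragment(
            start=int(s),
            end=int(min(s + ln - 1, params.sequence_length)),
            confidence=float(c),
            digest_id=digest_id,
            source=FragmentSource.SIMULATED,
        )
        for s, ln, c in zip(starts, lengths, confs)
    ]
    fragments.sort(key=lambda f: (f.start, f.end))
    return FragmentSet(digest_id=digest_id,
                       sequence_length=params.sequence_length,
                       fragments=fragments)


def length_window_model(
    min_length: int = 3,
    max_length: int = 30,
    confidence: float = 1.0,
) -> Callable[[int], float | None]:
    """Confidence model keeping oligos inside an identifiable length window.

    Returns a callable mapping oligo length to a confidence, or ``None``
    outside the window (very short oligos map non-uniquely; very long ones
    are hard to identify from their MS/MS spectra).
    """

    def model(length: int) -> float | None:
        if min_length <= length <= max_length:
            return confidence
        return None

    return model


def digest_to_fragmentset(
    oligos: Sequence[Oligo],
    confidence_model: Callable[[int], float | None] | dict[int, float],
    digest_id: str,
    sequence_length: int,
) -> FragmentSet:
    """Turn in-silico digestion products into a mapped fragment set.

    ``confidence_model`` maps oligo length to confidence; oligos whose
    length falls outside the model (``None`` / missing key) are dropped,
    emulating that only suitably sized products are identified.
    """
    if isinstance(confidence_model, dict):
        model = confidence_model.get
    else:
        model = confidence_model
    fragments = []
    for o in oligos:
        conf = model(o.length)
        if conf is None:
            continue
        fragments.append(
            Fragment(start=o.start, end=o.end, confidence=float(conf),
                     digest_id=digest_id, source=FragmentSource.SIMULATED)
        )
    fragments.sort(key=lambda f: (f.start, f.end))
    return FragmentSet(digest_id=digest_id, sequence_length=sequence_length,
                       fragments=fragments)


def _colour_for_confidence(
    confidence: float, cmap: ColorConfidenceMap
) -> tuple[int, int, int]:
    best = min(cmap.entries, key=lambda e: (abs(e[1] - confidence), -e[1]))
    return best[0]


def render_bpf_style(
    fragset: FragmentSet,
    out_path: str | Path,
    cmap: ColorConfidenceMap = DEFAULT_COLOR_MAP,
    params: FixtureParams | None = None,
    blur: float = 0.0,
) -> Path:
    """Render a fragment set as a synthetic sequence-map PNG.

    White background, optional outer margin, full-width grey ruler, then
    fragment bars packed first-fit into rows; each bar is a solid rectangle
    of the palette colour nearest its confidence spanning pixels
    ``(start-1)*ppn .. end*ppn - 1``.  No anti-aliasing, so rendering is
    deterministic and extraction can round-trip exactly; ``blur`` applies a
    Gaussian blur to stress-test extraction tolerance.
    """
    if params is None:
        params = FixtureParams(sequence_length=fragset.sequence_length)
    if params.sequence_length != fragset.sequence_length:
        raise ValidationError("params.sequence_length must match the fragment set")
    ppn = params.pixels_per_nucleotide
    content_w = fragset.sequence_length * ppn
    rows = pack_rows(fragset.fragments)
    n_rows = (max(rows) + 1) if rows else 1
    margin = params.margin
    bars_top = margin + RULER_HEIGHT + params.row_gap
    height = bars_top + n_rows * (params.row_height + params.row_gap) + margin
    width = content_w + 2 * margin
    img = np.full((height, width, 3), 255, dtype=np.uint8)
    # full-width ruler anchoring the crop to the whole sequence
    img[margin:margin + RULER_HEIGHT, margin:margin + content_w] = RULER_INTENSITY
    for frag, row in zip(fragset.fragments, rows):
        y0 = bars_top + row * (params.row_height + params.row_gap)
        x0 = margin + (frag.start - 1) * ppn
        x1 = margin + frag.end * ppn  # exclusive
        colour = _colour_for_confidence(frag.confidence, cmap)
        img[y0:y0 + params.row_height, x0:x1] = colour
    out_path = Path(out_path)
    pil = Image.fromarray(img, mode="RGB")
    if blur > 0:
        pil = pil.filter(ImageFilter.GaussianBlur(blur))
    pil.save(out_path, format="PNG")
    return out_path
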