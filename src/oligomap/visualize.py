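"""Linear sequence maps and spiral coverage plots.

A linear map stacks the fragment bars of one or two digests (first-fit row
packing, blue for digest 1 and yellow for digest 2) above a one-row
colourmetric strip whose per-nucleotide colour is the coverage category and
whose intensity encodes normalised cumulative confidence.

A spiral plot places one dot per nucleotide along an Archimedean spiral
(5' end innermost), dot colour giving the coverage category and dot size
and opacity jointly encoding the cumulative confidence, with the automatic
percentage-coverage figure displayed in the centre.

SVG is the canonical output: it is written by a small deterministic text
writer so identical inputs give byte-identical files and tests can read the
primitives back.  PNG output goes through matplotlib.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import Fragment, FragmentSet, ValidationError
from .coverage import (
    Category,
    CombinedCoverage,
    CoverageProfile,
    combined_percent,
    percent_coverage,
)

__all__ = [
    "SpiralParams",
    "DotSpec",
    "CategoryPalette",
    "pack_rows",
    "spiral_layout",
    "dots_from_coverage",
    "render_spiral",
    "render_linear",
    "spiral_figure",
    "linear_figure",
]


@dataclass(frozen=True)
class SpiralParams:
    """Geometry and encoding parameters of the spiral plot.

    The spiral is Archimedean, ``r(theta) = inner_radius +
    radial_gap_per_turn * theta / 2pi``, with dots spaced uniformly along
    the arc so neighbours are equidistant everywhere on the curve.
    """

    inner_radius: float = 1.0
    radial_gap_per_turn: float = 1.0
    dots_per_turn_initial: int = 36
    dot_size_range: tuple[float, float] = (0.06, 0.42)
    opacity_range: tuple[float, float] = (0.25, 1.0)
    direction: str = "counterclockwise"

    def __post_init__(self) -> None:
        if self.inner_radius <= 0:
            raise ValidationError("inner_radius must be > 0")
        if self.dot_size_range[0] > self.dot_size_range[1]:
            raise ValidationError("dot_size_range must be ordered (min, max)")
        if not (0 <= self.opacity_range[0] <= self.opacity_range[1] <= 1):
            raise ValidationError("opacity_range must be ordered within [0, 1]")
        if self.direction not in ("clockwise", "counterclockwise"):
            raise ValidationError("direction must be clockwise or counterclockwise")


@dataclass(frozen=True)
class DotSpec:
    """One spiral dot: a nucleotide with its plot geometry and encoding."""

    nucleotide_index: int
    x: float
    y: float
    size: float
    opacity: float
    category: str  # d1_only / d2_only / mutual / none, or covered / none


@dataclass(frozen=True)
class CategoryPalette:
    """Category colours: blue digest 1, yellow digest 2, red mutual, grey none."""

    d1_only: tuple[int, int, int] = (31, 119, 180)
    d2_only: tuple[int, int, int] = (255, 201, 14)
    mutual: tuple[int, int, int] = (214, 39, 40)
    none: tuple[int, int, int] = (200, 200, 200)

    def __post_init__(self) -> None:
        colours = {self.d1_only, self.d2_only, self.mutual, self.none}
        if len(colours) != 4:
            raise ValidationError("palette requires four distinct colours")

    def colour(self, category: str) -> tuple[int, int, int]:
        if category == "covered":  # single-digest plots reuse the digest-1 blue
            return self.d1_only
        return getattr(self, category)


def pack_rows(fragments: Sequence[Fragment], min_gap: int = 1) -> list[int]:
    """First-fit row packing by fragment start.

    Returns a row index per fragment such that fragments in the same row
    never overlap and keep at least ``min_gap`` nucleotides between them
    (so adjacent bars stay visually distinct).  Fragments are processed in
    (start, end) order; ties keep input order.
    """
    order = sorted(range(len(fragments)), key=lambda i: (fragments[i].start,
                                                         fragments[i].end, i))
    row_ends: list[int] = []  # last occupied position per row
    rows = [0] * len(fragments)
    for i in order:
        frag = fragments[i]
        for r, last_end in enumerate(row_ends):
            if frag.start > last_end + min_gap:
                rows[i] = r
                row_ends[r] = frag.end
                break
        else:
            rows[i] = len(row_ends)
            row_ends.append(frag.end)
    return rows


def spiral_layout(n: int, params: SpiralParams = SpiralParams()) -> np.ndarray:
    """(n, 2) array of dot centres along the spiral, nucleotide 1 innermost.

    Dot spacing along the arc is the circumference of the innermost turn
    divided by ``dots_per_turn_initial``; angles for uniform arc length are
    found by inverting a densely sampled cumulative arc-length table.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    r0 = params.inner_radius
    b = params.radial_gap_per_turn / (2 * math.pi)
    ds = 2 * math.pi * r0 / params.dots_per_turn_initial
    total_s = ds * (n - 1)
    # Invert s(theta) = int_0^theta sqrt(r^2 + b^2) dtheta >= r0 * theta.
    if b > 0:
        # Generous upper bound from s >= r0*theta + b*theta^2/2.
        theta_max = (-r0 + math.sqrt(r0 * r0 + 2 * b * total_s)) / b + 1.0
    else:
        theta_max = total_s / r0 + 1.0
    grid = np.linspace(0.0, max(theta_max, 1.0), max(20_000, 40 * n))
    r = r0 + b * grid
    speed = np.sqrt(r * r + b * b)
    s_grid = np.concatenate(
        ([0.0], np.cumsum(np.diff(grid) * 0.5 * (speed[1:] + speed[:-1])))
    )
    targets = ds * np.arange(n)
    theta = np.interp(targets, s_grid, grid)
    radius = r0 + b * theta
    if params.direction == "clockwise":
        theta = -theta
    return np.column_stack((radius * np.cos(theta), radius * np.sin(theta)))


def _category_labels(cov: CoverageProfile | CombinedCoverage) -> list[str]:
    if isinstance(cov, CombinedCoverage):
        names = {Category.NONE: "none", Category.D1_ONLY: "d1_only",
                 Category.D2_ONLY: "d2_only", Category.MUTUAL: "mutual"}
        return [names[Category(c)] for c in cov.category]
    return ["covered" if c else "none" for c in cov.covered]


def _values(cov: CoverageProfile | CombinedCoverage) -> np.ndarray:
    if isinstance(cov, CombinedCoverage):
        return np.asarray(cov.cum_confidence_combined, dtype=float)
    return np.asarray(cov.cum_confidence, dtype=float)


def dots_from_coverage(
    cov: CoverageProfile | CombinedCoverage,
    params: SpiralParams = SpiralParams(),
    palette: CategoryPalette = CategoryPalette(),
) -> list[DotSpec]:
    """One dot per nucleotide, size and opacity scaled by cumulative confidence.

    Values are normalised by the per-figure maximum, then mapped affinely
    into the configured size and opacity ranges; uncovered nucleotides get
    category ``none`` at minimum size and opacity.
    """
    values = _values(cov)
    labels = _category_labels(cov)
    xy = spiral_layout(cov.sequence_length, params)
    vmax = float(values.max()) if values.size else 0.0
    smin, smax = params.dot_size_range
    omin, omax = params.opacity_range
    dots: list[DotSpec] = []
    for i in range(cov.sequence_length):
        frac = (values[i] / vmax) if vmax > 0 else 0.0
        covered = labels[i] != "none"
        dots.append(
            DotSpec(
                nucleotide_index=i + 1,
                x=float(xy[i, 0]),
                y=float(xy[i, 1]),
                size=smin + (smax - smin) * frac if covered else smin,
                opacity=omin + (omax - omin) * frac if covered else omin,
                category=labels[i],
            )
        )
    return dots


# ---------------------------------------------------------------------------
# Deterministic SVG writing

def _fmt(x: float) -> str:
    return f"{x:.3f}"


def _rgb(colour: tuple[int, int, int]) -> str:
    return f"rgb({colour[0]},{colour[1]},{colour[2]})"


def _write_svg(path: Path, width: float, height: float,
               body: list[str]) -> None:
    head = (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{_fmt(width)}" '
        f'height="{_fmt(height)}" viewBox="0 0 {_fmt(width)} {_fmt(height)}">\n'
    )
    path.write_text(head + "\n".join(body) + "\n</svg>\n")


def render_spiral(
    dots: Sequence[DotSpec],
    out_path: str | Path,
    percent: int | None = None,
    title: str | None = None,
    palette: CategoryPalette = CategoryPalette(),
    scale: float = 24.0,
) -> Path:
    """Render spiral dots to SVG or (via matplotlib) PNG.

    The coverage percentage, when given, is displayed in the centre of the
    spiral exactly as computed by the coverage module.  SVG output is
    byte-identical for identical input.
    """
    out_path = Path(out_path)
    extent = max(max(abs(d.x), abs(d.y)) for d in dots) + max(
        d.size for d in dots
    )
    if out_path.suffix.lower() == ".png":
        _render_spiral_png(dots, out_path, percent, title, palette, extent)
        return out_path
    half = extent * scale * 1.05
    width = height = 2 * half + 20
    cx = cy = half + 10
    body = []
    if title:
        body.append(
            f'<text x="{_fmt(width / 2)}" y="16" text-anchor="middle" '
            f'font-family="sans-serif" font-size="14">{title}</text>'
        )
    for d in dots:
        body.append(
            f'<circle cx="{_fmt(cx + d.x * scale)}" cy="{_fmt(cy - d.y * scale)}" '
            f'r="{_fmt(max(d.size * scale, 0.1))}" fill="{_rgb(palette.colour(d.category))}" '
            f'fill-opacity="{_fmt(d.opacity)}" data-nt="{d.nucleotide_index}" '
            f'data-category="{d.category}"/>'
        )
    if percent is not None:
        body.append(
            f'<text x="{_fmt(cx)}" y="{_fmt(cy)}" text-anchor="middle" '
            f'dominant-baseline="middle" font-family="sans-serif" '
            f'font-size="{_fmt(scale * 0.9)}" class="coverage-percent">{percent}%</text>'
        )
    _write_svg(out_path, width, height, body)
    return out_path


def _render_spiral_png(dots, out_path, percent, title, palette, extent) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    xs = [d.x for d in dots]
    ys = [d.y for d in dots]
    colours = [
        (*(v / 255 for v in palette.colour(d.category)), d.opacity) for d in dots
    ]
    sizes = [(d.size * 40) ** 2 for d in dots]
    ax.scatter(xs, ys, s=sizes, c=colours, linewidths=0)
    if percent is not None:
        ax.text(0, 0, f"{percent}%", ha="center", va="center", fontsize=16)
    if title:
        ax.set_title(title)
    ax.set_aspect("equal")
    ax.set_xlim(-extent, extent)
    ax.set_ylim(-extent, extent)
    ax.axis("off")
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def render_linear(
    sets: Sequence[FragmentSet],
    cov: CoverageProfile | CombinedCoverage,
    out_path: str | Path,
    palette: CategoryPalette = CategoryPalette(),
    px_per_nt: float = 3.0,
    bar_height: float = 8.0,
    bar_gap: float = 2.0,
) -> Path:
    """Render a linear sequence map: stacked bars plus colourmetric strip.

    Fragment bars of each digest are packed first-fit into rows so
    overlapping fragments never share a row; digest 1 draws in blue and
    digest 2 in yellow.  Beneath, a one-row strip colours each nucleotide by
    its coverage category, with intensity (opacity) proportional to the
    normalised cumulative confidence; uncovered nucleotides are solid grey.
    """
    if not 1 <= len(sets) <= 2:
        raise ValidationError("render_linear takes one or two fragment sets")
    out_path = Path(out_path)
    n = cov.sequence_length
    for fs in sets:
        if fs.sequence_length != n:
            raise ValidationError("fragment set / coverage length mismatch")
    set_colours = [palette.d1_only, palette.d2_only]
    width = n * px_per_nt + 20
    body: list[str] = []
    y = 10.0
    for colour, fs in zip(set_colours, sets):
        rows = pack_rows(fs.fragments)
        n_rows = max(rows) + 1 if rows else 1
        for frag, row in zip(fs.fragments, rows):
            x0 = 10 + (frag.start - 1) * px_per_nt
            w = frag.length * px_per_nt
            body.append(
                f'<rect x="{_fmt(x0)}" y="{_fmt(y + row * (bar_height + bar_gap))}" '
                f'width="{_fmt(w)}" height="{_fmt(bar_height)}" '
                f'fill="{_rgb(colour)}" data-start="{frag.start}" '
                f'data-end="{frag.end}" data-digest="{fs.digest_id}"/>'
            )
        y += n_rows * (bar_height + bar_gap) + 6
    # colourmetric strip
    values = _values(cov)
    labels = _category_labels(cov)
    vmax = float(values.max()) if values.size else 0.0
    strip_y = y + 4
    for i in range(n):
        covered = labels[i] != "none"
        frac = (values[i] / vmax) if (vmax > 0 and covered) else 0.0
        opacity = 0.15 + 0.85 * frac if covered else 1.0
        body.append(
            f'<rect x="{_fmt(10 + i * px_per_nt)}" y="{_fmt(strip_y)}" '
            f'width="{_fmt(px_per_nt)}" height="{_fmt(bar_height)}" '
            f'fill="{_rgb(palette.colour(labels[i]))}" '
            f'fill-opacity="{_fmt(opacity)}" data-nt="{i + 1}" '
            f'data-category="{labels[i]}"/>'
        )
    height = strip_y + bar_height + 10
    if out_path.suffix.lower() == ".png":
        _render_linear_png(sets, cov, out_path, palette)
        return out_path
    _write_svg(out_path, width, height, body)
    return out_path


def _render_linear_png(sets, cov, out_path, palette) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    n = cov.sequence_length
    fig, ax = plt.subplots(figsize=(10, 4))
    y = 0.0
    set_colours = [palette.d1_only, palette.d2_only]
    for colour, fs in zip(set_colours, sets):
        rows = pack_rows(fs.fragments)
        n_rows = max(rows) + 1 if rows else 1
        rgb = tuple(v / 255 for v in colour)
        for frag, row in zip(fs.fragments, rows):
            ax.add_patch(Rectangle((frag.start - 1, y + row), frag.length, 0.8,
                                   color=rgb))
        y += n_rows + 0.8
    values = _values(cov)
    labels = _category_labels(cov)
    vmax = float(values.max()) if values.size else 0.0
    for i in range(n):
        covered = labels[i] != "none"
        frac = (values[i] / vmax) if (vmax > 0 and covered) else 0.0
        alpha = 0.15 + 0.85 * frac if covered else 1.0
        rgb = tuple(v / 255 for v in palette.colour(labels[i]))
        ax.add_patch(Rectangle((i, y + 0.4), 1, 0.8, color=rgb, alpha=alpha))
    ax.set_xlim(0, n)
    ax.set_ylim(0, y + 2)
    ax.set_yticks([])
    ax.set_xlabel("nucleotide position")
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# High-level figure wrappers (sidecar JSON keeps figures machine-checkable)

def spiral_figure(
    cov: CoverageProfile | CombinedCoverage,
    out_path: str | Path,
    params: SpiralParams = SpiralParams(),
    palette: CategoryPalette = CategoryPalette(),
    title: str | None = None,
) -> dict:
    """Render a spiral plot with its automatic percentage, plus sidecar JSON."""
    if isinstance(cov, CombinedCoverage):
        pct, raw = combined_percent(cov)
    else:
        pct, raw = percent_coverage(cov)
    dots = dots_from_coverage(cov, params, palette)
    render_spiral(dots, out_path, percent=pct, title=title, palette=palette)
    meta = {
        "figure": str(out_path),
        "percent": pct,
        "percent_raw": raw,
        "n_dots": len(dots),
        "categories": {
            lab: sum(1 for d in dots if d.category == lab)
            for lab in sorted({d.category for d in dots})
        },
    }
    Path(out_path).with_suffix(".json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n"
    )
    return meta


def linear_figure(
    sets: Sequence[FragmentSet],
    cov: CoverageProfile | CombinedCoverage,
    out_path: str | Path,
    palette: CategoryPalette = CategoryPalette(),
) -> dict:
    """Render a linear map and write its sidecar JSON."""
    if isinstance(cov, CombinedCoverage):
        pct, raw = combined_percent(cov)
    else:
        pct, raw = percent_coverage(cov)
    render_linear(sets, cov, out_path, palette=palette)
    meta = {
        "figure": str(out_path),
        "percent": pct,
        "percent_raw": raw,
        "n_fragments": [len(fs) for fs in sets],
    }
    Path(out_path).with_suffix(".json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n"
    )
    return meta
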