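"""Per-nucleotide cumulative-confidence coverage and two-digest combination.

For each nucleotide of the mRNA, the confidences of all mapped fragments
covering that position are summed (cumulative confidence), alongside a plain
fragment count.  Sequence coverage is the percentage of nucleotides covered
by at least one fragment.  Two digests combine position-wise into four
categories: covered by digest 1 only, digest 2 only, both (mutual), or
neither.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path

import numpy as np
import pandas as pd

from .core import FragmentSet, ValidationError

__all__ = [
    "CoverageProfile",
    "Category",
    "CombinedCoverage",
    "build_profile",
    "percent_coverage",
    "combine",
    "combined_percent",
    "write_coverage_csv",
    "write_summary_json",
]


@dataclass
class CoverageProfile:
    """Per-nucleotide cumulative confidence and fragment count for one digest."""

    sequence_length: int
    cum_confidence: np.ndarray  # float, length sequence_length
    fragment_count: np.ndarray  # int, same length
    digest_id: str = ""

    def __post_init__(self) -> None:
        self.cum_confidence = np.asarray(self.cum_confidence, dtype=float)
        self.fragment_count = np.asarray(self.fragment_count, dtype=np.int64)
        if (
            self.cum_confidence.shape != (self.sequence_length,)
            or self.fragment_count.shape != (self.sequence_length,)
        ):
            raise ValidationError("coverage vectors must have length sequence_length")

    @property
    def covered(self) -> np.ndarray:
        """Boolean mask: at least one fragment covers the position."""
        return self.fragment_count > 0


class Category(IntEnum):
    """Position category in a two-digest combination."""

    NONE = 0
    D1_ONLY = 1
    D2_ONLY = 2
    MUTUAL = 3


#: Stable text labels for CSV/JSON output.
CATEGORY_LABELS = {
    Category.NONE: "none",
    Category.D1_ONLY: "d1_only",
    Category.D2_ONLY: "d2_only",
    Category.MUTUAL: "mutual",
}


@dataclass
class CombinedCoverage:
    """Position-wise combination of two digests."""

    sequence_length: int
    category: np.ndarray  # Category codes, length sequence_length
    cum_confidence_combined: np.ndarray
    digest_ids: tuple[str, str] = ("digest1", "digest2")

    def __post_init__(self) -> None:
        self.category = np.asarray(self.category, dtype=np.int8)
        self.cum_confidence_combined = np.asarray(
            self.cum_confidence_combined, dtype=float
        )


def build_profile(fragments: FragmentSet) -> CoverageProfile:
    """Accumulate per-nucleotide cumulative confidence and fragment count.

    ``cum_confidence[i]`` is the sum of the confidences of every fragment
    whose interval contains position i; positions covered by no fragment are
    exactly zero.
    """
    n = fragments.sequence_length
    # Interval accumulation via prefix sums of endpoint deltas.
    dconf = np.zeros(n + 1, dtype=float)
    dcount = np.zeros(n + 1, dtype=np.int64)
    for frag in fragments:
        dconf[frag.start - 1] += frag.confidence
        dconf[frag.end] -= frag.confidence
        dcount[frag.start - 1] += 1
        dcount[frag.end] -= 1
    conf = np.cumsum(dconf)[:n]
    count = np.cumsum(dcount)[:n]
    conf[count == 0] = 0.0  # cancel float round-off on uncovered positions
    return CoverageProfile(
        sequence_length=n,
        cum_confidence=conf,
        fragment_count=count,
        digest_id=fragments.digest_id,
    )


def percent_coverage(profile: CoverageProfile) -> tuple[int, float]:
    """Sequence coverage of one digest.

    Returns ``(rounded, raw)``: the percentage of positions covered by at
    least one fragment, rounded to the nearest integer percent for display,
    plus the raw float.
    """
    if profile.sequence_length < 1:
        raise ValidationError("sequence_length must be positive")
    raw = 100.0 * int(np.count_nonzero(profile.covered)) / profile.sequence_length
    return int(round(raw)), raw


def combine(p1: CoverageProfile, p2: CoverageProfile) -> CombinedCoverage:
    """Combine two coverage profiles position-wise.

    A position is ``MUTUAL`` iff both digests cover it, ``D1_ONLY`` /
    ``D2_ONLY`` if exactly one does, ``NONE`` otherwise; the combined
    cumulative confidence is the elementwise sum of the two profiles.
    """
    if p1.sequence_length != p2.sequence_length:
        raise ValidationError(
            f"sequence lengths differ: {p1.sequence_length} vs {p2.sequence_length}"
        )
    c1, c2 = p1.covered, p2.covered
    category = np.full(p1.sequence_length, Category.NONE, dtype=np.int8)
    category[c1 & ~c2] = Category.D1_ONLY
    category[~c1 & c2] = Category.D2_ONLY
    category[c1 & c2] = Category.MUTUAL
    return CombinedCoverage(
        sequence_length=p1.sequence_length,
        category=category,
        cum_confidence_combined=p1.cum_confidence + p2.cum_confidence,
        digest_ids=(p1.digest_id, p2.digest_id),
    )


def combined_percent(c: CombinedCoverage) -> tuple[int, float]:
    """Coverage of the union of the two digests, as (rounded, raw) percent."""
    raw = 100.0 * int(np.count_nonzero(c.category != Category.NONE)) / c.sequence_length
    return int(round(raw)), raw


def write_coverage_csv(
    obj: CoverageProfile | CombinedCoverage, path: str | Path
) -> None:
    """Write a per-position coverage CSV: position,cum_confidence,count,category."""
    n = obj.sequence_length
    if isinstance(obj, CombinedCoverage):
        df = pd.DataFrame(
            {
                "position": np.arange(1, n + 1),
                "cum_confidence": obj.cum_confidence_combined,
                "count": (obj.category != Category.NONE).astype(int),
                "category": [CATEGORY_LABELS[Category(c)] for c in obj.category],
            }
        )
    else:
        covered = obj.covered
        df = pd.DataFrame(
            {
                "position": np.arange(1, n + 1),
                "cum_confidence": obj.cum_confidence,
                "count": obj.fragment_count,
                "category": np.where(covered, "covered", "none"),
            }
        )
    df.to_csv(path, index=False)


def write_summary_json(
    path: str | Path,
    profiles: list[CoverageProfile],
    combined: CombinedCoverage | None = None,
) -> dict:
    """Write (and return) the JSON coverage summary.

    Contains each digest id with its rounded and raw percentage and, when a
    combination is present, the combined percentage.
    """
    summary: dict = {"digests": []}
    for p in profiles:
        rounded, raw = percent_coverage(p)
        summary["digests"].append(
            {"digest_id": p.digest_id, "percent": rounded, "percent_raw": raw}
        )
    if combined is not None:
        rounded, raw = combined_percent(combined)
        summary["combined"] = {
            "digest_ids": list(combined.digest_ids),
            "percent": rounded,
            "percent_raw": raw,
        }
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
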