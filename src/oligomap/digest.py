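"""In-silico full, partial and stochastic RNase digestion of an mRNA.

RNase T1 cleaves single-stranded RNA 3' of guanosine; RNase U2 is used here
with strict purine specificity (3' of A and G).  A *partial* digest leaves
some cut sites uncleaved, producing longer overlapping fragments with missed
cleavages; deterministic enumeration gives the theoretical fragment space,
while the stochastic mode models digestion extent as an independent per-site
cut probability (enzyme amount / incubation time cannot be simulated
chemically, only their net effect on cut frequency).

Monoisotopic masses are computed from IUPAC atomic masses, with variable
3'-terminus chemistry: RNase transesterification leaves a 2',3'-cyclic
phosphate whose hydrolysis product is the linear 3'-phosphate (+H2O).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import ValidationError

__all__ = [
    "CleavageRule",
    "RNASE_T1",
    "RNASE_U2",
    "Terminus3p",
    "Oligo",
    "PartialDigestParams",
    "full_digest",
    "partial_digest",
    "stochastic_partial_digest",
    "is_unique",
    "mono_mass",
    "annotate_masses",
    "MASS_H2O",
    "MASS_HPO3",
    "MASS_CH2",
]

_RNA_BASES = frozenset("ACGU")


@dataclass(frozen=True)
class CleavageRule:
    """An endoribonuclease specificity: cut 3' of any base in ``cut_after_bases``."""

    name: str
    cut_after_bases: frozenset[str]

    def __post_init__(self) -> None:
        bases = frozenset(self.cut_after_bases)
        if not bases or not bases <= _RNA_BASES:
            raise ValidationError(
                f"cut_after_bases must be a non-empty subset of A/C/G/U, got {bases}"
            )
        object.__setattr__(self, "cut_after_bases", bases)

    @classmethod
    def custom(cls, bases: str, name: str = "custom") -> "CleavageRule":
        return cls(name=name, cut_after_bases=frozenset(bases.upper()))


#: RNase T1: "G-" specificity (cuts 3' of guanosine).
RNASE_T1 = CleavageRule(name="T1", cut_after_bases=frozenset("G"))
#: RNase U2 configured strictly purine-specific ("A-,G-").
RNASE_U2 = CleavageRule(name="U2", cut_after_bases=frozenset("AG"))


class Terminus3p(str, Enum):
    OH = "OH"
    LINEAR_PHOSPHATE = "linear_phosphate"
    CYCLIC_PHOSPHATE = "cyclic_phosphate"


@dataclass(frozen=True)
class Oligo:
    """A digestion product: mRNA substring with its interval and annotations."""

    sequence: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    missed_cleavages: int = 0
    terminus_3p: Terminus3p = Terminus3p.OH
    terminus_5p: str = "OH"
    mono_mass: float | None = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class PartialDigestParams:
    """Parameters for a partial digest; exactly one mode per call.

    Deterministic mode (``max_missed_cleavages``) enumerates the theoretical
    fragment space; stochastic mode (``cut_probability`` + ``seed``) samples
    one digestion realisation.  ``min_length``/``max_length`` optionally
    window the products (MS-identifiable sizes).
    """

    max_missed_cleavages: int | None = None
    cut_probability: float | None = None
    seed: int | None = None
    min_length: int = 1
    max_length: int | None = None

    def __post_init__(self) -> None:
        if (self.max_missed_cleavages is None) == (self.cut_probability is None):
            raise ValidationError(
                "exactly one of max_missed_cleavages (deterministic) or "
                "cut_probability (stochastic) must be set"
            )
        if self.cut_probability is not None:
            if not (0.0 <= self.cut_probability <= 1.0):
                raise ValidationError("cut_probability must be in [0, 1]")
            if self.seed is None:
                raise ValidationError("stochastic mode requires a seed")
        elif self.max_missed_cleavages < 0:
            raise ValidationError("max_missed_cleavages must be >= 0")


def _validate_seq(seq: str) -> str:
    if not seq:
        raise ValidationError("sequence is empty")
    seq = seq.upper().replace("T", "U")
    for i, base in enumerate(seq):
        if base not in _RNA_BASES:
            raise ValidationError(f"invalid base {base!r} at position {i + 1}")
    return seq


def cut_sites(seq: str, rule: CleavageRule) -> list[int]:
    """0-based indices i such that the enzyme cuts between seq[i] and seq[i+1].

    The 3'-terminal base is never a cut site (nothing downstream to release).
    """
    return [i for i in range(len(seq) - 1) if seq[i] in rule.cut_after_bases]


def _oligos_from_cutpoints(seq: str, cuts: Sequence[int],
                           all_sites: Sequence[int]) -> list[Oligo]:
    """Build oligos from fired cut indices; missed cleavages counted against
    ``all_sites`` (the theoretical sites of the rule)."""
    site_set = set(all_sites)
    boundaries = [-1, *sorted(cuts), len(seq) - 1]
    out: list[Oligo] = []
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        start0, end0 = a + 1, b  # 0-based inclusive
        missed = sum(1 for i in range(start0, end0) if i in site_set)
        is_terminal = end0 == len(seq) - 1
        term = Terminus3p.OH if is_terminal else Terminus3p.CYCLIC_PHOSPHATE
        out.append(
            Oligo(
                sequence=seq[start0:end0 + 1],
                start=start0 + 1,
                end=end0 + 1,
                missed_cleavages=missed,
                terminus_3p=term,
            )
        )
    return out


def full_digest(seq: str, rule: CleavageRule) -> list[Oligo]:
    """Complete digestion: cut at every recognised site.

    The products partition the sequence (their concatenation restores it);
    every oligo except possibly the 3'-terminal one ends in a recognised
    base and contains no internal cut sites.
    """
    seq = _validate_seq(seq)
    sites = cut_sites(seq, rule)
    return _oligos_from_cutpoints(seq, sites, sites)


def partial_digest(seq: str, rule: CleavageRule, max_missed: int) -> list[Oligo]:
    """Enumerate the theoretical partial-digest fragment space.

    Returns every contiguous run of ``1..(max_missed + 1)`` full-digest
    products, each annotated with its missed-cleavage count; a superset of
    the full digest, ordered by (start, end).
    """
    if max_missed < 0:
        raise ValidationError("max_missed must be >= 0")
    seq = _validate_seq(seq)
    products = full_digest(seq, rule)
    n = len(products)
    out: list[Oligo] = []
    for i in range(n):
        for m in range(min(max_missed + 1, n - i)):
            j = i + m
            first, last = products[i], products[j]
            out.append(
                Oligo(
                    sequence=seq[first.start - 1:last.end],
                    start=first.start,
                    end=last.end,
                    missed_cleavages=m,
                    terminus_3p=last.terminus_3p,
                )
            )
    out.sort(key=lambda o: (o.start, o.end))
    return out


def stochastic_partial_digest(
    seq: str, rule: CleavageRule, params: PartialDigestParams
) -> list[Oligo]:
    """Sample one digestion realisation.

    Each theoretical cut site fires independently with ``cut_probability``
    under a generator seeded from ``params.seed``; fragments are the maximal
    uncut runs.  p=1 reproduces the full digest, p=0 the intact sequence.
    """
    if params.cut_probability is None:
        raise ValidationError("params must be in stochastic mode (cut_probability set)")
    seq = _validate_seq(seq)
    sites = cut_sites(seq, rule)
    rng = np.random.default_rng(params.seed)
    fired = [s for s, u in zip(sites, rng.random(len(sites)))
             if u < params.cut_probability]
    oligos = _oligos_from_cutpoints(seq, fired, sites)
    lo, hi = params.min_length, params.max_length
    if lo > 1 or hi is not None:
        oligos = [o for o in oligos
                  if o.length >= lo and (hi is None or o.length <= hi)]
    return oligos


def is_unique(oligo_seq: str, mrna_seq: str) -> bool:
    """True iff ``oligo_seq`` occurs exactly once in ``mrna_seq``.

    Overlapping occurrences count; zero occurrences is an error (the oligo
    is supposed to derive from the mRNA).
    """
    if not oligo_seq:
        raise ValidationError("oligo sequence is empty")
    count = 0
    pos = mrna_seq.find(oligo_seq)
    while pos != -1:
        count += 1
        if count > 1:
            return False
        pos = mrna_seq.find(oligo_seq, pos + 1)
    if count == 0:
        raise ValidationError(
            f"oligo {oligo_seq!r} does not occur in the mRNA sequence"
        )
    return True


# ---------------------------------------------------------------------------
# Monoisotopic masses
#
# IUPAC 2021 atomic monoisotopic masses, 6 decimals:
_ATOM = {"H": 1.007825, "C": 12.0, "N": 14.003074, "O": 15.994915, "P": 30.973762}

def _formula_mass(formula: Mapping[str, int]) -> float:
    return sum(_ATOM[el] * n for el, n in formula.items())

#: Ribonucleoside elemental compositions (neutral, 5'-OH, 3'-OH).
_NUCLEOSIDE_FORMULA: dict[str, dict[str, int]] = {
    "A": {"C": 10, "H": 13, "N": 5, "O": 4},   # adenosine
    "C": {"C": 9, "H": 13, "N": 3, "O": 5},    # cytidine
    "G": {"C": 10, "H": 13, "N": 5, "O": 5},   # guanosine
    "U": {"C": 9, "H": 12, "N": 2, "O": 6},    # uridine
}
_NUCLEOSIDE_MASS = {b: _formula_mass(f) for b, f in _NUCLEOSIDE_FORMULA.items()}

MASS_H2O = _formula_mass({"H": 2, "O": 1})
MASS_HPO3 = _formula_mass({"H": 1, "P": 1, "O": 3})
#: Handy offset for N1-methylpseudouridine relative to uridine (+CH2).
MASS_CH2 = _formula_mass({"C": 1, "H": 2})


def mono_mass(
    oligo_seq: str,
    terminus_3p: Terminus3p | str = Terminus3p.OH,
    mass_offsets: Mapping[str, float] | None = None,
) -> float:
    """Neutral monoisotopic mass of an oligoribonucleotide (5'-OH).

    The chain is the sum of nucleoside masses plus one phosphodiester
    (HPO3 - H2O) per internucleotide bond.  3'-terminus variants: ``OH``
    adds nothing; ``linear_phosphate`` adds HPO3; ``cyclic_phosphate`` is
    the linear phosphate minus H2O (2',3'-cyclisation).

    ``mass_offsets`` maps a base character to a Da adjustment: for a
    standard base it is added to that base's nucleoside mass (e.g.
    ``{"U": MASS_CH2}`` treats every U as N1-methylpseudouridine); for a
    non-standard character it must supply the full nucleoside mass.
    """
    if not oligo_seq:
        raise ValidationError("oligo sequence is empty")
    offsets = dict(mass_offsets or {})
    total = 0.0
    for i, base in enumerate(oligo_seq.upper()):
        if base in _NUCLEOSIDE_MASS:
            total += _NUCLEOSIDE_MASS[base] + offsets.get(base, 0.0)
        elif base in offsets:
            total += offsets[base]
        else:
            raise ValidationError(
                f"unknown base {base!r} at position {i + 1} with no mass offset"
            )
    total += (len(oligo_seq) - 1) * (MASS_HPO3 - MASS_H2O)
    term = Terminus3p(terminus_3p)
    if term is Terminus3p.LINEAR_PHOSPHATE:
        total += MASS_HPO3
    elif term is Terminus3p.CYCLIC_PHOSPHATE:
        total += MASS_HPO3 - MASS_H2O
    return total


def annotate_masses(
    oligos: Iterable[Oligo],
    mass_offsets: Mapping[str, float] | None = None,
) -> list[Oligo]:
    """Return copies of the oligos with ``mono_mass`` filled in."""
    return [
        Oligo(
            sequence=o.sequence,
            start=o.start,
            end=o.end,
            missed_cleavages=o.missed_cleavages,
            terminus_3p=o.terminus_3p,
            terminus_5p=o.terminus_5p,
            mono_mass=mono_mass(o.sequence, o.terminus_3p, mass_offsets),
        )
        for o in oligos
    ]
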