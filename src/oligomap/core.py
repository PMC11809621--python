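"""Domain types, identification-table parsing and the review-filter stage.

Oligoribonucleotide identifications exported from LC-MS/MS analysis software
(BioPharma Finder style tables) are parsed into :class:`IdentificationRecord`
objects, passed through a configurable conjunction of review filters
(:class:`FilterSpec`), and converted into mapped :class:`Fragment` intervals
ready for coverage analysis.

Coordinates are 1-based inclusive throughout the package, matching how
position columns are reported in the exports; conversion to 0-based
half-open happens only at I/O edges (arrays, pixels).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "FragmentSource",
    "Fragment",
    "IdentificationRecord",
    "FilterSpec",
    "FragmentSet",
    "ConfigurationError",
    "ValidationError",
    "DEFAULT_DIALECT",
    "read_mrna_fasta",
    "parse_identifications",
    "apply_filters",
    "records_to_fragments",
    "read_fragment_table",
    "write_fragment_table",
]


class ConfigurationError(ValueError):
    """A configuration problem (missing column, bad mapping, bad YAML key)."""


class ValidationError(ValueError):
    """Input data violates a documented invariant."""


class FragmentSource(str, Enum):
    """Where a mapped fragment came from."""

    TABLE = "table"
    IMAGE = "image"
    SIMULATED = "simulated"


@dataclass(frozen=True)
class Fragment:
    """One mapped oligoribonucleotide interval.

    Attributes
    ----------
    start, end : int
        1-based inclusive sequence positions, ``1 <= start <= end``.
    confidence : float
        Identification confidence normalised to [0, 1].
    digest_id : str
        Label of the originating digest / data set.
    source : FragmentSource
        Provenance of the interval (table, image or simulated).
    """

    start: int
    end: int
    confidence: float
    digest_id: str = ""
    source: FragmentSource = FragmentSource.TABLE

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"fragment interval ({self.start}, {self.end}) is not 1-based "
                "inclusive with start <= end"
            )
        if not (0.0 <= self.confidence <= 1.0):
            raise ValidationError(
                f"fragment confidence {self.confidence!r} outside [0, 1]"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class IdentificationRecord:
    """One row of an identification export.

    Numeric fields that could not be parsed are ``None`` (missing), never
    silently zero; missing values fail any filter criterion that inspects
    them.
    """

    oligo_sequence: str = ""
    start: int | None = None
    end: int | None = None
    modification: str = ""
    confidence_score: float | None = None
    delta_ppm: float | None = None
    nonunique_count: int | None = None
    best_asr: float | None = None
    id_type: str = ""
    mono_mass_exp: float | None = None
    identification_flags: str = ""


#: Review filters applied to raw identifications.  The defaults reproduce the
#: full review filter set used for the published CSP mRNA analysis:
#: Conf. Score >= 90, |dppm| <= 20, Nonunique Seq <= 1, Best ASR <= 2.0,
#: ID Type contains MS2, Mod does not contain None, Identification does not
#: contain nonspecific / nonunique, Mono Mass Exp. > 0.
@dataclass(frozen=True)
class FilterSpec:
    min_confidence_score: float = 90.0
    max_abs_delta_ppm: float = 20.0
    max_nonunique: int = 1
    max_best_asr: float = 2.0
    require_ms2: bool = True
    require_modification: bool = True
    exclude_nonspecific: bool = True
    exclude_nonunique_flag: bool = True
    require_positive_mono_mass: bool = True

    def __post_init__(self) -> None:
        for name in ("min_confidence_score", "max_abs_delta_ppm", "max_best_asr"):
            v = getattr(self, name)
            if v is not None and not math.isfinite(v):
                raise ValidationError(f"FilterSpec.{name} must be finite, got {v!r}")

    @classmethod
    def disabled(cls) -> "FilterSpec":
        """A spec with every criterion switched off (identity filter)."""
        return cls(
            min_confidence_score=None,  # type: ignore[arg-type]
            max_abs_delta_ppm=None,  # type: ignore[arg-type]
            max_nonunique=None,  # type: ignore[arg-type]
            max_best_asr=None,  # type: ignore[arg-type]
            require_ms2=False,
            require_modification=False,
            exclude_nonspecific=False,
            exclude_nonunique_flag=False,
            require_positive_mono_mass=False,
        )


@dataclass
class FragmentSet:
    """An ordered collection of fragments from one digest."""

    digest_id: str
    sequence_length: int
    fragments: list[Fragment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sequence_length < 1:
            raise ValidationError(
                f"sequence_length must be >= 1, got {self.sequence_length}"
            )
        for frag in self.fragments:
            if frag.end > self.sequence_length:
                raise ValidationError(
                    f"fragment ({frag.start}, {frag.end}) exceeds sequence "
                    f"length {self.sequence_length}"
                )

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self):
        return iter(self.fragments)


def read_mrna_fasta(path: str | Path) -> str:
    """Read the mRNA sequence from a FASTA file.

    The first record is used; T is mapped to U and the sequence is
    upper-cased, so DNA-alphabet FASTA files of the construct are accepted.
    """
    records = SeqIO.parse(str(path), "fasta")
    try:
        record = next(iter(records))
    except StopIteration:
        raise ValidationError(f"no FASTA records found in {path}") from None
    return str(record.seq).upper().replace("T", "U")


#: Default column-name mapping for identification tables.  Keys are
#: IdentificationRecord field names, values are the column headers expected
#: in the delimited file.  Override entries (e.g. from a YAML config) to
#: match a specific export dialect.
DEFAULT_DIALECT: dict[str, str] = {
    "oligo_sequence": "Sequence",
    "start": "Start",
    "end": "End",
    "modification": "Mod",
    "confidence_score": "Conf. Score",
    "delta_ppm": "Delta ppm",
    "nonunique_count": "Nonunique Seq",
    "best_asr": "Best ASR",
    "id_type": "ID Type",
    "mono_mass_exp": "Mono Mass Exp.",
    "identification_flags": "Identification",
}

_NUMERIC_FIELDS = {
    "start": int,
    "end": int,
    "confidence_score": float,
    "delta_ppm": float,
    "nonunique_count": int,
    "best_asr": float,
    "mono_mass_exp": float,
}
_TEXT_FIELDS = (
    "oligo_sequence",
    "modification",
    "id_type",
    "identification_flags",
)
#: Columns that must be present for records to be usable downstream.
_MANDATORY_FIELDS = ("oligo_sequence", "start", "end", "confidence_score")


def parse_identifications(
    table_path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> list[IdentificationRecord]:
    """Parse a delimited identification table into records.

    Parameters
    ----------
    table_path:
        CSV or TSV file (delimiter inferred from the extension, ``.tsv`` /
        ``.txt`` read as tab-separated).
    dialect:
        Partial or full override of :data:`DEFAULT_DIALECT`, mapping record
        field names to the column headers present in the file.

    Unparseable numeric cells become missing values (``None``), never zeros,
    so downstream filters reject rather than silently accept them.
    """
    table_path = Path(table_path)
    if not table_path.exists():
        raise ConfigurationError(f"identification table not found: {table_path}")
    mapping = dict(DEFAULT_DIALECT)
    if dialect:
        unknown = set(dialect) - set(DEFAULT_DIALECT)
        if unknown:
            raise ConfigurationError(
                f"unknown dialect field(s): {sorted(unknown)}; "
                f"expected a subset of {sorted(DEFAULT_DIALECT)}"
            )
        mapping.update(dialect)

    sep = "\t" if table_path.suffix.lower() in {".tsv", ".txt", ".tab"} else ","
    try:
        df = pd.read_csv(table_path, sep=sep, dtype=str)
    except pd.errors.EmptyDataError:
        warnings.warn(f"identification table {table_path} is empty", stacklevel=2)
        return []
    if df.empty:
        warnings.warn(f"identification table {table_path} has no data rows",
                      stacklevel=2)
        return []

    missing = [
        mapping[f] for f in _MANDATORY_FIELDS if mapping[f] not in df.columns
    ]
    if missing:
        raise ConfigurationError(
            f"mandatory column(s) missing from {table_path.name}: {missing}"
        )

    records: list[IdentificationRecord] = []
    for _, row in df.iterrows():
        kwargs: dict[str, object] = {}
        for fname in _TEXT_FIELDS:
            col = mapping[fname]
            val = row.get(col)
            kwargs[fname] = "" if pd.isna(val) else str(val).strip()
        for fname, caster in _NUMERIC_FIELDS.items():
            col = mapping[fname]
            raw = row.get(col)
            num = pd.to_numeric(raw, errors="coerce")
            kwargs[fname] = None if pd.isna(num) else caster(num)
        records.append(IdentificationRecord(**kwargs))  # type: ignore[arg-type]
    return records


def _passes(rec: IdentificationRecord, spec: FilterSpec) -> bool:
    # Pure conjunction; a missing value fails any criterion inspecting it.
    if spec.min_confidence_score is not None:
        if rec.confidence_score is None or rec.confidence_score < spec.min_confidence_score:
            return False
    if spec.max_abs_delta_ppm is not None:
        if rec.delta_ppm is None or abs(rec.delta_ppm) > spec.max_abs_delta_ppm:
            return False
    if spec.max_nonunique is not None:
        if rec.nonunique_count is None or rec.nonunique_count > spec.max_nonunique:
            return False
    if spec.max_best_asr is not None:
        if rec.best_asr is None or rec.best_asr > spec.max_best_asr:
            return False
    if spec.require_ms2 and "MS2" not in rec.id_type.upper():
        return False
    if spec.require_modification:
        mod = rec.modification.strip()
        if not mod or "NONE" in mod.upper():
            return False
    flags = rec.identification_flags.lower()
    if spec.exclude_nonspecific and "nonspecific" in flags:
        return False
    if spec.exclude_nonunique_flag and "nonunique" in flags:
        return False
    if spec.require_positive_mono_mass:
        if rec.mono_mass_exp is None or rec.mono_mass_exp <= 0:
            return False
    return True


def apply_filters(
    records: Sequence[IdentificationRecord],
    spec: FilterSpec | None = None,
) -> list[IdentificationRecord]:
    """Return the records passing every enabled review criterion.

    Order is preserved and the input is not modified.  Filtering is a pure
    conjunction, hence idempotent and order-independent across criteria.
    """
    if spec is None:
        spec = FilterSpec()
    return [rec for rec in records if _passes(rec, spec)]


def records_to_fragments(
    records: Sequence[IdentificationRecord],
    digest_id: str,
    sequence_length: int,
) -> FragmentSet:
    """Convert (filtered) identification records into a sorted FragmentSet.

    Confidence scores on a 0-100 scale are rescaled to [0, 1]; the scale is
    detected table-wide (any score > 1 means the whole table is 0-100).
    Fragments are sorted by (start, end).
    """
    scores = [r.confidence_score for r in records if r.confidence_score is not None]
    divide = 100.0 if any(s > 1.0 for s in scores) else 1.0
    fragments: list[Fragment] = []
    for i, rec in enumerate(records):
        if rec.start is None or rec.end is None:
            raise ValidationError(f"record {i} ({rec.oligo_sequence!r}) lacks positions")
        if not (1 <= rec.start <= rec.end <= sequence_length):
            raise ValidationError(
                f"record {i} ({rec.oligo_sequence!r}) interval "
                f"({rec.start}, {rec.end}) outside sequence of length {sequence_length}"
            )
        conf = 0.0 if rec.confidence_score is None else rec.confidence_score / divide
        fragments.append(
            Fragment(
                start=rec.start,
                end=rec.end,
                confidence=min(max(conf, 0.0), 1.0),
                digest_id=digest_id,
                source=FragmentSource.TABLE,
            )
        )
    fragments.sort(key=lambda f: (f.start, f.end))
    return FragmentSet(digest_id=digest_id, sequence_length=sequence_length,
                       fragments=fragments)


_TABLE_COLUMNS = ["digest_id", "start", "end", "length", "confidence", "source"]


def write_fragment_table(fragset: FragmentSet, path: str | Path) -> None:
    """Write the canonical fragment table CSV.

    Header: ``digest_id,start,end,length,confidence,source``.
    """
    df = pd.DataFrame(
        [
            {
                "digest_id": f.digest_id or fragset.digest_id,
                "start": f.start,
                "end": f.end,
                "length": f.length,
                "confidence": f.confidence,
                "source": f.source.value,
            }
            for f in fragset.fragments
        ],
        columns=_TABLE_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_fragment_table(path: str | Path, sequence_length: int) -> FragmentSet:
    """Read a canonical fragment table CSV back into a FragmentSet."""
    df = pd.read_csv(path)
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns and c != "length"]
    if missing:
        raise ConfigurationError(f"fragment table {path} missing column(s) {missing}")
    digest_id = str(df["digest_id"].iloc[0]) if len(df) else ""
    fragments = [
        Fragment(
            start=int(r.start),
            end=int(r.end),
            confidence=float(r.confidence),
            digest_id=str(r.digest_id),
            source=FragmentSource(str(r.source)),
        )
        for r in df.itertuples()
    ]
    fragments.sort(key=lambda f: (f.start, f.end))
    return FragmentSet(digest_id=digest_id, sequence_length=sequence_length,
                       fragments=fragments)


def unique_only(fragset: FragmentSet, mrna_seq: str,
                oligo_sequences: Iterable[str] | None = None) -> FragmentSet:
    """Restrict a FragmentSet to fragments whose sequence is unique in the mRNA.

    The fragment's sequence is taken from the mRNA substring at its interval.
    ``oligo_sequences`` may override this per fragment (parallel iterable).
    """
    from .digest import is_unique  # local import to avoid cycle

    seqs = list(oligo_sequences) if oligo_sequences is not None else [
        mrna_seq[f.start - 1:f.end] for f in fragset.fragments
    ]
    kept = [
        f for f, s in zip(fragset.fragments, seqs)
        if s and mrna_seq.count(s) > 0 and is_unique(s, mrna_seq)
    ]
    return replace_fragments(fragset, kept)


def replace_fragments(fragset: FragmentSet, fragments: list[Fragment]) -> FragmentSet:
    return FragmentSet(digest_id=fragset.digest_id,
                       sequence_length=fragset.sequence_length,
                       fragments=list(fragments))
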