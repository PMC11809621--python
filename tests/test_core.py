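"""Identification parsing, review filtering and fragment conversion."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oligomap.core import (
    ConfigurationError,
    FilterSpec,
    Fragment,
    FragmentSet,
    IdentificationRecord,
    ValidationError,
    apply_filters,
    parse_identifications,
    read_mrna_fasta,
    records_to_fragments,
    read_fragment_table,
    write_fragment_table,
)

from conftest import passing_record


class TestParseIdentifications:
    def test_row_count_preserved(self, toy_csv):
        records = parse_identifications(toy_csv)
        assert len(records) == 3
        assert records[0].oligo_sequence == "AAG"
        assert records[0].confidence_score == 95.0
        assert records[2].identification_flags == "nonunique"

    def test_unparseable_numeric_becomes_missing(self, tmp_path):
        path = tmp_path / "ids.csv"
        path.write_text(
            "Sequence,Start,End,Mod,Conf. Score,Delta ppm,Nonunique Seq,"
            "Best ASR,ID Type,Mono Mass Exp.,Identification\n"
            "AAG,1,3,3' phosphate,n/a,2.5,1,1.2,Full MS2,972.1,specific\n"
        )
        (rec,) = parse_identifications(path)
        assert rec.confidence_score is None  # missing, not zero
        # and the missing value fails the confidence criterion downstream
        assert apply_filters([rec]) == []

    def test_shuffled_columns_with_mapping_identical(self, toy_csv, tmp_path):
        shuffled = tmp_path / "shuffled.csv"
        # same data, different column order and headers, mapped explicitly
        shuffled.write_text(
            "ppm,score,stop,begin,seq,mod,nuq,asr,idtype,mass,flags\n"
            "2.5,95,3,1,AAG,3' phosphate,1,1.2,Full MS2,972.1,specific\n"
            "-4.0,91,6,4,UCG,cyclic phosphate,1,1.0,Full MS2,934.1,specific\n"
            "30.0,50,7,7,A,3' phosphate,4,3.0,MS1 only,347.0,nonunique\n"
        )
        dialect = {
            "oligo_sequence": "seq",
            "start": "begin",
            "end": "stop",
            "modification": "mod",
            "confidence_score": "score",
            "delta_ppm": "ppm",
            "nonunique_count": "nuq",
            "best_asr": "asr",
            "id_type": "idtype",
            "mono_mass_exp": "mass",
            "identification_flags": "flags",
        }
        assert parse_identifications(shuffled, dialect) == parse_identifications(
            toy_csv
        )

    def test_missing_mandatory_column_names_it(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("Sequence,End\nAAG,3\n")
        with pytest.raises(ConfigurationError, match="Start"):
            parse_identifications(path)

    def test_empty_file_warns_and_returns_empty(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.warns(UserWarning):
            assert parse_identifications(path) == []

    def test_unknown_dialect_key_rejected(self, toy_csv):
        with pytest.raises(ConfigurationError, match="unknown dialect"):
            parse_identifications(toy_csv, {"no_such_field": "X"})


def oracle_passes(rec: IdentificationRecord, spec: FilterSpec) -> bool:
    """Independent per-record re-check of all nine criteria."""
    checks = []
    if spec.min_confidence_score is not None:
        checks.append(rec.confidence_score is not None
                      and rec.confidence_score >= spec.min_confidence_score)
    if spec.max_abs_delta_ppm is not None:
        checks.append(rec.delta_ppm is not None
                      and -spec.max_abs_delta_ppm <= rec.delta_ppm
                      <= spec.max_abs_delta_ppm)
    if spec.max_nonunique is not None:
        checks.append(rec.nonunique_count is not None
                      and rec.nonunique_count <= spec.max_nonunique)
    if spec.max_best_asr is not None:
        checks.append(rec.best_asr is not None
                      and rec.best_asr <= spec.max_best_asr)
    if spec.require_ms2:
        checks.append("ms2" in rec.id_type.lower())
    if spec.require_modification:
        checks.append(bool(rec.modification.strip())
                      and "none" not in rec.modification.lower())
    if spec.exclude_nonspecific:
        checks.append("nonspecific" not in rec.identification_flags.lower())
    if spec.exclude_nonunique_flag:
        checks.append("nonunique" not in rec.identification_flags.lower())
    if spec.require_positive_mono_mass:
        checks.append(rec.mono_mass_exp is not None and rec.mono_mass_exp > 0)
    return all(checks)


def random_record(rng: np.random.Generator) -> IdentificationRecord:
    maybe = lambda v: None if rng.random() < 0.15 else v
    return IdentificationRecord(
        oligo_sequence="AUCG",
        start=int(rng.integers(1, 50)),
        end=int(rng.integers(50, 100)),
        modification=str(rng.choice(["3' phosphate", "cyclic phosphate", "None", ""])),
        confidence_score=maybe(float(rng.uniform(0, 100))),
        delta_ppm=maybe(float(rng.uniform(-40, 40))),
        nonunique_count=maybe(int(rng.integers(0, 4))),
        best_asr=maybe(float(rng.uniform(0, 4))),
        id_type=str(rng.choice(["Full MS2", "partial MS2", "MS1 only"])),
        mono_mass_exp=maybe(float(rng.uniform(-10, 5000))),
        identification_flags=str(
            rng.choice(["specific", "nonspecific", "nonunique", ""])
        ),
    )


class TestApplyFilters:
    def test_default_retains_clean_record(self):
        assert apply_filters([passing_record()]) == [passing_record()]

    def test_confidence_score_cutoff_is_90(self):
        # review threshold: confidence score >= 90, so 89.9 is rejected
        rec = passing_record(confidence_score=89.9)
        assert apply_filters([rec]) == []
        assert apply_filters([passing_record(confidence_score=90.0)]) != []

    @pytest.mark.parametrize(
        "override",
        [
            {"delta_ppm": 20.5},
            {"delta_ppm": -25.0},
            {"nonunique_count": 2},
            {"best_asr": 2.1},
            {"id_type": "MS1 only"},
            {"modification": "None"},
            {"identification_flags": "nonspecific"},
            {"identification_flags": "nonunique"},
            {"mono_mass_exp": 0.0},
        ],
    )
    def test_each_criterion_rejects(self, override):
        assert apply_filters([passing_record(**override)]) == []

    def test_boundary_values_retained(self):
        rec = passing_record(delta_ppm=20.0, best_asr=2.0, nonunique_count=1,
                             confidence_score=90.0)
        assert apply_filters([rec]) == [rec]

    def test_random_records_match_per_record_oracle(self):
        rng = np.random.default_rng(29)
        records = [random_record(rng) for _ in range(50)]
        spec = FilterSpec()
        kept = apply_filters(records, spec)
        assert kept == [r for r in records if oracle_passes(r, spec)]

    def test_idempotent_and_order_preserving(self):
        rng = np.random.default_rng(31)
        records = [random_record(rng) for _ in range(80)]
        once = apply_filters(records)
        assert apply_filters(once) == once
        # order preserved: retained list is a subsequence of the input
        it = iter(records)
        assert all(any(r == x for x in it) for r in once)

    def test_all_disabled_spec_is_identity(self):
        rng = np.random.default_rng(37)
        records = [random_record(rng) for _ in range(40)]
        assert apply_filters(records, FilterSpec.disabled()) == records

    def test_input_not_modified(self):
        records = [passing_record(), passing_record(confidence_score=10.0)]
        snapshot = list(records)
        apply_filters(records)
        assert records == snapshot


class TestRecordsToFragments:
    def test_full_confidence_normalisation(self):
        rec = passing_record(start=10, end=15, confidence_score=100.0)
        fs = records_to_fragments([rec], "d1", 100)
        assert fs.fragments == [
            Fragment(start=10, end=15, confidence=1.0, digest_id="d1")
        ]

    def test_single_nucleotide_fragment(self):
        rec = passing_record(start=1, end=1, confidence_score=90.0)
        (frag,) = records_to_fragments([rec], "d1", 10).fragments
        assert (frag.start, frag.end, frag.confidence) == (1, 1, 0.9)

    def test_already_unit_scale_not_rescaled(self):
        recs = [passing_record(confidence_score=0.8),
                passing_record(confidence_score=0.4)]
        fs = records_to_fragments(recs, "d1", 100)
        assert sorted(f.confidence for f in fs.fragments) == [0.4, 0.8]

    def test_shuffled_records_sorted_and_counted(self):
        rng = np.random.default_rng(41)
        recs = [
            passing_record(start=int(s), end=int(s + rng.integers(0, 10)))
            for s in rng.integers(1, 80, size=20)
        ]
        rng.shuffle(recs)
        fs = records_to_fragments(recs, "d1", 100)
        assert len(fs) == 20
        keys = [(f.start, f.end) for f in fs.fragments]
        assert keys == sorted(keys)
        # endpoints unchanged
        assert sorted(keys) == sorted((r.start, r.end) for r in recs)

    def test_out_of_bounds_record_named(self):
        rec = passing_record(start=95, end=105, oligo_sequence="AUCGAUCGAUC")
        with pytest.raises(ValidationError, match="AUCGAUCGAUC"):
            records_to_fragments([rec], "d1", 100)


class TestFragmentTableRoundTrip:
    def test_write_then_read(self, tmp_path):
        fs = FragmentSet(
            digest_id="d1",
            sequence_length=50,
            fragments=[
                Fragment(1, 10, 0.75, "d1"),
                Fragment(5, 20, 1.0, "d1"),
            ],
        )
        path = tmp_path / "frags.csv"
        write_fragment_table(fs, path)
        header = path.read_text().splitlines()[0]
        assert header == "digest_id,start,end,length,confidence,source"
        back = read_fragment_table(path, 50)
        assert back.fragments == fs.fragments


class TestFasta:
    def test_first_record_t_mapped_to_u(self, tmp_path):
        path = tmp_path / "seq.fa"
        path.write_text(">construct\naagtcga\n>ignored\nCCCC\n")
        assert read_mrna_fasta(path) == "AAGUCGA"


class TestFragmentInvariants:
    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(start=st.integers(-5, 30), end=st.integers(-5, 30),
           conf=st.floats(-0.5, 1.5, allow_nan=False))
    def test_constructor_enforces_invariants(self, start, end, conf):
        valid = 1 <= start <= end and 0.0 <= conf <= 1.0
        if valid:
            frag = Fragment(start=start, end=end, confidence=conf)
            assert frag.length == end - start + 1 >= 1
        else:
            with pytest.raises(ValidationError):
                Fragment(start=start, end=end, confidence=conf)
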