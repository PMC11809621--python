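"""Shared fixtures: toy sequences, identification tables and random worlds."""

from __future__ import annotations

import numpy as np
import pytest

from oligomap.core import Fragment, FragmentSet, FragmentSource, IdentificationRecord

TOY_SEQ = "AAGUCGA"


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))


def random_fragmentset(
    rng: np.random.Generator,
    sequence_length: int,
    n_fragments: int,
    digest_id: str = "rand",
) -> FragmentSet:
    frags = []
    for _ in range(n_fragments):
        start = int(rng.integers(1, sequence_length + 1))
        end = int(rng.integers(start, sequence_length + 1))
        conf = float(rng.choice([0.25, 0.5, 0.75, 1.0]))
        frags.append(Fragment(start=start, end=end, confidence=conf,
                              digest_id=digest_id,
                              source=FragmentSource.SIMULATED))
    frags.sort(key=lambda f: (f.start, f.end))
    return FragmentSet(digest_id=digest_id, sequence_length=sequence_length,
                       fragments=frags)


def passing_record(**overrides) -> IdentificationRecord:
    """A record that passes the default review filters; override per test."""
    base = dict(
        oligo_sequence="AUCG",
        start=10,
        end=13,
        modification="3' phosphate",
        confidence_score=95.0,
        delta_ppm=5.0,
        nonunique_count=1,
        best_asr=1.1,
        id_type="Full MS2",
        mono_mass_exp=3200.0,
        identification_flags="specific",
    )
    base.update(overrides)
    return IdentificationRecord(**base)


@pytest.fixture
def toy_csv(tmp_path):
    path = tmp_path / "ids.csv"
    path.write_text(
        "Sequence,Start,End,Mod,Conf. Score,Delta ppm,Nonunique Seq,"
        "Best ASR,ID Type,Mono Mass Exp.,Identification\n"
        "AAG,1,3,3' phosphate,95,2.5,1,1.2,Full MS2,972.1,specific\n"
        "UCG,4,6,cyclic phosphate,91,-4.0,1,1.0,Full MS2,934.1,specific\n"
        "A,7,7,3' phosphate,50,30.0,4,3.0,MS1 only,347.0,nonunique\n"
    )
    return path
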