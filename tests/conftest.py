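from __future__ import annotations

import numpy as np
import pytest

from estkit.preprocess import FeatureAnnotation, MaskedEST
from estkit.seqio import SeqRecord, SourceTag, format_identifier

BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in np.flatnonzero(rng.random(len(out)) < rate):
        out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


def make_id(n: int, library: str = "embryo", strategy: str = "five_to_three") -> str:
    center = "JGI" if library == "embryo" else "GEN"
    return format_identifier(SourceTag(library, center, strategy, f"clone{n:04d}"))


def as_est(record: SeqRecord) -> MaskedEST:
    return MaskedEST(record, FeatureAnnotation((), record.bases))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
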