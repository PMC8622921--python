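import numpy as np
import pytest

from afgpkit.repeat_scanner import RepeatRegion, TripeptideUnit

#: canonical codon spellings used to build fixtures
TAA_DNA = "ACAGCAGCA"   # Thr-Ala-Ala
TPA_DNA = "ACACCAGCA"   # Thr-Pro-Ala
RAA_DNA = "AGAGCAGCA"   # Arg-Ala-Ala
KAA_DNA = "AAAGCAGCA"   # Lys-Ala-Ala


def region_from_units(unit_dnas, start=0) -> RepeatRegion:
    units = [TripeptideUnit.from_dna(i, d) for i, d in enumerate(unit_dnas)]
    return RepeatRegion(start, start + 9 * len(units), units)


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


def random_cds(rng, max_len=600) -> str:
    """A random CDS: either pure random DNA or random DNA with a planted,
    lightly mutated repeat tract — the scanner oracle's test distribution."""
    bases = "ACGT"
    if rng.random() < 0.3:
        length = int(rng.integers(9, max_len))
        return "".join(bases[i] for i in rng.integers(0, 4, size=length))
    n_units = int(rng.integers(2, 20))
    pool = [TAA_DNA, TPA_DNA, RAA_DNA, KAA_DNA]
    tract = "".join(pool[i] for i in rng.integers(0, 4, size=n_units))
    tract = list(tract)
    for _ in range(rng.poisson(0.15 * n_units)):
        tract[int(rng.integers(0, len(tract)))] = bases[int(rng.integers(0, 4))]
    tract = "".join(tract)
    lead = int(rng.integers(0, (max_len - len(tract)) // 2 + 1))
    tail = int(rng.integers(0, (max_len - len(tract) - lead) + 1))
    left = "".join(bases[i] for i in rng.integers(0, 4, size=lead))
    right = "".join(bases[i] for i in rng.integers(0, 4, size=tail))
    return (left + tract + right)[:max_len]
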