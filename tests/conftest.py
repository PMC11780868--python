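import numpy as np
import pytest

from g4therm.seqio import AlignedSequence, Alignment, NucleotideSequence


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_seq(residues: str, seq_id: str = "s1") -> NucleotideSequence:
    return NucleotideSequence(seq_id, residues)


def make_alignment(rows: dict[str, str]) -> Alignment:
    return Alignment(tuple(AlignedSequence(k, v) for k, v in rows.items()))


def random_dna(rng, length: int, gc: float = 0.5) -> str:
    bases = np.array(list("ACGT"))
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(bases[rng.choice(4, size=length, p=p)])
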