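import random

import pytest

from mitoarchitect.genome_io import CircularGenome
from mitoarchitect.synth_data import SirPlan, SynthConfig, generate_genome


def random_seq(rng: random.Random, n: int, gc: float = 0.45) -> str:
    w = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choices("ACGT", weights=w, k=n))


@pytest.fixture
def rng():
    return random.Random(20240917)


@pytest.fixture
def minimal_genbank(tmp_path):
    """Handcrafted 100-bp circular record: one + strand gene at 11..40 and
    one wrapping complement(join(90..100,1..10)) feature."""
    seq = ("gatcctccat atacaacggt atctccacct caggtttaga tctcaacaac ggaaccattg"
           " ccgacatgag acagttaggt atcgtcgaga gttacaagct").replace(" ", "")
    assert len(seq) == 100
    text = f"""LOCUS       TESTREC                  100 bp    DNA     circular INV 01-JAN-2020
DEFINITION  handcrafted test record.
ACCESSION   TESTREC
VERSION     TESTREC.1
FEATURES             Location/Qualifiers
     source          1..100
                     /organism="synthetic"
     CDS             11..40
                     /gene="genA"
     tRNA            complement(join(90..100,1..10))
                     /gene="trnW"
ORIGIN
"""
    for i in range(0, 100, 60):
        chunk = seq[i:i + 60]
        blocks = " ".join(chunk[j:j + 10] for j in range(0, len(chunk), 10))
        text += f"{i + 1:>9} {blocks}\n"
    text += "//\n"
    path = tmp_path / "test.gb"
    path.write_text(text)
    return path


@pytest.fixture(scope="session")
def planted_genome():
    """A 22-kb synthetic genome with planted SIR families (session-cached)."""
    cfg = SynthConfig(
        length=30000, gc=0.40, seed=7, genome_id="fix1",
        sir_plan=(SirPlan("GGCGCC", 12, stem_range=(7, 12), loop_range=(0, 5)),
                  SirPlan("AAAAAA", 6, stem_range=(8, 10), loop_range=(2, 4),
                          region="coding")),
    )
    return generate_genome(cfg)


def as_genome(seq: str, topology: str = "linear", gid: str = "g") -> CircularGenome:
    return CircularGenome(gid, seq, topology)
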