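import random

import pytest

from srnapipe.pipeline import run_pipeline
from srnapipe.records import ReadRecord
from srnapipe.simulate import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The default two-library synthetic study (shared across tests)."""
    return generate_dataset(seed=1)


@pytest.fixture(scope="session")
def default_result(default_dataset):
    ds = default_dataset
    return run_pipeline(
        ds.libraries, ds.bundle.family_alignments, ds.bundle.reference_sets,
        contigs=ds.contigs,
    )


@pytest.fixture(scope="session")
def tiny_dataset():
    cfg = SimulationConfig(
        n_known=4, n_novel_conserved=3, n_novel_specific=5,
        locus_min_count=300, locus_max_count=3000,
    )
    return generate_dataset(cfg, seed=11)


def random_sequence(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


def end_variant_reads(n_loci: int = 10, n_variants: int = 10, seed: int = 0) -> list[ReadRecord]:
    """Reads drawn as 5'/3' end variants of a few base sequences."""
    rng = random.Random(seed)
    reads = []
    for locus in range(n_loci):
        base = random_sequence(rng, 30)
        for v in range(n_variants):
            s5 = rng.randint(0, 3)
            s3 = rng.randint(0, 3)
            seq = base[s5 : len(base) - s3]
            tail = rng.choice(["", "T", "A"])
            reads.append(
                ReadRecord(
                    id=f"l{locus}v{v}", sequence=seq + tail,
                    counts={"lib": rng.randint(1, 500)},
                )
            )
    return reads
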