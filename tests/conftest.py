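import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from felsnp.io import AlignedRead, ReferenceAssembly
from felsnp.nqs import NqsParams
from felsnp.simulate import (
    PopulationModel,
    ReadModel,
    simulate_population,
    simulate_reads,
)


@pytest.fixture(scope="session")
def small_truth():
    """1-Mb single-chromosome eight-cat population."""
    model = PopulationModel(chromosome_plan=[("chr1", 1_000_000, False)])
    return simulate_population(model, 11)


@pytest.fixture(scope="session")
def small_reads(small_truth):
    """~1x total coverage of the 1-Mb population, errors on."""
    rm = ReadModel(coverage=1.0 / 8)
    return simulate_reads(small_truth, rm, 11)


@pytest.fixture
def params():
    return NqsParams()


def make_reference(seed: int, length: int = 2_000, n_run=None) -> ReferenceAssembly:
    """Random single-chromosome reference, optionally with one N-run."""
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = bases[rng.integers(0, 4, size=length)].copy()
    if n_run is not None:
        s, e = n_run
        seq[s:e] = ord("N")
    return ReferenceAssembly({"chr1": seq.tobytes().decode()})


def perfect_read(
    assembly: ReferenceAssembly,
    start: int = 100,
    length: int = 60,
    q: int = 40,
    individual: str = "Pixel",
    read_id: str = "r1",
) -> AlignedRead:
    """A read exactly matching the reference, uniform quality."""
    seq = assembly.sequences["chr1"][start : start + length]
    return AlignedRead(
        read_id=read_id,
        individual=individual,
        chrom="chr1",
        start=start,
        strand="+",
        seq=seq,
        quals=np.full(length, q, dtype=np.uint8),
        cigar=[("M", length)],
    )
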