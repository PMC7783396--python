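import itertools
from functools import lru_cache

import numpy as np
import pytest

from oligopaint import fixtures as fx
from oligopaint.core import DesignParameters, Genome, GenomicInterval, Oligo
from oligopaint.reporting import DesignResult, TargetRegion, run_design


@pytest.fixture
def params() -> DesignParameters:
    return DesignParameters()


def random_dna(n: int, seed: int, gc: float = 0.5) -> str:
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join("ACGT"[i] for i in rng.choice(4, size=n, p=p))


@pytest.fixture
def small_genome() -> Genome:
    return Genome(
        "small",
        {"s1": random_dna(20_000, seed=11), "s2": random_dna(15_000, seed=12)},
    )


_oligo_counter = itertools.count()


def make_oligo(seq: str, chrom: str = "s1", start: int | None = None,
               region_id: str | None = None, fluorochrome: str | None = None) -> Oligo:
    if start is None:  # distinct default origins keep oligo ids unique
        start = next(_oligo_counter) * 100
    return Oligo.from_origin(
        seq, GenomicInterval(chrom, start, start + len(seq)),
        region_id=region_id, fluorochrome=fluorochrome,
    )


@lru_cache(maxsize=8)
def design_for_seed(seed: int):
    """Full study-conditions run: source genome, derived sister genome with
    one translocation / inversion / deletion / duplication, and the complete
    design pipeline. Cached because several tests share it."""
    spec = fx.default_fixture_spec(seed)
    genome, truth = fx.make_genome(spec)
    reads = fx.simulate_reads(genome, spec.read_coverage, spec.read_len, spec.seed)
    genome2, truth2 = fx.derive_genome(
        genome, truth, spec.divergence, spec.indel_rate,
        spec.rearrangements, spec.seed + 1,
    )
    targets = [
        TargetRegion(t.interval, t.region_id, t.fluorochrome) for t in truth.targets
    ]
    result: DesignResult = run_design(
        genome, targets, DesignParameters(rng_seed=seed), reads=reads,
        known_repeat_seqs=list(truth.known_repeat_sequences().values()),
        secondary_genomes=[genome2],
    )
    return spec, genome, truth, genome2, truth2, result


@pytest.fixture(scope="session")
def demo_design():
    return design_for_seed(1)
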