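import numpy as np
import pytest

from repeatomekit import GenomeIndex, RepeatHit


@pytest.fixture
def small_genome() -> GenomeIndex:
    return GenomeIndex({"chr1": 10_000, "chr2": 5_000})


def make_hit(
    query="chr1",
    qstart=0,
    qend=100,
    divergence=10.0,
    repeat_name="Tc1-1",
    repeat_class="DNA/TcMar-Tc1",
    strand="+",
    **kwargs,
) -> RepeatHit:
    return RepeatHit(
        query=query,
        qstart=qstart,
        qend=qend,
        strand=strand,
        repeat_name=repeat_name,
        repeat_class=repeat_class,
        divergence=divergence,
        **kwargs,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
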