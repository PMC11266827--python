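import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def two_family_reads():
    """Small one-sample skim with two clean planted families (session-wide)."""
    from repskim.synth import (GenomeSpec, MonoploidBlueprint,
                               RepeatFamilySpec, build_genome, skim_reads)

    fams = (
        RepeatFamilySpec("famA", "LTR-Gypsy", 500, 40, 0.0),
        RepeatFamilySpec("famB", "LTR-Copia", 450, 36, 0.0),
    )
    bp = MonoploidBlueprint(background_length=30_000, families=fams,
                            site_spacing=300)
    spec = GenomeSpec(sample_code="TFAM", subgenomes=(bp,), seed=77)
    genome, truth = build_genome(spec)
    reads = skim_reads(genome, coverage=0.5, sample_code="TFAM",
                       rng=np.random.default_rng(7), error_rate=0.0,
                       truth=truth)
    return reads, truth
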