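import pytest

from mitocomp.synth import SynthSpec, synth_mitogenome


@pytest.fixture(scope="session")
def canonical_genome():
    """One deterministic canonical-order synthetic mitogenome."""
    return synth_mitogenome(SynthSpec(seed=7))


@pytest.fixture(scope="session")
def genome_set():
    """Five deterministic synthetic mitogenomes (a study-sized panel)."""
    return [synth_mitogenome(SynthSpec(seed=s)) for s in range(101, 106)]
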