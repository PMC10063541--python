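import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from nickedit import synthio as syn  # noqa: E402


@pytest.fixture(scope="session")
def small_digest():
    """100 kb genome with two planted sites per cleavage class, digested at
    30x; shared across tests that only read the result."""
    specs, models = syn.planted_site_layout("chr1", 100_000, 2, 2, 2, margin=3000)
    genome = syn.make_toy_genome(1, 100_000, specs, seed=11)
    reads = syn.simulate_digested_reads(
        genome, models, syn.FragmentationParams(seed=11)
    )
    return genome, models, reads


@pytest.fixture(scope="session")
def demo_edit_spec():
    return syn.make_demo_edit_spec(seed=2)
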