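import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from methstretch.readstats import MethRead
from methstretch.simulate import generate_cg_landscape

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


def make_read(calls, read_id="r0", chrom="chrSim", start=0, allele="U",
              spacing=10, contexts=None):
    """Build a MethRead from a plain call vector with evenly spaced CG sites."""
    calls = np.asarray(calls, dtype=np.uint8)
    positions = start + np.arange(calls.size, dtype=np.int64) * spacing
    end = start + max(calls.size * spacing, 1)
    return MethRead(read_id, chrom, start, end, positions, calls, allele, contexts)


@pytest.fixture
def small_landscape():
    return generate_cg_landscape(50_000, 10.0, seed=42)


@pytest.fixture
def dense_landscape():
    return generate_cg_landscape(120_000, 10.0, seed=7)
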