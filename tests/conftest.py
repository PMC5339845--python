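import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import nomekit.simulate as sim
from nomekit.calls import SampleCalls

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_calls(rows, sample_id="toy", **meta) -> SampleCalls:
    """Build a SampleCalls from (chrom, pos, strand, context, meth, unmeth) rows."""
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context", "meth", "unmeth"])
    return SampleCalls(sample_id, df, **meta)


@pytest.fixture(scope="session")
def small_bundle():
    """A small two-cell-type study reused across read-level tests."""
    cfg = sim.SimulationConfig(seed=7, genome_length=60_000, n_genes=10,
                               lambda_length=20_000, mean_depth=15.0)
    return sim.simulate_study(cfg, [sim.SampleSpec("fgc_rep1", "fgc"),
                                    sim.SampleSpec("soma_rep1", "soma")])


@pytest.fixture(scope="session")
def small_cfg(small_bundle):
    return small_bundle.config


@pytest.fixture(scope="session")
def fgc_calls(small_bundle):
    return small_bundle.samples["fgc_rep1"]


@pytest.fixture(scope="session")
def soma_calls(small_bundle):
    return small_bundle.samples["soma_rep1"]
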