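import numpy as np
import pandas as pd
import pytest


def make_calls(rows):
    """Build a call table from (chrom, pos, strand, context, mc, cov) rows."""
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context",
                                       "mc", "cov"])


@pytest.fixture
def calls_factory():
    return make_calls


@pytest.fixture(scope="session")
def default_sim():
    """Seed-1 default simulation (full 2 x 5 x 3 structure), shared across
    tests; coverage-filtered call tables alongside the raw result."""
    from hapmeth import default_config, simulate_all

    result = simulate_all(default_config(seed=1))
    filtered = {k: c[c["cov"] >= 4].reset_index(drop=True)
                for k, c in result.samples.items()}
    return result, filtered


def stage_groups(filtered, stage1, stage2):
    g1 = [c for (h, s, r), c in sorted(filtered.items()) if s == stage1]
    g2 = [c for (h, s, r), c in sorted(filtered.items()) if s == stage2]
    return g1, g2
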