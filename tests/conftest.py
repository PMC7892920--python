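import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from orthosim.design import ReplicateParams, replicate_seed
from orthosim.pipeline import PipelineConfig, run_replicate
from orthosim.trees import generate_guide_tree

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")

# fixed study conditions for the shared heavy runs
LADDER_RATES = (0.2, 2.0, 5.0, 10.0)
LADDER_ALPHA = 0.7
LADDER_SEEDS = (0, 1, 2)
LADDER_MASTER = 11


@pytest.fixture(scope="session")
def guide57():
    return generate_guide_tree(57, seed=1)


@pytest.fixture(scope="session")
def slow_run_57(guide57):
    """Slowest-rate regime on the 57-leaf guide tree: 30 families of length
    200 at multiplier 0.2, alpha 1.0 — the zero-error reference run."""
    params = ReplicateParams(
        replicate_id=0,
        gene_rate_multiplier=0.2,
        alpha=1.0,
        n_genes=30,
        sequence_lengths=(200,) * 30,
        rng_seed=replicate_seed(1, 0),
    )
    return run_replicate(guide57, params, PipelineConfig())


@pytest.fixture(scope="session")
def guide24():
    return generate_guide_tree(24, seed=7)


@pytest.fixture(scope="session")
def rate_ladder(guide24):
    """Rate ladder {0.2, 2, 5, 10} x 3 seeds at fixed alpha 0.7; 20 genes of
    length 200 on a 24-leaf guide tree. One row per replicate."""
    rows = []
    rid = 0
    for rate in LADDER_RATES:
        for s in LADDER_SEEDS:
            params = ReplicateParams(
                replicate_id=rid,
                gene_rate_multiplier=rate,
                alpha=LADDER_ALPHA,
                n_genes=20,
                sequence_lengths=(200,) * 20,
                rng_seed=replicate_seed(LADDER_MASTER + s, rid),
            )
            res = run_replicate(guide24, params, PipelineConfig())
            assert not res.failed, res.error
            rows.append({"rate": rate, "seed": s, **res.__dict__})
            rid += 1
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def alpha_runs(guide24):
    """Multiplier 5 at alpha 0.3 vs 2.5, 3 seeds each, same tree as the ladder."""
    rows = []
    for alpha in (0.3, 2.5):
        for s in LADDER_SEEDS:
            params = ReplicateParams(
                replicate_id=s,
                gene_rate_multiplier=5.0,
                alpha=alpha,
                n_genes=20,
                sequence_lengths=(200,) * 20,
                rng_seed=replicate_seed(LADDER_MASTER + 100 + s, 0),
            )
            res = run_replicate(guide24, params, PipelineConfig())
            assert not res.failed, res.error
            rows.append({"alpha": alpha, "seed": s, **res.__dict__})
    return pd.DataFrame(rows)
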