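"""Shared fixtures: the 4x5 reference alignment instance, the five-protein
demonstration score table, and the frozen two-family synthetic benchmark."""

import numpy as np
import pandas as pd
import pytest

from eigas import generate_synthetic_family
from eigas.evaluate import ScoreTable


@pytest.fixture(scope="session")
def demo_similarity() -> np.ndarray:
    """Reference 4x5 similarity matrix with a known optimal alignment at
    rho = 0.3: path (0,0), (gap,1), (1,2), (2,3), (3,4), value 0.9."""
    return np.array(
        [
            [0.1, 0.2, 0.8, 0.7, 1.2],
            [0.5, 0.4, 0.2, 0.1, 0.5],
            [0.2, 0.3, 0.1, 0.2, 0.2],
            [0.8, 0.7, 0.6, 0.1, 0.1],
        ]
    )


DEMO_OPTIMAL_PATH = [(0, 0), (None, 1), (1, 2), (2, 3), (3, 4)]
DEMO_COLUMN_COSTS = [0.1, 0.3, 0.2, 0.2, 0.1]

# per-entry stability intervals of demo_similarity at rho = 0.3
# (None upper bound = unbounded)
DEMO_ENTRY_INTERVALS = [
    [(0.0, 0.2), (0.1, None), (0.0, None), (0.0, None), (0.0, None)],
    [(0.0, None), (0.3, None), (0.0, 0.3), (0.0, None), (0.0, None)],
    [(0.0, None), (0.0, None), (0.0, None), (0.0, 0.3), (0.0, None)],
    [(0.0, None), (0.0, None), (0.0, None), (0.0, None), (0.0, 0.2)],
]


@pytest.fixture(scope="session")
def demo_score_table() -> ScoreTable:
    """Five-protein demonstration score table: families {A,B,D} and {C,E}.

    Known facts: 4 of the 10 pairs are same-family; at tau = 0.20 the rates
    are TPR 2/4, FPR 1/6; AUROC is 22/24."""
    ids = ["A", "B", "C", "D", "E"]
    scores = pd.DataFrame(
        [
            [0.00, 0.21, 0.43, 0.13, 0.68],
            [0.21, 0.00, 0.61, 0.26, 0.34],
            [0.43, 0.61, 0.00, 0.80, 0.08],
            [0.13, 0.26, 0.80, 0.00, 0.19],
            [0.68, 0.34, 0.08, 0.19, 0.00],
        ],
        index=ids,
        columns=ids,
    )
    families = {"A": "1", "B": "1", "C": "2", "D": "1", "E": "2"}
    return ScoreTable(scores=scores, families=families)


# frozen benchmark conditions: two families of 4 members, 40 residues,
# 0.3 Å within-family jitter
BENCHMARK_PARAMS = dict(n_members=4, length=40, jitter_sd=0.3)
BENCHMARK_SEEDS = [(11, 101), (22, 202)]


@pytest.fixture(scope="session")
def benchmark_chains():
    chains = []
    for template_seed, member_seed in BENCHMARK_SEEDS:
        chains.extend(
            generate_synthetic_family(
                template_seed=template_seed, member_seed=member_seed, **BENCHMARK_PARAMS
            )
        )
    return chains


@pytest.fixture(scope="session")
def benchmark_families(benchmark_chains):
    return {c.chain_id: c.family_id for c in benchmark_chains}
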