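"""Shared fixtures: the worked-example graph, small read sets, and one
session-scoped synthetic benchmark run reused by the acceptance tests."""

import warnings

import numpy as np
import pytest

from readfix import (CorrectionParams, ThresholdConfig, build_table,
                     correct_read, fig1_fixture, resolve_alpha)
from readfix.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def fig1():
    """(table, read, params) for the k=4 worked path-extension example."""
    return fig1_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def benchmark_run():
    """One full synthetic benchmark: simulate, build table, correct all reads.

    20 transcripts on 1:20:400 tiers, 20,000 x 100 bp reads, 0.5% flat
    errors, k=23. Shared across tests to keep the suite fast.
    """
    config = SimConfig(seed=1)
    transcripts, clean, mutated, truths, origins = simulate_dataset(config)
    table = build_table(mutated, 23)
    tc = ThresholdConfig()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        alpha = resolve_alpha(table, tc, seed=1)
    params = CorrectionParams(k=23, alpha=alpha, threshold_config=tc)
    results = [correct_read(r, table, params) for r in mutated]
    return {
        "config": config,
        "transcripts": transcripts,
        "clean": clean,
        "mutated": mutated,
        "truths": truths,
        "origins": origins,
        "table": table,
        "params": params,
        "results": results,
    }
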