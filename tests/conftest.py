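"""Shared fixtures: benchmark corpora and their pipeline runs.

The benchmark study condition is the simulator's default corpus (20
species, 6 families, substitution 0.15/site/branch, loss 0.1, 50 decoys
per species) plus two targeted scenario injections: a forced loss of
FAM1 in SP02 (a clean single-species hole) and a single-species loner
family seeded in the first reference species.  Five seeds are run once
per session and shared by every test that needs full-pipeline output.
"""

from __future__ import annotations

import pytest

from zfscan.formats_io import PipelineConfig
from zfscan.pipeline import run_pipeline
from zfscan.simdata import SimConfig, simulate

BENCH_SEEDS = (1, 2, 3, 4, 5)
FORCED_HOLE = ("SP02", "FAM1")


def benchmark_sim_config(seed: int) -> SimConfig:
    return SimConfig(rng_seed=seed, forced_losses=(FORCED_HOLE,), loner_family=True)


def benchmark_pipeline_config(seed: int) -> PipelineConfig:
    # score_threshold on this model's calibrated scale: any confidently
    # positive log-odds forwards, the E-value filter carries specificity
    return PipelineConfig(rng_seed=seed, score_threshold=1.0)


@pytest.fixture(scope="session")
def benchmark_runs():
    """seed -> (SimConfig, corpus, PipelineConfig, FamilyCallTable)."""
    runs = {}
    for seed in BENCH_SEEDS:
        sim = benchmark_sim_config(seed)
        corpus = simulate(sim)
        cfg = benchmark_pipeline_config(seed)
        calls = run_pipeline(
            corpus.seed_alignments,
            corpus.proteomes,
            corpus.reference_db,
            corpus.master,
            corpus.taxonomy,
            cfg,
        )
        runs[seed] = (sim, corpus, cfg, calls)
    return runs


@pytest.fixture(scope="session")
def small_corpus():
    """A cheaper corpus (3 families, 10 decoys/species) for plumbing tests."""
    sim = SimConfig(rng_seed=7, n_families=3, n_decoys=10)
    return sim, simulate(sim)
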