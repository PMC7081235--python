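"""Shared fixtures: small simulated experiments and one full pipeline run.

Everything is generated programmatically at fixed seeds; nothing is read
from disk.  The session-scoped pipeline bundle is reused by the regulon,
response and acceptance tests so the full pipeline runs only once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from stressregulon.core_io import AnnotationMap, CountExperiment
from stressregulon.pipeline import PipelineConfig, run_pipeline
from stressregulon.synthetic import (
    SimConfig,
    make_binding_map,
    make_modules,
    simulate_experiment,
    small_config,
)


def make_experiment(counts: np.ndarray, genotypes=None, stresses=None,
                    timepoints=None, replicates=None) -> CountExperiment:
    """Build a CountExperiment from a raw matrix with a synthesized design."""
    n_genes, n_samples = counts.shape
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{i}" for i in range(n_samples)]
    design = pd.DataFrame({
        "genotype": genotypes or ["wt"] * n_samples,
        "stress": stresses or ["heat"] * n_samples,
        "timepoint": timepoints or ["control"] * n_samples,
        "replicate": replicates or list(range(1, n_samples + 1)),
    }, index=samples)
    return CountExperiment(genes=genes, samples=samples, counts=counts,
                           design=design)


def two_group_experiment(ya: np.ndarray, yb: np.ndarray) -> CountExperiment:
    """Two design cells (control vs early) from per-group count blocks."""
    na, nb = ya.shape[1], yb.shape[1]
    return make_experiment(
        np.hstack([ya, yb]),
        timepoints=["control"] * na + ["early"] * nb,
        replicates=list(range(1, na + 1)) + list(range(1, nb + 1)),
    )


@pytest.fixture(scope="session")
def sim_small():
    """Small-preset simulation with planted structure (seed 1)."""
    cfg = small_config(seed=1)
    experiment, truth = simulate_experiment(cfg)
    binding = make_binding_map(cfg, truth)
    modules_df = make_modules(cfg, truth)
    module_map = AnnotationMap(targets={
        m: frozenset(sub["gene"]) for m, sub in modules_df.groupby("module")})
    return {"config": cfg, "experiment": experiment, "truth": truth,
            "binding": binding, "modules_df": modules_df,
            "module_map": module_map}


@pytest.fixture(scope="session")
def pipeline_bundle(sim_small):
    """Full pipeline run on the small preset (permutations kept modest)."""
    config = PipelineConfig(seed=1, n_perm=2000)
    bundle = run_pipeline(sim_small["experiment"], config,
                          binding_map=sim_small["binding"],
                          modules=sim_small["module_map"])
    return {"config": config, "bundle": bundle, **sim_small}
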