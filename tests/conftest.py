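"""Shared fixtures: small simulated experiments generated at session scope."""

from __future__ import annotations

import pytest

from silaf import (
    ExperimentDesign,
    NoiseModel,
    RunConfig,
    make_ground_truth,
    run_pipeline,
    simulate_experiment,
)


def _config_for(paths, **overrides) -> RunConfig:
    kwargs = dict(
        evidence=str(paths["evidence"]),
        protein_groups=str(paths["protein_groups"]),
        sites=str(paths.get("sites", "")),
        annotation=str(paths["annotation"]),
        gene_sets=str(paths["gene_sets"]),
    )
    kwargs.update(overrides)
    return RunConfig(**kwargs)


@pytest.fixture(scope="session")
def small_noisy(tmp_path_factory):
    """50-protein default-noise comparison experiment, simulated and run."""
    root = tmp_path_factory.mktemp("small_noisy")
    gt = make_ground_truth(n_proteins=50, seed=11)
    paths = simulate_experiment(gt, root / "sim")
    config = _config_for(paths, gsea_n_perm=200, rng_seed=11)
    summary = run_pipeline(config, root / "run")
    return {"gt": gt, "paths": paths, "config": config,
            "run_dir": root / "run", "summary": summary}


@pytest.fixture(scope="session")
def noise_free_run(tmp_path_factory):
    """200-protein noise-free comparison experiment (exact recovery regime)."""
    root = tmp_path_factory.mktemp("noise_free")
    gt = make_ground_truth(n_proteins=200, noise=NoiseModel.noise_free(), seed=7)
    paths = simulate_experiment(gt, root / "sim")
    config = _config_for(paths, gsea_n_perm=200, rng_seed=7)
    run_pipeline(config, root / "run")
    return {"gt": gt, "run_dir": root / "run"}


@pytest.fixture(scope="session")
def default_fixture(tmp_path_factory):
    """The 1000-protein default-noise fixture (n = 4 bio x 2 tech)."""
    root = tmp_path_factory.mktemp("default_fixture")
    gt = make_ground_truth(n_proteins=1000, seed=101)
    paths = simulate_experiment(gt, root / "sim")
    config = _config_for(paths, gsea_n_perm=1000, rng_seed=101)
    run_pipeline(config, root / "run")
    return {"gt": gt, "run_dir": root / "run"}


@pytest.fixture(scope="session")
def timecourse_run(tmp_path_factory):
    """200-protein pulse-labeling time course (8 timepoints, n = 2)."""
    root = tmp_path_factory.mktemp("timecourse")
    gt = make_ground_truth(
        n_proteins=200, seed=13,
        design=ExperimentDesign(mode="timecourse", n_bio=2))
    paths = simulate_experiment(gt, root / "sim")
    config = RunConfig(evidence=str(paths["evidence"]),
                       protein_groups=str(paths["protein_groups"]),
                       mode="timecourse")
    run_pipeline(config, root / "run")
    return {"gt": gt, "run_dir": root / "run"}
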