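import numpy as np
import pandas as pd
import pytest

from divergon.coexpression import ExpressionDataset
from divergon.pipeline import RunConfig, run_pipeline
from divergon.synthetic import SimulationConfig, simulate_all, write_simulation


@pytest.fixture(scope="session")
def default_sim():
    """The generator's default study conditions under one fixed seed."""
    return simulate_all(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_sim():
    """A desk-sized simulation for fast stage-level tests."""
    return simulate_all(
        SimulationConfig(
            seed=7,
            n_chromosomes=2,
            genes_per_chromosome=100,
            n_h2h_pairs=30,
            n_datasets=2,
            samples_per_dataset=40,
        )
    )


def _run_config_for(data, outdir, **overrides):
    paths = write_simulation(data, str(outdir))
    kwargs = dict(
        annotation=paths["annotation"],
        expression_manifest=paths["manifest"],
        tfmap=paths["tf"],
        obo=paths["obo"],
        annotations=paths["annot"],
        species=[
            (sp, paths[f"orthologs_{sp}"], paths[f"annotation_{sp}"])
            for sp in data.config.species
        ],
        seed=data.config.seed,
        log_level="WARNING",
    )
    kwargs.update(overrides)
    return RunConfig(**kwargs)


@pytest.fixture(scope="session")
def default_report(tmp_path_factory, default_sim):
    """Full pipeline run on the default synthetic config (shared, expensive)."""
    outdir = tmp_path_factory.mktemp("default_sim")
    cfg = _run_config_for(default_sim, outdir, out_dir=str(outdir / "run"))
    return run_pipeline(cfg)


@pytest.fixture
def make_run_config(tmp_path):
    def _make(data, **overrides):
        return _run_config_for(data, tmp_path, **overrides)

    return _make


@pytest.fixture
def toy_dataset():
    """8-gene, 12-sample reproducible expression matrix."""
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(8)]
    values = pd.DataFrame(
        rng.standard_normal((8, 12)), index=genes,
        columns=[f"s{j}" for j in range(12)],
    )
    return ExpressionDataset(dataset_id="toy", values=values)
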