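from types import SimpleNamespace

import pytest

from nbskit.pipeline import config_from_simdir, run_all
from nbskit.simulate import SimConfig, simulate_repertoire, write_bundles


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A small 3-species bundle: quick to generate, exercises every feature."""
    cfg = SimConfig(
        seed=11, n_ancestral_genes=6, dup_rate=2.0, loss_rate=0.5,
        expansions_per_species=1, segmental_events_per_species=1,
    )
    bundles, truth = simulate_repertoire(cfg)
    d = tmp_path_factory.mktemp("smallsim")
    write_bundles(bundles, truth, d)
    return SimpleNamespace(cfg=cfg, bundles=bundles, truth=truth, dir=d)


@pytest.fixture(scope="session")
def study_sim(tmp_path_factory):
    """The default study-scale bundle (3 species, ~130 NBS genes)."""
    cfg = SimConfig(seed=7)
    bundles, truth = simulate_repertoire(cfg)
    d = tmp_path_factory.mktemp("studysim")
    write_bundles(bundles, truth, d)
    return SimpleNamespace(cfg=cfg, bundles=bundles, truth=truth, dir=d)


@pytest.fixture(scope="session")
def study_run(study_sim, tmp_path_factory):
    """Full pipeline output on the study-scale bundle."""
    out = tmp_path_factory.mktemp("studyrun")
    cfg = config_from_simdir(study_sim.dir, out, seed=7, bootstrap_reps=200)
    return SimpleNamespace(result=run_all(cfg), out=out, config=cfg, sim=study_sim)
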