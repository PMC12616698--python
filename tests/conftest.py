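import pytest

from resmine.hook_panel import builtin_panel
from resmine.pipeline import RunConfig, run_mine
from resmine.synth import SimTruth, default_config, generate_genomes

SIM_SEED = 1


@pytest.fixture(scope="session")
def panel():
    return builtin_panel()


@pytest.fixture(scope="session")
def sim_run(tmp_path_factory):
    """Default synthetic study: 5 genomes, 4 true resistant BGCs, 9 decoys."""
    out = tmp_path_factory.mktemp("sim")
    manifest, truth = generate_genomes(default_config(SIM_SEED), out)
    return out, manifest, truth


def make_run_config(sim_dir, manifest, out_dir) -> RunConfig:
    return RunConfig(
        genomes=[
            {
                "fasta": m["fasta"],
                "gff3": m["gff3"],
                "assembly_id": m["assembly_id"],
            }
            for m in manifest
        ],
        taxa_tsv=str(sim_dir / "taxa.tsv"),
        out_dir=str(out_dir),
        seed=SIM_SEED,
    )


@pytest.fixture(scope="session")
def pipeline_run(sim_run, tmp_path_factory):
    """Full pipeline executed once on the default synthetic inputs."""
    sim_dir, manifest, truth = sim_run
    out = tmp_path_factory.mktemp("run")
    report = run_mine(make_run_config(sim_dir, manifest, out))
    return report, truth
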