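import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "hsdkit",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("hsdkit")

from hsdkit.pipeline import PipelineConfig, run_pipeline  # noqa: E402
from hsdkit.simulate import PlantSpec, SimConfig, default_planted, simulate  # noqa: E402


def bundle_config(seed: int = 11) -> SimConfig:
    """Default study conditions plus one tandem family carrying a diverged
    pseudo-copy (to exercise HSD identity exclusion)."""
    planted = default_planted()
    planted[2] = PlantSpec("TD", 3, 95.0, 0.15, diverged_extra=True)
    return SimConfig(seed=seed, planted=planted)


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    return simulate(bundle_config(), tmp_path_factory.mktemp("sim"))


@pytest.fixture(scope="session")
def pipeline_result(bundle, tmp_path_factory):
    p = bundle.paths
    cfg = PipelineConfig(
        gff=p["gff"],
        proteins=p["proteins"],
        cds=p["cds"],
        blast=p["blast"],
        out_dir=tmp_path_factory.mktemp("run"),
        outgroup_gff=p["outgroup_gff"],
        outgroup_blast=p["outgroup_blast"],
        interproscan=p["interproscan"],
        ko=p["ko"],
    )
    return run_pipeline(cfg)
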