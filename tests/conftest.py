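import pytest

from mtp9 import synth


@pytest.fixture(scope="session")
def small_cfg() -> synth.SimConfig:
    return synth.SimConfig(
        n_per_group=8, n_snps=60, n_transcripts=300, n_linked=30,
        depth_mean=300, seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg, tmp_path_factory):
    """One small cohort written to disk, shared across the session."""
    out = tmp_path_factory.mktemp("cohort")
    truth = synth.simulate_cohort(small_cfg, out)
    return out, truth
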