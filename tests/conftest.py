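import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "fosnet",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fosnet")


@pytest.fixture(scope="session")
def paper_study():
    """The canned 4-condition study (13 regions, n = 7/9/9/9), seed 7."""
    from fosnet import default_paper_study

    return default_paper_study(7)


@pytest.fixture()
def two_block_spec():
    """Factory for 13-region two-block condition specs."""
    from fosnet import ConditionSpec

    def make(rho_within=0.85, rho_between=0.0, n=200, name="test"):
        regions = [f"R{i:02d}" for i in range(13)]
        part = {r: (1 if i < 7 else 2) for i, r in enumerate(regions)}
        return ConditionSpec(
            condition_name=name,
            n_subjects=n,
            region_means={r: 100.0 for r in regions},
            region_sds={r: 10.0 for r in regions},
            planted_partition=part,
            rho_within=rho_within,
            rho_between={(1, 2): rho_between},
        )

    return make
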