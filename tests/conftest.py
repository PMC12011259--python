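import pytest

from forestcarbon.sampling_design import SamplingConfig, Stratum


@pytest.fixture
def two_strata():
    return [Stratum("s1", 0.6, 20.0), Stratum("s2", 0.4, 30.0)]


@pytest.fixture
def base_config():
    return SamplingConfig(
        total_area=100.0,
        plot_area=0.08,
        reliability_index=1.645,
        error_bound=5.0,
    )
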