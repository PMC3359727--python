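import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def single_dsf_curve(tmp_path):
    """Noiseless single-transition melt curve plus its generating parameters."""
    from xtalprio import synth_fixtures as sf
    from xtalprio import dsf_analysis as da
    spec = sf.DsfSpec(baseline=200.0, transitions=[(323.0, 1.5, 1000.0)], noise=0.0)
    csv, _ = sf.gen_dsf_curve(spec, tmp_path, seed=0)
    return da.parse_dsf_csv(csv)[0], spec


@pytest.fixture
def two_peak_chromatogram(tmp_path):
    from xtalprio import synth_fixtures as sf
    from xtalprio import sec_analysis as sa
    spec = sf.SecSpec(components=[(100.0, 20.0, 2.0), (50.0, 30.0, 2.0)], noise=0.0)
    cu, doc, _ = sf.gen_sec_chromatogram(spec, tmp_path, seed=0)
    return sa.parse_sec_ascii(cu, doc), spec
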