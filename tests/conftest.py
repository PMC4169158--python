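import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mutvar as mv

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def exact_line_bins():
    """Three bins lying exactly on log10(z) = -10.5 + 0.1 * MI."""
    n = 10 ** 12
    return [
        mv.MIBin(mi_mid=5.0, n=n, d=100),     # z = 1e-10
        mv.MIBin(mi_mid=15.0, n=n, d=1000),   # z = 1e-9
        mv.MIBin(mi_mid=25.0, n=n, d=10000),  # z = 1e-8
    ]


@pytest.fixture(scope="session")
def synthetic_study():
    """A DNM study sized like the real ones: ~650 DNMs, 12 width-10 MI
    bins over [0, 120), generating slope 0.01 per MI unit (log10)."""
    track = mv.make_mi_track(1_200_000, [(1.0, 60.0, 1e6)], (0, 119), seed=11)
    model = mv.TrueRateModel(intercept=-8.0, slope=0.01)
    dnms = mv.sample_dnms(track, model, 650, seed=12)
    bins = mv.bin_by_mi(dnms, track)
    fit = mv.fit_loglinear(bins)
    return track, model, dnms, bins, fit
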