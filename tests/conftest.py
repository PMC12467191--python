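import pandas as pd
import pytest

from fibroburden.synthetic import (
    CauseParams,
    PanelSpec,
    default_cause_params,
    generate_panel,
)


def delta_free_params():
    """Default cause parameters with the inefficiency offset switched off."""
    params = default_cause_params()
    return {
        m: {c: CauseParams(p.frontier_intercept, p.frontier_slope, 0.0,
                           p.gradient_intercept, p.gradient_slope)
            for c, p in per.items()}
        for m, per in params.items()
    }


@pytest.fixture(scope="session")
def small_spec():
    return PanelSpec(n_locations=30, years=(2000, 2009), seed=11)


@pytest.fixture(scope="session")
def small_panel(small_spec):
    """A 30-location, 10-year panel with the default noisy frontier structure."""
    return generate_panel(small_spec)


@pytest.fixture(scope="session")
def noiseless_panel():
    """Noise-free, inefficiency-free panel: every rate sits on the frontier."""
    spec = PanelSpec(n_locations=40, years=(2000, 2009), noise_sd=0.0,
                     cause_params=delta_free_params(), seed=13)
    return generate_panel(spec)


@pytest.fixture(scope="session")
def noiseless_panel_with_delta():
    """Noise-free panel keeping exponential inefficiencies, plus the pooled
    (SDI, rate) cloud for neoplasm DALYs used by frontier recovery tests."""
    import pandas as pd

    from fibroburden.gbd_io import slice_panel

    spec = PanelSpec(n_locations=80, years=(2000, 2015), noise_sd=0.0, seed=17)
    panel, truth = generate_panel(spec)
    pieces = []
    for yr in panel.years:
        s = slice_panel(panel, yr, "Neoplasms").rename(columns={"value": "asr"})
        s.insert(1, "year", yr)
        pieces.append(s)
    cloud = pd.concat(pieces, ignore_index=True)
    return panel, truth, cloud


@pytest.fixture
def three_countries():
    """Equal-population toy cross-section with closed-form ranks 1/6, 1/2, 5/6."""
    return pd.DataFrame({
        "location": ["Alphaland", "Betaland", "Gammaland"],
        "sdi": [0.2, 0.5, 0.8],
        "population": [1.0, 1.0, 1.0],
    })
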