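import numpy as np
import pandas as pd
import pytest

from droughtlegacy import SimConfig, generate_sites

SITE_DEFAULTS = {
    "srad": 180.0, "vpd": 8.0, "t": 10.0, "p": 800.0, "sm": 0.25, "lai": 3.0,
    "soc": 60.0, "soil_n": 4.0, "soil_cec": 20.0, "ai": 0.8, "igbp": "ENF",
    "diversity": 25.0, "sla": 15.0, "root_depth": 2.0, "root_shoot": 0.3,
    "wood_density": 0.55, "canopy_height": 20.0, "latitude": 45.0,
}


def make_site(pdsi, gpp=None, years=None, site_id="S1", cwd=None,
              cwd_q95=None, **overrides):
    """Hand-construct a one-site annual record.

    ``pdsi`` drives PDSI-metric drought status; ``years`` defaults to
    1..len(pdsi); ``gpp`` defaults to 1000 everywhere (NaN allowed).
    """
    pdsi = np.asarray(pdsi, dtype=float)
    n = len(pdsi)
    years = np.arange(1, n + 1) if years is None else np.asarray(years)
    gpp = np.full(n, 1000.0) if gpp is None else np.asarray(gpp, dtype=float)
    cwd = np.full(n, 100.0) if cwd is None else np.asarray(cwd, dtype=float)
    row = dict(SITE_DEFAULTS)
    row.update(overrides)
    df = pd.DataFrame({"site_id": site_id, "year": years, "gpp": gpp,
                       "pdsi": pdsi, "cwd": cwd, **row})
    if cwd_q95 is not None:
        df["cwd_q95"] = cwd_q95
    return df


@pytest.fixture(scope="session")
def default_population():
    """Moderate seeded population shared by read-only tests."""
    cfg = SimConfig(n_sites=80, years_per_site=25, seed=11)
    table, truth = generate_sites(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def clean_population():
    """Noise-free population: GPP is exactly baseline x multipliers."""
    cfg = SimConfig(n_sites=40, years_per_site=20, seed=7, noise_cv=0.0)
    table, truth = generate_sites(cfg)
    return cfg, table, truth
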