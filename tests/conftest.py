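import numpy as np
import pandas as pd
import pytest

from u5mproj.panel import CountyYearPanel
from u5mproj.synthetic import SyntheticConfig, make_adjacency, simulate_panel


@pytest.fixture(scope="session")
def default_panel():
    """Default synthetic study panel: 47 counties x 2003-2014, 10 factors."""
    cfg = SyntheticConfig(seed=1)
    graph = make_adjacency(cfg.n_counties, cfg.seed)
    panel, truth = simulate_panel(cfg, graph)
    return cfg, graph, panel, truth


def small_synthetic_config(seed, **kw):
    """Reduced-scale generator config used by the recovery simulations."""
    defaults = dict(
        n_counties=20,
        year_start=2003,
        year_end=2010,
        factor_names=["f1", "f2", "decoy"],
        true_beta={"f1": -0.8, "f2": 0.9, "decoy": 0.0},
        true_alpha=-3.0,
        sigma_w=0.3,
        sigma_nu=0.02,
        sigma_t=0.05,
        sigma_delta=0.12,
        factor_start_ranges={},
        seed=seed,
    )
    defaults.update(kw)
    return SyntheticConfig(**defaults)


def toy_panel(values, factors, years=(2003, 2014)):
    """Build a small panel from {factor: {county: {year: value}}} plus U5M.

    ``values`` maps column name ('u5m' or a factor) to a per-county list of
    per-year values aligned with ``years``.
    """
    counties = range(len(next(iter(values.values()))))
    rows = []
    for ci in counties:
        for yi, year in enumerate(years):
            row = {"county_id": ci, "year": year}
            for col, per_county in values.items():
                row[col] = per_county[ci][yi]
            rows.append(row)
    df = pd.DataFrame(rows)
    if "u5m" not in df.columns:
        df["u5m"] = 50.0
    return CountyYearPanel(df, factors)
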