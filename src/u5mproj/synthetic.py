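"""Synthetic county-panel generator with known ground truth.

The original Kenyan county panel (model-based U5M and coverage estimates,
2003-2014) is not publicly deposited, so every analysis in this package
runs on synthetic panels that reproduce the statistical structure the
model assumes:

* per-county coverage trajectories following a constant annual rate of
  change (exponential paths, clipped to (0.001, 0.999));
* a log-linear mortality surface
  ``log(U5M_it / 1000) = alpha + sum_k beta_k x_kit + w_i + nu_i + phi_t + delta_it``
  with ``w`` an intrinsic-CAR (ICAR) spatial field on a county adjacency
  graph, ``nu`` iid county effects, ``phi`` a sum-to-zero Gaussian random
  walk over years, and ``delta`` iid county-year noise.

Default parameter values (47 counties, years 2003-2014, ten intervention
factors, their regression coefficients and the four variance components)
mirror the fitted Kenyan analysis, so recovery tests exercise the model at
realistic signal-to-noise.  The generator returns the ground-truth effects
alongside the panel for those tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .panel import CountyYearPanel

__all__ = [
    "DEFAULT_FACTORS",
    "DEFAULT_TRUE_BETA",
    "DEFAULT_TRUE_ALPHA",
    "SyntheticConfig",
    "SyntheticTruth",
    "make_adjacency",
    "simulate_panel",
    "sample_icar",
]

# Ten intervention factors retained in the final Kenyan model, with their
# posterior-mean coefficients (per unit-proportion change in coverage).
# HIV prevalence is the one harmful factor (positive coefficient).
DEFAULT_TRUE_BETA = {
    "anc4": -0.7098,
    "antimalarial_use": -0.0416,
    "breastfed_1hr": -0.4162,
    "improved_sanitation": -0.2136,
    "facility_delivery": -0.4740,
    "fever_treatment": -1.2550,
    "hiv_prevalence": 6.5930,
    "child_itn_use": -0.0065,
    "fully_immunised": -0.5817,
    "improved_water": -0.3558,
}
DEFAULT_FACTORS = list(DEFAULT_TRUE_BETA)
DEFAULT_TRUE_ALPHA = -0.9273


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic panel generator.

    Coverage paths: each county-factor draws a 2003 starting proportion
    uniformly from ``coverage_start_range`` and an annual rate of change
    (percent/year) uniformly from ``coverage_arc_range``, then follows the
    constant-rate exponential path, clipped to (0.001, 0.999).  The default
    rate range (-5, +8) %/yr brackets the observed Kenyan factor trends
    (HIV prevalence fell ~4.7%/yr; facility delivery rose ~4.9%/yr).

    Variance components default to the fitted posterior means:
    ``sigma_w`` (spatial ICAR) 0.5336, ``sigma_nu`` (iid county) 0.0024,
    ``sigma_t`` (random-walk year effect) 0.0591 and ``sigma_delta``
    (county-year interaction, doubling as the residual) 0.1398.
    """

    n_counties: int = 47
    year_start: int = 2003
    year_end: int = 2014
    factor_names: list = field(default_factory=lambda: list(DEFAULT_FACTORS))
    seed: int = 0
    coverage_start_range: tuple = (0.15, 0.85)
    coverage_arc_range: tuple = (-5.0, 8.0)
    #: per-factor overrides of the starting range; prevalence-type factors
    #: live near the bottom of the unit interval (county HIV prevalence was
    #: a few percent, not tens of percent)
    factor_start_ranges: dict = field(
        default_factory=lambda: {"hiv_prevalence": (0.01, 0.15)}
    )
    sigma_w: float = 0.5336
    sigma_nu: float = 0.0024
    sigma_t: float = 0.0591
    sigma_delta: float = 0.1398
    true_beta: dict = field(default_factory=lambda: dict(DEFAULT_TRUE_BETA))
    true_alpha: float = DEFAULT_TRUE_ALPHA

    def __post_init__(self):
        if self.n_counties < 2:
            raise ValueError("n_counties must be >= 2")
        if self.year_end - self.year_start + 1 < 3:
            raise ValueError("year range must span at least 3 years")
        for name in ("sigma_w", "sigma_nu", "sigma_t", "sigma_delta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        lo, hi = self.coverage_start_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("coverage_start_range must lie inside (0, 1)")
        for f, (flo, fhi) in self.factor_start_ranges.items():
            if not (0.0 < flo <= fhi < 1.0):
                raise ValueError(f"start range for {f!r} must lie inside (0, 1)")
        missing = [f for f in self.factor_names if f not in self.true_beta]
        if missing:
            raise ValueError(f"true_beta missing entries for {missing}")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)


@dataclass
class SyntheticTruth:
    """Ground-truth effects behind a simulated panel (for recovery tests)."""

    alpha: float
    beta: dict
    w: dict        # county -> structured spatial effect (sums to zero)
    nu: dict       # county -> unstructured spatial effect
    phi: dict      # year -> temporal effect (sums to zero)
    delta: dict    # (county, year) -> interaction/residual

    def to_json_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "beta": dict(self.beta),
            "w": {str(k): v for k, v in self.w.items()},
            "nu": {str(k): v for k, v in self.nu.items()},
            "phi": {str(k): v for k, v in self.phi.items()},
            "delta": {f"{c},{t}": v for (c, t), v in self.delta.items()},
        }


def make_adjacency(n_counties: int, seed: int) -> nx.Graph:
    """Build a connected, irregular county adjacency graph.

    Counties are placed on a jittered square grid; each is linked to its
    nearest neighbours (Euclidean), the graph is symmetrized, and any
    remaining components are bridged through their closest cross-pair.
    This yields planar-ish contiguity structure similar to real county
    maps.  Deterministic for a given ``(n_counties, seed)``.
    """
    if n_counties < 2:
        raise ValueError("n_counties must be >= 2")
    rng = np.random.default_rng(seed)
    side = int(np.ceil(np.sqrt(n_counties)))
    grid = np.array([(i % side, i // side) for i in range(n_counties)], dtype=float)
    pts = grid + rng.uniform(-0.35, 0.35, size=grid.shape)

    g = nx.Graph()
    g.add_nodes_from(range(n_counties))
    k = min(3, n_counties - 1)
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    for i in range(n_counties):
        for j in np.argsort(d2[i])[:k]:
            g.add_edge(i, int(j))

    # bridge components deterministically through the closest pair
    comps = [sorted(c) for c in nx.connected_components(g)]
    while len(comps) > 1:
        comps.sort(key=lambda c: c[0])
        base, best = comps[0], None
        for other in comps[1:]:
            for i in base:
                for j in other:
                    if best is None or d2[i, j] < best[0]:
                        best = (d2[i, j], i, j)
        g.add_edge(best[1], best[2])
        comps = [sorted(c) for c in nx.connected_components(g)]
    return g


def sample_icar(graph: nx.Graph, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Draw one realisation of a sum-to-zero ICAR field on ``graph``.

    Uses the eigendecomposition of the graph Laplacian: the null eigenvector
    (constant) is removed, the remaining directions are scaled by
    ``sigma / sqrt(lambda)``, and the result is centred so the field sums to
    zero exactly (the ICAR identifiability constraint).
    """
    n = graph.number_of_nodes()
    if sigma == 0.0:
        return np.zeros(n)
    L = nx.laplacian_matrix(graph, nodelist=range(n)).toarray().astype(float)
    lam, V = np.linalg.eigh(L)
    keep = lam > 1e-10
    z = rng.standard_normal(keep.sum())
    w = V[:, keep] @ (z / np.sqrt(lam[keep])) * sigma
    return w - w.mean()


def simulate_panel(config: SyntheticConfig, adjacency: nx.Graph):
    """Simulate a county-year panel and its ground truth.

    Returns ``(panel, truth)``.  Coverage follows per-county constant-rate
    exponential paths; log-mortality is the additive log-linear surface
    described in the module docstring; U5M is returned in deaths per 1,000
    livebirths.
    """
    if adjacency.number_of_nodes() != config.n_counties:
        raise ValueError(
            f"adjacency has {adjacency.number_of_nodes()} nodes, "
            f"config expects {config.n_counties}"
        )
    rng = np.random.default_rng(config.seed)
    C, years = config.n_counties, config.years
    T, K = len(years), len(config.factor_names)

    # coverage paths, shape (C, T, K)
    start = rng.uniform(*config.coverage_start_range, size=(C, K))
    for ki, f in enumerate(config.factor_names):
        if f in config.factor_start_ranges:
            lo, hi = config.factor_start_ranges[f]
            start[:, ki] = lo + (hi - lo) * (start[:, ki] - config.coverage_start_range[0]) / (
                config.coverage_start_range[1] - config.coverage_start_range[0]
            )
    arcs = rng.uniform(*config.coverage_arc_range, size=(C, K))
    steps = (years - years[0])[None, :, None]
    X = start[:, None, :] * np.exp(arcs[:, None, :] / 100.0 * steps)
    X = np.clip(X, 0.001, 0.999)

    # random effects
    w = sample_icar(adjacency, config.sigma_w, rng)
    nu = rng.normal(0.0, config.sigma_nu, size=C) if config.sigma_nu > 0 else np.zeros(C)
    if config.sigma_t > 0:
        phi = np.cumsum(rng.normal(0.0, config.sigma_t, size=T))
        phi -= phi.mean()
    else:
        phi = np.zeros(T)
    delta = (
        rng.normal(0.0, config.sigma_delta, size=(C, T))
        if config.sigma_delta > 0
        else np.zeros((C, T))
    )

    beta = np.array([config.true_beta[f] for f in config.factor_names])
    log_rate = (
        config.true_alpha
        + X @ beta
        + w[:, None]
        + nu[:, None]
        + phi[None, :]
        + delta
    )
    u5m = 1000.0 * np.exp(log_rate)

    rows = []
    for ci in range(C):
        for ti, year in enumerate(years):
            row = {"county_id": ci, "year": int(year), "u5m": u5m[ci, ti]}
            row.update({f: X[ci, ti, ki] for ki, f in enumerate(config.factor_names)})
            rows.append(row)
    panel = CountyYearPanel(pd.DataFrame(rows), list(config.factor_names))

    truth = SyntheticTruth(
        alpha=config.true_alpha,
        beta={f: config.true_beta[f] for f in config.factor_names},
        w={ci: w[ci] for ci in range(C)},
        nu={ci: nu[ci] for ci in range(C)},
        phi={int(y): phi[ti] for ti, y in enumerate(years)},
        delta={(ci, int(y)): delta[ci, ti] for ci in range(C) for ti, y in enumerate(years)},
    )
    return panel, truth
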