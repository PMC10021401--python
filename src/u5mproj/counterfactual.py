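"""Counterfactual U5M prediction, percent change vs. BAU, SDG attainment.

Business-as-usual U5M is each county's 2014 level carried forward at its
own 2003-2014 annual rate of change.  Under a scale-up scenario, the
fitted log-linear coefficients convert coverage differences into a
mortality multiplier:

    U5M_scen(i, t) = U5M_bau(i, t) * exp( sum_k beta_k * (x_scen - x_bau) )

with coverage on the proportion scale.  The county-specific random effects
are constants within a county-year and cancel in the ratio, so the
counterfactual needs only the coefficients.  Because the model is
log-linear, the joint multiplier factorizes exactly into per-factor
multipliers (log-additivity), which is what the single-factor impact
decomposition reports.

SDG 3.2 attainment is a strict threshold: a county attains the target in
an evaluation year iff its projected U5M is below 25 deaths per 1,000
livebirths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import CountyYearPanel
from .rates import arc
from .scenarios import PROJECTION_YEARS, CoverageTrajectory

__all__ = [
    "CoefficientSet",
    "SdgConfig",
    "bau_u5m",
    "counterfactual_u5m",
    "percent_change",
    "single_factor_impacts",
    "sdg_report",
]


@dataclass
class CoefficientSet:
    """Fitted coefficients used for counterfactual prediction.

    ``beta`` maps factor name to the posterior-mean coefficient per
    unit-proportion change in coverage; ``beta_draws`` optionally carries
    the pooled posterior draws (n_draws x K, same factor order) for
    credible-interval propagation.
    """

    alpha: float
    beta: dict
    beta_draws: np.ndarray | None = field(default=None, repr=False)

    @classmethod
    def from_draws(cls, draws) -> "CoefficientSet":
        return cls(
            alpha=draws.alpha_mean(),
            beta=draws.beta_mean(),
            beta_draws=draws.pooled("beta"),
        )


@dataclass(frozen=True)
class SdgConfig:
    threshold: float = 25.0  # deaths per 1,000 livebirths
    evaluation_years: tuple = (2022, 2025)

    def __post_init__(self):
        if self.threshold <= 0:
            raise ValueError("SDG threshold must be positive")


def bau_u5m(panel: CountyYearPanel) -> pd.DataFrame:
    """Project U5M 2015-2025 at each county's own 2003-2014 rate.

    Returns a (county x year) table in deaths per 1,000 livebirths.
    """
    wide = panel.u5m_wide()
    y0, y1 = panel.years[0], panel.years[-1]
    if wide[y0].isna().any() or wide[y1].isna().any():
        raise ValueError("U5M missing baseline endpoint years")
    a = arc(wide[y0].to_numpy(), wide[y1].to_numpy(), int(y1 - y0))
    k = (PROJECTION_YEARS - y1)[None, :]
    vals = wide[y1].to_numpy()[:, None] * np.exp(a[:, None] / 100.0 * k)
    return pd.DataFrame(vals, index=wide.index, columns=PROJECTION_YEARS)


def _aligned_delta(
    bau_traj: CoverageTrajectory,
    scen_traj: CoverageTrajectory,
    coefficients: CoefficientSet,
    counties,
):
    factors = sorted(set(bau_traj.data["factor"].unique()))
    missing = [f for f in factors if f not in coefficients.beta]
    if missing:
        raise ValueError(f"no coefficient for trajectory factor(s): {missing}")
    xb = bau_traj.array(factors, counties, PROJECTION_YEARS)
    xs = scen_traj.array(factors, counties, PROJECTION_YEARS)
    beta = np.array([coefficients.beta[f] for f in factors])
    return factors, xs - xb, beta


def counterfactual_u5m(
    bau: pd.DataFrame,
    bau_traj: CoverageTrajectory,
    scen_traj: CoverageTrajectory,
    coefficients: CoefficientSet,
) -> pd.DataFrame:
    """Scenario U5M as a multiplicative adjustment of BAU U5M."""
    counties = bau.index.to_numpy()
    _, dx, beta = _aligned_delta(bau_traj, scen_traj, coefficients, counties)
    log_mult = dx @ beta  # (C, T)
    return bau * np.exp(log_mult)


def percent_change(u5m_scen, u5m_bau):
    """Percent change vs. BAU; negative means a mortality reduction."""
    u5m_bau = np.asarray(u5m_bau, dtype=float)
    if np.any(u5m_bau <= 0):
        raise ValueError("BAU U5M must be positive")
    out = 100.0 * (np.asarray(u5m_scen, dtype=float) - u5m_bau) / u5m_bau
    return float(out) if out.ndim == 0 else out


def single_factor_impacts(
    bau: pd.DataFrame,
    bau_traj: CoverageTrajectory,
    scen_traj: CoverageTrajectory,
    coefficients: CoefficientSet,
) -> dict:
    """Per-factor percent change: only one factor follows the scenario path.

    Returns ``{factor: (county x year) DataFrame of percent change}``.
    On the log scale these per-factor effects add up exactly to the joint
    effect.
    """
    counties = bau.index.to_numpy()
    factors, dx, beta = _aligned_delta(bau_traj, scen_traj, coefficients, counties)
    out = {}
    for k, f in enumerate(factors):
        mult = np.exp(beta[k] * dx[:, :, k])
        out[f] = pd.DataFrame(
            100.0 * (mult - 1.0), index=bau.index, columns=PROJECTION_YEARS
        )
    return out


def sdg_report(u5m: pd.DataFrame, config: SdgConfig = SdgConfig(), n_counties=None):
    """SDG 3.2 attainment flags and summary.

    ``u5m`` is a (county x year) table.  Returns ``(flags, attainment)``:
    ``flags`` is a boolean (county x evaluation-year) table (True iff
    strictly below the threshold) and ``attainment`` a DataFrame with one
    row per evaluation year holding the attained count and the percent of
    counties, rounded to one decimal.
    """
    n = len(u5m.index) if n_counties is None else int(n_counties)
    years = [y for y in config.evaluation_years if y in u5m.columns]
    if not years:
        raise ValueError("no evaluation year present in the projection")
    flags = u5m[years] < config.threshold
    rows = [
        {
            "year": int(y),
            "n_attained": int(flags[y].sum()),
            "pct_attained": round(100.0 * int(flags[y].sum()) / n, 1),
        }
        for y in years
    ]
    return flags, pd.DataFrame(rows)
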