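"""Coverage-trajectory construction: business-as-usual and four scale-ups.

All five engines extrapolate intervention coverage from the 2003-2014
baseline window to 2015-2025 with constant-annual-rate (exponential)
arithmetic, differing only in which rate is applied:

* BAU — each county-factor keeps its own 2003-2014 annual rate of change.
* Scenario 1 — every county converges on the best-performing county's 2014
  level: a single national rate is computed from the national 2014 mean to
  the best county's value over 8 years, and applied to each county's own
  baseline; counties that reach the target by 2022 switch to a rate
  attaining 99% ("universal") coverage by 2025.
* Scenario 2 — the fastest county-level 2003-2014 rate (in the improving
  direction) is applied everywhere for the whole horizon.
* Scenario 3 — the national-mean 2003-2014 rate sets national 2022/2025
  targets; the implied period rates are applied to every county's baseline.
* Scenario 4 — national 2022 and 2025 policy targets (strategic health
  plans) define the two period rates applied to every county's baseline.

"Improving" means increasing for coverage indicators and decreasing for
prevalence-type indicators (HIV), flagged by ``FactorMeta.higher_is_better``.
All trajectories are clipped to [0.001, 0.99]; the ceiling is the 99%
universal-coverage cap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import CountyYearPanel, SCHEMA_PREFIX
from .rates import arc, clamp_coverage, project

__all__ = [
    "FactorMeta",
    "ScenarioSpec",
    "CoverageTrajectory",
    "DEFAULT_FACTOR_META",
    "bau",
    "scenario1",
    "scenario2",
    "scenario3",
    "scenario4",
    "build_scenario",
]

PROJECTION_YEARS = np.arange(2015, 2026)


@dataclass(frozen=True)
class FactorMeta:
    """Per-factor scenario metadata.

    ``policy_target_2022``/``policy_target_2025`` are national targets in
    percent (scenario 4); ``higher_is_better`` is False for prevalence-type
    indicators where improvement means decline.
    """

    name: str
    higher_is_better: bool = True
    policy_target_2022: float | None = None
    policy_target_2025: float | None = None

    def __post_init__(self):
        for t in (self.policy_target_2022, self.policy_target_2025):
            if t is not None and not (0.0 < t <= 100.0):
                raise ValueError("policy targets must be in (0, 100]")


# National 2022/2025 policy targets (percent) from the Kenyan strategic
# health plans and WHO guidance; HIV prevalence is the decreasing-good factor.
DEFAULT_FACTOR_META = {
    "anc4": FactorMeta("anc4", True, 70.0, 80.0),
    "antimalarial_use": FactorMeta("antimalarial_use", True, 70.0, 90.0),
    "breastfed_1hr": FactorMeta("breastfed_1hr", True, 70.0, 80.0),
    "improved_sanitation": FactorMeta("improved_sanitation", True, 65.0, 70.0),
    "facility_delivery": FactorMeta("facility_delivery", True, 73.0, 75.0),
    "fever_treatment": FactorMeta("fever_treatment", True, 80.0, 90.0),
    "hiv_prevalence": FactorMeta("hiv_prevalence", False, 3.3, 2.8),
    "child_itn_use": FactorMeta("child_itn_use", True, 80.0, 95.0),
    "fully_immunised": FactorMeta("fully_immunised", True, 80.0, 85.0),
    "improved_water": FactorMeta("improved_water", True, 78.0, 80.0),
}


@dataclass(frozen=True)
class ScenarioSpec:
    id: str
    horizon_mid: int = 2022
    horizon_end: int = 2025
    universal_cap: float = 0.99

    def __post_init__(self):
        if self.horizon_mid >= self.horizon_end:
            raise ValueError("horizon_mid must precede horizon_end")


@dataclass
class CoverageTrajectory:
    """Projected coverage 2015-2025, long format, proportions in memory."""

    scenario: str
    data: pd.DataFrame  # columns county_id, factor, year, value

    def wide(self, factor: str) -> pd.DataFrame:
        sub = self.data[self.data["factor"] == factor]
        return sub.pivot(index="county_id", columns="year", values="value")

    def array(self, factors, counties, years) -> np.ndarray:
        """Values as an array of shape (C, T, K) on the proportion scale."""
        out = np.empty((len(counties), len(years), len(factors)))
        for k, f in enumerate(factors):
            out[:, :, k] = (
                self.wide(f).loc[counties, years].to_numpy()
            )
        return out

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out["value"] = out["value"] * 100.0
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{SCHEMA_PREFIX} trajectory-v1\n")
            out.to_csv(fh, index=False)


def _endpoints(panel: CountyYearPanel, factor: str):
    """(counties, x2003, x2014) for one factor; errors if endpoints missing."""
    wide = panel.factor_wide(factor)
    y0, y1 = panel.years[0], panel.years[-1]
    if wide[y0].isna().any() or wide[y1].isna().any():
        raise ValueError(f"factor {factor!r} missing baseline endpoint years")
    return wide.index.to_numpy(), wide[y0].to_numpy(), wide[y1].to_numpy()


def _assemble(per_factor: dict, scenario_id: str) -> CoverageTrajectory:
    frames = []
    for factor, (counties, paths) in per_factor.items():
        df = pd.DataFrame(paths, index=counties, columns=PROJECTION_YEARS)
        long = df.stack().rename("value").reset_index()
        long.columns = ["county_id", "year", "value"]
        long["factor"] = factor
        frames.append(long[["county_id", "factor", "year", "value"]])
    data = pd.concat(frames, ignore_index=True)
    data["value"] = clamp_coverage(data["value"].to_numpy())
    return CoverageTrajectory(scenario_id, data)


def _two_period_paths(x14, arc1, arc2, mid_year=2022):
    """County paths with one rate to ``mid_year`` and another after it."""
    k = PROJECTION_YEARS - 2014
    paths = np.empty((len(np.atleast_1d(x14)), len(PROJECTION_YEARS)))
    x14 = np.atleast_1d(x14).astype(float)
    x_mid = x14 * np.exp(np.asarray(arc1) / 100.0 * (mid_year - 2014))
    for j, year in enumerate(PROJECTION_YEARS):
        if year <= mid_year:
            paths[:, j] = x14 * np.exp(np.asarray(arc1) / 100.0 * (year - 2014))
        else:
            paths[:, j] = x_mid * np.exp(np.asarray(arc2) / 100.0 * (year - mid_year))
    return paths


def bau(panel: CountyYearPanel) -> CoverageTrajectory:
    """Continue each county-factor's own 2003-2014 rate through 2025."""
    n_base = int(panel.years[-1] - panel.years[0])
    per_factor = {}
    for f in panel.factors:
        counties, x03, x14 = _endpoints(panel, f)
        a = arc(x03, x14, n_base)
        k = (PROJECTION_YEARS - 2014)[None, :]
        per_factor[f] = (counties, x14[:, None] * np.exp(a[:, None] / 100.0 * k))
    return _assemble(per_factor, "BAU")


def scenario1(panel: CountyYearPanel, factor_meta=None) -> CoverageTrajectory:
    """Converge on the best-performing county's 2014 level by 2022.

    A single national rate (national 2014 mean -> best county, 8 years) is
    applied to every county's own baseline.  Counties at or beyond the
    target by 2022 switch to the rate reaching 99% coverage by 2025
    (decreasing-good factors instead keep the same rate); the rest keep the
    national rate through 2025.
    """
    factor_meta = factor_meta or DEFAULT_FACTOR_META
    per_factor = {}
    for f in panel.factors:
        meta = factor_meta.get(f, FactorMeta(f))
        counties, _, x14 = _endpoints(panel, f)
        best = float(x14.max() if meta.higher_is_better else x14.min())
        national = float(x14.mean())
        a = arc(national, best, 8)
        k = (PROJECTION_YEARS - 2014)[None, :]
        paths = x14[:, None] * np.exp(a / 100.0 * k)
        x22 = x14 * np.exp(a / 100.0 * 8)
        if meta.higher_is_better:
            reached = x22 >= best - 1e-9
            late = PROJECTION_YEARS > 2022
            for i in np.where(reached)[0]:
                a2 = arc(x22[i], 0.99, 3)
                paths[i, late] = x22[i] * np.exp(
                    a2 / 100.0 * (PROJECTION_YEARS[late] - 2022)
                )
        # decreasing-good factors always continue the same rate
        per_factor[f] = (counties, paths)
    return _assemble(per_factor, "S1")


def scenario2(panel: CountyYearPanel, factor_meta=None) -> CoverageTrajectory:
    """Apply the fastest improving county rate (2003-2014) everywhere."""
    factor_meta = factor_meta or DEFAULT_FACTOR_META
    n_base = int(panel.years[-1] - panel.years[0])
    per_factor = {}
    for f in panel.factors:
        meta = factor_meta.get(f, FactorMeta(f))
        counties, x03, x14 = _endpoints(panel, f)
        arcs = arc(x03, x14, n_base)
        fastest = float(arcs.max() if meta.higher_is_better else arcs.min())
        k = (PROJECTION_YEARS - 2014)[None, :]
        per_factor[f] = (counties, x14[:, None] * np.exp(fastest / 100.0 * k))
    return _assemble(per_factor, "S2")


def scenario3(panel: CountyYearPanel) -> CoverageTrajectory:
    """Project every county at the national-mean 2003-2014 rate.

    The national 2022 and 2025 targets are the national mean projected at
    its own rate; the implied 2014->2022 and 2022->2025 period rates are
    then applied to each county's own baseline, so projected coverage
    still differs by county.
    """
    n_base = int(panel.years[-1] - panel.years[0])
    per_factor = {}
    for f in panel.factors:
        counties, x03, x14 = _endpoints(panel, f)
        nat03, nat14 = float(x03.mean()), float(x14.mean())
        nat_arc = arc(nat03, nat14, n_base)
        nat22 = project(nat14, nat_arc, 8)
        nat25 = project(nat22, nat_arc, 3)
        arc1 = arc(nat14, nat22, 8)
        arc2 = arc(nat22, nat25, 3)
        per_factor[f] = (counties, _two_period_paths(x14, arc1, arc2))
    return _assemble(per_factor, "S3")


def scenario4(panel: CountyYearPanel, factor_meta=None) -> CoverageTrajectory:
    """Scale toward national 2022/2025 policy targets.

    National rates are computed from the national 2014 mean to the 2022
    target, then from the 2022 target to the 2025 target, and applied to
    each county's own baseline path.
    """
    factor_meta = factor_meta or DEFAULT_FACTOR_META
    per_factor = {}
    for f in panel.factors:
        meta = factor_meta.get(f)
        if (
            meta is None
            or meta.policy_target_2022 is None
            or meta.policy_target_2025 is None
        ):
            raise ValueError(f"missing 2022/2025 policy targets for factor {f!r}")
        counties, _, x14 = _endpoints(panel, f)
        nat14 = float(x14.mean())
        t22 = meta.policy_target_2022 / 100.0
        t25 = meta.policy_target_2025 / 100.0
        arc1 = arc(nat14, t22, 8)
        arc2 = arc(t22, t25, 3)
        per_factor[f] = (counties, _two_period_paths(x14, arc1, arc2))
    return _assemble(per_factor, "S4")


def build_scenario(scenario_id: str, panel: CountyYearPanel, factor_meta=None):
    """Dispatch on scenario id ('BAU', 'S1' ... 'S4')."""
    sid = scenario_id.upper()
    if sid == "BAU":
        return bau(panel)
    if sid == "S1":
        return scenario1(panel, factor_meta)
    if sid == "S2":
        return scenario2(panel, factor_meta)
    if sid == "S3":
        return scenario3(panel)
    if sid == "S4":
        return scenario4(panel, factor_meta)
    raise ValueError(f"unknown scenario {scenario_id!r}")
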