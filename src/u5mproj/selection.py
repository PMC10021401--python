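"""Factor selection: bivariate screen, redundancy pruning, ANC index, elastic net.

The candidate interventions are reduced to a parsimonious set in stages:

1. a permissive bivariate screen — pooled OLS of log(U5M) on each factor,
   keeping factors with a two-sided p below 0.2;
2. redundancy exclusions — factors whose contribution is captured by an
   umbrella factor (e.g. individual vaccines vs. fully-immunised status)
   are dropped when the umbrella factor survived the screen;
3. an antenatal-care (ANC) index — the first principal component of the
   interventions delivered during ANC visits (iron supplementation,
   tetanus injection, vitamin A), which are strongly collinear with each
   other and with ANC attendance;
4. elastic-net regression over an (l1-ratio, penalty) grid with
   county-grouped cross-validation; two candidate models are fit (model 1:
   ANC plus the individual ANC-delivered interventions; model 2: ANC plus
   the PCA index) and the one with the smaller cross-validated MSE wins.
   Factors with non-zero penalized coefficients at the winning grid point
   are retained.

Cross-validation folds are grouped by county so that years of one county
never straddle the train/test split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import ElasticNet, LinearRegression
from sklearn.model_selection import GroupKFold

from .panel import CountyYearPanel

__all__ = [
    "ScreeningConfig",
    "SelectionResult",
    "bivariate_screen",
    "apply_redundancy_exclusions",
    "build_anc_index",
    "elastic_net_select",
    "run_model_pair",
]

ANC_INDEX_NAME = "anc_index"


@dataclass
class ScreeningConfig:
    """Tuning knobs for the selection stages.

    ``enr_alpha_grid`` holds elastic-net mixing weights (1.0 = lasso,
    0.0 = ridge); ``enr_lambda_grid`` the penalty strengths, on the
    scikit-learn scale (objective ``1/(2n)||y - Xb||^2 + lambda * penalty``).
    """

    p_threshold: float = 0.2
    redundancy_map: dict = field(default_factory=dict)
    enr_alpha_grid: list = field(default_factory=lambda: [0.1, 0.5, 0.9, 1.0])
    enr_lambda_grid: list = field(
        default_factory=lambda: list(np.round(np.logspace(-4, -0.5, 8), 6))
    )
    cv_folds: int = 10

    def __post_init__(self):
        if not (0.0 < self.p_threshold < 1.0):
            raise ValueError("p_threshold must be in (0, 1)")
        if not self.enr_alpha_grid or not self.enr_lambda_grid:
            raise ValueError("elastic-net grids must be non-empty")


@dataclass
class SelectionResult:
    screened: list
    excluded_redundant: list
    anc_index_loadings: dict
    chosen_model: int
    retained: list
    cv_mse: dict  # model number -> cross-validated MSE


def bivariate_screen(panel: CountyYearPanel, factor: str, p_threshold: float = 0.2):
    """Pooled log-linear OLS of one factor against U5M.

    Returns ``(coefficient, p_value, passes)`` where the coefficient is per
    unit-proportion change in coverage and ``passes`` is a two-sided Wald
    test at ``p_threshold``.
    """
    df = panel.data
    x = df[factor].to_numpy(dtype=float)
    y = np.log(df["u5m"].to_numpy(dtype=float))
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("bivariate screen needs at least 3 county-year rows")
    if np.ptp(x) == 0:
        raise ValueError(f"factor {factor!r} is constant: degenerate design")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    coef, p = float(fit.params[1]), float(fit.pvalues[1])
    return coef, p, bool(p < p_threshold)


def apply_redundancy_exclusions(screened, redundancy_map):
    """Drop factors whose umbrella factor is itself in the screened set.

    ``redundancy_map`` maps a factor to the umbrella factor that captures
    it (e.g. ``{"dtp3": "fully_immunised"}``).  A mapped factor is removed
    only when its umbrella survived the screen; chains are followed, and a
    cyclic map is a configuration error.
    """
    # cycle check
    for start in redundancy_map:
        seen, node = set(), start
        while node in redundancy_map:
            if node in seen:
                raise ValueError(f"redundancy_map contains a cycle through {node!r}")
            seen.add(node)
            node = redundancy_map[node]
    screened = list(screened)
    keep = [
        f
        for f in screened
        if not (f in redundancy_map and redundancy_map[f] in screened)
    ]
    return keep


def build_anc_index(panel: CountyYearPanel, components=("iron_supplement", "tetanus_injection", "vitamin_a")):
    """First principal component of the standardized ANC-delivered interventions.

    Returns ``(index, loadings)``: the index is a numpy array aligned with
    ``panel.data`` rows, standardized to mean 0 / SD 1 and sign-oriented to
    correlate positively with the mean of its components; loadings map each
    component to its weight in the (unit-norm) first eigenvector.
    """
    components = list(components)
    present = [c for c in components if c in panel.data.columns]
    if len(present) < 2:
        raise ValueError("ANC index needs at least 2 component columns present")
    M = panel.data[present].to_numpy(dtype=float)
    sd = M.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = [c for c, s in zip(present, sd) if s == 0]
        raise ValueError(f"constant ANC component(s): {bad}")
    Z = (M - M.mean(axis=0)) / sd
    cov = Z.T @ Z / len(Z)
    lam, V = np.linalg.eigh(cov)
    v1 = V[:, -1]
    index = Z @ v1
    if np.corrcoef(index, Z.mean(axis=1))[0, 1] < 0:
        v1, index = -v1, -index
    index = (index - index.mean()) / index.std(ddof=0)
    return index, {c: float(w) for c, w in zip(present, v1)}


def _standardize(X: np.ndarray):
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("cannot standardize a constant column")
    return (X - mu) / sd


def elastic_net_select(X, y, config: ScreeningConfig, groups=None, names=None):
    """Grid-searched elastic net with grouped cross-validation.

    ``X`` must already be standardized.  Returns a dict with the minimizing
    ``(alpha, lambda)`` pair, the cross-validated MSE there, the full-data
    coefficients at that pair and the names of the non-zero ones.  Ties on
    CV MSE break toward the smaller penalty, then the smaller mixing weight.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    if groups is None:
        groups = np.arange(n)
    n_folds = min(config.cv_folds, len(np.unique(groups)))
    if n < config.cv_folds:
        raise ValueError("fewer rows than cross-validation folds")
    cv = GroupKFold(n_splits=n_folds)
    splits = list(cv.split(X, y, groups))

    def make(a, lam):
        if lam == 0:
            return LinearRegression()
        return ElasticNet(alpha=lam, l1_ratio=a, fit_intercept=True, max_iter=50_000)

    best = None  # (mse, lam, a)
    for a in config.enr_alpha_grid:
        for lam in config.enr_lambda_grid:
            sse = 0.0
            for tr, te in splits:
                m = make(a, lam).fit(X[tr], y[tr])
                resid = y[te] - m.predict(X[te])
                sse += float(resid @ resid)
            mse = sse / n
            key = (mse, lam, a)
            if best is None or key < best:
                best = key
    mse, lam, a = best
    final = make(a, lam).fit(X, y)
    coefs = np.atleast_1d(final.coef_)
    retained = [nm for nm, c in zip(names, coefs) if c != 0.0]
    return {
        "alpha": a,
        "lambda": lam,
        "cv_mse": mse,
        "coefficients": {nm: float(c) for nm, c in zip(names, coefs)},
        "retained": retained,
    }


def run_model_pair(
    panel: CountyYearPanel,
    config: ScreeningConfig,
    anc_factor: str = "anc4",
    anc_components=("iron_supplement", "tetanus_injection", "vitamin_a"),
):
    """Run the full selection pipeline and choose between the two ENR models.

    Model 1's design is the screened factors plus ANC attendance and each
    ANC-delivered intervention individually; model 2 replaces the
    individual ANC-delivered interventions with their first-PC index.
    The model with the smaller cross-validated MSE wins (tie -> model 1).
    """
    anc_components = list(anc_components)
    missing = [c for c in [anc_factor, *anc_components] if c not in panel.data.columns]
    if missing:
        raise ValueError(f"panel lacks ANC columns: {missing}")

    screened = []
    for f in panel.factors:
        _, _, passes = bivariate_screen(panel, f, config.p_threshold)
        if passes:
            screened.append(f)
    after_redund = apply_redundancy_exclusions(screened, config.redundancy_map)
    excluded = [f for f in screened if f not in after_redund]

    base = [f for f in after_redund if f not in anc_components and f != anc_factor]
    feats1 = [anc_factor, *anc_components, *base]
    feats2_named = [anc_factor, ANC_INDEX_NAME, *base]

    y = np.log(panel.data["u5m"].to_numpy(dtype=float))
    groups = panel.data["county_id"].to_numpy()

    X1 = _standardize(panel.data[feats1].to_numpy(dtype=float))
    index, loadings = build_anc_index(panel, anc_components)
    X2 = np.column_stack(
        [_standardize(panel.data[[anc_factor]].to_numpy(dtype=float)), index[:, None]]
        + ([_standardize(panel.data[base].to_numpy(dtype=float))] if base else [])
    )

    res1 = elastic_net_select(X1, y, config, groups, names=feats1)
    res2 = elastic_net_select(X2, y, config, groups, names=feats2_named)

    chosen = 1 if res1["cv_mse"] <= res2["cv_mse"] else 2
    winner = res1 if chosen == 1 else res2
    return SelectionResult(
        screened=screened,
        excluded_redundant=excluded,
        anc_index_loadings=loadings,
        chosen_model=chosen,
        retained=winner["retained"],
        cv_mse={1: res1["cv_mse"], 2: res2["cv_mse"]},
    )
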