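"""Factor-selection stages: screen, redundancy, PCA index, elastic net."""

import numpy as np
import pandas as pd
import pytest

from u5mproj.panel import CountyYearPanel
from u5mproj.selection import (
    ScreeningConfig,
    apply_redundancy_exclusions,
    bivariate_screen,
    build_anc_index,
    elastic_net_select,
    run_model_pair,
)
from u5mproj.synthetic import make_adjacency, simulate_panel

from conftest import small_synthetic_config


def _panel_from_xy(x, logy, factor="f"):
    df = pd.DataFrame(
        {
            "county_id": np.arange(len(x)),
            "year": 2000,
            "u5m": 1000.0 * np.exp(logy),
            factor: x,
        }
    )
    return CountyYearPanel(df, [factor])


class TestBivariateScreen:
    def test_perfect_fit(self):
        x = np.linspace(0.1, 0.9, 20)
        panel = _panel_from_xy(x, 2.0 * x - 5.0)
        coef, p, passes = bivariate_screen(panel, "f", 0.2)
        assert coef == pytest.approx(2.0, abs=1e-10)
        assert p < 1e-12
        assert passes

    def test_three_point_closed_form(self):
        # (x, log y) = (0,0), (1,1), (2,2): OLS slope exactly 1
        panel = _panel_from_xy(np.array([0.0, 1.0, 2.0]), np.array([0.0, 1.0, 2.0]))
        coef, _, _ = bivariate_screen(panel, "f", 0.2)
        assert coef == pytest.approx(1.0, abs=1e-10)

    def test_type_one_error_near_threshold(self):
        # pure-noise factors should pass a p<0.2 screen about 20% of the time
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(200):
            x = rng.uniform(0.2, 0.8, 500)
            logy = rng.normal(-3.0, 0.3, 500)
            _, _, passes = bivariate_screen(_panel_from_xy(x, logy), "f", 0.2)
            hits += passes
        assert 0.14 <= hits / 200 <= 0.26

    def test_constant_factor_degenerate(self):
        panel = _panel_from_xy(np.full(10, 0.5), np.zeros(10))
        with pytest.raises(ValueError):
            bivariate_screen(panel, "f", 0.2)


class TestRedundancyExclusions:
    def test_mapped_factor_removed_when_umbrella_screened(self):
        out = apply_redundancy_exclusions(
            ["dtp3", "fully_immunised"], {"dtp3": "fully_immunised"}
        )
        assert out == ["fully_immunised"]

    def test_empty_map_is_identity(self):
        assert apply_redundancy_exclusions(["a", "b"], {}) == ["a", "b"]

    def test_unscreened_umbrella_keeps_factor(self):
        out = apply_redundancy_exclusions(["dtp3"], {"dtp3": "fully_immunised"})
        assert out == ["dtp3"]

    def test_cycle_rejected(self):
        with pytest.raises(ValueError):
            apply_redundancy_exclusions(["a", "b"], {"a": "b", "b": "a"})


class TestAncIndex:
    def _panel(self, comps):
        df = pd.DataFrame(comps)
        df["county_id"] = np.arange(len(df))
        df["year"] = 2000
        df["u5m"] = 50.0
        return CountyYearPanel(df, list(comps))

    def test_perfectly_correlated_components(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0.2, 0.8, 50)
        panel = self._panel({"a": base, "b": 0.5 * base + 0.1})
        index, _ = build_anc_index(panel, ["a", "b"])
        std_a = (base - base.mean()) / base.std()
        assert abs(np.corrcoef(index, std_a)[0, 1]) == pytest.approx(1.0, abs=1e-10)

    def test_two_variable_explained_variance(self):
        # first PC of a 2x2 correlation matrix explains (1 + rho) / 2
        rng = np.random.default_rng(1)
        a = rng.normal(size=2000)
        b = 0.6 * a + 0.8 * rng.normal(size=2000)
        panel = self._panel({"a": a, "b": b})
        _, loadings = build_anc_index(panel, ["a", "b"])
        Z = np.column_stack(
            [(v - v.mean()) / v.std() for v in (a, b)]
        )
        rho = np.corrcoef(a, b)[0, 1]
        v1 = np.array([loadings["a"], loadings["b"]])
        explained = v1 @ (Z.T @ Z / len(a)) @ v1
        assert explained == pytest.approx(1 + rho, abs=1e-10)  # top eigenvalue
        assert explained / 2 == pytest.approx((1 + rho) / 2, abs=1e-10)

    def test_loading_symmetry_under_relabeling(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0.1, 0.9, 100)
        b = np.clip(a + rng.normal(0, 0.05, 100), 0.01, 0.99)
        c = np.clip(a + rng.normal(0, 0.05, 100), 0.01, 0.99)
        panel = self._panel({"a": a, "b": b, "c": c})
        _, l1 = build_anc_index(panel, ["a", "b", "c"])
        _, l2 = build_anc_index(panel, ["c", "b", "a"])
        for k in ("a", "b", "c"):
            assert l1[k] == pytest.approx(l2[k], abs=1e-10)

    def test_index_standardized_and_oriented(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0.1, 0.9, 100)
        b = np.clip(a + rng.normal(0, 0.1, 100), 0.01, 0.99)
        panel = self._panel({"a": a, "b": b})
        index, _ = build_anc_index(panel, ["a", "b"])
        assert index.mean() == pytest.approx(0.0, abs=1e-10)
        assert index.std() == pytest.approx(1.0, abs=1e-10)
        assert np.corrcoef(index, a)[0, 1] > 0

    def test_constant_component_rejected(self):
        panel = self._panel({"a": np.full(10, 0.5), "b": np.linspace(0.1, 0.9, 10)})
        with pytest.raises(ValueError):
            build_anc_index(panel, ["a", "b"])


class TestElasticNet:
    def test_zero_penalty_equals_ols(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(100, 3))
        X = (X - X.mean(0)) / X.std(0)
        y = X @ np.array([1.0, -0.5, 0.2]) + rng.normal(0, 0.1, 100)
        cfg = ScreeningConfig(enr_alpha_grid=[1.0], enr_lambda_grid=[0.0], cv_folds=5)
        res = elastic_net_select(X, y, cfg, groups=np.arange(100) % 5)
        Xc = np.column_stack([np.ones(100), X])
        ols = np.linalg.lstsq(Xc, y, rcond=None)[0][1:]
        for j, name in enumerate(["x0", "x1", "x2"]):
            assert res["coefficients"][name] == pytest.approx(ols[j], abs=1e-6)

    def test_huge_penalty_shrinks_all_to_zero(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(50, 3))
        y = X @ np.array([1.0, -1.0, 0.5]) + rng.normal(0, 0.1, 50)
        cfg = ScreeningConfig(enr_alpha_grid=[0.5], enr_lambda_grid=[1e6], cv_folds=5)
        res = elastic_net_select(X, y, cfg, groups=np.arange(50) % 5)
        assert res["retained"] == []

    def test_lasso_soft_threshold_on_orthonormal_design(self):
        # with X'X = n I and l1 ratio 1, the lasso solution is the
        # soft-thresholded OLS estimate sign(b) max(|b| - lambda, 0)
        n, k = 64, 4
        H = np.array([[1.0]])
        while H.shape[0] < n:
            H = np.block([[H, H], [H, -H]])  # Hadamard: orthogonal columns
        X = H[:, 1 : k + 1]  # columns with X'X = n I
        b_true = np.array([0.9, -0.4, 0.15, 0.0])
        y = X @ b_true
        lam = 0.25
        cfg = ScreeningConfig(enr_alpha_grid=[1.0], enr_lambda_grid=[lam], cv_folds=4)
        res = elastic_net_select(X, y, cfg, groups=np.arange(n) % 4)
        b_ols = X.T @ y / n
        expected = np.sign(b_ols) * np.maximum(np.abs(b_ols) - lam, 0.0)
        for j in range(k):
            assert res["coefficients"][f"x{j}"] == pytest.approx(expected[j], abs=1e-6)

    def test_tie_breaks_to_smallest_penalty(self):
        # y identically zero: every grid point has the same CV MSE
        X = np.random.default_rng(6).normal(size=(40, 2))
        y = np.zeros(40)
        cfg = ScreeningConfig(
            enr_alpha_grid=[0.3, 0.9], enr_lambda_grid=[0.5, 0.01, 0.1], cv_folds=4
        )
        res = elastic_net_select(X, y, cfg, groups=np.arange(40) % 4)
        assert res["lambda"] == 0.01
        assert res["alpha"] == 0.3

    def test_agrees_with_glmnet_reference(self, tmp_path):
        # independent route: R's glmnet at the same (alpha, lambda) and
        # penalty convention must give the same coefficients
        import subprocess

        rng = np.random.default_rng(42)
        n, k = 120, 5
        X = rng.normal(size=(n, k))
        X = (X - X.mean(0)) / X.std(0)
        y = X @ np.array([0.8, -0.5, 0.0, 0.3, 0.0]) + rng.normal(0, 0.3, n)
        lam, l1 = 0.1, 1.0
        np.savetxt(tmp_path / "X.csv", X, delimiter=",")
        np.savetxt(tmp_path / "y.csv", y)
        script = (
            "suppressMessages(library(glmnet));"
            f'X <- as.matrix(read.csv("{tmp_path}/X.csv", header=FALSE));'
            f'y <- scan("{tmp_path}/y.csv");'
            f"fit <- glmnet(X, y, alpha={l1}, lambda={lam},"
            " standardize=FALSE, intercept=TRUE, thresh=1e-14);"
            'cat(as.numeric(coef(fit))[-1], sep="\\n")'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        reference = np.array([float(v) for v in out.stdout.split()])
        cfg = ScreeningConfig(enr_alpha_grid=[l1], enr_lambda_grid=[lam], cv_folds=4)
        res = elastic_net_select(X, y, cfg, groups=np.arange(n) % 4)
        ours = np.array([res["coefficients"][f"x{j}"] for j in range(k)])
        assert np.allclose(ours, reference, atol=1e-6)

    def test_fewer_rows_than_folds_rejected(self):
        cfg = ScreeningConfig(cv_folds=10)
        with pytest.raises(ValueError):
            elastic_net_select(np.ones((5, 1)), np.ones(5), cfg)


class TestModelPair:
    @staticmethod
    def _index_driven_panel(seed):
        rng = np.random.default_rng(seed)
        n_counties, n_years = 47, 12
        n = n_counties * n_years
        base = rng.uniform(0.3, 0.9, (n, 1))
        comps = np.clip(base + rng.normal(0, 0.05, (n, 3)), 0.01, 0.99)
        anc = np.clip(comps.mean(1) + rng.normal(0, 0.05, n), 0.01, 0.99)
        idx = (comps - comps.mean(0)).sum(1)
        idx = (idx - idx.mean()) / idx.std()
        logy = -3.0 - 0.15 * idx + rng.normal(0, 0.1, n)
        df = pd.DataFrame(
            {
                "county_id": np.repeat(np.arange(n_counties), n_years),
                "year": np.tile(np.arange(2003, 2003 + n_years), n_counties),
                "u5m": 1000 * np.exp(logy),
                "anc4": anc,
                "iron_supplement": comps[:, 0],
                "tetanus_injection": comps[:, 1],
                "vitamin_a": comps[:, 2],
            }
        )
        return CountyYearPanel(
            df, ["anc4", "iron_supplement", "tetanus_injection", "vitamin_a"]
        )

    def test_index_driven_data_prefers_model_2(self):
        cfg = ScreeningConfig()
        wins = 0
        for rep in range(20):
            res = run_model_pair(self._index_driven_panel(200 + rep), cfg)
            assert res.chosen_model == (1 if res.cv_mse[1] <= res.cv_mse[2] else 2)
            wins += res.chosen_model == 2
        assert wins >= 16  # >= 80% of replicates

    def test_sparse_truth_recovered(self):
        # 3 active of 10 standardized factors at the study's county-year count
        cfg = ScreeningConfig()
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            n = 564
            X = rng.normal(size=(n, 10))
            beta = np.zeros(10)
            beta[[1, 4, 7]] = [0.5, -0.7, 0.4]
            y = X @ beta + rng.normal(0, 0.5, n)
            groups = np.repeat(np.arange(47), 12)
            res = elastic_net_select(
                X, y, cfg, groups, names=[f"f{i}" for i in range(10)]
            )
            hits += {"f1", "f4", "f7"} <= set(res["retained"])
        assert hits >= 18  # >= 90% of replicates

    def test_missing_anc_columns_rejected(self):
        df = pd.DataFrame(
            {"county_id": [0, 1], "year": [2003, 2003], "u5m": [50, 60], "anc4": [0.4, 0.5]}
        )
        with pytest.raises(ValueError):
            run_model_pair(CountyYearPanel(df, ["anc4"]), ScreeningConfig())

    def test_default_truth_drops_decoys_keeps_strong_drivers(self):
        # under the fitted study conditions the spatial field dominates the
        # grouped-CV error, so weak true effects are not reliably retained;
        # the decoy ANC components must go and the strong drivers must stay
        components = ("iron_supplement", "tetanus_injection", "vitamin_a")
        cfg = ScreeningConfig()
        decoys_dropped = strong_kept = 0
        n_rep = 10
        for rep in range(n_rep):
            syn = small_synthetic_config(
                300 + rep,
                n_counties=47,
                year_end=2014,
                factor_names=["anc4", "fever_treatment", "hiv_prevalence", *components],
                true_beta={
                    "anc4": -0.7098,
                    "fever_treatment": -1.2550,
                    "hiv_prevalence": 6.5930,
                    **{c: 0.0 for c in components},
                },
                sigma_w=0.5336,
                factor_start_ranges={"hiv_prevalence": (0.01, 0.15)},
            )
            panel, _ = simulate_panel(syn, make_adjacency(47, 300 + rep))
            res = run_model_pair(panel, cfg, anc_components=components)
            retained = set(res.retained)
            decoys_dropped += not (set(components) & retained)
            strong_kept += {"anc4", "fever_treatment", "hiv_prevalence"} <= retained
        assert decoys_dropped >= 0.8 * n_rep
        assert strong_kept >= 0.8 * n_rep
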