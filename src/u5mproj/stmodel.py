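"""Bayesian log-linear spatio-temporal mixed-effects model of U5M.

The observation model for county i, year t is

    log(U5M_it / 1000) = alpha + sum_k beta_k x_kit + w_i + nu_i + phi_t + delta_it

where

* ``w``     — spatially structured county effect, intrinsic CAR (ICAR) on the
              county adjacency graph, constrained to sum to zero;
* ``nu``    — unstructured iid county effect, N(0, sigma_nu1^2);
* ``phi``   — first-order random-walk year effect, constrained to sum to
              zero for identifiability with the intercept;
* ``delta`` — iid county-year space-time interaction, N(0, sigma_nu2^2),
              which doubles as the residual term (the model has exactly
              four variance components and no separate observation noise).

Priors: alpha, beta_k ~ N(0, 10^2); each standard deviation has a
half-Normal(0, prior_sd_scale) prior (weakly informative, standard for
BYM-type models).

Sampling is Metropolis-within-Gibbs.  Given the four standard deviations,
the location parameters (alpha, beta, w, nu, phi) are jointly Gaussian, so
they are refreshed in one exact block draw per sweep; ``w`` and ``phi``
are parametrized in orthonormal sum-to-zero bases, the proper construction
of the constrained ICAR / random-walk priors, which keeps the joint
precision positive definite and the constraints exact.  Each standard
deviation is then updated by slice sampling on the log scale targeting
its conditional with its own random-effect block integrated out (a
partially collapsed sweep that removes the funnel coupling between a
variance and its block), after which the block is redrawn exactly from
its Gaussian conditional.  The kernel is identical at every sweep.

Convergence is reported as the Brooks-Gelman-Rubin interval ratio
(pooled 80% interval width over the mean within-chain width, minus one, in
percent) together with the Monte Carlo standard error of the posterior
mean (batch means) and its ratio to the posterior SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .panel import CountyYearPanel

__all__ = [
    "ModelSpec",
    "McmcConfig",
    "PosteriorDraws",
    "fit",
    "summarize",
    "check_convergence",
    "prune_nonsignificant",
]


@dataclass
class ModelSpec:
    factors: list
    spatial_structured: bool = True
    spatial_unstructured: bool = True
    temporal: bool = True
    interaction: bool = True
    prior_sd_scale: float = 5.0
    prior_beta_sd: float = 10.0

    def __post_init__(self):
        if self.prior_sd_scale <= 0 or self.prior_beta_sd <= 0:
            raise ValueError("prior scales must be positive")


@dataclass
class McmcConfig:
    n_chains: int = 2
    n_iter: int = 25_000
    burn_in: int = 5_000
    thin: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.n_chains < 2:
            raise ValueError("need >= 2 chains for convergence diagnostics")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class PosteriorDraws:
    """Post-burn-in draws, kept per chain for diagnostics.

    Array shapes: ``alpha`` (M, N); ``beta`` (M, N, K); ``w``/``nu``
    (M, N, C); ``phi`` (M, N, T); sigmas (M, N); ``delta`` (M, N, C, T),
    where M = chains, N = retained iterations.
    """

    factors: list
    counties: np.ndarray
    years: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    w: np.ndarray
    nu: np.ndarray
    phi: np.ndarray
    delta: np.ndarray
    sigma_w: np.ndarray
    sigma_nu1: np.ndarray
    sigma_t: np.ndarray
    sigma_nu2: np.ndarray

    @property
    def n_chains(self) -> int:
        return self.alpha.shape[0]

    def pooled(self, name: str) -> np.ndarray:
        """Draws pooled over chains (first two axes merged)."""
        a = getattr(self, name)
        return a.reshape(-1, *a.shape[2:])

    def beta_mean(self) -> dict:
        m = self.pooled("beta").mean(axis=0)
        return dict(zip(self.factors, m.tolist()))

    def alpha_mean(self) -> float:
        return float(self.pooled("alpha").mean())

    def scalar_params(self) -> dict:
        """Per-chain draw matrix (M, N) for every summarized parameter."""
        out = {"intercept": self.alpha}
        for k, f in enumerate(self.factors):
            out[f] = self.beta[:, :, k]
        out["sigma_w"] = self.sigma_w
        out["sigma_nu1"] = self.sigma_nu1
        out["sigma_t"] = self.sigma_t
        out["sigma_nu2"] = self.sigma_nu2
        return out


# --------------------------------------------------------------------------
# sampler internals
# --------------------------------------------------------------------------

def _slice_sample_log(logp, x0, rng, width=1.0, max_out=50):
    """One slice-sampling update of x = log(sigma) (stepping out + shrinkage).

    Tuning-free and, unlike a random-walk step, traverses the full
    conditional in a single call, so successive sigma draws are close to
    independent."""
    y = logp(x0) + np.log(rng.uniform())
    L = x0 - width * rng.uniform()
    R = L + width
    j = int(max_out * rng.uniform())
    k = max_out - 1 - j
    while j > 0 and y < logp(L):
        L -= width
        j -= 1
    while k > 0 and y < logp(R):
        R += width
        k -= 1
    while True:
        x1 = L + (R - L) * rng.uniform()
        if y < logp(x1):
            return x1
        if x1 < x0:
            L = x1
        else:
            R = x1


def _half_normal_logpdf(s, scale):
    return -0.5 * (s / scale) ** 2


def _sample_sigma(rng, s, quad, rank, scale):
    """Slice-sample a standard deviation given the sum of squares it governs.

    ``quad`` is the squared norm of the rank-``rank`` Gaussian vector; the
    target includes the half-Normal prior and the log-scale Jacobian.
    """
    def logp(x):
        sv = np.exp(x)
        return -rank * x - quad / (2.0 * sv * sv) + _half_normal_logpdf(sv, scale) + x

    return float(np.exp(_slice_sample_log(logp, np.log(s), rng)))


def _sample_sigma_marginal(rng, s, stat, lam, lik_var, scale):
    """Slice-sample a sigma with its random-effect block integrated out.

    In the prior eigenbasis the sufficient statistics ``stat`` are
    independent with variance ``sigma^2 / lam + lik_var``, so the collapsed
    conditional is a cheap product of normals; integrating the block out
    removes the funnel coupling between a variance component and its block.
    """
    def logp(x):
        sv = np.exp(x)
        v = sv * sv / lam + lik_var
        return float(
            -0.5 * np.sum(np.log(v) + stat * stat / v)
            + _half_normal_logpdf(sv, scale)
            + x
        )

    return float(np.exp(_slice_sample_log(logp, np.log(s), rng)))


def _sum_to_zero_basis(n: int) -> np.ndarray:
    """Orthonormal basis (n x n-1) of the subspace orthogonal to the constant."""
    from scipy.linalg import null_space

    return null_space(np.ones((1, n)))


def _rw1_structure(T: int) -> np.ndarray:
    """Structure matrix of a first-order random walk (tridiagonal, rank T-1)."""
    Q = np.zeros((T, T))
    for t in range(T - 1):
        Q[t, t] += 1.0
        Q[t + 1, t + 1] += 1.0
        Q[t, t + 1] -= 1.0
        Q[t + 1, t] -= 1.0
    return Q


def _run_chain(z, X, laplacian, spec: ModelSpec, n_iter, burn_in, thin, seed):
    C, T = z.shape
    K = X.shape[2]
    n = C * T
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    # Sum-to-zero bases: columns span the orthogonal complement of the
    # constant vector, so w = F_w u and phi = F_t v satisfy the ICAR / RW1
    # identifiability constraints exactly, and the joint precision below is
    # positive definite (the improper priors are proper on these subspaces).
    F_w = _sum_to_zero_basis(C)
    F_t = _sum_to_zero_basis(T)

    # Location-parameter layout: [alpha, beta (K), u (C-1), nu (C), v (T-1)],
    # with the u / nu / v blocks present only when the spec enables them.
    blocks = [("ab", K + 1)]
    if spec.spatial_structured:
        blocks.append(("w", C - 1))
    if spec.spatial_unstructured:
        blocks.append(("nu", C))
    if spec.temporal:
        blocks.append(("phi", T - 1))
    offsets, off = {}, 0
    for name, size in blocks:
        offsets[name] = (off, off + size)
        off += size
    D = off

    # fixed design A: z_flat = A @ theta + delta
    county_ix = np.repeat(np.arange(C), T)
    year_ix = np.tile(np.arange(T), C)
    E_c = np.zeros((n, C))
    E_c[np.arange(n), county_ix] = 1.0
    E_t = np.zeros((n, T))
    E_t[np.arange(n), year_ix] = 1.0
    A = np.zeros((n, D))
    A[:, 0] = 1.0
    A[:, 1 : K + 1] = X.reshape(n, K)
    if "w" in offsets:
        A[:, slice(*offsets["w"])] = E_c @ F_w
    if "nu" in offsets:
        A[:, slice(*offsets["nu"])] = E_c
    if "phi" in offsets:
        A[:, slice(*offsets["phi"])] = E_t @ F_t
    AtA = A.T @ A
    Atz = A.T @ z.reshape(-1)
    Lw_basis = F_w.T @ laplacian @ F_w       # ICAR precision in the basis
    Qt_basis = F_t.T @ _rw1_structure(T) @ F_t
    # eigenbases used by the collapsed sigma updates: in these coordinates
    # both the prior and the county/year-mean likelihood are diagonal
    lam_w, U_w = np.linalg.eigh(Lw_basis)    # all > 0 for a connected graph
    lam_t, U_t = np.linalg.eigh(Qt_basis)
    G_w = F_w @ U_w                          # (C, C-1) map to w space
    G_t = F_t @ U_t

    s_w = s_nu1 = s_t = s_nu2 = 0.5
    theta = np.zeros(D)

    n_keep = (n_iter - burn_in) // thin
    out = {
        "alpha": np.empty(n_keep),
        "beta": np.empty((n_keep, K)),
        "w": np.empty((n_keep, C)),
        "nu": np.empty((n_keep, C)),
        "phi": np.empty((n_keep, T)),
        "delta": np.empty((n_keep, C, T)),
        "s_w": np.empty(n_keep),
        "s_nu1": np.empty(n_keep),
        "s_t": np.empty(n_keep),
        "s_nu2": np.empty(n_keep),
    }
    kept = 0

    for it in range(n_iter):
        prec_d = 1.0 / (s_nu2 * s_nu2)

        # -- joint Gaussian draw of all location parameters ----------------
        P = AtA * prec_d
        P[np.diag_indices(K + 1)] += 1.0 / spec.prior_beta_sd**2
        if "w" in offsets:
            i0, i1 = offsets["w"]
            P[i0:i1, i0:i1] += Lw_basis / (s_w * s_w)
        if "nu" in offsets:
            i0, i1 = offsets["nu"]
            P[np.arange(i0, i1), np.arange(i0, i1)] += 1.0 / (s_nu1 * s_nu1)
        if "phi" in offsets:
            i0, i1 = offsets["phi"]
            P[i0:i1, i0:i1] += Qt_basis / (s_t * s_t)
        Lc = np.linalg.cholesky(P)
        mean = np.linalg.solve(Lc.T, np.linalg.solve(Lc, Atz * prec_d))
        theta = mean + np.linalg.solve(Lc.T, rng.standard_normal(D))

        alpha = theta[0]
        beta = theta[1 : K + 1]
        w = F_w @ theta[slice(*offsets["w"])] if "w" in offsets else np.zeros(C)
        nu = theta[slice(*offsets["nu"])] if "nu" in offsets else np.zeros(C)
        phi = F_t @ theta[slice(*offsets["phi"])] if "phi" in offsets else np.zeros(T)
        w -= w.mean()  # exact sum-to-zero against accumulated rounding

        fixed = alpha + X @ beta  # (C, T)
        lik_var_c = (s_nu2 * s_nu2) / T  # variance of a county-mean residual
        lik_var_t = (s_nu2 * s_nu2) / C  # variance of a year-mean residual

        # -- collapsed sigma updates -----------------------------------------
        # Standard deviations are updated with their random-effect blocks
        # integrated out (breaking the funnel coupling), then the blocks are
        # redrawn exactly from their Gaussian conditionals in the prior
        # eigenbasis.  The two county-level fields w and nu compete for the
        # same county-mean residual, so (sigma_w, sigma_nu1) are updated
        # jointly against the marginal with BOTH fields integrated out, and
        # (w, nu) redrawn from per-eigendirection 2x2 Gaussians.
        if spec.spatial_structured and spec.spatial_unstructured:
            rbar = (z - fixed - phi[None, :]).mean(axis=1)
            stat = G_w.T @ rbar          # sum-to-zero directions, C-1
            s0 = rbar.sum() / np.sqrt(C)  # constant direction (nu only)

            def logp_pair(sw, sn):
                v = sw * sw / lam_w + sn * sn + lik_var_c
                v0 = sn * sn + lik_var_c
                return (
                    -0.5 * float(np.sum(np.log(v) + stat * stat / v))
                    - 0.5 * (np.log(v0) + s0 * s0 / v0)
                )

            for _ in range(2):  # alternate 1-D slice scans on the pair
                s_w = float(np.exp(_slice_sample_log(
                    lambda x: logp_pair(np.exp(x), s_nu1)
                    + _half_normal_logpdf(np.exp(x), spec.prior_sd_scale) + x,
                    np.log(s_w), rng,
                )))
                s_nu1 = float(np.exp(_slice_sample_log(
                    lambda x: logp_pair(s_w, np.exp(x))
                    + _half_normal_logpdf(np.exp(x), spec.prior_sd_scale) + x,
                    np.log(s_nu1), rng,
                )))

            # exact joint redraw of (w, nu): per sum-to-zero eigendirection,
            # (t_j, nu_j) is bivariate Gaussian; the constant direction has
            # nu only.
            a = lam_w / (s_w * s_w) + 1.0 / lik_var_c
            b = 1.0 / lik_var_c
            c = 1.0 / (s_nu1 * s_nu1) + 1.0 / lik_var_c
            det = a * c - b * b
            mean_t = (c - b) * stat / lik_var_c / det
            mean_n = (a - b) * stat / lik_var_c / det
            cov11, cov12, cov22 = c / det, -b / det, a / det
            l11 = np.sqrt(cov11)
            l21 = cov12 / l11
            l22 = np.sqrt(cov22 - l21 * l21)
            z1 = rng.standard_normal(C - 1)
            z2 = rng.standard_normal(C - 1)
            t_draw = mean_t + l11 * z1
            n_draw = mean_n + l21 * z1 + l22 * z2
            prec0 = 1.0 / (s_nu1 * s_nu1) + 1.0 / lik_var_c
            n0 = s0 / lik_var_c / prec0 + rng.standard_normal() / np.sqrt(prec0)
            w = G_w @ t_draw
            w -= w.mean()
            nu = G_w @ n_draw + n0 / np.sqrt(C)
        elif spec.spatial_structured:
            rbar = (z - fixed - nu[:, None] - phi[None, :]).mean(axis=1)
            stat = G_w.T @ rbar  # coords with prior var s_w^2/lam_w
            s_w = _sample_sigma_marginal(rng, s_w, stat, lam_w, lik_var_c, spec.prior_sd_scale)
            post_prec = lam_w / (s_w * s_w) + 1.0 / lik_var_c
            t_draw = stat / lik_var_c / post_prec + rng.standard_normal(C - 1) / np.sqrt(post_prec)
            w = G_w @ t_draw
            w -= w.mean()
        elif spec.spatial_unstructured:
            rbar = (z - fixed - w[:, None] - phi[None, :]).mean(axis=1)
            s_nu1 = _sample_sigma_marginal(rng, s_nu1, rbar, np.ones(C), lik_var_c, spec.prior_sd_scale)
            post_prec = 1.0 / (s_nu1 * s_nu1) + 1.0 / lik_var_c
            nu = rbar / lik_var_c / post_prec + rng.standard_normal(C) / np.sqrt(post_prec)
        if spec.temporal:
            rbar = (z - fixed - w[:, None] - nu[:, None]).mean(axis=0)
            stat = G_t.T @ rbar
            s_t = _sample_sigma_marginal(rng, s_t, stat, lam_t, lik_var_t, spec.prior_sd_scale)
            post_prec = lam_t / (s_t * s_t) + 1.0 / lik_var_t
            t_draw = stat / lik_var_t / post_prec + rng.standard_normal(T - 1) / np.sqrt(post_prec)
            phi = G_t @ t_draw
            phi -= phi.mean()

        delta = z - fixed - w[:, None] - nu[:, None] - phi[None, :]
        s_nu2 = _sample_sigma(rng, s_nu2, float(np.sum(delta * delta)), n, spec.prior_sd_scale)

        if it >= burn_in and (it - burn_in) % thin == 0:
            out["alpha"][kept] = alpha
            out["beta"][kept] = beta
            out["w"][kept] = w
            out["nu"][kept] = nu
            out["phi"][kept] = phi
            out["delta"][kept] = delta
            out["s_w"][kept] = s_w
            out["s_nu1"][kept] = s_nu1
            out["s_t"][kept] = s_t
            out["s_nu2"][kept] = s_nu2
            kept += 1
    return out


def fit(
    panel: CountyYearPanel,
    adjacency: nx.Graph,
    model_spec: ModelSpec,
    mcmc_config: McmcConfig,
) -> PosteriorDraws:
    """Sample the posterior of the spatio-temporal model by MCMC.

    Runs ``n_chains`` chains with distinct seeds derived from
    ``mcmc_config.seed``; burn-in is discarded and draws are returned per
    chain.  The panel must be complete over counties x years and the
    adjacency graph connected.
    """
    if not panel.is_complete():
        raise ValueError("panel must be complete over counties x years")
    if adjacency.number_of_nodes() != panel.n_counties:
        raise ValueError("adjacency node count does not match panel counties")
    if not nx.is_connected(adjacency):
        raise ValueError("adjacency graph must be connected")

    z, X = panel.design_arrays(model_spec.factors)
    if set(adjacency.nodes) != set(panel.counties):
        raise ValueError("adjacency nodes must match panel county ids")
    laplacian = nx.laplacian_matrix(
        adjacency, nodelist=list(panel.counties)
    ).toarray().astype(float)

    chains = []
    for m in range(mcmc_config.n_chains):
        chain_seed = int(
            np.random.SeedSequence([mcmc_config.seed, m]).generate_state(1)[0] % (2**31)
        )
        chains.append(
            _run_chain(
                z, X, laplacian, model_spec,
                mcmc_config.n_iter, mcmc_config.burn_in, mcmc_config.thin, chain_seed,
            )
        )

    stack = lambda key: np.stack([c[key] for c in chains])
    return PosteriorDraws(
        factors=list(model_spec.factors),
        counties=panel.counties,
        years=panel.years,
        alpha=stack("alpha"),
        beta=stack("beta"),
        w=stack("w"),
        nu=stack("nu"),
        phi=stack("phi"),
        delta=stack("delta"),
        sigma_w=stack("s_w"),
        sigma_nu1=stack("s_nu1"),
        sigma_t=stack("s_t"),
        sigma_nu2=stack("s_nu2"),
    )


# --------------------------------------------------------------------------
# posterior summaries and diagnostics
# --------------------------------------------------------------------------

def _mc_error(chains: np.ndarray) -> float:
    """Monte Carlo SE of the pooled posterior mean, by batch means.

    Per chain, batches of size floor(sqrt(N)) estimate the variance of the
    chain mean under autocorrelation; chain means are averaged, so their
    variances combine as 1/M^2 times the sum.
    """
    m, n = chains.shape
    var_sum = 0.0
    for row in chains:
        b = max(1, int(np.sqrt(n)))
        nb = n // b
        if nb < 2:
            return float("nan")
        bm = row[: nb * b].reshape(nb, b).mean(axis=1)
        var_sum += float(np.var(bm, ddof=1)) / nb
    return float(np.sqrt(var_sum) / m)


def _gelman_interval_pct(chains: np.ndarray) -> float:
    """Brooks-Gelman-Rubin interval diagnostic, as a percentage.

    Ratio of the pooled 80% interval width to the mean within-chain 80%
    interval width, minus one, times 100.  Exactly 0 for identical chains.
    """
    lo, hi = 10.0, 90.0
    if np.all(chains == chains[0]):
        return 0.0  # no between-chain spread at all
    within = np.mean([np.diff(np.percentile(row, [lo, hi]))[0] for row in chains])
    pooled = np.diff(np.percentile(chains.reshape(-1), [lo, hi]))[0]
    if within == 0.0:
        return 0.0 if pooled == 0.0 else float("inf")
    return float((pooled / within - 1.0) * 100.0)


def summarize(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior summary table: one row per fixed effect / variance component.

    Columns: ``mean``, ``q2.5``, ``q97.5``, ``sd``, ``mc_error``,
    ``mc_sd_ratio_pct`` and ``gelman_pct``; quantiles are empirical over
    the pooled post-burn-in draws.
    """
    if draws.n_chains < 2:
        raise ValueError("Gelman diagnostic undefined for a single chain")
    rows = {}
    for name, chains in draws.scalar_params().items():
        pooled = chains.reshape(-1)
        sd = float(pooled.std(ddof=1)) if len(pooled) > 1 else 0.0
        mc = _mc_error(chains)
        if sd == 0.0:
            mc = 0.0
        rows[name] = {
            "mean": float(pooled.mean()),
            "q2.5": float(np.percentile(pooled, 2.5)),
            "q97.5": float(np.percentile(pooled, 97.5)),
            "sd": sd,
            "mc_error": mc,
            "mc_sd_ratio_pct": 0.0 if sd == 0.0 else 100.0 * mc / sd,
            "gelman_pct": _gelman_interval_pct(chains),
        }
    return pd.DataFrame(rows).T


def check_convergence(
    summary: pd.DataFrame,
    gelman_threshold: float = 5.0,
    mc_ratio_threshold: float = 5.0,
) -> dict:
    """Apply the convergence gate to a posterior summary.

    A parameter passes iff its Gelman interval statistic and its
    MC-error/SD ratio are both below their thresholds (percent); the
    overall verdict requires every summarized parameter to pass.
    """
    per_param = {
        name: bool(
            row["gelman_pct"] < gelman_threshold
            and row["mc_sd_ratio_pct"] < mc_ratio_threshold
        )
        for name, row in summary.iterrows()
    }
    return {"per_parameter": per_param, "overall": all(per_param.values())}


def prune_nonsignificant(
    draws: PosteriorDraws,
    panel: CountyYearPanel,
    adjacency: nx.Graph,
    model_spec: ModelSpec,
    mcmc_config: McmcConfig,
):
    """Drop factors whose 95% credible interval straddles zero, refitting.

    Removal is one factor at a time — the one whose posterior is most
    centred on zero (smallest |mean|/SD) — followed by a refit, until every
    retained interval excludes zero or no factors remain.  Returns
    ``(final_factors, final_draws)``.
    """
    from dataclasses import replace

    factors = list(model_spec.factors)
    current = draws
    while factors:
        summary = summarize(current)
        cand = [
            f for f in factors
            if summary.loc[f, "q2.5"] <= 0.0 <= summary.loc[f, "q97.5"]
        ]
        if not cand:
            break
        drop = min(
            cand,
            key=lambda f: abs(summary.loc[f, "mean"]) / summary.loc[f, "sd"]
            if summary.loc[f, "sd"] > 0 else np.inf,
        )
        factors.remove(drop)
        spec = replace(model_spec, factors=factors)
        current = fit(panel, adjacency, spec, mcmc_config)
    return factors, current
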