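"""Hierarchical Bayesian linear mixed model fit by conjugate Gibbs sampling.

Model
-----
For observation *i* in field *j(i)* and year *t(i)*::

    y_i = x_i' beta + u_{j(i)} + v_{t(i)} + eps_i,    eps_i ~ N(0, sigma2)
    u_j ~ N(0, sigma2_field)       v_t ~ N(0, sigma2_year)
    beta_k ~ N(0, beta_sd^2)       variances ~ InvGamma(ig_shape, ig_scale)

Every full conditional is available in closed form (Gaussian for beta, u,
v; inverse-gamma for the three variances), so the posterior is sampled by
a plain Gibbs cycle — no tuning, no gradients. Multiple chains are run
from jittered initial states on independent seed substreams; convergence
is checked with the classic Gelman–Rubin potential scale reduction
factor.

The random-effect prior means are pinned at 0 (a free mean would be
unidentifiable against the fixed intercept). An optional per-iteration
recentering sweep that moves the means of u and v into the intercept is
available for badly mixing problems but is off by default.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .preprocess import ModelDesign

#: Lower bound applied to variance draws as a guard against the
#: near-improper InvGamma(0.001, 0.001) prior collapsing numerically.
VARIANCE_FLOOR = 1e-12


@dataclass(frozen=True)
class PriorSpec:
    """Prior hyperparameters shared by every model stage.

    Fixed effects get independent Normal(0, ``beta_sd``²) priors
    (``beta_sd`` = 100 is effectively flat on the kg/ha scale); the
    residual and both random-effect variances get the near-improper
    InvGamma(``ig_shape``, ``ig_scale``) prior with both set to 0.001.
    """

    beta_sd: float = 100.0
    ig_shape: float = 0.001
    ig_scale: float = 0.001

    def __post_init__(self):
        if min(self.beta_sd, self.ig_shape, self.ig_scale) <= 0:
            raise ValueError("all prior hyperparameters must be strictly positive")


@dataclass(frozen=True)
class McmcConfig:
    """Chain protocol: 3 chains of 10,000 iterations, first 5,000 burned,
    no thinning; inference pools the remaining draws.

    ``joint_effects`` selects the default blocked update in which the
    fixed and both random effects are drawn as a single joint Gaussian
    per iteration; ``False`` falls back to the sequential
    beta -> u -> v cycle, which targets the same posterior but mixes
    far more slowly when most fields contribute only a few records.
    ``collapse_variances`` draws each random-effect variance jointly
    with its effects — the variance from its conditional with the
    effects integrated out (an exact 1-D slice-sampling step on the
    closed-form marginal), then the effects given the new variance —
    which removes the variance/effect "funnel" that otherwise stalls
    mixing when most clusters are singletons. Both switches change only
    the transition kernel, never the posterior.

    ``center_response`` fits the model with the response and every
    non-intercept column centred at their sample means, then maps the
    intercept draws back to the original parameterization. The
    Normal(0, beta_sd²) fixed-effect prior is only noninformative for
    the level if the level is removed: fitted on raw scales, the prior
    shrinks the covariate combination that carries the mean response,
    which leaks systematic bias into slopes of covariates with nonzero
    means. Centring makes the prior act on deviations only; slope and
    contrast definitions are untouched. On by default.
    """

    n_chains: int = 3
    n_iter: int = 10_000
    n_burn: int = 5_000
    master_seed: int = 0
    recenter: bool = False
    joint_effects: bool = True
    collapse_variances: bool = True
    center_response: bool = True

    def __post_init__(self):
        if not self.n_burn < self.n_iter:
            raise ValueError("n_burn must be < n_iter")
        if self.n_chains < 2:
            raise ValueError("need >= 2 chains for convergence diagnostics")

    @property
    def n_kept(self) -> int:
        return self.n_iter - self.n_burn


@dataclass
class PosteriorSamples:
    """Post-burn-in draws, kept per chain.

    Arrays are shaped ``(n_chains, n_kept, dim)`` (``(n_chains, n_kept)``
    for scalars). ``u``/``v`` and their variances are ``None`` when the
    corresponding random effect is absent from the design.
    """

    beta: np.ndarray
    beta_names: list
    sigma2: np.ndarray
    u: Optional[np.ndarray] = None
    v: Optional[np.ndarray] = None
    sigma2_field: Optional[np.ndarray] = None
    sigma2_year: Optional[np.ndarray] = None
    field_levels: list = field(default_factory=list)
    year_levels: list = field(default_factory=list)
    floor_hits: int = 0
    config: Optional[McmcConfig] = None

    def pooled(self, name: str) -> np.ndarray:
        """All post-burn-in draws of one parameter, chains concatenated."""
        if name in self.beta_names:
            return self.beta[:, :, self.beta_names.index(name)].reshape(-1)
        scalars = {
            "sigma2": self.sigma2,
            "sigma2_field": self.sigma2_field,
            "sigma2_year": self.sigma2_year,
        }
        if name in scalars and scalars[name] is not None:
            return scalars[name].reshape(-1)
        raise KeyError(f"unknown parameter {name!r}")

    def chain_draws(self, name: str) -> np.ndarray:
        """Per-chain draws ``(n_chains, n_kept)`` of one parameter."""
        if name in self.beta_names:
            return self.beta[:, :, self.beta_names.index(name)]
        return {
            "sigma2": self.sigma2,
            "sigma2_field": self.sigma2_field,
            "sigma2_year": self.sigma2_year,
        }[name]

    def parameter_names(self) -> list:
        names = list(self.beta_names) + ["sigma2"]
        if self.sigma2_field is not None:
            names.append("sigma2_field")
        if self.sigma2_year is not None:
            names.append("sigma2_year")
        return names

    def rhat_table(self) -> dict:
        """Gelman–Rubin R-hat for every reported parameter."""
        return {name: rhat(self.chain_draws(name)) for name in self.parameter_names()}

    def save(self, out_dir) -> None:
        """Write draws as a columnar CSV plus a JSON sidecar with the
        config, seed, R-hat table and variance-floor hit count."""
        os.makedirs(out_dir, exist_ok=True)
        C, S, _ = self.beta.shape
        cols = {
            "chain": np.repeat(np.arange(C), S),
            "iteration": np.tile(np.arange(S), C),
        }
        for k, name in enumerate(self.beta_names):
            cols[name] = self.beta[:, :, k].reshape(-1)
        cols["sigma2"] = self.sigma2.reshape(-1)
        if self.sigma2_field is not None:
            cols["sigma2_field"] = self.sigma2_field.reshape(-1)
        if self.sigma2_year is not None:
            cols["sigma2_year"] = self.sigma2_year.reshape(-1)
        pd.DataFrame(cols).to_csv(os.path.join(out_dir, "draws.csv"), index=False)
        rhats = self.rhat_table()
        meta = {
            "config": None
            if self.config is None
            else {
                "n_chains": self.config.n_chains,
                "n_iter": self.config.n_iter,
                "n_burn": self.config.n_burn,
                "master_seed": self.config.master_seed,
                "recenter": self.config.recenter,
            },
            "rhat": {k: (None if v is None or math.isnan(v) else v) for k, v in rhats.items()},
            "floor_hits": self.floor_hits,
        }
        with open(os.path.join(out_dir, "meta.json"), "w") as fh:
            json.dump(meta, fh, indent=2)


def beta_full_conditional(
    design: ModelDesign,
    u: Optional[np.ndarray],
    v: Optional[np.ndarray],
    sigma2: float,
    prior: PriorSpec,
):
    """Exact Gaussian full conditional of the fixed effects.

    ``cov = (X'X / sigma2 + I / beta_sd^2)^{-1}`` and
    ``mean = cov @ X'(y - u - v) / sigma2``.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    X = design.fixed_matrix
    y = design.response.copy()
    if u is not None and design.field_index is not None:
        y = y - u[design.field_index]
    if v is not None and design.year_index is not None:
        y = y - v[design.year_index]
    p = X.shape[1]
    prec = X.T @ X / sigma2 + np.eye(p) / prior.beta_sd**2
    try:
        cf = cho_factor(prec, lower=True)
    except np.linalg.LinAlgError:
        _raise_collinear(design)
    cov = cho_solve(cf, np.eye(p))
    mean = cov @ (X.T @ y / sigma2)
    return mean, cov


def _raise_collinear(design: ModelDesign):
    # name the offending columns via the near-nullspace of X
    X = design.fixed_matrix
    _, _, Vt = np.linalg.svd(X, full_matrices=True)
    null = np.abs(Vt[-1])
    bad = [
        design.fixed_names[j]
        for j in range(X.shape[1])
        if null[j] > 0.3 * null.max()
    ]
    raise ValueError(f"singular fixed-effect system; collinear columns: {bad}")


def variance_full_conditional(values: np.ndarray, prior: PriorSpec):
    """Inverse-gamma full conditional (shape, scale) for a variance.

    ``shape = ig_shape + n/2``, ``scale = ig_scale + sum(values^2)/2``;
    applied to residuals for sigma2 and to the realized random effects
    for their variance hyperparameters.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("variance update needs a non-empty vector")
    shape = prior.ig_shape + values.size / 2.0
    scale = prior.ig_scale + float(values @ values) / 2.0
    return shape, scale


def _draw_inverse_gamma(rng, shape: float, scale: float) -> float:
    return scale / rng.gamma(shape)


def _slice_sample(logpdf, x0: float, rng, w: float = 1.0, max_steps: int = 50) -> float:
    """One exact univariate slice-sampling update (stepping out, then
    shrinkage). Leaves the density invariant; no tuning beyond the
    initial bracket width ``w``."""
    z = logpdf(x0) - rng.exponential()
    r = rng.random()
    lo, hi = x0 - w * r, x0 + w * (1.0 - r)
    k = max_steps
    while k > 0 and logpdf(lo) > z:
        lo -= w
        k -= 1
    k = max_steps
    while k > 0 and logpdf(hi) > z:
        hi += w
        k -= 1
    while True:
        x1 = lo + rng.random() * (hi - lo)
        if logpdf(x1) > z:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1


def _marginal_variance_draw(
    rng, current: float, resid: np.ndarray, idx: np.ndarray, counts: np.ndarray,
    s2: float, prior: PriorSpec,
) -> float:
    """Draw a random-effect variance with its effects integrated out.

    ``resid`` is the response minus every other model component; groups
    are given by ``idx`` with sizes ``counts``. Marginally each group's
    covariance is ``s2*I + s2g*J`` (J the all-ones matrix), so the
    1-D conditional of the group variance ``s2g`` is available in
    closed form up to normalization and is sampled exactly by slice
    sampling on log(s2g). Pairing this with a fresh conditional draw of
    the effects is a blocked update that removes the variance/effect
    funnel that stalls the plain conjugate cycle when most groups hold
    a single observation.
    """
    S = np.bincount(idx, weights=resid, minlength=len(counts))

    def logpdf(t: float) -> float:
        s2g = math.exp(t)
        denom = s2 + counts * s2g
        ll = -0.5 * float(np.sum(np.log(denom)))
        ll += 0.5 * s2g / s2 * float(np.sum(S * S / denom))
        # IG(a, b) prior on s2g plus the log-scale Jacobian
        return ll - prior.ig_shape * t - prior.ig_scale / s2g

    return math.exp(_slice_sample(logpdf, math.log(max(current, VARIANCE_FLOOR)), rng))


def _draw_partitioned(rng, a, B, C, r_g, r_w, design):
    """One draw from N(P⁻¹r, P⁻¹) for the partitioned precision
    ``P = [[diag(a), B], [B', C]]``: the small block w from its Schur
    marginal, then the diagonal group block g from its conditional.
    Returns ``(w, g)``."""
    Binv = B / a[:, None]
    S = C - B.T @ Binv
    try:
        L = np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        _raise_collinear(design)
    mean_w = cho_solve((L, True), r_w - Binv.T @ r_g)
    w = mean_w + solve_triangular(L.T, rng.standard_normal(len(r_w)), lower=False)
    g = (r_g - B @ w) / a + rng.standard_normal(len(a)) / np.sqrt(a)
    return w, g


def gibbs_fit(
    design: ModelDesign,
    prior: PriorSpec = PriorSpec(),
    config: McmcConfig = McmcConfig(),
    fixed_sigma2: Optional[float] = None,
) -> PosteriorSamples:
    """Sample the posterior by conjugate Gibbs.

    By default each iteration draws the full coefficient vector
    (beta, u, v) from its joint Gaussian full conditional, then updates
    sigma2, sigma2_field and sigma2_year from their inverse-gamma
    conditionals. With ``config.joint_effects=False`` the effects are
    instead cycled sequentially (beta -> u -> v), which targets the
    identical posterior but can mix poorly when fields contribute few
    records each. Random effects are skipped when their index is
    ``None`` in the design; ``fixed_sigma2`` pins the residual variance
    (used by the conjugate-oracle checks). Identical inputs including
    ``master_seed`` give bit-identical output; chain *k* draws from
    seed substream *k*.
    """
    X = design.fixed_matrix
    y = design.response
    n, p = X.shape
    intercept_col = (
        design.fixed_names.index("intercept") if "intercept" in design.fixed_names else None
    )
    center = config.center_response and intercept_col is not None
    if center:
        ybar = float(np.mean(y))
        y = y - ybar
        xbar = X.mean(axis=0)
        xbar[intercept_col] = 0.0
        X = X - xbar
    has_field = design.field_index is not None and len(design.field_levels) > 0
    has_year = design.year_index is not None and len(design.year_levels) > 0
    J = len(design.field_levels) if has_field else 0
    T = len(design.year_levels) if has_year else 0
    fi = design.field_index if has_field else None
    yi = design.year_index if has_year else None

    XtX = X.T @ X
    eye_p = np.eye(p)
    prior_prec = eye_p / prior.beta_sd**2

    joint = config.joint_effects and (has_field or has_year)
    if joint:
        # constant cross-products for the partitioned joint draw: the
        # largest random-effect block of the precision is diagonal and
        # is eliminated by Schur complement, so the per-iteration
        # factorization is only (p + T)-dimensional
        Xty = X.T @ y
        if has_field:
            ZfX = np.zeros((J, p))
            np.add.at(ZfX, fi, X)
            Zfy = np.bincount(fi, weights=y, minlength=J)
        if has_year:
            ZyX = np.zeros((T, p))
            np.add.at(ZyX, yi, X)
            Zyy = np.bincount(yi, weights=y, minlength=T)
        if has_field and has_year:
            FY = np.zeros((J, T))
            np.add.at(FY, (fi, yi), 1.0)
    var_y = float(np.var(y)) if n > 1 else 1.0
    if var_y <= 0:
        var_y = 1.0
    nj = np.bincount(fi, minlength=J).astype(float) if has_field else None
    nt = np.bincount(yi, minlength=T).astype(float) if has_year else None
    S = config.n_kept
    beta_out = np.empty((config.n_chains, S, p))
    sigma2_out = np.empty((config.n_chains, S))
    u_out = np.empty((config.n_chains, S, J)) if has_field else None
    v_out = np.empty((config.n_chains, S, T)) if has_year else None
    s2f_out = np.empty((config.n_chains, S)) if has_field else None
    s2y_out = np.empty((config.n_chains, S)) if has_year else None
    floor_hits = 0

    substreams = np.random.SeedSequence(config.master_seed).spawn(config.n_chains)
    for c in range(config.n_chains):
        rng = np.random.default_rng(substreams[c])
        # jittered start: beta near 0, effects at 0, variances near var(y)
        beta = rng.normal(0.0, 0.1 * math.sqrt(var_y), size=p)
        u = np.zeros(J)
        v = np.zeros(T)
        s2 = fixed_sigma2 if fixed_sigma2 is not None else var_y * math.exp(rng.normal(0, 0.3))
        s2f = var_y * math.exp(rng.normal(0, 0.3)) if has_field else None
        s2y = var_y * math.exp(rng.normal(0, 0.3)) if has_year else None

        for it in range(config.n_iter):
            if joint:
                # (beta, u, v) | variances: one exact joint Gaussian
                # draw, the diagonal field block eliminated by Schur
                # complement (u drawn from its conditional given the rest)
                if has_field:
                    a = nj / s2 + 1.0 / s2f
                    if has_year:
                        q = T + p
                        C = np.zeros((q, q))
                        C[:T, :T] = np.diag(nt / s2 + 1.0 / s2y)
                        C[:T, T:] = ZyX / s2
                        C[T:, :T] = C[:T, T:].T
                        C[T:, T:] = XtX / s2 + prior_prec
                        B = np.concatenate([FY, ZfX], axis=1) / s2
                        r_w = np.concatenate([Zyy, Xty]) / s2
                    else:
                        C = XtX / s2 + prior_prec
                        B = ZfX / s2
                        r_w = Xty / s2
                    w, u = _draw_partitioned(rng, a, B, C, Zfy / s2, r_w, design)
                    if has_year:
                        v = w[:T]
                        beta = w[T:]
                    else:
                        beta = w
                else:  # year effects only
                    a = nt / s2 + 1.0 / s2y
                    w, v = _draw_partitioned(
                        rng, a, ZyX / s2, XtX / s2 + prior_prec, Zyy / s2, Xty / s2, design
                    )
                    beta = w
                mu = X @ beta
            else:
                u_row = u[fi] if has_field else 0.0
                v_row = v[yi] if has_year else 0.0

                # beta | rest
                prec = XtX / s2 + prior_prec
                try:
                    L = np.linalg.cholesky(prec)
                except np.linalg.LinAlgError:
                    _raise_collinear(design)
                rhs = X.T @ (y - u_row - v_row) / s2
                mean = cho_solve((L, True), rhs)
                beta = mean + solve_triangular(L.T, rng.standard_normal(p), lower=False)
                mu = X @ beta

                # u | rest
                if has_field:
                    res = y - mu - v_row
                    sums = np.bincount(fi, weights=res, minlength=J)
                    var_u = 1.0 / (nj / s2 + 1.0 / s2f)
                    u = var_u * sums / s2 + np.sqrt(var_u) * rng.standard_normal(J)
                    u_row = u[fi]

                # v | rest
                if has_year:
                    res = y - mu - u_row
                    sums = np.bincount(yi, weights=res, minlength=T)
                    var_v = 1.0 / (nt / s2 + 1.0 / s2y)
                    v = var_v * sums / s2 + np.sqrt(var_v) * rng.standard_normal(T)
                    v_row = v[yi]

            if config.recenter and intercept_col is not None:
                if has_field:
                    m = u.mean()
                    u -= m
                    beta[intercept_col] += m
                if has_year:
                    m = v.mean()
                    v -= m
                    beta[intercept_col] += m
                mu = X @ beta

            # variances | rest
            if fixed_sigma2 is None:
                resid = y - mu - (u[fi] if has_field else 0.0) - (v[yi] if has_year else 0.0)
                sh, sc = variance_full_conditional(resid, prior)
                s2 = _draw_inverse_gamma(rng, sh, sc)
                if s2 < VARIANCE_FLOOR:
                    s2 = VARIANCE_FLOOR
                    floor_hits += 1
            if has_field:
                if config.collapse_variances:
                    # blocked (sigma2_field, u): variance from its
                    # u-marginalized conditional, then u refreshed
                    resid_f = y - mu - (v[yi] if has_year else 0.0)
                    s2f = _marginal_variance_draw(rng, s2f, resid_f, fi, nj, s2, prior)
                    if s2f < VARIANCE_FLOOR:
                        s2f = VARIANCE_FLOOR
                        floor_hits += 1
                    sums = np.bincount(fi, weights=resid_f, minlength=J)
                    var_u = 1.0 / (nj / s2 + 1.0 / s2f)
                    u = var_u * sums / s2 + np.sqrt(var_u) * rng.standard_normal(J)
                else:
                    sh, sc = variance_full_conditional(u, prior)
                    s2f = _draw_inverse_gamma(rng, sh, sc)
                    if s2f < VARIANCE_FLOOR:
                        s2f = VARIANCE_FLOOR
                        floor_hits += 1
            if has_year:
                if config.collapse_variances:
                    resid_y = y - mu - (u[fi] if has_field else 0.0)
                    s2y = _marginal_variance_draw(rng, s2y, resid_y, yi, nt, s2, prior)
                    if s2y < VARIANCE_FLOOR:
                        s2y = VARIANCE_FLOOR
                        floor_hits += 1
                    sums = np.bincount(yi, weights=resid_y, minlength=T)
                    var_v = 1.0 / (nt / s2 + 1.0 / s2y)
                    v = var_v * sums / s2 + np.sqrt(var_v) * rng.standard_normal(T)
                else:
                    sh, sc = variance_full_conditional(v, prior)
                    s2y = _draw_inverse_gamma(rng, sh, sc)
                    if s2y < VARIANCE_FLOOR:
                        s2y = VARIANCE_FLOOR
                        floor_hits += 1

            if it >= config.n_burn:
                k = it - config.n_burn
                if not (np.all(np.isfinite(beta)) and math.isfinite(s2)):
                    raise FloatingPointError(
                        f"non-finite state at chain {c}, iteration {it} (beta/sigma2)"
                    )
                beta_out[c, k] = beta
                sigma2_out[c, k] = s2
                if has_field:
                    u_out[c, k] = u
                    s2f_out[c, k] = s2f
                if has_year:
                    v_out[c, k] = v
                    s2y_out[c, k] = s2y

    if center:
        # back to the original parameterization:
        # intercept = centred intercept + ybar - sum_k xbar_k * beta_k
        beta_out[:, :, intercept_col] += ybar - np.einsum("csk,k->cs", beta_out, xbar)

    return PosteriorSamples(
        beta=beta_out,
        beta_names=list(design.fixed_names),
        sigma2=sigma2_out,
        u=u_out,
        v=v_out,
        sigma2_field=s2f_out,
        sigma2_year=s2y_out,
        field_levels=list(design.field_levels),
        year_levels=list(design.year_levels),
        floor_hits=floor_hits,
        config=config,
    )


def rhat(chains: np.ndarray) -> float:
    """Classic Gelman–Rubin potential scale reduction factor.

    ``chains`` is ``(n_chains, n_draws)``. With W the mean within-chain
    variance and B = n x variance of the chain means, returns
    ``sqrt(((n-1)/n * W + B/n) / W)``. Returns ``nan`` (diagnostic
    undefined) when the within-chain variance is zero rather than
    silently reporting 1.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2 or chains.shape[1] < 2:
        raise ValueError("rhat needs >= 2 chains with >= 2 draws each")
    n = chains.shape[1]
    W = float(np.mean(np.var(chains, axis=1, ddof=1)))
    if W == 0.0:
        return float("nan")
    B = n * float(np.var(np.mean(chains, axis=1), ddof=1))
    var_hat = (n - 1) / n * W + B / n
    return float(math.sqrt(var_hat / W))
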