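"""Univariable MR estimators, heterogeneity diagnostics, Steiger filtering,
and a mixture-model collider-slope correction.

All estimators consume a :class:`~mrforge.sumstats_io.HarmonizedSet` and
return an :class:`MRResult` with the causal effect on the log-odds scale, a
95% Wald confidence interval (also exported on the OR scale), and, where
applicable, Cochran's Q and the Egger intercept test.

Estimator dispatch follows the variant-count rule: one variant uses the Wald
ratio, two or three use fixed-effects IVW, and more than three use IVW with
multiplicative random effects (the fixed-effects SE inflated by
``max(1, sqrt(Q / (L - 1)))``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats_io import HarmonizedSet

logger = logging.getLogger(__name__)

Z95 = stats.norm.ppf(0.975)

Method = Literal["wald", "ivw_fixed", "ivw_mre", "egger", "weighted_median", "weighted_mode"]


@dataclass
class MRResult:
    """A causal estimate with its diagnostics.

    ``beta`` is the causal effect per log-odds (or SD) increase in the
    genetically predicted exposure; ``odds_ratio`` and its CI are the
    exponentiated values.
    """

    method: str
    n_variants: int
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    Q: float | None = None
    Q_pval: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pval: float | None = None
    bootstrap_reps: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.ci_low >= self.ci_high:
            raise ValueError("ci_low must be < ci_high")
        if not 0 < self.pval <= 1:
            raise ValueError("pval must lie in (0, 1]")
        if self.Q is not None and self.Q < -1e-12:
            raise ValueError("Q must be non-negative")
        if self.n_variants < 1:
            raise ValueError("need at least one variant")

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_ci_low(self) -> float:
        return float(np.exp(self.ci_low))

    @property
    def or_ci_high(self) -> float:
        return float(np.exp(self.ci_high))


def _normal_p(z: float) -> float:
    return float(max(2 * stats.norm.sf(abs(z)), np.finfo(float).tiny))


def _wald_ci(beta: float, se: float) -> tuple[float, float]:
    return beta - Z95 * se, beta + Z95 * se


def _arrays(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    df = h.df
    return (
        df["beta_exp"].to_numpy(float),
        df["se_exp"].to_numpy(float),
        df["beta_out"].to_numpy(float),
        df["se_out"].to_numpy(float),
    )


def wald_ratio(h: HarmonizedSet) -> MRResult:
    """Single-variant causal estimate: beta_out / beta_exp.

    The SE uses the first-order delta method, |se_out / beta_exp|, which is
    accurate for strong instruments (|beta_exp| / se_exp large).
    """
    if len(h) != 1:
        raise ValueError("wald_ratio requires exactly one variant")
    bx, _, by, sy = (a.item() for a in _arrays(h))
    if bx == 0:
        raise ValueError("wald_ratio undefined for beta_exp = 0")
    beta = by / bx
    se = abs(sy / bx)
    lo, hi = _wald_ci(beta, se)
    return MRResult("wald", 1, beta, se, lo, hi, _normal_p(beta / se))


def cochran_q(h: HarmonizedSet, theta: float) -> tuple[float, float]:
    """Cochran's heterogeneity statistic around a causal effect ``theta``.

    Q = sum_j (beta_out_j - theta * beta_exp_j)^2 / se_out_j^2, compared to
    chi-square with L - 1 degrees of freedom.
    """
    if len(h) < 2:
        raise ValueError("cochran_q requires at least two variants")
    bx, _, by, sy = _arrays(h)
    q = float(np.sum(((by - theta * bx) / sy) ** 2))
    return q, float(stats.chi2.sf(q, len(h) - 1))


def ivw(
    h: HarmonizedSet,
    effects: Literal["fixed", "multiplicative_random"] = "multiplicative_random",
) -> MRResult:
    """Inverse-variance weighted estimate (origin-constrained WLS).

    theta = sum(w b_x b_y) / sum(w b_x^2) with w = 1 / se_y^2.  The
    multiplicative random-effects model scales the fixed-effects SE by
    ``max(1, sqrt(Q / (L - 1)))`` and never shrinks it.
    """
    if len(h) < 2:
        raise ValueError("ivw requires >= 2 variants; use wald_ratio for one")
    if effects not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown effects model {effects!r}")
    bx, _, by, sy = _arrays(h)
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    theta = float(np.sum(w * bx * by)) / denom
    se = denom**-0.5
    q, q_p = cochran_q(h, theta)
    method = "ivw_fixed"
    if effects == "multiplicative_random":
        se *= max(1.0, np.sqrt(q / (len(h) - 1)))
        method = "ivw_mre"
    lo, hi = _wald_ci(theta, se)
    return MRResult(method, len(h), theta, se, lo, hi, _normal_p(theta / se), Q=q, Q_pval=q_p)


def _orient_positive_exposure(bx, by):
    s = np.where(bx < 0, -1.0, 1.0)
    return bx * s, by * s


def mr_egger(h: HarmonizedSet) -> MRResult:
    """MR-Egger regression: WLS of beta_out on beta_exp with an intercept.

    Variants are oriented so all exposure effects are non-negative (the
    estimator is not orientation-invariant).  The intercept estimates the
    average directional pleiotropic effect; slope and intercept SEs are
    inflated by ``max(1, sqrt(Q_egger / (L - 2)))``.
    """
    L = len(h)
    if L < 3:
        raise ValueError("mr_egger requires at least three variants")
    bx, _, by, sy = _arrays(h)
    bx, by = _orient_positive_exposure(bx, by)
    w = 1.0 / sy**2
    # closed-form 2-parameter weighted least squares
    X = np.column_stack([np.ones(L), bx])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = by - X @ coef
    q = float(np.sum(w * resid**2))
    phi = max(1.0, np.sqrt(q / (L - 2)))
    cov = np.linalg.inv(xtwx)
    se_int, se_slope = phi * np.sqrt(np.diag(cov))
    intercept, slope = coef
    lo, hi = _wald_ci(slope, se_slope)
    return MRResult(
        "egger", L, float(slope), float(se_slope), lo, hi,
        _normal_p(slope / se_slope),
        Q=q, Q_pval=float(stats.chi2.sf(q, L - 2)),
        egger_intercept=float(intercept),
        egger_intercept_se=float(se_int),
        egger_intercept_pval=_normal_p(intercept / se_int),
    )


def weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float = 0.5) -> float:
    """Linear interpolation of the weighted empirical quantile function.

    With normalized weights sorted by value, the cumulative coordinate of the
    j-th point is S_j = (sum_{k<=j} w_k - w_j / 2); the quantile is the
    piecewise-linear interpolation of value against S at ``q``.
    """
    order = np.argsort(values, kind="mergesort")
    v = np.asarray(values, float)[order]
    w = np.asarray(weights, float)[order]
    w = w / w.sum()
    s = np.cumsum(w) - w / 2
    return float(np.interp(q, s, v))


def _ratio_weights(bx: np.ndarray, sy: np.ndarray) -> np.ndarray:
    return bx**2 / sy**2


def _batch_weighted_median(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-wise weighted median of a (reps, L) matrix."""
    order = np.argsort(values, axis=1, kind="mergesort")
    v = np.take_along_axis(values, order, axis=1)
    w = np.take_along_axis(weights, order, axis=1)
    w = w / w.sum(axis=1, keepdims=True)
    s = np.cumsum(w, axis=1) - w / 2
    out = np.empty(len(values))
    for i in range(len(values)):
        out[i] = np.interp(0.5, s[i], v[i])
    return out


def _bootstrap_draws(h: HarmonizedSet, reps: int, seed: int):
    """Parametric bootstrap of (beta_exp, beta_out) from their sampling normals."""
    bx, sx, by, sy = _arrays(h)
    rng = np.random.default_rng(seed)
    bx_b = rng.normal(bx, sx, size=(reps, len(bx)))
    by_b = rng.normal(by, sy, size=(reps, len(by)))
    return bx_b, by_b, sy


def weighted_median(h: HarmonizedSet, reps: int = 5000, seed: int = 0) -> MRResult:
    """Weighted median of the per-variant ratio estimates.

    Consistent when more than half of the total weight
    (w_j = beta_exp_j^2 / se_out_j^2) comes from valid instruments.  The SE
    is a parametric bootstrap over ``reps`` resamples of the summary effects.
    """
    if len(h) < 3:
        raise ValueError("weighted_median requires at least three variants")
    if reps < 2:
        raise ValueError("reps must be at least 2")
    if reps < 100:
        warnings.warn("bootstrap reps < 100 gives an unstable SE", stacklevel=2)
    bx, _, by, sy = _arrays(h)
    ratios = by / bx
    weights = _ratio_weights(bx, sy)
    est = weighted_quantile(ratios, weights, 0.5)

    bx_b, by_b, sy_row = _bootstrap_draws(h, reps, seed)
    boot = _batch_weighted_median(by_b / bx_b, bx_b**2 / sy_row**2)
    se = float(boot.std(ddof=1))
    lo, hi = _wald_ci(est, se)
    return MRResult(
        "weighted_median", len(h), est, se, lo, hi, _normal_p(est / se),
        bootstrap_reps=reps, seed=seed,
    )


def _mode_bandwidth(ratios: np.ndarray, weights: np.ndarray, phi: float) -> float:
    """Silverman-type bandwidth on the weighted ratio sample, scaled by phi."""
    w = weights / weights.sum()
    mu = float(np.sum(w * ratios))
    sd = float(np.sqrt(np.sum(w * (ratios - mu) ** 2)))
    q1 = weighted_quantile(ratios, weights, 0.25)
    q3 = weighted_quantile(ratios, weights, 0.75)
    iqr = q3 - q1
    candidates = [c for c in (sd, iqr / 1.349) if c > 0]
    if not candidates:
        return 0.0
    return phi * 0.9 * min(candidates) * len(ratios) ** (-1 / 5)


def _mode_point(ratios: np.ndarray, weights: np.ndarray, phi: float, grid_size: int = 512):
    h = _mode_bandwidth(ratios, weights, phi)
    if h == 0.0:  # degenerate: all mass at one point
        return float(ratios[np.argmax(weights)]), h
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, grid_size)
    w = weights / weights.sum()
    dens = w @ np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / h) ** 2)
    return float(grid[np.argmax(dens)]), h


def weighted_mode(
    h: HarmonizedSet, phi: float = 1.0, reps: int = 5000, seed: int = 0,
    grid_size: int = 512,
) -> MRResult:
    """Mode of the weighted kernel density over the ratio estimates.

    Uses a normal kernel with bandwidth
    ``phi * 0.9 * min(sd, IQR/1.349) * L^(-1/5)`` computed on the weighted
    ratio sample; consistent when the largest share of instrument weight is
    valid.  SE by the same parametric bootstrap as the weighted median.
    """
    if len(h) < 3:
        raise ValueError("weighted_mode requires at least three variants")
    if phi <= 0:
        raise ValueError("phi must be positive")
    if reps < 2:
        raise ValueError("reps must be at least 2")
    bx, _, by, sy = _arrays(h)
    ratios = by / bx
    weights = _ratio_weights(bx, sy)
    est, _ = _mode_point(ratios, weights, phi, grid_size)

    bx_b, by_b, sy_row = _bootstrap_draws(h, reps, seed)
    r_b = by_b / bx_b
    w_b = bx_b**2 / sy_row**2
    boot = _batch_weighted_mode(r_b, w_b, phi, grid_size)
    # MAD-based spread: the bootstrap distribution of a mode has heavy tails
    # (replicates occasionally jump between density bumps), so the normalized
    # median absolute deviation is the conventional scale estimate here
    se = float(1.4826 * np.median(np.abs(boot - np.median(boot))))
    lo, hi = _wald_ci(est, se)
    return MRResult(
        "weighted_mode", len(h), est, se, lo, hi, _normal_p(est / se),
        bootstrap_reps=reps, seed=seed,
    )


def _batch_weighted_mode(
    ratios: np.ndarray, weights: np.ndarray, phi: float, grid_size: int = 256
) -> np.ndarray:
    """Row-wise weighted KDE argmax for a (reps, L) bootstrap sample."""
    reps, L = ratios.shape
    w = weights / weights.sum(axis=1, keepdims=True)
    mu = np.sum(w * ratios, axis=1, keepdims=True)
    sd = np.sqrt(np.sum(w * (ratios - mu) ** 2, axis=1))
    # row-wise weighted IQR
    order = np.argsort(ratios, axis=1, kind="mergesort")
    v = np.take_along_axis(ratios, order, axis=1)
    ws = np.take_along_axis(w, order, axis=1)
    s = np.cumsum(ws, axis=1) - ws / 2
    q1 = np.empty(reps)
    q3 = np.empty(reps)
    for i in range(reps):
        q1[i] = np.interp(0.25, s[i], v[i])
        q3[i] = np.interp(0.75, s[i], v[i])
    spread = np.minimum(np.where(sd > 0, sd, np.inf), np.where(q3 > q1, (q3 - q1) / 1.349, np.inf))
    h = phi * 0.9 * np.where(np.isfinite(spread), spread, 0.0) * L ** (-1 / 5)
    out = np.empty(reps)
    lo = ratios.min(axis=1) - 3 * h
    hi = ratios.max(axis=1) + 3 * h
    for i in range(reps):
        if h[i] == 0:
            out[i] = v[i, np.argmax(ws[i])]
            continue
        grid = np.linspace(lo[i], hi[i], grid_size)
        dens = w[i] @ np.exp(-0.5 * ((grid[None, :] - ratios[i][:, None]) / h[i]) ** 2)
        out[i] = grid[np.argmax(dens)]
    return out


def dispatch_mr(h: HarmonizedSet, **ivw_kwargs) -> MRResult:
    """Choose the primary estimator by variant count.

    One variant: Wald ratio.  Two or three: fixed-effects IVW.  More than
    three: IVW with multiplicative random effects.
    """
    if len(h) == 0:
        raise ValueError("empty harmonized set")
    if len(h) == 1:
        return wald_ratio(h)
    if len(h) <= 3:
        return ivw(h, effects="fixed")
    return ivw(h, effects="multiplicative_random")


@dataclass
class SteigerResult:
    """Per-variant variance-explained comparison between exposure and outcome."""

    table: pd.DataFrame  # columns: variant_id, r2_exposure, r2_outcome, keep
    n_removed: int


def steiger_filter(h: HarmonizedSet) -> tuple[HarmonizedSet, SteigerResult]:
    """Remove variants explaining more outcome than exposure variance.

    Per-trait variance explained is approximated as r^2 = z^2 / (z^2 + n - 2)
    with z = beta / se, on the observed scale for both trait types.  A
    variant is kept iff r2_exposure > r2_outcome.
    """
    df = h.df
    if df["n_exp"].isna().any() or df["n_out"].isna().any():
        raise ValueError("steiger_filter requires n_exp and n_out per variant")
    z_exp = df["beta_exp"] / df["se_exp"]
    z_out = df["beta_out"] / df["se_out"]
    r2_exp = z_exp**2 / (z_exp**2 + df["n_exp"] - 2)
    r2_out = z_out**2 / (z_out**2 + df["n_out"] - 2)
    keep = (r2_exp > r2_out).to_numpy()
    table = pd.DataFrame({
        "variant_id": df["variant_id"],
        "r2_exposure": r2_exp,
        "r2_outcome": r2_out,
        "keep": keep,
    })
    filtered = h.subset(keep)
    return filtered, SteigerResult(table.reset_index(drop=True), int((~keep).sum()))


@dataclass
class SlopeHunterFit:
    """Fitted collider slope from the two-component mixture model."""

    b_hat: float
    cluster_probs: np.ndarray  # P(incidence-only component) per variant
    pi: float
    tau2: float
    converged: bool
    n_iter: int
    log_likelihood: float


def _em_slope_mixture(
    x: np.ndarray, y: np.ndarray, gamma0: np.ndarray, max_iter: int, tol: float
):
    """EM for: comp 1 (weight pi): x~N(0,s2), y|x~N(b x, tau2);
    comp 2: free bivariate normal."""
    n = len(x)
    gamma = np.clip(gamma0, 1e-6, 1 - 1e-6)
    ll_old = -np.inf
    ll = ll_old
    b = 0.0
    tau2 = np.var(y) + 1e-12
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # M step
        g1 = gamma.sum()
        g2 = n - g1
        pi = np.clip(g1 / n, 1e-6, 1 - 1e-6)
        s2 = max(float(np.sum(gamma * x**2) / g1), 1e-12)
        b = float(np.sum(gamma * x * y) / max(np.sum(gamma * x**2), 1e-300))
        tau2 = max(float(np.sum(gamma * (y - b * x) ** 2) / g1), 1e-12)
        w2 = (1 - gamma) / g2
        mu2 = np.array([np.sum(w2 * x), np.sum(w2 * y)])
        dx, dy = x - mu2[0], y - mu2[1]
        cov2 = np.array([
            [np.sum(w2 * dx * dx), np.sum(w2 * dx * dy)],
            [np.sum(w2 * dx * dy), np.sum(w2 * dy * dy)],
        ]) + 1e-10 * np.eye(2)
        # E step (log densities)
        log_f1 = (
            stats.norm.logpdf(x, 0.0, np.sqrt(s2))
            + stats.norm.logpdf(y, b * x, np.sqrt(tau2))
        )
        log_f2 = stats.multivariate_normal.logpdf(np.column_stack([x, y]), mu2, cov2)
        a1 = np.log(pi) + log_f1
        a2 = np.log(1 - pi) + log_f2
        m = np.maximum(a1, a2)
        lse = m + np.log(np.exp(a1 - m) + np.exp(a2 - m))
        gamma = np.exp(a1 - lse)
        ll = float(lse.sum())
        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
    return b, gamma, float(pi), float(tau2), converged, it, ll


def slope_hunter_adjust(
    incidence: pd.DataFrame,
    progression: pd.DataFrame,
    p_incidence_threshold: float = 5e-8,
    max_iter: int = 2000,
    tol: float = 1e-8,
    seed: int | None = None,
    n_restarts: int = 3,
) -> tuple[SlopeHunterFit, pd.DataFrame]:
    """Estimate the collider-induced slope and return corrected effects.

    A GWAS of disease progression run only in affected individuals conditions
    on the index event; variants affecting incidence then acquire spurious
    progression effects proportional to their incidence effects (slope b).
    Among incidence-associated variants (p below ``p_incidence_threshold``),
    a two-component mixture is fitted to paired effects (b_I, b_P): the
    incidence-only component satisfies b_P = b * b_I + eps, eps ~ N(0, tau2),
    while variants with genuine progression effects form a free bivariate
    normal component.  EM alternates responsibilities and parameters until
    the log-likelihood change drops below ``tol``.

    Adjusted effects for every shared variant are
    beta_adj = beta_P - b_hat * beta_I with
    se_adj = sqrt(se_P^2 + b_hat^2 * se_I^2).

    When ``seed`` is given, responsibilities are initialized at random
    (useful for restart checks); otherwise initialization assigns high
    incidence-only responsibility to the variants closest to a preliminary
    through-origin fit.
    """
    merged = incidence.merge(progression, on="variant_id", suffixes=("_inc", "_prog"))
    if merged.empty:
        raise ValueError("incidence and progression share no variants")
    assoc = merged[merged["pval_inc"] <= p_incidence_threshold]
    if len(assoc) < 10:
        raise ValueError(
            f"only {len(assoc)} incidence-associated variants at "
            f"p <= {p_incidence_threshold:g}; need >= 10"
        )
    # betas enter unoriented: the slope and both component densities are
    # invariant under a joint sign flip of (b_I, b_P), and orienting all
    # incidence effects positive would break the zero-mean marginal of the
    # incidence-only component
    x = assoc["beta_inc"].to_numpy(float)
    y = assoc["beta_prog"].to_numpy(float)

    # deterministic init (responsibility high near a preliminary
    # through-origin fit) plus seeded random restarts; keep the best
    # log-likelihood so the fit is invariant to initialization
    b0 = float(np.sum(x * y) / np.sum(x**2))
    resid = np.abs(y - b0 * x)
    inits = [np.where(resid <= np.median(resid), 0.9, 0.1)]
    rng = np.random.default_rng(seed if seed is not None else 0)
    inits += [rng.uniform(0.05, 0.95, size=len(x)) for _ in range(n_restarts)]
    best = None
    for gamma0 in inits:
        candidate = _em_slope_mixture(x, y, gamma0, max_iter, tol)
        if best is None or candidate[-1] > best[-1]:
            best = candidate
    b, gamma, pi, tau2, converged, n_iter, ll = best
    if not converged:
        logger.warning("slope-hunter EM did not converge in %d iterations", max_iter)
    fit = SlopeHunterFit(b, gamma, pi, tau2, converged, n_iter, ll)

    adjusted = progression.merge(
        incidence[["variant_id", "beta", "se"]].rename(
            columns={"beta": "beta_inc", "se": "se_inc"}
        ),
        on="variant_id", how="left",
    )
    b_i = adjusted["beta_inc"].fillna(0.0)
    se_i = adjusted["se_inc"].fillna(0.0)
    out = progression.copy()
    out["beta"] = (adjusted["beta"] - b * b_i).to_numpy()
    out["se"] = np.sqrt(adjusted["se"] ** 2 + b**2 * se_i**2).to_numpy()
    z = out["beta"] / out["se"]
    out["pval"] = 2 * stats.norm.sf(np.abs(z))
    out["pval"] = out["pval"].clip(lower=np.finfo(float).tiny)
    return fit, out
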