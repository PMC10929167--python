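"""Univariable two-sample MR estimators.

All estimators consume a :class:`~mrscreen.summary_data.HarmonizedSet`
(aligned per-instrument exposure/outcome effects and SEs) and return an
:class:`MREstimate`.  Six methods are provided:

* Wald ratio — single-instrument building block,
* IVW — inverse-variance-weighted regression through the origin,
* ML — joint normal maximum likelihood over (θ, per-instrument γ),
* MR-Egger — weighted regression with an intercept (directional
  pleiotropy), instruments re-oriented to non-negative exposure effects,
* weighted median — consistent when <50% of weight is on invalid
  instruments; SE by seeded parametric bootstrap,
* weighted mode — kernel-density cluster estimate; SE by bootstrap.

Sign convention: a negative causal estimate against the time-to-toxicity
outcome means the exposure shortens time to the adverse event, i.e. it is
a risk factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from mrscreen.errors import (
    ConvergenceError,
    DegenerateInstrumentError,
    EmptySetError,
    InsufficientInstrumentsError,
    ValidationError,
)
from mrscreen.summary_data import HarmonizedSet

Z95 = 1.959963984540054  # Phi^{-1}(0.975)


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate for one exposure-outcome pair."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int

    def __post_init__(self):
        if not self.ci_low <= self.beta <= self.ci_high:
            raise ValidationError("confidence interval does not bracket the estimate")
        if self.n_snp < 1:
            raise ValidationError("n_snp must be >= 1")


@dataclass(frozen=True)
class EstimatorConfig:
    """Shared estimator settings.

    ivw_mode
        ``fixed`` or ``multiplicative_random``; the latter inflates the
        fixed-effect SE by sqrt(Q/(J-1)) when that exceeds 1.
    n_boot
        Parametric-bootstrap replicates for median/mode SEs.
    mode_bandwidth_factor
        φ multiplier on the Silverman-style bandwidth of the mode method.
    seed
        Single master seed for all estimator randomness.
    """

    ivw_mode: str = "multiplicative_random"
    n_boot: int = 1000
    mode_bandwidth_factor: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.ivw_mode not in ("fixed", "multiplicative_random"):
            raise ValidationError(f"unknown ivw_mode {self.ivw_mode!r}")
        if self.n_boot < 100:
            raise ValidationError("n_boot must be >= 100")
        if self.mode_bandwidth_factor <= 0:
            raise ValidationError("mode_bandwidth_factor must be > 0")


DEFAULT_CONFIG = EstimatorConfig()


def _normal_estimate(method: str, beta: float, se: float, n_snp: int) -> MREstimate:
    z = beta / se if se > 0 else np.inf * np.sign(beta)
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z)))) if se > 0 else 0.0
    return MREstimate(method, float(beta), float(se),
                      float(beta - Z95 * se), float(beta + Z95 * se), p, n_snp)


def wald_ratio(beta_exp: float, se_exp: float, beta_out: float, se_out: float,
               second_order: bool = False) -> MREstimate:
    """Single-instrument ratio estimate beta_out/beta_exp.

    SE by the first-order delta method se_out/|beta_exp|; with
    ``second_order`` the exposure uncertainty term
    beta_out²·se_exp²/beta_exp⁴ is added.
    """
    if beta_exp == 0:
        raise DegenerateInstrumentError("Wald ratio undefined for beta_exp = 0")
    if se_out <= 0 or se_exp <= 0:
        raise ValidationError("SEs must be > 0")
    beta = beta_out / beta_exp
    var = se_out**2 / beta_exp**2
    if second_order:
        var += beta_out**2 * se_exp**2 / beta_exp**4
    return _normal_estimate("wald_ratio", beta, np.sqrt(var), 1)


def _ivw_core(bx, by, sy):
    w = 1.0 / sy**2
    sxx = float(np.sum(w * bx * bx))
    if sxx <= 0:
        raise DegenerateInstrumentError("all exposure effects are zero")
    beta = float(np.sum(w * bx * by)) / sxx
    se_fixed = 1.0 / np.sqrt(sxx)
    q = float(np.sum(w * (by - beta * bx) ** 2))
    return beta, se_fixed, q


def ivw(h: HarmonizedSet, cfg: EstimatorConfig = DEFAULT_CONFIG) -> MREstimate:
    """Inverse-variance-weighted estimate.

    Weighted least squares of outcome effects on exposure effects through
    the origin with weights 1/se_out²; equivalently the precision-weighted
    mean of the Wald ratios.  Fixed-effect SE = (Σ beta_exp²/se_out²)^-1/2;
    in ``multiplicative_random`` mode the SE is inflated by sqrt(Q/(J−1))
    when that factor exceeds 1 (J ≥ 2).
    """
    if h.n_snp < 1:
        raise EmptySetError("IVW needs at least one instrument")
    beta, se, q = _ivw_core(h.beta_exp, h.beta_out, h.se_out)
    if cfg.ivw_mode == "multiplicative_random" and h.n_snp >= 2:
        infl = np.sqrt(q / (h.n_snp - 1))
        if infl > 1.0:
            se *= infl
    return _normal_estimate("ivw", beta, se, h.n_snp)


def maximum_likelihood(
    h: HarmonizedSet, cfg: EstimatorConfig = DEFAULT_CONFIG, max_iter: int = 200
) -> MREstimate:
    """Joint-normal maximum-likelihood estimate.

    Model: beta_exp_j ~ N(γ_j, se_exp_j²), beta_out_j ~ N(θ·γ_j, se_out_j²).
    θ is found by minimizing the profile deviance
    Σ (beta_out − θ·beta_exp)² / (se_out² + θ²·se_exp²) from the IVW start;
    the SE comes from the observed Fisher information of the full (θ, γ)
    model at the optimum (arrowhead inversion).
    """
    if h.n_snp < 2:
        raise InsufficientInstrumentsError("ML needs at least 2 instruments")
    bx, sx, by, sy = h.beta_exp, h.se_exp, h.beta_out, h.se_out

    def profile_dev(theta):
        return float(np.sum((by - theta * bx) ** 2 / (sy**2 + theta**2 * sx**2)))

    start, _, _ = _ivw_core(bx, by, sy)
    span = 1.0 + abs(start)
    res = optimize.minimize_scalar(
        profile_dev,
        bounds=(start - 50 * span, start + 50 * span), method="bounded",
        options={"xatol": 1e-10, "maxiter": max_iter},
    )
    if not res.success:
        raise ConvergenceError("ML profile optimization failed", trace=res)
    theta = float(res.x)
    se = _ml_se(theta, bx, sx, by, sy)
    return _normal_estimate("maximum_likelihood", theta, se, h.n_snp)


def _ml_gamma(theta, bx, sx, by, sy):
    return (bx / sx**2 + theta * by / sy**2) / (1.0 / sx**2 + theta**2 / sy**2)


def _ml_se(theta, bx, sx, by, sy):
    # observed information of the (theta, gamma) model, arrowhead inverse
    g = _ml_gamma(theta, bx, sx, by, sy)
    i_tt = np.sum(g**2 / sy**2)
    i_tg = (2.0 * theta * g - by) / sy**2
    i_gg = 1.0 / sx**2 + theta**2 / sy**2
    denom = i_tt - np.sum(i_tg**2 / i_gg)
    if denom <= 0:
        raise ConvergenceError("non-positive observed information at the ML optimum")
    return float(1.0 / np.sqrt(denom))


def ml_profile_loglik(h: HarmonizedSet, theta: float) -> float:
    """Profile log-likelihood (up to constants) of θ under the ML model."""
    bx, sx, by, sy = h.beta_exp, h.se_exp, h.beta_out, h.se_out
    g = _ml_gamma(theta, bx, sx, by, sy)
    return float(-0.5 * np.sum((bx - g) ** 2 / sx**2 + (by - theta * g) ** 2 / sy**2))


def egger(h: HarmonizedSet, cfg: EstimatorConfig = DEFAULT_CONFIG
          ) -> tuple[MREstimate, dict]:
    """MR-Egger regression: slope (causal) and intercept (pleiotropy) terms.

    Instruments are first oriented so exposure effects are non-negative
    (both betas flipped where needed); then beta_out is regressed on
    beta_exp *with* an intercept, weights 1/se_out².  SEs use the
    residual-variance-scaled covariance; p-values use t with J−2 df.
    Returns (slope estimate, intercept record).
    """
    if h.n_snp < 3:
        raise InsufficientInstrumentsError("MR-Egger needs at least 3 instruments")
    flip = np.where(h.beta_exp < 0, -1.0, 1.0)
    bx, by, sy = h.beta_exp * flip, h.beta_out * flip, h.se_out
    w = 1.0 / sy**2

    sw, swx = np.sum(w), np.sum(w * bx)
    swxx, swy, swxy = np.sum(w * bx * bx), np.sum(w * by), np.sum(w * bx * by)
    det = sw * swxx - swx**2
    if det <= 0:
        raise ValidationError("degenerate Egger design (constant exposure effects)")
    slope = (sw * swxy - swx * swy) / det
    intercept = (swy * swxx - swx * swxy) / det
    resid = by - intercept - slope * bx
    df = h.n_snp - 2
    s2 = float(np.sum(w * resid**2)) / df
    var_slope = s2 * sw / det
    var_int = s2 * swxx / det
    se_slope, se_int = np.sqrt(var_slope), np.sqrt(var_int)

    p_slope = float(min(1.0, 2.0 * stats.t.sf(abs(slope / se_slope), df)))
    p_int = float(min(1.0, 2.0 * stats.t.sf(abs(intercept / se_int), df)))
    tcrit = float(stats.t.ppf(0.975, df))
    slope_est = MREstimate(
        "egger", float(slope), float(se_slope),
        float(slope - tcrit * se_slope), float(slope + tcrit * se_slope),
        p_slope, h.n_snp,
    )
    intercept_rec = {
        "estimate": float(intercept), "se": float(se_int), "pval": p_int, "df": df,
    }
    return slope_est, intercept_rec


def _ratio_weights(bx, by, sy):
    return by / bx, bx**2 / sy**2


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Interpolated weighted median along the last axis (broadcastable)."""
    order = np.argsort(ratios, axis=-1)
    r = np.take_along_axis(ratios, order, axis=-1)
    w = np.take_along_axis(weights, order, axis=-1)
    cum = np.cumsum(w, axis=-1)
    total = cum[..., -1:]
    p = (cum - w / 2.0) / total
    # piecewise-linear inverse CDF at 0.5 per row
    below = p < 0.5
    idx = np.clip(below.sum(axis=-1), 1, r.shape[-1] - 1)
    i0, i1 = idx - 1, idx
    p0 = np.take_along_axis(p, i0[..., None], axis=-1)[..., 0]
    p1 = np.take_along_axis(p, i1[..., None], axis=-1)[..., 0]
    r0 = np.take_along_axis(r, i0[..., None], axis=-1)[..., 0]
    r1 = np.take_along_axis(r, i1[..., None], axis=-1)[..., 0]
    frac = np.where(p1 > p0, (0.5 - p0) / np.where(p1 > p0, p1 - p0, 1.0), 0.0)
    est = r0 + frac * (r1 - r0)
    # clamp to the data range when 0.5 falls outside the interpolation grid
    est = np.where(p[..., 0] >= 0.5, r[..., 0], est)
    est = np.where(p[..., -1] <= 0.5, r[..., -1], est)
    return est


def _boot_draws(h: HarmonizedSet, n_boot: int, seed: int):
    rng = np.random.default_rng(seed)
    bx = rng.normal(h.beta_exp, h.se_exp, size=(n_boot, h.n_snp))
    by = rng.normal(h.beta_out, h.se_out, size=(n_boot, h.n_snp))
    bx = np.where(bx == 0, np.finfo(float).tiny, bx)
    return bx, by


def weighted_median(h: HarmonizedSet, cfg: EstimatorConfig = DEFAULT_CONFIG) -> MREstimate:
    """Weighted-median causal estimate.

    Wald ratios are ordered and the estimate is the linear interpolation
    of the ordered ratios where the standardized cumulative weight
    (S_j − w_j/2)/S_J crosses one half; weights are beta_exp²/se_out².
    The SE is the standard deviation of the estimate over a seeded
    parametric bootstrap of both effect vectors.
    """
    if h.n_snp < 3:
        raise InsufficientInstrumentsError("weighted median needs >= 3 instruments")
    if np.any(h.beta_exp == 0):
        raise DegenerateInstrumentError("zero exposure effect among instruments")
    ratios, weights = _ratio_weights(h.beta_exp, h.beta_out, h.se_out)
    est = float(_weighted_median(ratios, weights))

    bxb, byb = _boot_draws(h, cfg.n_boot, cfg.seed)
    rb, wb = _ratio_weights(bxb, byb, h.se_out)
    boots = _weighted_median(rb, wb)
    se = float(np.std(boots, ddof=1))
    return _normal_estimate("weighted_median", est, se, h.n_snp)


def _mode_bandwidth(ratios: np.ndarray, phi: float) -> np.ndarray:
    """φ · 0.9 · min(sd, IQR/1.34) · J^(−1/5), rowwise over the last axis."""
    sd = np.std(ratios, axis=-1, ddof=1)
    q75, q25 = np.percentile(ratios, [75, 25], axis=-1)
    spread = np.minimum(sd, (q75 - q25) / 1.34)
    return phi * 0.9 * spread * ratios.shape[-1] ** (-0.2)


def _mode_point(ratios: np.ndarray, weights: np.ndarray, phi: float,
                grid_size: int = 512) -> np.ndarray:
    """Argmax of the weighted Gaussian-kernel density, rowwise."""
    ratios = np.atleast_2d(ratios)
    weights = np.atleast_2d(weights)
    h = _mode_bandwidth(ratios, phi)
    out = np.empty(ratios.shape[0])
    degenerate = h <= 0
    out[degenerate] = ratios[degenerate, 0] if degenerate.any() else 0.0
    live = ~degenerate
    if live.any():
        r, w, hh = ratios[live], weights[live], h[live]
        lo = r.min(axis=-1) - 3 * hh
        hi = r.max(axis=-1) + 3 * hh
        grid = lo[:, None] + (hi - lo)[:, None] * np.linspace(0, 1, grid_size)[None, :]
        z = (grid[:, :, None] - r[:, None, :]) / hh[:, None, None]
        dens = np.einsum("ij,ikj->ik", w, np.exp(-0.5 * z * z))
        out[live] = np.take_along_axis(grid, dens.argmax(axis=1)[:, None], axis=1)[:, 0]
    return out


def weighted_mode(h: HarmonizedSet, cfg: EstimatorConfig = DEFAULT_CONFIG) -> MREstimate:
    """Weighted-mode causal estimate (largest cluster of Wald ratios).

    A weighted Gaussian kernel density over the ratio estimates is
    evaluated on a 512-point grid spanning the ratios ± 3 bandwidths; the
    estimate is the density argmax.  Bandwidth is φ·0.9·min(sd, IQR/1.34)
    ·J^(−1/5) on the ratios.  If all ratios coincide (zero bandwidth) the
    common ratio is returned.  SE by seeded parametric bootstrap.
    """
    if h.n_snp < 3:
        raise InsufficientInstrumentsError("weighted mode needs >= 3 instruments")
    if np.any(h.beta_exp == 0):
        raise DegenerateInstrumentError("zero exposure effect among instruments")
    phi = cfg.mode_bandwidth_factor
    ratios, weights = _ratio_weights(h.beta_exp, h.beta_out, h.se_out)
    weights = weights / weights.sum()
    est = float(_mode_point(ratios, weights, phi)[0])

    bxb, byb = _boot_draws(h, cfg.n_boot, cfg.seed + 1)
    rb, wb = _ratio_weights(bxb, byb, h.se_out)
    wb = wb / wb.sum(axis=-1, keepdims=True)
    boots = _mode_point(rb, wb, phi)
    se = float(np.std(boots, ddof=1))
    return _normal_estimate("weighted_mode", est, se, h.n_snp)


ALL_METHODS = {
    "ivw": ivw,
    "maximum_likelihood": maximum_likelihood,
    "weighted_median": weighted_median,
    "weighted_mode": weighted_mode,
}


def estimates_to_frame(estimates, exposure: str, outcome: str):
    """Tidy forest-table rows: exposure, outcome, method, nsnp, beta, se, CI, p."""
    import pandas as pd

    return pd.DataFrame([
        {
            "exposure": exposure, "outcome": outcome, "method": e.method,
            "nsnp": e.n_snp, "beta": e.beta, "se": e.se,
            "ci_low": e.ci_low, "ci_high": e.ci_high, "pval": e.pval,
        }
        for e in estimates
    ])
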