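"""Constrained maximum likelihood with BIC model averaging (cML-MA-BIC).

For a fixed count K of invalid instruments, the joint normal likelihood
of (beta_exp_j, beta_out_j) given (γ_j, θ, r_j) is maximized under the
constraint that at most K pleiotropy terms r_j are nonzero.  Instruments
granted a free r_j contribute nothing to the outcome residual (γ_j =
beta_exp_j, r_j = beta_out_j − θ·beta_exp_j), so the constrained optimum
is found by block-coordinate iteration: select the K instruments with the
largest standardized outcome residuals as invalid, update the valid γ_j
in closed form, update θ by weighted least squares on the valid set, and
repeat to tolerance.  Model averaging weights each K by
exp(−(BIC_K − min BIC)/2) with BIC_K = 2·NLL_K + K·log(n_eff).

This construction is robust to both uncorrelated and correlated
pleiotropy (InSIDE violations), since invalid instruments are removed
from the likelihood rather than modeled through a mean shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from mrscreen.errors import ConvergenceError, InsufficientInstrumentsError, ValidationError
from mrscreen.estimators import Z95, _ivw_core, _ml_se
from mrscreen.summary_data import HarmonizedSet


@dataclass(frozen=True)
class CMLFit:
    """Constrained ML fit for one fixed invalid-instrument count K."""

    K: int
    theta: float
    se: float
    invalid: tuple
    nll: float
    n_iter: int


@dataclass
class CMLResult:
    """Model-averaged cML estimate with the per-K table."""

    theta_ma: float
    se_ma: float
    p_ma: float
    per_k: list
    weights: np.ndarray
    n_eff: float

    @property
    def ci_low(self) -> float:
        return self.theta_ma - Z95 * self.se_ma

    @property
    def ci_high(self) -> float:
        return self.theta_ma + Z95 * self.se_ma

    def per_k_frame(self) -> pd.DataFrame:
        rows = []
        for fit, w in zip(self.per_k, self.weights):
            rows.append({
                "K": fit.K, "theta": fit.theta, "se": fit.se,
                "bic": 2.0 * fit.nll + fit.K * np.log(self.n_eff),
                "weight": w, "invalid": ",".join(map(str, fit.invalid)),
            })
        return pd.DataFrame(rows)


def _profile_terms(bx, sx, by, sy, theta):
    """Per-instrument profile negative log-likelihood contributions.

    Maximizing over γ_j in closed form collapses each instrument's term to
    (beta_out − θ·beta_exp)² / (2·(se_out² + θ²·se_exp²)); an instrument
    granted a free pleiotropy term contributes 0.
    """
    return 0.5 * (by - theta * bx) ** 2 / (sy**2 + theta**2 * sx**2)


def _theta_on_support(bx, sx, by, sy, valid, theta, tol, max_iter):
    """Exact profile-likelihood θ with the invalid set held fixed."""
    from scipy import optimize

    vx, vsx, vy, vsy = bx[valid], sx[valid], by[valid], sy[valid]

    def profile_dev(t):
        return float(np.sum((vy - t * vx) ** 2 / (vsy**2 + t**2 * vsx**2)))

    span = 1.0 + abs(theta)
    res = optimize.minimize_scalar(
        profile_dev, bounds=(theta - 50 * span, theta + 50 * span),
        method="bounded", options={"xatol": min(tol, 1e-9), "maxiter": 500},
    )
    return float(res.x)


def _cml_iterate(bx, sx, by, sy, K, theta0, tol, max_iter):
    """Alternating exact maximization over θ and the invalid-instrument set.

    Given the support, θ is the restricted profile-ML optimum; given θ,
    the optimal size-K invalid set is the K largest profile residuals
    (largest standardized outcome residuals).  Each step is an exact
    block maximization, so the likelihood is monotone and the alternation
    terminates; the best support encountered is returned.
    """
    J = len(bx)
    all_idx = np.arange(J)
    theta = float(theta0)
    terms = _profile_terms(bx, sx, by, sy, theta)
    invalid = np.sort(np.argsort(-terms, kind="stable")[:K])
    best = None
    seen = set()
    for it in range(1, max_iter + 1):
        valid = np.setdiff1d(all_idx, invalid)
        if len(valid) < 2 or np.sum(bx[valid] ** 2) <= 0:
            raise ConvergenceError("degenerate valid set in cML iteration")
        theta = _theta_on_support(bx, sx, by, sy, valid, theta, tol, max_iter)
        nll = float(np.sum(_profile_terms(bx, sx, by, sy, theta)[valid]))
        if best is None or nll < best[0] - 1e-15:
            best = (nll, theta, invalid)
        support = frozenset(invalid.tolist())
        if support in seen:
            break
        seen.add(support)
        if K == 0:
            break
        terms = _profile_terms(bx, sx, by, sy, theta)
        new_invalid = np.sort(np.argsort(-terms, kind="stable")[:K])
        if np.array_equal(new_invalid, invalid):
            break
        invalid = new_invalid
    nll, theta, invalid = best
    valid = np.setdiff1d(all_idx, invalid)
    se = _ml_se(theta, bx[valid], sx[valid], by[valid], sy[valid])
    return CMLFit(K, theta, se, tuple(int(i) for i in invalid), nll, it)


def cml_fixed_k(
    h: HarmonizedSet,
    K: int,
    n_eff: float | None = None,
    tol: float = 1e-7,
    max_iter: int = 200,
    n_restart: int = 5,
    seed: int = 0,
) -> CMLFit:
    """Constrained ML with exactly-K invalid instruments.

    ``n_restart`` seeded random restarts of the θ start are used for
    K > 0 (the invalid-set support problem is combinatorial); the fit
    with the best likelihood is returned.
    """
    J = h.n_snp
    if not 0 <= K <= J - 2:
        raise ValidationError(f"K={K} outside [0, J-2] for J={J}")
    bx, sx, by, sy = h.beta_exp, h.se_exp, h.beta_out, h.se_out
    theta_ivw, _, _ = _ivw_core(bx, by, sy)
    starts = [theta_ivw]
    if K > 0 and n_restart > 1:
        rng = np.random.default_rng(seed)
        scale = 1.0 + abs(theta_ivw)
        starts += list(rng.normal(theta_ivw, scale, size=n_restart - 1))
    best = None
    for s in starts:
        fit = _cml_iterate(bx, sx, by, sy, K, s, tol, max_iter)
        if best is None or fit.nll < best.nll:
            best = fit
    return best


def cml_ma_bic(
    h: HarmonizedSet,
    n_eff: float,
    K_max: int | None = None,
    tol: float = 1e-7,
    max_iter: int = 200,
    n_restart: int = 5,
    seed: int = 0,
) -> CMLResult:
    """BIC-model-averaged cML estimate over K = 0..K_max.

    ``n_eff`` is the sample-size parameter of the BIC penalty; the
    pipeline uses min(exposure n, outcome n) when available.  The
    model-averaged variance combines within-model variance and
    between-model spread: Σ w_K·(se_K² + (θ_K − θ_MA)²).
    """
    J = h.n_snp
    if J < 3:
        raise InsufficientInstrumentsError("cML-MA-BIC needs >= 3 instruments")
    if n_eff <= 1:
        raise ValidationError("n_eff must exceed 1")
    if K_max is None:
        K_max = J - 2
    K_max = min(K_max, J - 2)
    fits = []
    for K in range(K_max + 1):
        try:
            fits.append(cml_fixed_k(h, K, n_eff, tol, max_iter, n_restart, seed + K))
        except ConvergenceError as err:
            raise ConvergenceError(f"cML failed at K={K}: {err}", trace=err.trace) from err
    bic = np.array([2.0 * f.nll + f.K * np.log(n_eff) for f in fits])
    w = np.exp(-(bic - bic.min()) / 2.0)
    w /= w.sum()
    thetas = np.array([f.theta for f in fits])
    ses = np.array([f.se for f in fits])
    theta_ma = float(np.sum(w * thetas))
    se_ma = float(np.sqrt(np.sum(w * (ses**2 + (thetas - theta_ma) ** 2))))
    p_ma = float(min(1.0, 2.0 * stats.norm.sf(abs(theta_ma / se_ma)))) if se_ma > 0 else 0.0
    return CMLResult(theta_ma, se_ma, p_ma, fits, w, float(n_eff))
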