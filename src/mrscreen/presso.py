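"""MR-PRESSO: pleiotropy residual sum of squares and outlier test.

The global test compares the observed weighted residual sum of squares
(RSS), built from leave-one-out IVW predictions, with a parametric null
distribution simulated under the fitted no-pleiotropy model.  Instruments
whose simulated per-residual tail probability survives Bonferroni
correction are flagged as outliers; the distortion test asks whether
removing them changes the IVW estimate more than resampling noise would.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mrscreen.errors import InsufficientInstrumentsError
from mrscreen.estimators import EstimatorConfig, MREstimate, ivw
from mrscreen.summary_data import HarmonizedSet


@dataclass
class PressoResult:
    """Global, outlier, and distortion test results for one pair."""

    exposure_name: str
    outcome_name: str
    global_rss_observed: float
    global_p: float
    outlier_p: np.ndarray          # Bonferroni-adjusted per-instrument p
    outlier_indices: np.ndarray    # indices into the harmonized set
    outlier_snps: list
    distortion_p: float | None
    estimate_before: MREstimate
    estimate_after: MREstimate | None
    n_sim: int
    seed: int
    audit: dict = field(default_factory=dict)

    @property
    def n_outliers(self) -> int:
        return len(self.outlier_indices)

    def to_row(self) -> dict:
        return {
            "exposure": self.exposure_name, "outcome": self.outcome_name,
            "rss": self.global_rss_observed, "global_p": self.global_p,
            "n_outliers": self.n_outliers, "distortion_p": self.distortion_p,
        }


def _loo_ivw_theta(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW estimates, vectorized over the last axis."""
    sxy = np.sum(w * bx * by, axis=-1, keepdims=True)
    sxx = np.sum(w * bx * bx, axis=-1, keepdims=True)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def _weighted_rss(bx, by, w):
    theta_loo = _loo_ivw_theta(bx, by, w)
    resid2 = w * (by - theta_loo * bx) ** 2
    return resid2, resid2.sum(axis=-1)


def run_presso(
    h: HarmonizedSet,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int = 0,
    cfg: EstimatorConfig | None = None,
) -> PressoResult:
    """Run the global, outlier, and distortion tests.

    Requires at least 4 instruments (leave-one-out IVW on 3+ remaining).
    ``global_p`` has resolution 1/(n_sim+1) and is never reported as 0.
    The outlier-corrected IVW (``estimate_after``) is reported only when
    outliers are found; the headline estimate is left to the caller.
    """
    if h.n_snp < 4:
        raise InsufficientInstrumentsError(
            f"MR-PRESSO needs >= 4 instruments, got {h.n_snp}"
        )
    cfg = cfg or EstimatorConfig(seed=seed)
    rng = np.random.default_rng(seed)
    bx, by = h.beta_exp, h.beta_out
    sx, sy = h.se_exp, h.se_out
    J = h.n_snp
    w = 1.0 / sy**2

    obs_resid2, obs_rss = _weighted_rss(bx, by, w)
    obs_rss = float(obs_rss)

    # parametric null centered at the LOO no-pleiotropy fit
    theta_loo = _loo_ivw_theta(bx, by, w)
    bx_sim = rng.normal(bx, sx, size=(n_sim, J))
    by_sim = rng.normal(theta_loo * bx, sy, size=(n_sim, J))
    sim_resid2, sim_rss = _weighted_rss(bx_sim, by_sim, w)

    global_p = float((1 + np.sum(sim_rss >= obs_rss)) / (n_sim + 1))

    # per-instrument outlier p: upper tail of each simulated residual distribution
    p_raw = (1 + np.sum(sim_resid2 >= obs_resid2[None, :], axis=0)) / (n_sim + 1)
    p_adj = np.minimum(1.0, p_raw * J)
    outliers = np.flatnonzero(p_adj < outlier_alpha)

    before = ivw(h, cfg)
    after = None
    distortion_p = None
    if len(outliers) > 0 and len(outliers) < J - 1:
        keep = np.setdiff1d(np.arange(J), outliers)
        after = ivw(h.subset(keep), cfg)
        distortion_p = _distortion_test(
            bx, by, w, keep, outliers, before.beta, after.beta, n_sim, rng
        )

    return PressoResult(
        h.exposure_name, h.outcome_name, obs_rss, global_p,
        p_adj, outliers, [h.snp[i] for i in outliers],
        distortion_p, before, after, n_sim, seed,
    )


def _ivw_beta(bx, by, w):
    return np.sum(w * bx * by, axis=-1) / np.sum(w * bx * bx, axis=-1)


def _distortion_test(bx, by, w, keep, outliers, beta_before, beta_after,
                     n_sim, rng) -> float:
    """Two-sided test of the observed distortion against a resampling null.

    For each replicate, a pseudo 'outlier' block of the observed size is
    drawn with replacement from the non-outlier instruments; the null
    distortion is the relative change in IVW when that block is appended.
    """
    obs_d = (beta_before - beta_after) / abs(beta_after) if beta_after != 0 else np.inf
    n_out = len(outliers)
    draws = rng.integers(0, len(keep), size=(n_sim, n_out))
    idx = keep[draws]
    bx_blk, by_blk, w_blk = bx[idx], by[idx], w[idx]
    sxy = np.sum(w[keep] * bx[keep] * by[keep]) + np.sum(w_blk * bx_blk * by_blk, axis=-1)
    sxx = np.sum(w[keep] * bx[keep] * bx[keep]) + np.sum(w_blk * bx_blk * bx_blk, axis=-1)
    beta_with = sxy / sxx
    null_d = (beta_with - beta_after) / abs(beta_after) if beta_after != 0 else beta_with
    return float((1 + np.sum(np.abs(null_d) >= abs(obs_d))) / (n_sim + 1))


def presso_to_frame(results) -> pd.DataFrame:
    """Tidy rows (exposure, outcome, rss, global_p, n_outliers, distortion_p)."""
    return pd.DataFrame([r.to_row() for r in results])
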