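"""Multivariable MR: joint direct effects of several exposures.

Outcome effects are regressed on the instrument-by-exposure effect
matrix without an intercept, weights 1/se_out² — each coefficient is an
exposure's direct effect holding the other modeled exposures fixed.
Instrument selection pools every exposure's instruments, clumps jointly
on the best p-value across exposures, and harmonizes all tables to a
single allele coding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from mrscreen.errors import (
    CollinearityError,
    InsufficientInstrumentsError,
    ValidationError,
)
from mrscreen.estimators import MREstimate, _normal_estimate
from mrscreen.instruments import LDReference, clump, select_by_pvalue
from mrscreen.summary_data import is_palindromic


@dataclass
class MVHarmonizedSet:
    """Aligned effects of k exposures and one outcome over shared instruments."""

    outcome_name: str
    exposure_names: list
    snp: np.ndarray
    beta_exp: np.ndarray   # (J, k)
    se_exp: np.ndarray     # (J, k)
    beta_out: np.ndarray   # (J,)
    se_out: np.ndarray     # (J,)
    provenance: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)

    def __post_init__(self):
        self.beta_exp = np.atleast_2d(np.asarray(self.beta_exp, dtype=float))
        self.se_exp = np.atleast_2d(np.asarray(self.se_exp, dtype=float))
        J, k = self.beta_exp.shape
        if k != len(self.exposure_names):
            raise ValidationError("exposure-effect matrix width != exposure count")
        if not (len(self.snp) == J == len(self.beta_out) == len(self.se_out)):
            raise ValidationError("instrument dimensions inconsistent")
        if np.isnan(self.beta_exp).any():
            raise ValidationError("exposure-effect matrix must be complete")
        if k >= J:
            raise ValidationError("need more instruments than exposures")

    @property
    def n_snp(self) -> int:
        return len(self.snp)

    @property
    def k(self) -> int:
        return len(self.exposure_names)


def build_mv_set(
    exposures: Mapping[str, pd.DataFrame],
    outcome: pd.DataFrame,
    ld: LDReference | None = None,
    iv_pvalue: float = 1e-5,
    clump_r2: float = 0.001,
    clump_window: float = 10_000_000,
    drop_palindromic: bool = True,
    outcome_name: str = "outcome",
) -> MVHarmonizedSet:
    """Select and harmonize the joint instrument set for multivariable MR.

    Instruments are the union of each exposure's p-screened variants,
    clumped jointly on each variant's best p across exposures; every
    retained instrument must carry an effect in *every* exposure table
    (rows missing any exposure are dropped and logged in provenance) and
    in the outcome.  All effects are aligned to the allele coding of the
    exposure listing that variant with the best p.
    """
    if len(exposures) < 2:
        raise ValidationError("multivariable MR needs >= 2 exposures")
    names = list(exposures)

    # union of screened instruments with best-p annotation and reference coding
    candidates: dict[str, dict] = {}
    for name, df in exposures.items():
        for rec in select_by_pvalue(df, iv_pvalue).itertuples(index=False):
            cur = candidates.get(str(rec.snp))
            if cur is None or rec.pval < cur["pval"]:
                candidates[str(rec.snp)] = {
                    "snp": str(rec.snp), "chrom": rec.chrom, "pos": rec.pos,
                    "effect_allele": rec.effect_allele.upper(),
                    "other_allele": rec.other_allele.upper(),
                    "pval": rec.pval, "source": name,
                }
    pooled = pd.DataFrame(candidates.values())
    if pooled.empty:
        raise InsufficientInstrumentsError("no instruments pass the p-value screen")
    if ld is not None:
        pooled = clump(pooled, ld, clump_r2, clump_window)

    index = {
        name: {str(r.snp): r for r in df.itertuples(index=False)}
        for name, df in exposures.items()
    }
    out_index = {str(r.snp): r for r in outcome.itertuples(index=False)}

    rows, prov = [], []
    for rec in pooled.itertuples(index=False):
        snp, ea, oa = rec.snp, rec.effect_allele, rec.other_allele
        if drop_palindromic and is_palindromic(ea, oa):
            prov.append({"snp": snp, "status": "removed_palindromic"})
            continue
        out_rec = out_index.get(snp)
        if out_rec is None:
            prov.append({"snp": snp, "status": "removed_missing_in_outcome"})
            continue
        aligned = _align(out_rec, ea, oa)
        if aligned is None:
            prov.append({"snp": snp, "status": "removed_mismatch_outcome"})
            continue
        by, sy = aligned
        bx_row, sx_row, ok = [], [], True
        for name in names:
            x_rec = index[name].get(snp)
            if x_rec is None:
                ok = False
                prov.append({"snp": snp, "status": f"removed_missing_in_{name}"})
                break
            ax = _align(x_rec, ea, oa)
            if ax is None:
                ok = False
                prov.append({"snp": snp, "status": f"removed_mismatch_{name}"})
                break
            bx_row.append(ax[0])
            sx_row.append(ax[1])
        if not ok:
            continue
        rows.append((snp, bx_row, sx_row, by, sy))
        prov.append({"snp": snp, "status": "kept", "coding_source": rec.source})

    k = len(names)
    if len(rows) < k + 2:
        raise InsufficientInstrumentsError(
            f"only {len(rows)} joint instruments survive for {k} exposures "
            f"(need >= {k + 2})"
        )
    snp_ids = np.array([r[0] for r in rows], dtype=object)
    bx = np.array([r[1] for r in rows], dtype=float)
    sx = np.array([r[2] for r in rows], dtype=float)
    by = np.array([r[3] for r in rows], dtype=float)
    sy = np.array([r[4] for r in rows], dtype=float)
    return MVHarmonizedSet(outcome_name, names, snp_ids, bx, sx, by, sy,
                           pd.DataFrame(prov))


def _align(rec, ea: str, oa: str):
    """Return (beta, se) of ``rec`` aligned to the (ea, oa) coding, or None."""
    r_ea = str(rec.effect_allele).upper()
    r_oa = str(rec.other_allele).upper()
    if (r_ea, r_oa) == (ea, oa):
        return float(rec.beta), float(rec.se)
    if (r_ea, r_oa) == (oa, ea):
        return -float(rec.beta), float(rec.se)
    return None


def mvmr_ivw(mv: MVHarmonizedSet) -> list[MREstimate]:
    """Multivariable IVW: weighted LS of outcome effects on the exposure matrix.

    No intercept; weights 1/se_out²; per-coefficient SEs from the
    unscaled weighted-regression covariance (fixed-effect), normal CIs
    and p-values.  Raises on a rank-deficient design, naming the
    collinear exposures.
    """
    J, k = mv.beta_exp.shape
    if J <= k + 1:
        raise InsufficientInstrumentsError(
            f"multivariable IVW needs more than {k + 1} instruments, got {J}"
        )
    w = 1.0 / mv.se_out**2
    X = mv.beta_exp
    y = mv.beta_out
    xtwx = X.T @ (w[:, None] * X)
    rank = np.linalg.matrix_rank(xtwx, tol=1e-10 * np.abs(xtwx).max())
    if rank < k:
        corr = np.corrcoef(X.T)
        pairs = [
            (mv.exposure_names[i], mv.exposure_names[j])
            for i in range(k) for j in range(i + 1, k)
            if abs(corr[i, j]) > 1 - 1e-8
        ]
        offenders = sorted({n for p in pairs for n in p}) or list(mv.exposure_names)
        raise CollinearityError(
            f"rank-deficient multivariable design; collinear exposures: {offenders}",
            exposures=offenders,
        )
    cov = np.linalg.inv(xtwx)
    beta = cov @ (X.T @ (w * y))
    ses = np.sqrt(np.diag(cov))
    return [
        _normal_estimate(f"mvmr_ivw[{name}]", float(b), float(s), J)
        for name, b, s in zip(mv.exposure_names, beta, ses)
    ]


def conditional_f(mv: MVHarmonizedSet) -> pd.DataFrame:
    """Heuristic conditional instrument strength per exposure.

    Each exposure's effects are regressed (weights 1/se_out²) on the
    other exposures' effects; the conditional F is the mean squared
    residual standardized by that exposure's SEs.  Reported as a
    diagnostic only — no automatic exclusion.
    """
    J, k = mv.beta_exp.shape
    w = 1.0 / mv.se_out**2
    rows = []
    for i in range(k):
        xi = mv.beta_exp[:, i]
        if k == 1:
            resid = xi
        else:
            others = np.delete(mv.beta_exp, i, axis=1)
            coef, *_ = np.linalg.lstsq(
                np.sqrt(w)[:, None] * others, np.sqrt(w) * xi, rcond=None
            )
            resid = xi - others @ coef
        f_cond = float(np.mean((resid / mv.se_exp[:, i]) ** 2))
        rows.append({"exposure": mv.exposure_names[i], "conditional_f": f_cond})
    return pd.DataFrame(rows)


def mvmr_to_frame(mv: MVHarmonizedSet, estimates: Sequence[MREstimate]) -> pd.DataFrame:
    """Tidy rows: outcome, exposure, beta, ci_low, ci_high, pval."""
    return pd.DataFrame([
        {
            "outcome": mv.outcome_name, "exposure": name,
            "beta": e.beta, "se": e.se,
            "ci_low": e.ci_low, "ci_high": e.ci_high, "pval": e.pval,
            "nsnp": e.n_snp,
        }
        for name, e in zip(mv.exposure_names, estimates)
    ])
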