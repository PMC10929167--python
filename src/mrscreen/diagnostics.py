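"""Heterogeneity, pleiotropy, leave-one-out, and confounder-annotation checks.

Cochran's Q quantifies dispersion of the per-instrument Wald ratios
around the fixed-effect IVW center (chi-square with J−1 df); the
MR-Egger intercept tests directional pleiotropy; leave-one-out flags
reliance on single instruments; the confounder screen is a user-supplied
variant→trait annotation join (no network lookups), mirroring a manual
PhenoScanner-style review — hits are flagged, never auto-excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from mrscreen.errors import InsufficientInstrumentsError
from mrscreen.estimators import DEFAULT_CONFIG, EstimatorConfig, egger, ivw
from mrscreen.summary_data import HarmonizedSet


@dataclass
class DiagnosticsReport:
    """Heterogeneity/pleiotropy/LOO summary for one exposure-outcome pair."""

    exposure_name: str
    outcome_name: str
    Q: float
    df: int
    p_Q: float
    egger_intercept: float
    intercept_se: float
    intercept_p: float
    loo: pd.DataFrame
    annotation_hits: pd.DataFrame | None = None

    def to_row(self) -> dict:
        return {
            "exposure": self.exposure_name, "outcome": self.outcome_name,
            "Q": self.Q, "df": self.df, "p_Q": self.p_Q,
            "egger_intercept": self.egger_intercept,
            "intercept_se": self.intercept_se, "intercept_p": self.intercept_p,
        }


def cochran_q(h: HarmonizedSet) -> tuple[float, int, float]:
    """Cochran's Q = Σ w_j (θ_j − θ_IVW)² with w_j = beta_exp²/se_out².

    θ_j are the Wald ratios and θ_IVW the fixed-effect center; p from
    chi-square with J−1 df.
    """
    if h.n_snp < 2:
        raise InsufficientInstrumentsError("Cochran's Q needs >= 2 instruments")
    w = h.beta_exp**2 / h.se_out**2
    ratios = h.beta_out / h.beta_exp
    center = float(np.sum(w * ratios) / np.sum(w))
    Q = float(np.sum(w * (ratios - center) ** 2))
    df = h.n_snp - 1
    p = float(stats.chi2.sf(Q, df))
    return Q, df, p


def leave_one_out(h: HarmonizedSet, cfg: EstimatorConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """IVW re-estimates dropping one instrument at a time.

    Returns J rows labeled by the dropped variant, each carrying the IVW
    estimate on the remaining J−1 instruments.
    """
    if h.n_snp < 2:
        raise InsufficientInstrumentsError("leave-one-out needs >= 2 instruments")
    rows = []
    for j in range(h.n_snp):
        keep = np.arange(h.n_snp) != j
        est = ivw(h.subset(keep), cfg)
        rows.append({
            "dropped_snp": h.snp[j], "beta": est.beta, "se": est.se,
            "ci_low": est.ci_low, "ci_high": est.ci_high,
            "pval": est.pval, "nsnp": est.n_snp,
        })
    return pd.DataFrame(rows)


def annotate_confounders(
    instruments: pd.DataFrame, trait_table: pd.DataFrame
) -> pd.DataFrame:
    """Left-join instruments against a variant→trait annotation table.

    ``trait_table`` needs columns ``snp`` and ``trait``.  Instruments
    with one or more matched traits are flagged for analyst review; the
    join never removes instruments.
    """
    if trait_table is None or trait_table.empty:
        return pd.DataFrame(columns=["snp", "trait"])
    hits = instruments[["snp"]].merge(
        trait_table[["snp", "trait"]], on="snp", how="inner"
    )
    return hits.reset_index(drop=True)


def rerun_excluding(
    h: HarmonizedSet, snp_ids, cfg: EstimatorConfig = DEFAULT_CONFIG
):
    """Re-run IVW with the named instruments excluded (the flagged-SNP check)."""
    drop = set(np.atleast_1d(snp_ids).tolist())
    keep = np.array([s not in drop for s in h.snp])
    return ivw(h.subset(keep), cfg)


def diagnostics_report(
    h: HarmonizedSet,
    cfg: EstimatorConfig = DEFAULT_CONFIG,
    trait_table: pd.DataFrame | None = None,
    instruments: pd.DataFrame | None = None,
) -> DiagnosticsReport:
    """Assemble the heterogeneity/pleiotropy/LOO report for one pair."""
    Q, df, p_Q = cochran_q(h)
    _, intercept = egger(h, cfg)
    loo = leave_one_out(h, cfg)
    hits = None
    if trait_table is not None:
        inst = instruments if instruments is not None else pd.DataFrame({"snp": h.snp})
        hits = annotate_confounders(inst, trait_table)
    return DiagnosticsReport(
        h.exposure_name, h.outcome_name, Q, df, p_Q,
        intercept["estimate"], intercept["se"], intercept["pval"], loo, hits,
    )
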