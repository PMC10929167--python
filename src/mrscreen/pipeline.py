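"""Orchestration: forward screen, sensitivity battery, reverse MR, reports.

The forward screen runs every exposure through instrument selection
(p < 1e-5, LD clumping at r² < 0.001 within 10 Mb), harmonization to the
outcome, the post-harmonization F > 10 / ≥3-instrument filter, then IVW
and MR-PRESSO as the primary analysis.  Pairs with IVW p < 0.05 are
flagged suggestive; pairs additionally passing the MR-PRESSO global test
threshold enter the sensitivity battery (ML, Egger, weighted median,
weighted mode, cML-MA-BIC, Cochran's Q, leave-one-out).  The
family-wise threshold is Bonferroni 0.05/m with m the number of
exposure-outcome pairs actually analyzed, recomputed per run.  Reverse
MR reuses the identical machinery with trait roles swapped.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from mrscreen.cml import cml_ma_bic
from mrscreen.diagnostics import diagnostics_report
from mrscreen.errors import (
    EmptySetError,
    InsufficientInstrumentsError,
    MRScreenError,
)
from mrscreen.estimators import (
    EstimatorConfig,
    egger,
    estimates_to_frame,
    ivw,
    maximum_likelihood,
    weighted_median,
    weighted_mode,
)
from mrscreen.instruments import (
    InstrumentSet,
    LDReference,
    f_statistic,
    select_by_pvalue,
    clump,
)
from mrscreen.presso import run_presso
from mrscreen.summary_data import HarmonizedSet, harmonize


@dataclass(frozen=True)
class ScreenConfig:
    """All thresholds of the screening pipeline, with study defaults."""

    iv_pvalue: float = 1e-5
    clump_r2: float = 0.001
    clump_window: float = 10_000_000
    proxy_r2: float = 0.8
    min_snps: int = 3
    f_min: float = 10.0
    alpha: float = 0.05
    drop_palindromic: bool = True
    presso_n_sim: int = 1000
    presso_min_snps: int = 4
    run_sensitivity: bool = True
    ivw_mode: str = "multiplicative_random"
    n_boot: int = 1000
    cml_n_restart: int = 5
    cml_k_max: int | None = None
    n_eff: float | None = None   # default: min(exposure n, outcome n) from tables
    seed: int = 0

    def estimator_config(self, seed: int) -> EstimatorConfig:
        return EstimatorConfig(ivw_mode=self.ivw_mode, n_boot=self.n_boot, seed=seed)


@dataclass
class ScreenResult:
    """Per-pair estimates, diagnostics, PRESSO results, and significance flags."""

    estimates: pd.DataFrame
    flags: pd.DataFrame
    diagnostics: pd.DataFrame
    presso: pd.DataFrame
    loo: dict = field(repr=False, default_factory=dict)
    harmonized: dict = field(repr=False, default_factory=dict)
    dropped: pd.DataFrame = field(default_factory=pd.DataFrame)
    metadata: dict = field(default_factory=dict)

    @property
    def m_tested(self) -> int:
        return self.metadata["m_tested"]

    @property
    def bonferroni_threshold(self) -> float:
        return self.metadata["bonferroni_threshold"]

    def scatter_data(self) -> pd.DataFrame:
        """Plot-ready per-instrument effects for scatter figures."""
        rows = []
        for (exp, out), h in self.harmonized.items():
            for j in range(h.n_snp):
                rows.append({
                    "exposure": exp, "outcome": out, "snp": h.snp[j],
                    "beta_exp": h.beta_exp[j], "se_exp": h.se_exp[j],
                    "beta_out": h.beta_out[j], "se_out": h.se_out[j],
                })
        return pd.DataFrame(rows)


def _pair_seed(master: int, exposure: str, outcome: str) -> int:
    tag = zlib.crc32(f"{exposure}|{outcome}".encode())
    return int((master * 1_000_003 + tag) % (2**31 - 1))


def _prepare_pair(
    exposure_name: str,
    exposure: pd.DataFrame,
    outcome_name: str,
    outcome: pd.DataFrame,
    ld: LDReference,
    cfg: ScreenConfig,
    proxy_map: pd.DataFrame | None,
) -> tuple[HarmonizedSet | None, str]:
    """Instrument selection + harmonization + strength filter for one pair."""
    selected = select_by_pvalue(exposure, cfg.iv_pvalue)
    if selected.empty:
        return None, "no instruments pass the p-value screen"
    selected = clump(selected, ld, cfg.clump_r2, cfg.clump_window)
    try:
        h = harmonize(
            selected, outcome, proxy_map=proxy_map,
            drop_palindromic=cfg.drop_palindromic, proxy_r2_min=cfg.proxy_r2,
            exposure_name=exposure_name, outcome_name=outcome_name,
        )
    except EmptySetError:
        return None, "no instruments survive harmonization"
    # instrument strength screened after harmonization so reported
    # instruments match analysis instruments
    f = f_statistic(h.beta_exp, h.se_exp)
    strong = f > cfg.f_min
    if int(strong.sum()) < cfg.min_snps:
        return None, (
            f"fewer than {cfg.min_snps} instruments with F > {cfg.f_min:g} "
            f"after harmonization ({int(strong.sum())} remain)"
        )
    return h.subset(strong), ""


def _screen_pairs(
    pairs: list,
    ld: LDReference | None,
    cfg: ScreenConfig,
    proxy_map: pd.DataFrame | None = None,
) -> ScreenResult:
    ld = ld or LDReference()
    est_frames, flag_rows, diag_rows, presso_rows = [], [], [], []
    loo_tables, harmonized = {}, {}
    dropped = []

    analyzed = []
    for exposure_name, exposure, outcome_name, outcome in pairs:
        h, reason = _prepare_pair(
            exposure_name, exposure, outcome_name, outcome, ld, cfg, proxy_map
        )
        if h is None:
            dropped.append({
                "exposure": exposure_name, "outcome": outcome_name, "reason": reason,
            })
            continue
        analyzed.append(h)

    if not analyzed:
        raise EmptySetError("screen is empty: every exposure was filtered out")

    m = len(analyzed)
    bonf = cfg.alpha / m

    for h in analyzed:
        key = (h.exposure_name, h.outcome_name)
        seed = _pair_seed(cfg.seed, *key)
        ecfg = cfg.estimator_config(seed)
        harmonized[key] = h

        primary = [ivw(h, ecfg)]
        presso_res = None
        if cfg.presso_n_sim > 0 and h.n_snp >= cfg.presso_min_snps:
            presso_res = run_presso(
                h, n_sim=cfg.presso_n_sim, outlier_alpha=cfg.alpha,
                seed=seed, cfg=ecfg,
            )
            presso_rows.append(presso_res.to_row())
            if presso_res.estimate_after is not None:
                from dataclasses import replace

                primary.append(
                    replace(presso_res.estimate_after, method="ivw_outlier_corrected")
                )

        ivw_p = primary[0].pval
        # dual gate: IVW p < alpha AND the MR-PRESSO causal estimate
        # (outlier-corrected when outliers were found) p < alpha; IVW-only
        # fallback when PRESSO is undefined at small J
        if presso_res is not None:
            presso_est = presso_res.estimate_after or presso_res.estimate_before
            suggestive = ivw_p < cfg.alpha and presso_est.pval < cfg.alpha
            presso_p = presso_est.pval
            gate_note = ""
        else:
            suggestive = ivw_p < cfg.alpha
            presso_p = np.nan
            gate_note = "presso unavailable (J < 4); IVW-only gate"
        flag_rows.append({
            "exposure": key[0], "outcome": key[1], "nsnp": h.n_snp,
            "ivw_pval": ivw_p,
            "presso_pval": presso_p,
            "presso_global_p": presso_res.global_p if presso_res else np.nan,
            "suggestive": suggestive,
            "sensitivity_eligible": suggestive,
            "bonferroni": ivw_p < bonf,
            "note": gate_note,
        })
        eligible = suggestive

        estimates = list(primary)
        if cfg.run_sensitivity and eligible:
            try:
                estimates.append(maximum_likelihood(h, ecfg))
            except MRScreenError:
                pass
            if h.n_snp >= 3:
                slope, _ = egger(h, ecfg)
                estimates.append(slope)
                estimates.append(weighted_median(h, ecfg))
                estimates.append(weighted_mode(h, ecfg))
                diag = diagnostics_report(h, ecfg)
                diag_rows.append(diag.to_row())
                loo_tables[key] = diag.loo
                # BIC sample size: min(exposure n, outcome n) resolved by the
                # callers; documented fallback when tables carry no n
                n_eff = cfg.n_eff if cfg.n_eff else 1000.0
                cml = cml_ma_bic(
                    h, n_eff, K_max=cfg.cml_k_max,
                    n_restart=cfg.cml_n_restart, seed=seed,
                )
                from mrscreen.estimators import _normal_estimate

                estimates.append(
                    _normal_estimate("cml_ma_bic", cml.theta_ma, cml.se_ma, h.n_snp)
                )
        est_frames.append(estimates_to_frame(estimates, *key))

    estimates = pd.concat(est_frames, ignore_index=True).sort_values(
        ["exposure", "outcome", "method"], kind="mergesort"
    ).reset_index(drop=True)
    flags = pd.DataFrame(flag_rows).sort_values(
        ["exposure", "outcome"], kind="mergesort"
    ).reset_index(drop=True)
    diagnostics = pd.DataFrame(
        diag_rows, columns=["exposure", "outcome", "Q", "df", "p_Q",
                            "egger_intercept", "intercept_se", "intercept_p"],
    )
    presso = pd.DataFrame(
        presso_rows, columns=["exposure", "outcome", "rss", "global_p",
                              "n_outliers", "distortion_p"],
    )
    metadata = {
        "m_tested": m,
        "bonferroni_threshold": bonf,
        "config": asdict(cfg),
        "seed": cfg.seed,
    }
    return ScreenResult(
        estimates, flags, diagnostics, presso, loo_tables, harmonized,
        pd.DataFrame(dropped, columns=["exposure", "outcome", "reason"]), metadata,
    )


def _table_n_eff(exposure: pd.DataFrame, outcome: pd.DataFrame) -> float | None:
    ns = []
    for df in (exposure, outcome):
        if "n" in df.columns and df["n"].notna().any():
            ns.append(float(df["n"].dropna().median()))
    return min(ns) if ns else None


def run_forward_screen(
    exposures: Mapping[str, pd.DataFrame],
    outcome: pd.DataFrame,
    ld: LDReference | None = None,
    cfg: ScreenConfig = ScreenConfig(),
    outcome_name: str = "outcome",
    proxy_map: pd.DataFrame | None = None,
) -> ScreenResult:
    """Screen many exposures against one outcome (the forward direction)."""
    if not exposures:
        raise EmptySetError("no exposures supplied")
    if cfg.n_eff is None:
        first = next(iter(exposures.values()))
        n_eff = _table_n_eff(first, outcome)
        if n_eff is not None:
            cfg = ScreenConfig(**{**asdict(cfg), "n_eff": n_eff})
    pairs = [
        (name, exposures[name], outcome_name, outcome)
        for name in sorted(exposures)
    ]
    return _screen_pairs(pairs, ld, cfg, proxy_map)


def run_reverse_mr(
    outcome_as_exposure: pd.DataFrame,
    taxa_as_outcomes: Mapping[str, pd.DataFrame],
    ld: LDReference | None = None,
    cfg: ScreenConfig = ScreenConfig(),
    exposure_name: str = "irAE",
    proxy_map: pd.DataFrame | None = None,
) -> ScreenResult:
    """Reverse MR: the toxicity phenotype as exposure, taxa as outcomes."""
    if not taxa_as_outcomes:
        raise EmptySetError("no reverse outcomes supplied")
    if cfg.n_eff is None:
        first = next(iter(taxa_as_outcomes.values()))
        n_eff = _table_n_eff(outcome_as_exposure, first)
        if n_eff is not None:
            cfg = ScreenConfig(**{**asdict(cfg), "n_eff": n_eff})
    pairs = [
        (exposure_name, outcome_as_exposure, name, taxa_as_outcomes[name])
        for name in sorted(taxa_as_outcomes)
    ]
    return _screen_pairs(pairs, ld, cfg, proxy_map)
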