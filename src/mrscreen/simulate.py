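"""Synthetic paired GWAS summary statistics with known causal truth.

The generator emulates the statistical structure of a microbiota-to-
immunotherapy-toxicity MR study: many weakly-instrumented exposure taxa
from a large consortium GWAS (default n_X = 18,340) against a small
time-to-event outcome GWAS (default n_Y = 1,751).  Per instrument with
minor-allele frequency p, SEs follow the standardized-trait
approximation se = 1/sqrt(2·p·(1−p)·n); true instrument effects γ_j are
drawn so that instrument strength F = (γ/se)² falls in the range
observed for such consortium instruments (default 17–37, median ≈ 22),
which automatically places instrument p-values beyond the suggestive
1e-5 screen.  Observed effects add sampling noise:

    beta_exp_j ~ N(γ_j, se_X²),
    beta_out_j ~ N(θ·γ_j + r_j, se_Y²),

where θ is the taxon's causal effect on time-to-toxicity (negative =
shorter time = higher risk) and r_j is a horizontal-pleiotropy term,
nonzero for a configurable fraction of instruments and drawn balanced
(zero-mean), directional (one-signed), or correlated with γ_j (InSIDE
violation).  LD blocks, palindromic allele pairs, and allele-swapped
outcome records are emitted to exercise clumping and harmonization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from mrscreen.errors import ValidationError
from mrscreen.instruments import LDReference

_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_NONPALINDROMIC = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]


@dataclass(frozen=True)
class SimConfig:
    """Generating conditions for one synthetic exposure/outcome panel.

    Defaults mirror the real study's scale: 132 taxa, ~7 instruments
    each, exposure GWAS of 18,340 and outcome GWAS of 1,751 samples,
    instrument F statistics in [17, 37].
    """

    n_taxa: int = 132
    instruments_per_taxon: int = 7
    theta: float | Sequence[float] | Mapping[str, float] = 0.0
    pleiotropy_fraction: float = 0.0
    pleiotropy_scale: float = 0.15
    pleiotropy_type: str = "balanced"   # balanced | directional | correlated
    pleiotropy_rho: float = 2.0         # slope of r on γ for correlated type
    n_x: int = 18_340
    n_y: int = 1_751
    maf_range: tuple = (0.05, 0.5)
    f_range: tuple = (17.0, 37.0)
    ld_block_size: int = 1
    ld_block_r2: float = 0.8
    palindromic_fraction: float = 0.0
    swapped_fraction: float = 0.0
    taxa_names: tuple | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 1:
            raise ValidationError("n_taxa must be >= 1")
        if self.instruments_per_taxon < 1:
            raise ValidationError("instruments_per_taxon must be >= 1")
        if not 0.0 <= self.pleiotropy_fraction <= 1.0:
            raise ValidationError("pleiotropy_fraction outside [0, 1]")
        if self.pleiotropy_type not in ("balanced", "directional", "correlated"):
            raise ValidationError(f"unknown pleiotropy_type {self.pleiotropy_type!r}")
        if self.n_x < 100 or self.n_y < 100:
            raise ValidationError("sample sizes must be >= 100")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValidationError("MAF range must lie in (0, 0.5]")
        if self.ld_block_size < 1:
            raise ValidationError("ld_block_size must be >= 1")
        if self.taxa_names is not None and len(self.taxa_names) != self.n_taxa:
            raise ValidationError("taxa_names length != n_taxa")

    def names(self) -> list:
        if self.taxa_names is not None:
            if len(self.taxa_names) != self.n_taxa:
                raise ValidationError("taxa_names length != n_taxa")
            return list(self.taxa_names)
        width = len(str(self.n_taxa))
        return [f"taxon_{i + 1:0{width}d}" for i in range(self.n_taxa)]

    def theta_by_taxon(self) -> dict:
        names = self.names()
        if isinstance(self.theta, Mapping):
            return {n: float(self.theta.get(n, 0.0)) for n in names}
        if np.isscalar(self.theta):
            return {n: float(self.theta) for n in names}
        values = list(self.theta)
        if len(values) != self.n_taxa:
            raise ValidationError("theta sequence length != n_taxa")
        return dict(zip(names, map(float, values)))


@dataclass
class SimTruth:
    """Generating parameters behind a synthetic panel, for recovery tests."""

    theta: dict
    instruments: pd.DataFrame = field(repr=False)  # taxon, snp, gamma, pleiotropy, outlier
    seed: int = 0

    def gamma(self, taxon: str) -> np.ndarray:
        sub = self.instruments[self.instruments["taxon"] == taxon]
        return sub["gamma"].to_numpy()

    def to_json(self, path: str | Path) -> None:
        payload = {
            "theta": self.theta,
            "seed": self.seed,
            "instruments": self.instruments.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _gwas_se(maf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _draw_pleiotropy(rng, gamma: np.ndarray, cfg: SimConfig) -> np.ndarray:
    J = len(gamma)
    r = np.zeros(J)
    n_pleio = int(round(cfg.pleiotropy_fraction * J))
    if n_pleio == 0:
        return r
    which = rng.choice(J, size=n_pleio, replace=False)
    if cfg.pleiotropy_type == "balanced":
        r[which] = rng.normal(0.0, cfg.pleiotropy_scale, size=n_pleio)
    elif cfg.pleiotropy_type == "directional":
        r[which] = np.abs(rng.normal(0.0, cfg.pleiotropy_scale, size=n_pleio))
    else:  # correlated: r tracks instrument strength, violating InSIDE
        r[which] = (cfg.pleiotropy_rho * gamma[which]
                    + rng.normal(0.0, cfg.pleiotropy_scale / 2.0, size=n_pleio))
    return r


def simulate_pair(cfg: SimConfig) -> tuple[dict, pd.DataFrame, SimTruth, LDReference]:
    """Generate per-taxon exposure tables, a shared outcome table, the truth,
    and the LD reference for clumping.

    Instruments are laid out on chromosomes 1–22 at 20 Mb spacing so that
    only same-block variants are in LD; when ``ld_block_size`` > 1 each
    lead instrument is accompanied by tag variants 1 kb apart whose
    effects are attenuated by sqrt(r²), which the clumping step must
    remove.  A ``swapped_fraction`` of outcome records is emitted with
    effect/other alleles exchanged (beta negated, EAF complemented) and a
    ``palindromic_fraction`` of instruments with strand-ambiguous
    alleles, to exercise harmonization.
    """
    names = cfg.names()
    thetas = cfg.theta_by_taxon()
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_taxa)

    exposures: dict[str, pd.DataFrame] = {}
    outcome_rows = []
    truth_rows = []
    ld = LDReference()
    locus = 0  # global locus counter for positions

    for t_idx, name in enumerate(names):
        rng = np.random.default_rng(children[t_idx])
        theta = thetas[name]
        J = cfg.instruments_per_taxon

        maf = rng.uniform(*cfg.maf_range, size=J)
        se_x = _gwas_se(maf, cfg.n_x)
        se_y = _gwas_se(maf, cfg.n_y)
        f_target = rng.uniform(*cfg.f_range, size=J)
        sign = rng.choice([-1.0, 1.0], size=J)
        gamma = sign * np.sqrt(f_target) * se_x
        r = _draw_pleiotropy(rng, gamma, cfg)

        beta_x = rng.normal(gamma, se_x)
        beta_y = rng.normal(theta * gamma + r, se_y)

        pal = rng.random(J) < cfg.palindromic_fraction
        swap = rng.random(J) < cfg.swapped_fraction
        pal_idx = rng.integers(0, len(_PALINDROMIC), size=J)
        nonpal_idx = rng.integers(0, len(_NONPALINDROMIC), size=J)
        eaf = np.where(rng.random(J) < 0.5, maf, 1.0 - maf)

        exp_rows = []
        for j in range(J):
            locus += 1
            chrom = str((locus - 1) % 22 + 1)
            pos = 1_000_000 + ((locus - 1) // 22) * 20_000_000
            snp = f"rs{t_idx + 1:03d}{j:03d}"
            ea, oa = (_PALINDROMIC[pal_idx[j]] if pal[j]
                      else _NONPALINDROMIC[nonpal_idx[j]])
            z = beta_x[j] / se_x[j]
            exp_rows.append({
                "snp": snp, "chrom": chrom, "pos": pos,
                "effect_allele": ea, "other_allele": oa,
                "beta": beta_x[j], "se": se_x[j],
                "pval": _p_from_z(z), "eaf": eaf[j], "n": cfg.n_x,
            })
            o_ea, o_oa, o_beta, o_eaf = ea, oa, beta_y[j], eaf[j]
            if swap[j]:
                o_ea, o_oa, o_beta, o_eaf = oa, ea, -beta_y[j], 1.0 - eaf[j]
            outcome_rows.append({
                "snp": snp, "chrom": chrom, "pos": pos,
                "effect_allele": o_ea, "other_allele": o_oa,
                "beta": o_beta, "se": se_y[j],
                "pval": _p_from_z(o_beta / se_y[j]), "eaf": o_eaf, "n": cfg.n_y,
            })
            truth_rows.append({
                "taxon": name, "snp": snp, "gamma": gamma[j],
                "pleiotropy": r[j],
                "outlier": bool(abs(r[j]) > 3.0 * se_y[j]),
            })

            # tag variants within the LD block; clumping must discard them
            for b in range(1, cfg.ld_block_size):
                tag_snp = f"{snp}t{b}"
                r_ld = np.sqrt(cfg.ld_block_r2)
                tag_beta = rng.normal(r_ld * gamma[j], se_x[j])
                tag_z = tag_beta / se_x[j]
                # nudge the tag's p above the lead's so the lead wins ties
                tag_p = min(1.0, max(_p_from_z(tag_z), exp_rows[-1]["pval"] * 1.01))
                exp_rows.append({
                    "snp": tag_snp, "chrom": chrom, "pos": pos + 1_000 * b,
                    "effect_allele": ea, "other_allele": oa,
                    "beta": tag_beta, "se": se_x[j],
                    "pval": tag_p, "eaf": eaf[j], "n": cfg.n_x,
                })
                outcome_rows.append({
                    "snp": tag_snp, "chrom": chrom, "pos": pos + 1_000 * b,
                    "effect_allele": ea, "other_allele": oa,
                    "beta": rng.normal(theta * r_ld * gamma[j], se_y[j]),
                    "se": se_y[j],
                    "pval": 1.0, "eaf": eaf[j], "n": cfg.n_y,
                })
                ld.add(snp, tag_snp, cfg.ld_block_r2)
                for b2 in range(1, b):
                    ld.add(f"{snp}t{b2}", tag_snp, cfg.ld_block_r2)

        exposures[name] = pd.DataFrame(exp_rows)

    outcome = pd.DataFrame(outcome_rows).drop_duplicates("snp").reset_index(drop=True)
    truth = SimTruth(thetas, pd.DataFrame(truth_rows), cfg.seed)
    return exposures, outcome, truth, ld


def _p_from_z(z: float) -> float:
    from scipy import stats

    return float(max(np.finfo(float).tiny, 2.0 * stats.norm.sf(abs(z))))


def make_null_panel(cfg: SimConfig) -> tuple[dict, pd.DataFrame, SimTruth, LDReference]:
    """Panel with every taxon's causal effect forced to zero.

    Used for screening-calibration tests: any significance flag raised on
    this panel is a false positive by construction.
    """
    null_cfg = SimConfig(**{**asdict(cfg), "theta": 0.0})
    return simulate_pair(null_cfg)


def simulate_mv(
    n_exposures: int = 2,
    instruments_per_exposure: int = 30,
    theta: Sequence[float] = (0.0, 0.0),
    cross_effect_sd: float = 0.0,
    n_x: int = 18_340,
    n_y: int = 1_751,
    maf_range: tuple = (0.05, 0.5),
    f_range: tuple = (17.0, 37.0),
    seed: int = 0,
) -> tuple[dict, pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Multivariable panel: every exposure table covers the instrument union.

    Each instrument primarily instruments one exposure (γ drawn from the
    F range); its true effect on the other exposures is a small
    ``cross_effect_sd``-scaled draw (0 = orthogonal design).  The outcome
    is generated from the joint model beta_out_j ~ N(Σ_k θ_k·Γ_jk, se_Y²).

    Returns (exposure tables, outcome table, true effect matrix Γ (J×k),
    instrument metadata frame).
    """
    theta = np.asarray(theta, dtype=float)
    if len(theta) != n_exposures:
        raise ValidationError("theta length != n_exposures")
    rng = np.random.default_rng(seed)
    J = n_exposures * instruments_per_exposure
    maf = rng.uniform(*maf_range, size=J)
    se_x = _gwas_se(maf, n_x)
    se_y = _gwas_se(maf, n_y)
    gamma = rng.normal(0.0, cross_effect_sd, size=(J, n_exposures)) if cross_effect_sd > 0 \
        else np.zeros((J, n_exposures))
    owner = np.repeat(np.arange(n_exposures), instruments_per_exposure)
    f_target = rng.uniform(*f_range, size=J)
    sign = rng.choice([-1.0, 1.0], size=J)
    gamma[np.arange(J), owner] = sign * np.sqrt(f_target) * se_x

    snp = np.array([f"rs{j:05d}" for j in range(J)], dtype=object)
    chrom = ((np.arange(J) % 22) + 1).astype(str)
    pos = 1_000_000 + (np.arange(J) // 22) * 20_000_000
    meta = pd.DataFrame({"snp": snp, "owner": owner})

    exposures = {}
    names = [f"exposure_{k + 1}" for k in range(n_exposures)]
    for k, name in enumerate(names):
        beta = rng.normal(gamma[:, k], se_x)
        z = beta / se_x
        exposures[name] = pd.DataFrame({
            "snp": snp, "chrom": chrom, "pos": pos,
            "effect_allele": "A", "other_allele": "G",
            "beta": beta, "se": se_x,
            "pval": 2.0 * _sf(np.abs(z)), "eaf": maf, "n": n_x,
        })
    beta_y = rng.normal(gamma @ theta, se_y)
    outcome = pd.DataFrame({
        "snp": snp, "chrom": chrom, "pos": pos,
        "effect_allele": "A", "other_allele": "G",
        "beta": beta_y, "se": se_y,
        "pval": 2.0 * _sf(np.abs(beta_y / se_y)), "eaf": maf, "n": n_y,
    })
    return exposures, outcome, gamma, meta


def _sf(z):
    from scipy import stats

    return np.maximum(stats.norm.sf(z), np.finfo(float).tiny)


def write_dataset(
    exposures: Mapping[str, pd.DataFrame],
    outcome: pd.DataFrame,
    truth: SimTruth,
    ld: LDReference,
    outdir: str | Path,
) -> None:
    """Write a panel in the same TSV dialect the readers consume."""
    from mrscreen.summary_data import write_summary_stats

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "exposures").mkdir(exist_ok=True)
    for name, df in exposures.items():
        write_summary_stats(df, outdir / "exposures" / f"{name}.tsv")
    write_summary_stats(outcome, outdir / "outcome.tsv")
    truth.to_json(outdir / "truth.json")
    ld.to_long_frame().to_csv(outdir / "ld.tsv", sep="\t", index=False)
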