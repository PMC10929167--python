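"""GWAS summary-statistic data model, I/O, and allele harmonization.

A *collection* of variant associations is represented as a
:class:`pandas.DataFrame` with the canonical columns

    snp, chrom, pos, effect_allele, other_allele, beta, se, pval, eaf, n

one row per variant per trait.  ``eaf`` (effect-allele frequency) and ``n``
(sample size) may be missing; every other field is required.  Effect sizes
are on the trait's native scale: relative taxon abundance for the
microbiota exposures, and signed association with time-to-toxicity for the
outcome, where a *negative* beta means a shorter time to the adverse event
(higher risk).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from mrscreen.errors import ConfigurationError, EmptySetError, ValidationError

CANONICAL_COLUMNS = (
    "snp", "chrom", "pos", "effect_allele", "other_allele",
    "beta", "se", "pval", "eaf", "n",
)

REQUIRED_COLUMNS = ("snp", "effect_allele", "other_allele", "beta", "se", "pval")

#: Default file-header -> canonical-column mapping (GWAS summary conventions).
DEFAULT_DIALECT: Mapping[str, str] = {
    "SNP": "snp",
    "chr": "chrom",
    "pos": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "eaf": "eaf",
    "samplesize": "n",
}

_VALID_ALLELES = frozenset("ACGT")
_PALINDROMIC_PAIRS = (frozenset("AT"), frozenset("CG"))

# dispositions recorded in the harmonization audit trail
KEPT = "kept"
SIGN_FLIPPED = "sign_flipped"
PROXIED = "proxied"
REMOVED_PALINDROMIC = "removed_palindromic"
REMOVED_MISMATCH = "removed_mismatch"
REMOVED_MISSING = "removed_missing_in_outcome"

KEPT_DISPOSITIONS = frozenset({KEPT, SIGN_FLIPPED, PROXIED})


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's summary association with one trait.

    Mirrors a single canonical row; used where a scalar record is clearer
    than a one-row frame.
    """

    snp: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    chrom: str | None = None
    pos: int | None = None
    eaf: float | None = None
    n: float | None = None

    def __post_init__(self):
        problems = _record_problems(
            self.effect_allele, self.other_allele, self.se, self.pval, self.eaf
        )
        if problems:
            raise ValidationError(f"{self.snp}: {'; '.join(problems)}")


@dataclass
class HarmonizedSet:
    """Aligned exposure/outcome effect vectors for one exposure-outcome pair.

    All four effect vectors are index-aligned with ``snp`` and strictly
    positive in the SE components.  ``audit`` records the disposition of
    every input instrument (kept / sign_flipped / proxied /
    removed_palindromic / removed_mismatch / removed_missing_in_outcome).
    """

    exposure_name: str
    outcome_name: str
    snp: np.ndarray
    beta_exp: np.ndarray
    se_exp: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    audit: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        self.snp = np.asarray(self.snp, dtype=object)
        for name in ("beta_exp", "se_exp", "beta_out", "se_out"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        J = len(self.snp)
        if not all(len(getattr(self, v)) == J
                   for v in ("beta_exp", "se_exp", "beta_out", "se_out")):
            raise ValidationError("harmonized vectors have unequal lengths")
        if J < 1:
            raise EmptySetError(
                f"no instruments for {self.exposure_name} vs {self.outcome_name}"
            )
        if np.any(self.se_exp <= 0) or np.any(self.se_out <= 0):
            raise ValidationError("harmonized SEs must be strictly positive")

    @property
    def n_snp(self) -> int:
        return len(self.snp)

    def subset(self, keep: np.ndarray) -> "HarmonizedSet":
        """Restrict to instruments selected by a boolean mask or index array."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        kept_ids = set(self.snp[keep])
        audit = self.audit.copy()
        return HarmonizedSet(
            self.exposure_name, self.outcome_name,
            self.snp[keep], self.beta_exp[keep], self.se_exp[keep],
            self.beta_out[keep], self.se_out[keep],
            audit[audit["snp"].isin(kept_ids) | ~audit["disposition"].isin(KEPT_DISPOSITIONS)],
        )

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Re-emit aligned exposure and outcome tables (identical allele coding).

        Alleles are synthesized as a fixed non-palindromic pair because the
        harmonized vectors are allele-coding invariant; used for
        idempotence checks and round-tripping into harmonize().
        """
        exp = pd.DataFrame({
            "snp": self.snp, "chrom": "1", "pos": np.arange(1, self.n_snp + 1),
            "effect_allele": "A", "other_allele": "G",
            "beta": self.beta_exp, "se": self.se_exp,
            "pval": _two_sided_p(self.beta_exp / self.se_exp),
            "eaf": np.nan, "n": np.nan,
        })
        out = exp.copy()
        out["beta"] = self.beta_out
        out["se"] = self.se_out
        out["pval"] = _two_sided_p(self.beta_out / self.se_out)
        return exp, out


def _two_sided_p(z: np.ndarray) -> np.ndarray:
    from scipy import stats

    return np.clip(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)


def _record_problems(ea, oa, se, pval, eaf) -> list[str]:
    problems = []
    for label, a in (("effect_allele", ea), ("other_allele", oa)):
        if not (isinstance(a, str) and len(a) == 1 and a.upper() in _VALID_ALLELES):
            problems.append(f"{label} {a!r} is not a single A/C/G/T base")
    if not problems and ea.upper() == oa.upper():
        problems.append("effect and other allele are identical")
    if not (np.isfinite(se) and se > 0):
        problems.append(f"se {se!r} must be finite and > 0")
    if not (np.isfinite(pval) and 0 < pval <= 1):
        problems.append(f"pval {pval!r} outside (0, 1]")
    if eaf is not None and not (isinstance(eaf, float) and np.isnan(eaf)):
        if not (np.isfinite(eaf) and 0 <= eaf <= 1):
            problems.append(f"eaf {eaf!r} outside [0, 1]")
    return problems


def validate_records(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a canonical frame into (valid, rejects-with-reasons).

    The rejects frame carries a ``line`` column (1-based data-row number,
    header excluded) and a ``reason`` column.
    """
    df = df.copy()
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()
    reasons = []
    for i, row in enumerate(df.itertuples(index=False)):
        eaf = getattr(row, "eaf", np.nan)
        problems = _record_problems(
            row.effect_allele, row.other_allele, row.se, row.pval,
            float(eaf) if pd.notna(eaf) else np.nan,
        )
        reasons.append("; ".join(problems))
    df = df.assign(_reason=reasons, _line=np.arange(1, len(df) + 1))
    valid = df[df["_reason"] == ""].drop(columns=["_reason", "_line"]).reset_index(drop=True)
    rejects = (
        df[df["_reason"] != ""]
        .rename(columns={"_reason": "reason", "_line": "line"})
        .reset_index(drop=True)
    )
    return valid, rejects


def read_summary_stats(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a delimited summary-statistic table into canonical form.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    dialect
        Mapping from file column names to canonical names; defaults to
        :data:`DEFAULT_DIALECT`.  Only mapped columns are used.
    sep
        Field delimiter; autodetected (tab vs comma) when ``None``.

    Returns
    -------
    (records, rejects)
        ``records`` holds rows passing all invariants, in file order;
        ``rejects`` lists failing rows with 1-based data line numbers and
        the reason each failed.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"summary-statistic file not found: {path}")
    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if header.count("\t") >= header.count(",") else ","
    raw = pd.read_csv(path, sep=sep, dtype={"SNP": str, "snp": str})
    dialect = dict(dialect or DEFAULT_DIALECT)
    missing = [src for src, dst in dialect.items()
               if dst in REQUIRED_COLUMNS and src not in raw.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: required columns missing from header: {missing} "
            f"(have {list(raw.columns)})"
        )
    df = raw.rename(columns=dialect)
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[list(CANONICAL_COLUMNS)]
    df["snp"] = df["snp"].astype(str)
    if df["chrom"].notna().any():
        df["chrom"] = df["chrom"].astype("string").astype(object)
    for col in ("beta", "se", "pval", "eaf", "n", "pos"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return validate_records(df)


def write_summary_stats(
    df: pd.DataFrame, path: str | Path, sep: str = "\t",
    dialect: Mapping[str, str] | None = None,
) -> None:
    """Serialize canonical records back to a delimited table.

    The inverse of :func:`read_summary_stats` under the same dialect:
    canonical columns are renamed back to their file headers.
    """
    inverse = {dst: src for src, dst in (dialect or DEFAULT_DIALECT).items()}
    out = df.copy().rename(columns=inverse)
    out.to_csv(path, sep=sep, index=False)


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is strand-ambiguous ({A,T} or {C,G})."""
    ea, oa = str(effect_allele).upper(), str(other_allele).upper()
    for a in (ea, oa):
        if a not in _VALID_ALLELES:
            raise ValidationError(f"allele {a!r} outside A/C/G/T")
    return frozenset((ea, oa)) in _PALINDROMIC_PAIRS


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    proxy_map: pd.DataFrame | None = None,
    drop_palindromic: bool = True,
    proxy_r2_min: float = 0.8,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
    eaf_rescue: bool = False,
) -> HarmonizedSet:
    """Align outcome effects to the exposure's allele coding.

    For each selected instrument: the outcome record with the same variant
    identifier is located (or a proxy with r² above ``proxy_r2_min`` from a
    user-supplied ``proxy_map`` with columns proxy_id/target_id/r2); when
    the outcome lists effect/other alleles swapped relative to the
    exposure, the outcome beta's sign is flipped and its EAF replaced by
    1−EAF.  Palindromic (strand-ambiguous) instruments are removed when
    ``drop_palindromic`` unless ``eaf_rescue`` resolves the strand from
    clearly informative allele frequencies on both sides (< 0.35 or
    > 0.65 and concordant).  Every input instrument receives exactly one
    audit disposition.
    """
    exposure = exposure.reset_index(drop=True)
    out_by_id: dict[str, tuple] = {}
    has_eaf = "eaf" in outcome.columns
    for row in outcome.itertuples(index=False):
        out_by_id.setdefault(
            str(row.snp),
            (str(row.effect_allele).upper(), str(row.other_allele).upper(),
             float(row.beta), float(row.se),
             float(row.eaf) if has_eaf and pd.notna(row.eaf) else np.nan),
        )

    proxies: dict[str, tuple[str, float]] = {}
    if proxy_map is not None and len(proxy_map):
        best = proxy_map[proxy_map["r2"] > proxy_r2_min].sort_values("r2", ascending=False)
        for _, row in best.iterrows():
            proxies.setdefault(str(row["target_id"]), (str(row["proxy_id"]), float(row["r2"])))

    rows, audit = [], []

    def _dispose(snp: str, disposition: str, note: str = "") -> None:
        audit.append({"snp": snp, "disposition": disposition, "note": note})

    for rec in exposure.itertuples(index=False):
        snp = str(rec.snp)
        ea, oa = rec.effect_allele.upper(), rec.other_allele.upper()
        palindromic = is_palindromic(ea, oa)

        out_rec = out_by_id.get(snp)
        if out_rec is None and snp in proxies:
            proxy_id, r2 = proxies[snp]
            proxy_rec = out_by_id.get(proxy_id)
            if proxy_rec is not None:
                rows.append((snp, rec.beta, rec.se, proxy_rec[2], proxy_rec[3]))
                _dispose(snp, PROXIED, f"proxy={proxy_id} r2={r2:g}")
                continue
        if out_rec is None:
            _dispose(snp, REMOVED_MISSING)
            continue

        o_ea, o_oa, beta_out, se_out, eaf_out = out_rec

        if palindromic:
            rescued = False
            if eaf_rescue and not drop_palindromic:
                eaf_exp = getattr(rec, "eaf", np.nan)
                if (pd.notna(eaf_exp) and pd.notna(eaf_out)
                        and _informative(eaf_exp) and _informative(eaf_out)):
                    # concordant minor-allele side implies same strand coding
                    if (eaf_exp < 0.5) != (eaf_out < 0.5):
                        beta_out = -beta_out
                        eaf_out = 1.0 - eaf_out
                    rescued = True
            if drop_palindromic or not rescued:
                _dispose(snp, REMOVED_PALINDROMIC)
                continue
            rows.append((snp, rec.beta, rec.se, beta_out, se_out))
            _dispose(snp, KEPT, "palindromic, EAF-rescued")
            continue

        if (o_ea, o_oa) == (ea, oa):
            rows.append((snp, rec.beta, rec.se, beta_out, se_out))
            _dispose(snp, KEPT)
        elif (o_ea, o_oa) == (oa, ea):
            rows.append((snp, rec.beta, rec.se, -beta_out, se_out))
            _dispose(snp, SIGN_FLIPPED)
        else:
            _dispose(snp, REMOVED_MISMATCH, f"outcome alleles {o_ea}/{o_oa}")

    if not rows:
        raise EmptySetError(
            f"harmonization of {exposure_name} vs {outcome_name} left no instruments"
        )
    snp_ids, bx, sx, by, sy = map(np.asarray, zip(*rows))
    return HarmonizedSet(
        exposure_name, outcome_name,
        snp_ids, bx.astype(float), sx.astype(float), by.astype(float), sy.astype(float),
        pd.DataFrame(audit, columns=["snp", "disposition", "note"]),
    )


def _informative(eaf: float) -> bool:
    return eaf < 0.35 or eaf > 0.65


def write_audit(h: HarmonizedSet, path: str | Path, sep: str = "\t") -> None:
    """Serialize the harmonization audit trail."""
    h.audit.to_csv(path, sep=sep, index=False)
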