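"""Instrument selection: p-value screen, greedy LD clumping, F statistics.

The selection chain mirrors standard two-sample MR practice for weakly
powered exposure GWAS: genome-wide-suggestive screen (p < 1e-5 by
default), PLINK-style greedy clumping at r² < 0.001 within a 10 Mb
window, per-instrument strength F = (beta/se)² with the conventional
F > 10 screen, and a minimum of 3 instruments per exposure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from mrscreen.errors import ValidationError


class LDReference:
    """Symmetric pairwise r² lookup; absent pairs are independent (r² = 0)."""

    def __init__(self, pairs: Mapping[tuple[str, str], float] | None = None):
        self._r2: dict[frozenset, float] = {}
        for (a, b), r2 in (pairs or {}).items():
            self.add(a, b, r2)

    def add(self, a: str, b: str, r2: float) -> None:
        if not 0.0 <= r2 <= 1.0:
            raise ValidationError(f"r2({a},{b}) = {r2} outside [0, 1]")
        if a != b:
            self._r2[frozenset((a, b))] = float(r2)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(frozenset((a, b)), 0.0)

    def __len__(self) -> int:
        return len(self._r2)

    @classmethod
    def from_long_tsv(cls, path: str | Path, sep: str = "\t") -> "LDReference":
        """Load from a long-format table with columns snp_a, snp_b, r2."""
        df = pd.read_csv(path, sep=sep)
        ref = cls()
        for row in df.itertuples(index=False):
            ref.add(str(row.snp_a), str(row.snp_b), float(row.r2))
        return ref

    @classmethod
    def from_matrix(cls, matrix: np.ndarray, index: Iterable[str]) -> "LDReference":
        """Build from a dense symmetric r² matrix and its variant index."""
        index = list(index)
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (len(index), len(index)):
            raise ValidationError("r² matrix shape does not match variant index")
        ref = cls()
        for i in range(len(index)):
            for j in range(i + 1, len(index)):
                if matrix[i, j] > 0:
                    ref.add(index[i], index[j], matrix[i, j])
        return ref

    def to_long_frame(self) -> pd.DataFrame:
        rows = [(*sorted(pair), r2) for pair, r2 in self._r2.items()]
        return pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"])


@dataclass
class InstrumentSet:
    """Selected instruments for one exposure with per-variant F statistics."""

    exposure_name: str
    records: pd.DataFrame
    f: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.f is None:
            self.f = f_statistic(
                self.records["beta"].to_numpy(), self.records["se"].to_numpy()
            )
        self.f = np.asarray(self.f, dtype=float)
        if len(self.f) != len(self.records):
            raise ValidationError("F vector length mismatch")
        if self.records["snp"].duplicated().any():
            raise ValidationError(
                f"{self.exposure_name}: duplicate instruments in set"
            )

    @property
    def n_snp(self) -> int:
        return len(self.records)


def select_by_pvalue(records: pd.DataFrame, threshold: float = 1e-5) -> pd.DataFrame:
    """Keep records with p strictly below ``threshold``, preserving order."""
    if not 0.0 < threshold <= 1.0:
        raise ValidationError(f"p-value threshold {threshold} outside (0, 1]")
    return records[records["pval"] < threshold].reset_index(drop=True)


def clump(
    records: pd.DataFrame,
    ld: LDReference,
    r2_threshold: float = 0.001,
    window: float = 10_000_000,
) -> pd.DataFrame:
    """Greedy best-p-first LD clumping.

    Records are visited in ascending p (ties broken lexicographically by
    variant id); each kept record discards every remaining record on the
    same chromosome within ±``window`` bp whose r² with it is at or above
    ``r2_threshold``.  Pairs absent from ``ld`` are treated as independent.
    """
    if records.empty:
        return records.reset_index(drop=True)
    if records["pos"].isna().any() or records["chrom"].isna().any():
        bad = records.loc[records["pos"].isna() | records["chrom"].isna(), "snp"].tolist()
        raise ValidationError(f"records lack chrom/pos, cannot clump: {bad}")

    order = records.assign(_snp=records["snp"].astype(str)).sort_values(
        ["pval", "_snp"], kind="mergesort"
    )
    alive = dict.fromkeys(order.index, True)
    kept_idx = []
    chrom = records["chrom"].astype(str)
    pos = records["pos"].astype(float)
    snp = records["snp"].astype(str)
    for i in order.index:
        if not alive[i]:
            continue
        kept_idx.append(i)
        alive[i] = False
        for j in list(alive):
            if not alive[j]:
                continue
            if chrom[j] != chrom[i] or abs(pos[j] - pos[i]) > window:
                continue
            if ld.r2(snp[i], snp[j]) >= r2_threshold:
                alive[j] = False
    return records.loc[kept_idx].reset_index(drop=True)


def f_statistic(beta, se):
    """Instrument strength F = (beta/se)²; scalar or elementwise."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0) or not np.all(np.isfinite(se)):
        raise ValidationError("se must be finite and > 0 for the F statistic")
    out = (beta / se) ** 2
    return float(out) if out.ndim == 0 else out


def filter_exposures(
    instrument_sets: Mapping[str, InstrumentSet],
    min_snps: int = 3,
    f_min: float = 10.0,
) -> tuple[dict[str, InstrumentSet], pd.DataFrame]:
    """Drop weak instruments and under-instrumented exposures.

    An exposure is retained iff at least ``min_snps`` of its instruments
    have F > ``f_min``; retained sets contain only those instruments.
    Returns the retained sets and a log of dropped exposures with reasons.
    """
    kept: dict[str, InstrumentSet] = {}
    dropped = []
    for name, iset in instrument_sets.items():
        strong = iset.f > f_min
        n_strong = int(strong.sum())
        if n_strong >= min_snps:
            kept[name] = InstrumentSet(
                name, iset.records[strong].reset_index(drop=True), iset.f[strong]
            )
        else:
            dropped.append({
                "exposure": name,
                "n_instruments": iset.n_snp,
                "n_strong": n_strong,
                "reason": f"fewer than {min_snps} instruments with F > {f_min:g}",
            })
    return kept, pd.DataFrame(dropped, columns=["exposure", "n_instruments", "n_strong", "reason"])
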