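"""Reading, validation, and allele harmonization of summary statistics."""

import numpy as np
import pandas as pd
import pytest

from mrscreen.errors import ConfigurationError, EmptySetError, ValidationError
from mrscreen.summary_data import (
    DEFAULT_DIALECT,
    HarmonizedSet,
    VariantAssociation,
    harmonize,
    is_palindromic,
    read_summary_stats,
    write_summary_stats,
)

HEADER = "SNP\tchr\tpos\teffect_allele\tother_allele\tbeta\tse\tpval\teaf\tsamplesize\n"


def _write(tmp_path, rows, header=HEADER, name="stats.tsv"):
    path = tmp_path / name
    path.write_text(header + "".join(rows))
    return path


GOOD_ROWS = [
    "rs1\t1\t1000\tA\tG\t0.1\t0.02\t1e-6\t0.3\t18340\n",
    "rs2\t2\t2000\tC\tT\t-0.05\t0.01\t1e-7\t0.4\t18340\n",
    "rs3\t3\t3000\tG\tA\t0.07\t0.015\t2e-6\t0.2\t18340\n",
]


class TestReadWrite:
    def test_well_formed_tsv_round_trips_byte_identically(self, tmp_path):
        path = _write(tmp_path, GOOD_ROWS)
        records, rejects = read_summary_stats(path)
        assert len(records) == 3 and rejects.empty
        out1 = tmp_path / "rt1.tsv"
        out2 = tmp_path / "rt2.tsv"
        write_summary_stats(records, out1)
        records2, _ = read_summary_stats(out1)
        write_summary_stats(records2, out2)
        assert out1.read_bytes() == out2.read_bytes()
        pd.testing.assert_frame_equal(records, records2)

    def test_zero_se_row_rejected_with_line_number(self, tmp_path):
        rows = GOOD_ROWS[:1] + ["rs9\t1\t99\tA\tG\t0.1\t0\t1e-6\t0.3\t100\n"]
        records, rejects = read_summary_stats(_write(tmp_path, rows))
        assert list(records["snp"]) == ["rs1"]
        assert len(rejects) == 1
        assert rejects.loc[0, "line"] == 2
        assert "se" in rejects.loc[0, "reason"]

    def test_dialect_remapping_equals_default_read(self, tmp_path):
        default_path = _write(tmp_path, GOOD_ROWS)
        renamed_header = HEADER.replace("beta", "ES").replace("\tse\t", "\tSE\t")
        renamed_path = _write(tmp_path, GOOD_ROWS, header=renamed_header, name="renamed.tsv")
        dialect = dict(DEFAULT_DIALECT)
        del dialect["beta"], dialect["se"]
        dialect["ES"] = "beta"
        dialect["SE"] = "se"
        base, _ = read_summary_stats(default_path)
        remapped, _ = read_summary_stats(renamed_path, dialect=dialect)
        pd.testing.assert_frame_equal(base, remapped)

    def test_missing_required_column_is_configuration_error(self, tmp_path):
        bad_header = HEADER.replace("\tse\t", "\tstderr\t")
        path = _write(tmp_path, GOOD_ROWS, header=bad_header)
        with pytest.raises(ConfigurationError):
            read_summary_stats(path)

    def test_missing_file_is_io_error(self, tmp_path):
        with pytest.raises(IOError):
            read_summary_stats(tmp_path / "nope.tsv")

    def test_invalid_pval_and_indel_rejected(self, tmp_path):
        rows = [
            "rs1\t1\t1\tA\tG\t0.1\t0.02\t0\t0.3\t100\n",        # p = 0
            "rs2\t1\t2\tAT\tG\t0.1\t0.02\t1e-6\t0.3\t100\n",     # indel
            "rs3\t1\t3\tA\tA\t0.1\t0.02\t1e-6\t0.3\t100\n",      # same alleles
        ]
        records, rejects = read_summary_stats(_write(tmp_path, rows))
        assert records.empty and len(rejects) == 3


class TestVariantAssociation:
    def test_invariants_enforced(self):
        with pytest.raises(ValidationError):
            VariantAssociation("rs1", "A", "G", 0.1, -0.1, 1e-5)
        with pytest.raises(ValidationError):
            VariantAssociation("rs1", "A", "A", 0.1, 0.1, 1e-5)
        ok = VariantAssociation("rs1", "A", "G", 0.1, 0.1, 1e-5)
        assert ok.beta == 0.1


@pytest.mark.parametrize("ea,oa,expected", [
    ("A", "T", True), ("T", "A", True), ("C", "G", True), ("G", "C", True),
    ("A", "G", False), ("A", "C", False), ("G", "T", False),
    ("a", "t", True),
])
def test_is_palindromic(ea, oa, expected):
    assert is_palindromic(ea, oa) is expected


def test_is_palindromic_rejects_bad_allele():
    with pytest.raises(ValidationError):
        is_palindromic("A", "N")


def _frame(rows):
    return pd.DataFrame(rows, columns=[
        "snp", "chrom", "pos", "effect_allele", "other_allele",
        "beta", "se", "pval", "eaf", "n",
    ])


EXPOSURE = _frame([
    ("rs1", "1", 100, "A", "G", 0.10, 0.01, 1e-6, 0.3, 1000),
    ("rs2", "1", 200, "A", "T", 0.20, 0.02, 1e-7, 0.2, 1000),   # palindromic
    ("rs3", "2", 300, "C", "T", 0.15, 0.01, 1e-6, 0.4, 1000),
    ("rs4", "2", 400, "A", "G", 0.12, 0.01, 1e-6, 0.1, 1000),   # mismatch in outcome
    ("rs5", "3", 500, "G", "A", 0.11, 0.01, 1e-6, 0.6, 1000),   # absent from outcome
])

OUTCOME = _frame([
    ("rs1", "1", 100, "G", "A", 0.05, 0.03, 0.1, 0.7, 500),     # swapped coding
    ("rs2", "1", 200, "A", "T", 0.02, 0.03, 0.5, 0.2, 500),
    ("rs3", "2", 300, "C", "T", -0.04, 0.03, 0.2, 0.4, 500),
    ("rs4", "2", 400, "A", "C", 0.01, 0.03, 0.8, 0.1, 500),
    ("rs6", "3", 505, "A", "G", 0.03, 0.04, 0.4, 0.5, 500),     # proxy for rs5
])


class TestHarmonize:
    def test_allele_swap_flips_outcome_sign(self):
        h = harmonize(EXPOSURE, OUTCOME)
        row = dict(zip(h.snp, h.beta_out))
        assert row["rs1"] == pytest.approx(-0.05)
        audit = h.audit.set_index("snp")["disposition"]
        assert audit["rs1"] == "sign_flipped"

    def test_palindromic_removed_by_default(self):
        h = harmonize(EXPOSURE, OUTCOME)
        assert "rs2" not in set(h.snp)
        audit = h.audit.set_index("snp")["disposition"]
        assert audit["rs2"] == "removed_palindromic"

    def test_incompatible_alleles_removed_as_mismatch(self):
        h = harmonize(EXPOSURE, OUTCOME)
        audit = h.audit.set_index("snp")["disposition"]
        assert audit["rs4"] == "removed_mismatch"

    def test_missing_without_proxy_removed(self):
        h = harmonize(EXPOSURE, OUTCOME)
        audit = h.audit.set_index("snp")["disposition"]
        assert audit["rs5"] == "removed_missing_in_outcome"

    def test_proxy_substitution_respects_r2_threshold(self):
        proxies = pd.DataFrame({
            "proxy_id": ["rs6"], "target_id": ["rs5"], "r2": [0.9],
        })
        h = harmonize(EXPOSURE, OUTCOME, proxy_map=proxies)
        audit = h.audit.set_index("snp")["disposition"]
        assert audit["rs5"] == "proxied"
        weak = proxies.assign(r2=[0.5])
        h2 = harmonize(EXPOSURE, OUTCOME, proxy_map=weak)
        assert h2.audit.set_index("snp")["disposition"]["rs5"] == "removed_missing_in_outcome"

    def test_audit_conservation(self):
        h = harmonize(EXPOSURE, OUTCOME)
        assert len(h.audit) == len(EXPOSURE)
        assert set(h.audit["snp"]) == set(EXPOSURE["snp"])
        kept = h.audit["disposition"].isin({"kept", "sign_flipped", "proxied"}).sum()
        assert kept == h.n_snp

    def test_idempotence(self):
        h = harmonize(EXPOSURE, OUTCOME)
        exp2, out2 = h.to_frames()
        h2 = harmonize(exp2, out2)
        np.testing.assert_allclose(h2.beta_out, h.beta_out)
        np.testing.assert_allclose(h2.beta_exp, h.beta_exp)
        assert (h2.audit["disposition"] == "kept").all()

    def test_sign_antisymmetry_in_outcome(self):
        h = harmonize(EXPOSURE, OUTCOME)
        negated = OUTCOME.assign(beta=-OUTCOME["beta"])
        h2 = harmonize(EXPOSURE, negated)
        np.testing.assert_allclose(h2.beta_out, -h.beta_out)
        np.testing.assert_allclose(h2.beta_exp, h.beta_exp)

    def test_empty_intersection_raises(self):
        lone = EXPOSURE.iloc[[4]]  # rs5 absent from outcome
        with pytest.raises(EmptySetError):
            harmonize(lone, OUTCOME, exposure_name="lone")

    def test_eaf_rescue_keeps_informative_palindromes(self):
        h = harmonize(EXPOSURE, OUTCOME, drop_palindromic=False, eaf_rescue=True)
        audit = h.audit.set_index("snp")["disposition"]
        assert audit["rs2"] == "kept"  # eaf 0.2 both sides: same strand
        assert dict(zip(h.snp, h.beta_out))["rs2"] == pytest.approx(0.02)


def test_harmonized_set_rejects_nonpositive_se():
    audit = pd.DataFrame({"snp": ["a"], "disposition": ["kept"], "note": [""]})
    with pytest.raises(ValidationError):
        HarmonizedSet("e", "o", np.array(["a"]), [0.1], [0.0], [0.1], [0.1], audit)
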