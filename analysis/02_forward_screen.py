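"""Forward screen: every taxon against the toxicity outcome.

Instrument selection (p < 1e-5, clumping at r² < 0.001 / 10 Mb,
post-harmonization F > 10 with >= 3 instruments), then IVW + MR-PRESSO
as the primary analysis.  Taxa with IVW p < 0.05 and MR-PRESSO p < 0.05
are flagged for the sensitivity battery; the family-wise threshold is
0.05/m for the m taxa actually analyzed.

Reads results/data/, writes results/screen/.
"""

from pathlib import Path

import pandas as pd

from mrscreen.instruments import LDReference
from mrscreen.pipeline import ScreenConfig, run_forward_screen
from mrscreen.summary_data import read_summary_stats

SEED = 1
ROOT = Path(__file__).resolve().parents[1] / "results"


def load_panel(data_dir: Path):
    exposures = {
        f.stem: read_summary_stats(f)[0]
        for f in sorted((data_dir / "exposures").glob("*.tsv"))
    }
    outcome, _ = read_summary_stats(data_dir / "outcome.tsv")
    ld = LDReference.from_long_tsv(data_dir / "ld.tsv")
    return exposures, outcome, ld


def main() -> None:
    exposures, outcome, ld = load_panel(ROOT / "data")
    cfg = ScreenConfig(seed=SEED, presso_n_sim=1000, cml_k_max=5)
    res = run_forward_screen(exposures, outcome, ld, cfg, outcome_name="irae")

    out = ROOT / "screen"
    out.mkdir(parents=True, exist_ok=True)
    res.estimates.to_csv(out / "estimates.tsv", sep="\t", index=False)
    res.flags.to_csv(out / "flags.tsv", sep="\t", index=False)
    res.diagnostics.to_csv(out / "diagnostics.tsv", sep="\t", index=False)
    res.presso.to_csv(out / "presso.tsv", sep="\t", index=False)
    res.dropped.to_csv(out / "dropped.tsv", sep="\t", index=False)
    res.scatter_data().to_csv(out / "scatter_data.tsv", sep="\t", index=False)

    hits = res.flags[res.flags["suggestive"]]
    bonf = res.flags[res.flags["bonferroni"]]
    print(f"analyzed {res.m_tested} taxa "
          f"(dropped {len(res.dropped)}: too few strong instruments)")
    print(f"Bonferroni threshold 0.05/{res.m_tested} = "
          f"{res.bonferroni_threshold:.4g}")
    print(f"suggestive (IVW & PRESSO p < 0.05): {len(hits)} taxa: "
          f"{', '.join(hits['exposure'])}")
    print(f"family-wise significant: {len(bonf)} taxa: "
          f"{', '.join(bonf['exposure'])}")
    with pd.option_context("display.width", 120):
        ivw_rows = res.estimates[
            res.estimates["method"].isin(["ivw", "cml_ma_bic"])
            & res.estimates["exposure"].isin(hits["exposure"])
        ]
        print(ivw_rows.to_string(index=False))


if __name__ == "__main__":
    main()
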