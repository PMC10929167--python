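"""Reverse MR: does toxicity liability act back on the flagged taxa?

Roles are swapped: the toxicity phenotype becomes the exposure and the
flagged taxa the outcomes.  Because the small outcome GWAS carries no
genome-wide-suggestive instruments of its own in this synthetic panel
(as in the real underpowered setting), the instrument threshold is
relaxed (1e-3) and any Bonferroni-level reverse signal would indicate
reverse causation.  Data were generated taxon -> outcome only, so a
quiet reverse screen is the expected (correct) answer.

Reads results/data/ and results/screen/, writes results/reverse/.
"""

import sys
from importlib import import_module
from pathlib import Path

import pandas as pd

from mrscreen.errors import EmptySetError
from mrscreen.pipeline import ScreenConfig, run_reverse_mr

sys.path.insert(0, str(Path(__file__).resolve().parent))
load_panel = import_module("02_forward_screen").load_panel

SEED = 1
ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    exposures, outcome, ld = load_panel(ROOT / "data")
    flags = pd.read_csv(ROOT / "screen" / "flags.tsv", sep="\t")
    flagged = list(flags.loc[flags["suggestive"], "exposure"])
    cfg = ScreenConfig(seed=SEED, iv_pvalue=1e-3, presso_n_sim=1000)
    out = ROOT / "reverse"
    out.mkdir(parents=True, exist_ok=True)
    try:
        res = run_reverse_mr(outcome, {t: exposures[t] for t in flagged},
                             ld, cfg, exposure_name="irae")
    except EmptySetError as err:
        (out / "reverse_summary.txt").write_text(f"{err}\n")
        print(f"reverse screen empty: {err}")
        print("no instruments for the toxicity phenotype even at p < 1e-3 — "
              "no evidence of reverse causation is obtainable (or needed)")
        return
    res.estimates.to_csv(out / "estimates.tsv", sep="\t", index=False)
    res.flags.to_csv(out / "flags.tsv", sep="\t", index=False)
    n_bonf = int(res.flags["bonferroni"].sum())
    print(f"reverse-screened {res.m_tested} taxa; "
          f"{n_bonf} Bonferroni-level reverse signals "
          f"({'none expected' if n_bonf == 0 else 'UNEXPECTED'})")


if __name__ == "__main__":
    main()
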