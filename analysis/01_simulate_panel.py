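"""Generate the synthetic study panel.

Emulates the real study's scale: 132 gut-microbiota taxa instrumented by
a large consortium exposure GWAS (n = 18,340) screened against a small
time-to-toxicity outcome GWAS (n = 1,751).  Three taxa are given nonzero
causal effects (negative = shorter time to the adverse event = risk
factor); the rest are null.  Harmonization hazards (15% palindromic
alleles, 15% swapped allele coding) and 3-variant LD blocks are included
so every downstream step does real work.

Writes results/data/ (exposure TSVs, outcome TSV, LD table, truth JSON).
"""

from pathlib import Path

from mrscreen.simulate import SimConfig, simulate_pair, write_dataset

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "data"

CAUSAL = {"taxon_007": -2.0, "taxon_042": -1.0, "taxon_101": 1.0}


def main() -> None:
    theta = {f"taxon_{i:03d}": CAUSAL.get(f"taxon_{i:03d}", 0.0)
             for i in range(1, 133)}
    cfg = SimConfig(
        n_taxa=132, instruments_per_taxon=7, theta=theta,
        palindromic_fraction=0.15, swapped_fraction=0.15,
        ld_block_size=3, seed=SEED,
    )
    exposures, outcome, truth, ld = simulate_pair(cfg)
    write_dataset(exposures, outcome, truth, ld, OUT)
    n_rows = sum(len(df) for df in exposures.values())
    print(f"wrote {len(exposures)} taxa ({n_rows} exposure records, "
          f"{len(outcome)} outcome records) to {OUT}")
    print(f"causal truth: {CAUSAL} (negative beta = higher toxicity risk)")


if __name__ == "__main__":
    main()
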