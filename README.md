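# mrscreen

Two-sample Mendelian randomization (MR) screening toolkit for linking
gut-microbiota GWAS summary statistics to immunotherapy-toxicity GWAS
summary statistics — and, more generally, for screening many weakly
instrumented exposures against one outcome using only published
per-variant association tables.

Immune-checkpoint-inhibitor therapy causes immune-related adverse
events (irAEs) in a substantial fraction of cancer patients, and
observational studies implicate the gut microbiome — but they cannot
separate causation from confounding by diet, medication, or disease.
MR sidesteps this by using germline variants associated with taxon
abundance (mbQTLs) as instrumental variables: because genotypes are
fixed at conception, an association between taxon-raising alleles and
time-to-toxicity supports a causal effect of the taxon. The outcome
here is a time-to-event phenotype, so a **negative** causal estimate
means a shorter time to the adverse event, i.e. the taxon is a risk
factor.

## What the package implements

For each exposure–outcome pair with per-instrument effects
(β̂_Xj, σ_Xj) and (β̂_Yj, σ_Yj), j = 1..J:

- **Instrument selection** — p < 1e-5 screen, PLINK-style greedy LD
  clumping (r² < 0.001 within 10 Mb, best p first), instrument strength
  F_j = (β̂_Xj/σ_Xj)² with an F > 10 / ≥3-instrument filter applied
  after harmonization.
- **Harmonization** — allele alignment with sign flips for swapped
  coding, removal of palindromic (A/T, C/G) variants, optional proxy
  substitution (user-supplied table, r² > 0.8), full audit trail.
- **Estimators** — Wald ratio; IVW (weighted regression of β̂_Y on β̂_X
  through the origin, weights 1/σ_Yj², fixed-effect or multiplicative
  random-effects); joint-normal maximum likelihood; MR-Egger (with
  intercept, the intercept testing directional pleiotropy); weighted
  median and weighted mode with seeded parametric-bootstrap SEs.
- **MR-PRESSO** — simulation-based global residual-sum-of-squares test,
  per-instrument outlier flags (Bonferroni-corrected), outlier-corrected
  IVW, and distortion test.
- **cML-MA-BIC** — constrained maximum likelihood allowing K invalid
  instruments (nonzero pleiotropy terms r_j), solved by alternating
  exact profile-θ and top-K-residual support updates, model-averaged
  over K with weights ∝ exp(−ΔBIC/2), BIC_K = 2·NLL_K + K·log(n_eff).
- **Diagnostics** — Cochran's Q (χ², J−1 df), Egger intercept,
  leave-one-out IVW, confounder-annotation join (user-supplied
  variant→trait table; flagged, never auto-excluded).
- **MVMR** — multivariable IVW: weighted multiple regression of outcome
  effects on several exposures' effect columns (direct effects), with
  joint clumping, collinearity detection and conditional-F diagnostics.
- **Pipeline** — forward screen over many taxa with the dual
  IVW + MR-PRESSO p < 0.05 gate, Bonferroni threshold 0.05/m recomputed
  from the m pairs actually analyzed, sensitivity battery for flagged
  pairs, reverse MR with roles swapped, and a `mrscreen` CLI
  (`simulate` / `screen` / `reverse` / `mvmr` / `report`).
- **Synthetic data** — a generator of paired exposure/outcome summary
  statistics with known truth (per-taxon causal effects, pleiotropy of
  balanced/directional/correlated type, LD blocks, palindromic and
  allele-swapped records), defaulting to the real study's scale:
  132 taxa, exposure GWAS n = 18,340, outcome GWAS n = 1,751,
  instrument F in [17, 37].

## Worked example

The `analysis/` directory is a numbered, self-contained synthetic
study. `01_simulate_panel.py` generates 132 taxa (three causal:
θ = −2, −1, +1) with realistic harmonization hazards;
`02_forward_screen.py` screens them:

```
$ python analysis/01_simulate_panel.py
$ python analysis/02_forward_screen.py
analyzed 121 taxa (dropped 11: too few strong instruments)
Bonferroni threshold 0.05/121 = 0.0004132
suggestive (IVW & PRESSO p < 0.05): 4 taxa: taxon_007, taxon_035, taxon_040, taxon_101
family-wise significant: 2 taxa: taxon_007, taxon_101
 exposure outcome     method  nsnp      beta       se    ci_low   ci_high         pval
taxon_007    irae        ivw     4 -1.821539 0.339504 -2.486956 -1.156123 8.081995e-08
taxon_007    irae cml_ma_bic     4 -1.882410 0.332271 -2.533650 -1.231171 1.467802e-08
...
```

Reading: `taxon_007` (true θ = −2, a risk taxon — negative beta means
shorter time to toxicity) and `taxon_101` (true θ = +1, protective) are
recovered at the family-wise level; the weaker θ = −1 taxon is missed
(the outcome GWAS is small — an honest power limit, as in the real
setting); two null taxa reach the nominal 5% gate, as expected by
chance. `03_sensitivity.py` (Q, Egger intercept, leave-one-out,
annotation join), `04_reverse_mr.py` (swapped roles; correctly quiet,
since the data were generated taxon → outcome only) and `05_mvmr.py`
(separating a taxon's direct effect from a BMI-like co-exposure)
complete the chain. Outputs land under `results/`.

The same operations are scriptable via the CLI:

```bash
mrscreen simulate --seed 7 --taxa 5 --theta taxon_1=-2 --out data/
mrscreen screen --exposures data/exposures --outcome data/outcome.tsv \
         --ld data/ld.tsv --out results/
```

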