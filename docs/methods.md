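# Methods

## Data model and conventions

A summary-statistic table is one row per variant: identifier,
chromosome, 1-based position, effect/other allele (single A/C/G/T
bases; indels rejected), beta, SE (> 0), two-sided p in (0, 1], and
optionally effect-allele frequency and sample size. Exposure effects
are on the relative-abundance scale of a bacterial taxon; outcome
effects are signed associations with time to an immune-related adverse
event under immunotherapy, where negative beta = shorter time = higher
risk. Allele strings are upper-cased on ingest; rows violating any
invariant are reported with line numbers rather than silently dropped.

## Instrument selection

1. p < 1e-5 (strict inequality; the screen threshold for weakly
   powered microbiome GWAS).
2. Greedy best-p-first clumping: records sorted by (p, id); each kept
   record discards all remaining same-chromosome records within ±10 Mb
   with r² ≥ 0.001 against it. LD comes from a user-supplied pairwise
   table (long TSV or dense matrix + index); absent pairs count as
   independent. Ties in p are broken lexicographically by variant id,
   making the procedure order-invariant and deterministic.
3. F = (beta/SE)² per instrument; instruments with F ≤ 10 are dropped
   and exposures with fewer than 3 surviving instruments are excluded.
   The F screen runs *after* harmonization so the instruments reported
   are exactly the instruments analyzed.

## Harmonization

Outcome records are matched by variant id. Swapped effect/other
alleles flip the outcome beta's sign and complement its EAF. Any other
allele combination is an incompatibility and removes the instrument.
Palindromic (A/T, C/G) variants are removed by default; an optional
EAF rescue keeps them when both studies' frequencies are clearly
informative (< 0.35 or > 0.65) and resolves strand by frequency
concordance — off by default because the source protocol removes all
palindromes. Instruments absent from the outcome may be replaced from
a user-supplied proxy table (proxy_id, target_id, r²; threshold 0.8);
the proxy's outcome association is used as-is, which assumes the proxy
is coded on the positively correlated haplotype — no cross-variant
allele re-alignment is attempted, and no network lookup exists
anywhere in the package. Every input instrument receives exactly one
audit disposition (kept / sign_flipped / proxied / removed_*), so
|kept ∪ removed| always equals the input count.

## Estimators

With x_j = β̂_Xj, y_j = β̂_Yj, w_j = 1/σ_Yj²:

- **Wald ratio**: y/x, SE σ_Y/|x| (first-order delta; a second-order
  term adding y²σ_X²/x⁴ is available by flag).
- **IVW**: θ̂ = Σw x y / Σw x², fixed SE (Σw x²)^-1/2. Default
  variance mode is fixed-effect with multiplicative random-effects
  inflation √(Q/(J−1)) applied only when > 1 (the common package
  default). Fixed mode is used wherever a correctly specified
  simulation null is being calibrated, since inflation-only-when-
  overdispersed is deliberately conservative there.
- **Maximum likelihood**: model β̂_Xj ~ N(γ_j, σ_Xj²),
  β̂_Yj ~ N(θγ_j, σ_Yj²); γ profiled in closed form, leaving the 1-D
  deviance Σ (y−θx)²/(σ_Y²+θ²σ_X²) minimized by bounded Brent search
  from the IVW start; SE from the observed information of the full
  (θ, γ) model via arrowhead inversion.
- **MR-Egger**: instruments re-oriented so x_j ≥ 0 (both betas
  flipped), then weighted regression *with* intercept. SEs use the
  residual-variance-scaled covariance (s² = weighted RSS/(J−2), the
  lm convention) and t(J−2) p-values, for both slope and intercept.
- **Weighted median**: ratios ordered; estimate interpolates the
  ordered ratios where the standardized cumulative weight
  (S_j − w_j/2)/S_J crosses 0.5, weights x²/σ_Y². SE is the SD of the
  estimate over a parametric bootstrap (both effect vectors redrawn
  from their normals; default 1000 draws, single seed).
- **Weighted mode**: Gaussian-kernel weighted density over the ratios,
  bandwidth φ·0.9·min(sd, IQR/1.34)·J^(−1/5) (φ = 1 by default),
  argmax on a 512-point grid spanning ratios ± 3 bandwidths; identical
  ratios (zero bandwidth) return the common ratio. Bootstrap SE as for
  the median.

All estimators are sign-antisymmetric in the outcome and
scale-equivariant in the exposure; these are property-tested.

## MR-PRESSO

Observed RSS = Σ_j w_j (y_j − θ̂_(−j) x_j)² with θ̂_(−j) the
leave-one-out IVW. The null distribution redraws both effect vectors
from normals centered at (x_j, θ̂_(−j)x_j) (default 1000 simulations);
global p = (1 + #{RSS_sim ≥ RSS_obs})/(n_sim+1), floored at
1/(n_sim+1) — never zero. Per-instrument outlier p-values take each
instrument's simulated residual tail, Bonferroni-corrected over J
(two-sided in the residual's sign since residuals enter squared). When
outliers are found the IVW is recomputed without them, and the
distortion test compares the observed relative estimate shift against
a null built by resampling pseudo-outlier blocks from the non-outliers.
The distortion result is reported but never changes the headline
estimate; the outlier-corrected IVW is reported alongside. The test
requires J ≥ 4.

## cML-MA-BIC

For fixed K, instruments granted a free pleiotropy term r_j drop out
of the outcome likelihood (γ_j = x_j, r_j = y_j − θx_j), so the
constrained optimum alternates two exact block maximizations: (i) θ by
1-D profile ML on the currently valid set, (ii) the invalid set as the
K largest per-instrument profile residuals
(y−θx)²/(σ_Y²+θ²σ_X²) — the standardized outcome residuals. Each step
is exact, so the likelihood is monotone and the alternation terminates
without cycling (ties excepted, in which case the best support seen is
kept). Five seeded random restarts of the θ start guard against local
optima in the combinatorial support (K > 0 only). SE comes from the
Fisher information restricted to valid instruments. BIC_K = 2·NLL_K +
K·log(n_eff); weights ∝ exp(−ΔBIC/2); θ_MA = Σ w_K θ_K with variance
Σ w_K (se_K² + (θ_K − θ_MA)²). K ranges over 0..J−2 (θ stays
identifiable). n_eff defaults to min(exposure n, outcome n) from the
input tables (a user-set override exists; 1000 is the documented
fallback when the tables carry no sample sizes).

**Known limitation.** This is the plain BIC-averaged variant, without
the data-perturbation (DP) refinement. The model-averaged SE does not
propagate uncertainty in *which* instruments are selected as invalid,
so when pleiotropy sits near the outcome noise floor (≈ 2–3 outcome
SEs — the generator's default directional-pleiotropy scale) the null
rejection rate at α = 0.05 is measurably inflated (≈ 12% at J = 20,
30% directional pleiotropy, n_eff = 1751). With clearly identifiable
pleiotropy (twice that scale and above) the rate returns to ≈ 5–8%.
Relatedly, BIC selection consistency needs log(n_eff) large against
the extreme valid-instrument residuals (~2·log J); with small n_eff
the averaging correctly spreads weight over K instead of concentrating
on K = 0.

## Diagnostics

Cochran's Q = Σ w_j (θ_j − θ_IVW)², w_j = x²/σ_Y², around the
fixed-effect center regardless of the reporting variance mode; p from
χ²(J−1). Leave-one-out recomputes IVW J times. Confounder screening is
a pure left join of instruments against a user-supplied variant→trait
table — mirroring a manual lookup review — with a helper to re-run IVW
excluding a flagged instrument; nothing is ever auto-excluded.

## Multivariable MR

Instruments are the union of each exposure's screened variants,
clumped jointly on each variant's best p across exposures, aligned to
the coding of the exposure listing it with the best p, and required to
carry an effect in every exposure table and the outcome (a real
multi-GWAS table covers essentially all variants, so missingness is
logged attrition, not the common case). Estimation is no-intercept
weighted least squares with weights 1/σ_Y²; fixed-effect coefficient
covariance (X'WX)^-1; rank deficiency raises an error naming the
collinear exposures. A heuristic conditional-F (each exposure's
effects regressed on the others'; mean squared standardized residual)
is reported as a strength diagnostic only.

## Screening pipeline

Per pair: selection → clumping → harmonization → F filter → IVW +
MR-PRESSO (primary). The suggestive gate is IVW p < 0.05 **and** the
MR-PRESSO causal-estimate p < 0.05 (the outlier-corrected IVW when
outliers were found, the raw IVW otherwise — the global RSS p is a
pleiotropy diagnostic, not an association test, and gating on it would
make the gate's null rate ≪ 5%). Pairs with fewer than 4 instruments
fall back to the IVW-only gate with a logged caveat. Gated pairs get
the full sensitivity battery (ML, Egger, median, mode, diagnostics,
cML-MA-BIC). The family-wise threshold is α/m with m the number of
pairs actually analyzed, recomputed every run and never hard-coded
(0.05/132 = 3.7879e-4 at the study's scale). Per-pair seeds derive
from the master seed and the pair's name (CRC32), so results are
independent of exposure iteration order. Reverse MR swaps the trait
roles and reuses the identical machinery; its instrument threshold is
configurable (default 1e-5) since an underpowered outcome GWAS may
carry no genome-wide-suggestive instruments at all — an empty reverse
screen is then the correct, reported outcome.

## Synthetic data generator

Per taxon and instrument: MAF ~ U(0.05, 0.5); SEs follow the
standardized-trait approximation 1/√(2p(1−p)n) (rank-normalized mbQTL
convention); true effect γ = ±√F·σ_X with F ~ U(17, 37), matching the
instrument-strength profile of consortium mbQTL instruments (observed
F range ≈ 17–37, median ≈ 22–31 after selection noise); observed
effects add N(0, σ²) noise; outcome β̂_Y ~ N(θγ + r, σ_Y²). Defaults
emulate the real study's scale: 132 taxa, 7 instruments each,
n_X = 18,340, n_Y = 1,751. Pleiotropy r is nonzero for a fraction π of
instruments: balanced N(0, s), directional |N(0, s)|, or correlated
ρ·γ + N(0, s/2) (violating InSIDE, the regime cML-MA-BIC targets);
s = 0.15 by default — roughly 2–4 outcome SEs, i.e. direct effects
comparable to the causal signals of interest. LD blocks emit tag
variants 1 kb from the lead with effects attenuated by √r² and an LD
table entry, so clumping must prune them; configurable fractions of
palindromic allele pairs and swapped-coding outcome records exercise
harmonization. One master seed drives per-taxon spawned streams —
identical seeds give byte-identical output files.

What the generator does **not** emulate: compositional covariance
between taxa (taxa are independent), linkage between taxa's loci,
strand errors beyond clean swaps, indels, population-stratification
artifacts, and sample overlap between the two GWAS. Passing tests
therefore demonstrate correctness of the statistical machinery under
the stated model, not robustness to every pathology of real summary
data.

## Test design and problem sizes

- Closed-form estimators (IVW, Egger, Q, MVMR) are verified against an
  independent generic weighted-least-squares solver (numpy lstsq on
  √w-scaled designs) to 1e-10 on 100 random instances; reductions
  (IVW(J=1) = Wald, MVMR(k=1) = IVW, cML(K=0) = ML) to at least 1e-6.
- Parameter-recovery tests (θ ∈ {−2, 0, 1}, 50 instruments, 200
  seeded replicates; MVMR with 60 instruments) run in the
  strong-instrument limit (F ~ 1e6–4e6): every ratio-based MR
  estimator carries O(1/F) regression-dilution attenuation, so mean
  unbiasedness within Monte-Carlo error is the testable claim only
  where that term is negligible. At the study-default F ∈ [17, 37]
  the attenuation is ≈ 1/F̄ ≈ 4% of θ — visible in the worked example
  (IVW ≈ −1.82 for θ = −2) and inherent to the regime, not the code.
- Calibration tests use the study-default strength: IVW fixed-effect
  type-I over 2000 nulls (4–6% band), MR-PRESSO planted-outlier
  detection over 100 replicates (10·σ_Y offset), null-panel screening
  over 200 seeded panels of 132 taxa (family-wise false positives and
  the ≈ 5% suggestive rate). The full suite runs in ≈ 6 minutes on one
  CPU; the acceptance script (scaled-down replicate counts, same
  machinery) in ≈ 1 minute.

## Numerical choices

Normal-based p-values and 95% CIs everywhere except Egger (t, J−2 df);
p-values floored at the smallest positive double; simulation p-values
floored at 1/(n_sim+1). Bootstrap and simulation randomness always
flows from one explicit integer seed (numpy Generator); nothing reads
global RNG state. Optimizers: bounded Brent with tolerance 1e-10 (ML)
and 1e-9 (cML support steps); cML convergence tolerance 1e-7 on θ;
weighted-median interpolation clamps to the extreme ratios when 0.5
falls outside the half-weight grid. MVMR rank checks use a relative
1e-10 eigenvalue tolerance.
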