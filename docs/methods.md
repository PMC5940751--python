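# Methods

## Scope and model

`mrlink` implements the analysis stack of a two-sample Mendelian
randomization (MR) study of one binary exposure on one binary outcome,
plus the two genome-scale companions such a study leans on: cross-trait
LD-score regression for overall genetic correlation, and a Bayesian
pairwise scan that asks whether a single locus drives both traits through
the same or through distinct variants. All estimators work from GWAS
summary statistics (per-allele log-odds effects and standard errors);
individual-level data are never required.

Assumptions, by stage:

* **MR core.** Instruments are valid (associated with the exposure, no
  direct outcome path, no confounder path); the Wald ratio
  θ̂ᵢ = β_Yi/β_Xi is combined by fixed-effect inverse-variance weighting.
  Fixed-effect (not random-effects) pooling is the headline estimator:
  under instrument validity all ratios estimate one causal parameter, and
  heterogeneity is treated as a diagnostic (Cochran's Q), not absorbed
  into a wider interval. Egger regression relaxes the exclusion
  restriction to the InSIDE assumption (instrument strength independent of
  direct effects); its intercept estimates average directional pleiotropy.
* **LD-score regression.** The polygenic model
  E[z²] = 1 + n·h²·ℓ/m (+ confounding intercept) and its cross-trait
  analogue. Sample overlap between the two GWAS moves the cross-trait
  intercept, never the slope; that is why the genetic covariance is
  overlap-robust.
* **Region scan.** One causal variant per trait per model (the standard
  assumption of this model family); LD between variants is therefore
  ignored inside the evidence sums. Consequently the "distinct variants"
  model can be preferred over "shared" only when the two association peaks
  are not in strong LD.

## Key parameters (defaults and reasons)

| parameter | default | meaning / rationale |
|---|---|---|
| `gws_alpha` | 5×10⁻⁸ | genome-wide significance for instrument selection |
| `fdr_q` | 0.05 | Benjamini–Hochberg rate for the relaxed instrument set |
| `maf_min` | 0.05 | low-frequency instruments are *flagged*, never removed — rare variants can be legitimate instruments but deserve scrutiny |
| `palindrome_eaf_window` | 0.08 | A/T and C/G variants are strand-ambiguous; they are resolved by allele-frequency agreement only when both frequencies are outside 0.5 ± 0.08, otherwise dropped. Conservative standard practice. |
| `r2_min` (proxy search) | 0.80 | minimum LD for a proxy to stand in for a missing instrument; ties broken by base-pair distance, then rsid, so the choice is deterministic |
| Wald se order | first | `se_out/|b_exp|`; the second-order delta form (adding `b_out²se_exp²/b_exp⁴`) is available by flag. With strong instruments the difference is negligible; first-order is the common default of two-sample MR practice. |
| outlier rule | residual p_het > 0.05 | a variant is *the* outlier when its removal yields the largest Q reduction **and** leaves no significant residual heterogeneity; `leave_one_out` also reports the ungated max-ΔQ variant (`dominant`) for recovery checks |
| LDSC blocks | 200 | delete-one-block jackknife over contiguous position blocks |
| LDSC χ² cap | 80 | guards the regression against single-locus outliers; applied symmetrically to both traits so that regressing a trait on itself returns r_g = 1 exactly |
| scan priors | π₁ = π₂ = 10⁻⁴, π₁₂ = 10⁻⁵, w = 0.04 | per-variant association priors and prior effect variance on the log-odds scale, in the range conventional for this model family; all configurable. Region posteriors therefore reproduce published numbers only approximately — the exact priors behind any published scan are rarely stated. |

Numerical choices: all five region-model evidences are computed in log
space with log-sum-exp (and log1p-based differencing for the
distinct-variants evidence), so z-scores of 60 and beyond — p-values far
below the smallest positive double — are handled without overflow;
−log₁₀ p columns come from `norm.logsf` for the same reason. LD metrics
clip D′ and r² into [0, 1] against float round-off. Weighted regressions
use `numpy.linalg.lstsq` on √w-scaled design matrices; Egger inference
uses the t distribution on k−2 df via `statsmodels` WLS. P-values below
2.2×10⁻³⁰⁸ are printed as "<2.2e-308" in formatted tables while the
unformatted doubles are kept in the result objects.

Degenerate inputs are errors, not silent results: zero exposure effect
(undefined ratio), monomorphic variants (undefined LD), constant LD scores
(unidentifiable regression), constant exposure effects after orientation
(degenerate Egger design), non-PSD LD matrices, infeasible bivariate
covariances.

## The synthetic-data generator

The generator works entirely at the summary-statistic level and defines
the conditions every recovery test runs under:

* **MR studies** default to 52 instruments, an exposure GWAS of
  60,801/123,504 cases/controls and an outcome GWAS of 17,008/37,154;
  true exposure effects have magnitudes uniform on [0.03, 0.3] (odds
  ratios ≈ 1.03–1.35) with random signs; standard errors follow the
  binary-trait approximation 1/√(2p(1−p)·N·φ(1−φ)). Pleiotropy is either
  absent, directional (a constant direct effect), or a single outlier
  with direct effect log 3.2 — the scale of the APOE ε4 heterozygote
  odds ratio. Allele representations in the outcome table are randomly
  swapped and strand-complemented so harmonization is always exercised.
* **LDSC panels** default to m = 5,000 variants. A real regression runs
  on millions of variants; the panel is a scaled-down genome, so default
  sample sizes are scaled by the same ~1/1000 factor (n₁ = 184,
  n₂ = 54) to keep per-variant χ² on the realistic scale (mean ≈ 1.3–1.9).
  Sample overlap enters the cross-covariance as
  ρ_pheno·N_s/√(n₁n₂) with ρ_pheno defaulting to 0.5 — a moderate
  phenotypic correlation among shared participants.
* **Regions** draw z ~ MVN(Rλ, R) with AR(1) LD (ρ = 0.5 by default),
  causal z = 8, constant se; distinct-configuration causal variants sit a
  quarter and three quarters of the way through the region, where AR(1)
  correlation between them is negligible.
* **Haplotype panels** use a Markov copying process (retention
  probability e^(−decay) per adjacent variant) and can plant a
  four-variant block whose low-frequency member rides exclusively on one
  common haplotype — complete D′ with r² < 0.1, the classic signature of
  an ε2-like allele.

What the generator does **not** emulate: LD between MR instruments
(instruments are independent, as intended after clumping), winner's-curse
selection of instruments, population stratification, MAF-dependent
genetic architecture, imputation error, or real LD-score distributions
beyond a gamma-shaped spread. Passing recovery tests therefore
demonstrates correctness of the estimators under their own model
assumptions — not robustness to the full messiness of real cohort data.

Every simulator takes an explicit seed, draws from a single
`numpy.random.default_rng`, is byte-reproducible, and emits a
`TruthRecord`; recovery tests read ground truth only from that record.

## Design choices where the design was open

* **Leave-one-out flagging.** The pipeline's outlier verdict requires the
  heterogeneity to actually resolve (residual p_het above threshold),
  mirroring how an APOE-style exclusion is argued in practice. Because
  residual p_het is approximately uniform when the remaining instruments
  are clean, recovery tests assert identification via the ungated
  max-ΔQ variant; the gated rule would pass only ~95% of the time by
  construction even with perfect identification.
* **Self-consistent LDSC weights.** All three regressions (two
  single-trait, one cross) take their heteroskedasticity weights from the
  same first-pass slopes, which makes r_g(trait, itself) = 1 an exact
  identity rather than an approximation.
* **Few-instrument behaviour.** Automatic selection aborts below 3
  surviving instruments (a 2-instrument MR invites over-interpretation);
  an explicitly supplied instrument list instead runs IVW and skips Q,
  leave-one-out and Egger with recorded notices, since an explicit list
  signals the user knows what they have.
* **Pleiotropy lookup is local.** The phenome-scan stage joins against a
  user-supplied annotation table (variant, phenotype, p, source) with a
  Bonferroni default threshold of 0.05/#phenotypes; no web service is
  ever contacted, keeping runs hermetic and reproducible.
* **Recessive-model instruments** cannot be recognised from summary
  statistics; an optional boolean input column marks them and the
  pipeline excludes them with reason `recessive-model`.

## Problem sizes

Recovery tests run at the study scale they emulate: 52 instruments with
500 replicates for unbiasedness and Q calibration, 200 replicates for
outlier identification, LDSC panels of 5,000 variants with 200 jackknife
blocks, and 100 replicates per region configuration at 200 variants.
These sizes give Monte-Carlo error comfortably below the assertion
tolerances while keeping the full suite fast enough for routine runs.

## Known limitations

* LD-aware multi-causal fine-mapping is out of scope; the region scan's
  single-causal-variant assumption is both its strength (closed form,
  log-safe) and its limit (shared-vs-distinct verdicts blur when the
  candidate variants are in strong LD).
* LDSC here is the plain (unpartitioned) regression; no
  annotation-stratified variant, no INFO/MAF filtering policy beyond the
  χ² cap — genome-wide reproductions on real cohorts depend on those
  filtering details.
* Weighted-median/mode MR estimators, multivariable MR and winner's-curse
  corrections are deliberately absent.
* The power formula is a normal approximation for binary outcomes; it
  ignores instrument count beyond the variance they jointly explain.
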