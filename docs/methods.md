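# Methods

This note documents the models, conventions and numerical choices behind
eubflow, and what the synthetic-data tests do and do not establish about
real data.

## Synthetic study conditions

The microbiome generator emulates a paired before/after 16S genus survey of
a therapy trial in a rodent arthritis model:

| parameter | default | units / meaning | rationale |
|---|---|---|---|
| `depth` | 10 000 | expected reads per sample | sequencing depth of the emulated first experiment batch |
| `n_subjects_per_arm` | 11 | animals per arm, sampled before (B) and after (A) | 55 animals split over 5 therapy arms |
| `arms` | MS, MTX, PLA, ANE, NOCIA | therapy arms | first-batch design; second-batch arms (CIA, MTXMS, NOCIAMS) available via `BATCH2_ARMS` |
| `n_genera` | 60 | genera in the table | typical detectable genus richness at 10⁴ reads |
| `frac_harmful/unharmful/unknown` | 0.3 / 0.3 / 0.4 | annotation mix | literature registries label roughly half of observed genera; the rest stay unknown |
| `eubiotic_effect` | MS +1.5, PLA +0.75, MTX −0.75, ANE 0, NOCIA 0 | per-arm log2 shift of annotated genera in after samples | signs mirror the qualitative arm ordering the pipeline is meant to resolve; 1.5 log2 ≈ 2.8-fold sits clearly above the FC > 2 differential threshold |
| `dispersion` | 0.2 | NB overdispersion φ in var = μ + φμ² | mid-range for 16S genus counts |
| `subject_concentration` | 200 | Dirichlet concentration of subject compositions around the cohort mean | moderate between-animal variation |

Counts are drawn as follows: one cohort composition ~ Dirichlet(1); per
subject a composition ~ Dirichlet(200 × cohort mean); per sample,
negative-binomial counts around depth × composition. In after samples the
unharmful genera are multiplied by 2^e and the harmful by 2^−e (e = the
arm's eubiotic effect) and the composition is renormalized, so planted
shifts ripple compositionally through unplanted genera as in real
relative-abundance data. A positive e is therefore *eubiotic by
construction*, and the truth object records each genus's label and per-arm
planted effect.

What the generator does **not** emulate: read-level errors, chimeras and
taxonomy misassignment (it starts at the genus table), batch effects beyond
library-size variation, correlated genus networks, and any coupling between
the planted shifts and diversity — the eubiotic shift changes evenness only
incidentally, so diversity behavior is tested with separately constructed
evenness shifts. Passing tests show the statistics behave correctly under
this model, not that real 16S data meet its assumptions.

Expression matrices are log-normal (baseline log2 means uniform on [3, 10],
residual sd 0.35 log2 units) with planted-set genes shifted in the treated
group. qPCR replicates are mean-preserving log-normal at a given CV; ELISA
standards come from known 4-PL parameters.

## Normalization

TMM scaling factors follow the weighted trimmed mean of M-values: features
zero in either library are excluded; log-ratios M are trimmed 30% per tail
and average log-abundances A 5% per tail (rank-based, average ranks on
ties); surviving M values are averaged with inverse asymptotic-variance
(delta-method binomial) weights; the reference library is the sample whose
75th-percentile count/library ratio is closest to the across-sample mean;
factors are rescaled to geometric mean 1. A pair with fewer than one usable
feature, or with max |M| < 1e-6, gets factor 1.

Scale invariance: multiplying *all* samples by a constant, or any single
sample when weighting is disabled, leaves factors unchanged exactly. With
weighting enabled, single-sample scaling perturbs the weights (they depend
on raw counts), so invariance holds only to O(1/depth); this matches the
reference formulation of the weights and is accepted as a limitation.

log2-cpm uses a library-size-scaled prior count (default 0.5):
log2((count + prior_j)/(L_j + 2·prior_j) × 1e6) with L_j the effective
(TMM-scaled) library size, so a zero count at prior 0.5 and L = 1e6 maps to
log2(0.5) up to O(prior/L). "Normalized abundance" elsewhere in the package
means count/(L_j) × 1e6 — cpm before the log.

## Moderated differential model

Two-group contrasts only (the study's comparisons are pairwise). Per
feature, the pooled residual variance s² on d = n₁+n₂−2 df is shrunk to
s²_post = (d₀s₀² + ds²)/(d₀+d); (d₀, s₀²) are estimated by moment-matching
log s² to the log of a scaled-F distribution (digamma/trigamma inversion,
Newton iteration for the inverse trigamma; 50 iterations, relative
tolerance 1e-8). When the observed spread of log s² does not exceed the
theoretical sampling noise, d₀ = ∞ and s₀² is the pooled mean variance (the
MLE in that limit). The total df is capped at the pooled residual df. The
implementation reproduces the R reference implementation's moderated t and
p to ~1e-4 relative on shared inputs (verified in the test suite).
Constant features get a finite moderated t through the prior variance;
with prior_df = 0 the ordinary two-sample t is recovered exactly.

The differential call is |fold change| > 2 and p < 0.05 on the *raw* p by
default: the calling rule names the (FC, P) pair without an FDR qualifier,
so raw p is the default and `use_adjusted` is provided. Whether precision
weights (voom scheme: lowess of √sd on average log2 count, span 0.5,
predicted at each observation's fitted log-count, weight = trend⁻⁴) were
applied to genus counts in the original analysis is not recoverable; both
paths are provided and default to trend-free moderation.

## Diversity

Shannon H in natural-log units; base only rescales H and cancels in the
deltas that are interpreted. No rarefaction by default (the analysed design
has near-constant depth); per-arm means are reported with SEM (NaN for
n = 1) and a signed delta against the pooled before-therapy samples
("after" mode) or as paired per-subject differences ("delta" mode) — which
of the two the original figure used is not recoverable, so neither is
asserted as canonical.

## Eubiosis statistic and contingency testing

Deltas default to arm-mean differences (after − before) of cpm-scale
TMM-normalized abundance; per-subject paired differences are available.
Genus scope defaults to genera flagged differential in *any* arm (the union
keeps both rows of a comparison populated); `--all-genera` covers the
alternative reading. Eubiotic / dysbiotic frequencies follow the strict
sign rule; zero deltas and unknown genera contribute to neither side, so
eubiotic + dysbiotic = Σ|δ| over non-unknown nonzero genera exactly.

**Integerization.** Fisher's exact test needs integer counts; the
frequencies are sums of continuous deltas whose absolute scale is
arbitrary. Write w_g = |δ_g| over the contributing genera and let each
genus vote for one side. Under a random-sign null, eub − dys = Σ ±w_g has
variance Σw². A 2×2 test treats a row with total count T as binomial-like
with variance T/4 per cell, i.e. SD(eub − dys) = √T. Scaling the
frequencies by c = Σw/Σw² gives T = c·Σw = (Σw)²/Σw² = n_eff (the Kish
effective sample size of the weights) and SD(c·(eub−dys)) = c·√(Σw²) =
√n_eff — the two variances agree exactly, so the test is a correctly
calibrated |δ|-weighted sign test. Scaling to the raw genus count instead
(Σw → n) understates the null variance whenever the weights are uneven and
was measured to reject a true null at ~0.20 instead of 0.05; it remains
available (`scale="per-genus"`), as do fixed numeric scales, but
"effective" is the default. Rounding is half-up; the unrounded frequencies
and the per-genus ledger are always retained.

Chi-square uses the Yates continuity correction by default (flag to
disable). Fisher p-values are computed by exact summation of the
hypergeometric pmf over the fixed margins; the two-sided p sums all tables
with point probability ≤ the observed one (×(1+1e-7) tolerance for
floating-point ties). A zero margin yields p = 1 with a warning and
chi-square NaN. The pairwise therapy matrix is asymmetric — cell (A, B)
tests "A more eubiotic than B" — with flags at p < 0.05.

Measured operating characteristics under the default study conditions
(200-replicate Monte Carlo, two arms, one-sided test at 0.05): null
rejection 0.01; power 0.86 at the documented planted effect (log2 1.5,
differential-scope genera). These numbers are recomputed by
`scripts/acceptance.py`.

## Enrichment

Three methodological variants per (context × gene set): exact
hypergeometric P(X ≥ k) of the differential-set overlap; the same with BH
adjustment across sets (threshold 0.05, mirroring a "corrected
P (Benjamini) < 0.05" convention); and a running-sum enrichment score —
hits increment by |stat|^p normalized over set hits (uniform at p = 0, the
default), misses decrement by 1/(N−|set|), ES = maximum-magnitude
deviation, clipped to [−1, 1] against cumulative rounding. The ES null
permutes *gene labels*, not samples: the target designs have too few
samples per group for a sample-permutation null; this overstates
significance when genes are co-expressed and is documented as a limitation.
The permutation p is (1 + #{|ES_perm| ≥ |ES|})/(n_perm+1); the significance
call for the grid additionally requires ES > 0 (enrichment toward the top).
NES divides ES by the mean permuted |ES|. Gene ids are matched by exact id
after upper-casing; cross-species symbol mapping is the user's
responsibility.

The robustness grid counts, per (spatiotemporal context × functional
phase), how many tested analysis variants (set variant × method, optionally
× molecular layer × batch) called the enrichment significant; untested
cells are NA, distinct from a tested zero, and duplicate variant
coordinates are rejected. The phase columns are user-declared via the
set → phase mapping; nothing is hard-coded about their number or order.

## Validation assays

qRT-PCR fold change between groups g and g′ is mean(g)/mean(g′) of
calibrator-relative expression (a 2^−ΔCt helper is provided; the ΔΔCt
variant is deliberately not asserted). The error range is the quadrature
(first-order delta-method) propagation of both groups' SEMs onto the
ratio: FC·√((SEM_g/m_g)² + (SEM_g′/m_g′)²); the per-group SEMs are also
reported, since the error-range convention of the original analysis is a
documented choice of this package. A single replicate yields NaN SEM.

The 4-PL curve is f(x) = upper + (lower−upper)/(1+(x/ec50)^slope), fit by
least squares (initial values: data range for the asymptotes, geometric
mean concentration for ec50, slope ±1 by monotonicity), reparametrized so
upper > lower; non-monotone standards raise a warning, non-convergence an
error. The inverse returns NaN outside the open asymptote range. ELISA fold
changes flag strictly: FC > cutoff or FC < 1/cutoff; a fold change exactly
at the cutoff is not flagged.

## Determinism and problem sizes

Every generator takes an explicit seed; no global random state is used, and
pipeline outputs are byte-identical across repeated runs of the same
configuration (floats are written at 10 significant digits; the provenance
record hashes the analysis configuration, excluding the output path).

Monte-Carlo checks use 200 replicates for calibration/power and recovery
contracts, 100 for the enrichment top-ranking rate, and 1000 draws for pure
invariant sweeps; exact-test oracles enumerate all 2×2 tables to N = 30 and
all hypergeometric configurations to N = 25. These sizes keep the full
suite to well under a minute of Monte Carlo per contract while holding the
binomial standard error of estimated rates near 1.5–3 percentage points.

## Known limitations

- Two-group contrasts only; no multi-factor designs or random effects.
- The harmful/unharmful registry is an input; the package does not mine
  literature, and genus-level labels inherit the coarseness of collapsing
  species-level knowledge.
- Gene-label permutation null for the ES (see above).
- BIOM containers are not read; tables travel as TSV.
- The synthetic generator's compositional renormalization means planted
  "null" genera are not exactly null in relative abundance when other
  genera are planted in the same arm — as in real compositional data; the
  null-calibration checks therefore use arms with no planted effects.
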