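# Methods

## Scope and model

`gcmeta` implements the allele-model meta-analysis of case–control SNP
association studies from aggregate genotype counts. The estimand is the
per-allele (additive) odds ratio of the effect allele: each individual
contributes two alleles, so a study's CC/CT/TT counts collapse to a 2×2
allele table, T = CT + 2·TT vs C = 2·CC + CT per arm. This treats the two
alleles of an individual as independent, which is exactly the assumption
under which the allele-level OR equals the per-allele genotype odds
parameter; it is adequate when control genotypes sit in Hardy–Weinberg
equilibrium — which is why the HWE screen precedes pooling.

Pooling is inverse-variance on the log-OR scale. The alternative
Mantel–Haenszel stratified estimator is implemented
(`pool_mantel_haenszel`, with the Robins–Breslow–Greenland variance) as a
cross-check; it agrees with the inverse-variance pool to two decimals on
the bundled table. Inverse variance is the default because the
heterogeneity (Q, I²), model-selection and Z-test stages are all defined
on inverse-variance weights, making the pipeline internally coherent.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.05 | CI level (95%) and pooled Z-test level |
| `q_p_threshold` | 0.1 | Q-test p below which heterogeneity is "significant" |
| `i2_threshold` | 50 (%) | I² above which heterogeneity is "large" |
| `hwe_threshold` | 0.001 | control-arm HWE screen level |
| `egger_alpha` | 0.01 | Egger intercept significance level |
| `correction` | `add_half_if_zero` | 0.5 to all four cells iff any is zero |
| `orientation` | `t_vs_c` | effect-allele orientation of the OR |

These defaults are the conventional thresholds of the genetic-association
meta-analysis literature and are what the bundled worked example uses.
Model selection is the strict conjunction: random effects iff
p_Q < 0.1 **and** I² > 50%. Note the asymmetry this creates: moderate
heterogeneity with a significant Q but I² ≤ 50% still pools fixed-effect.
The HWE screen *flags* failing studies (a warning and a column in the
report) but never drops them — exclusion is an analyst decision, and the
bundled table itself contains a control arm with HWE p ≈ 0.048 that
belongs in the pool at the 0.001 screen.

## Numerical choices

- The 0.975 normal quantile is fixed at 1.959964 so that 95% intervals
  are bit-reproducible; other levels use `scipy.stats.norm.ppf`.
- Pooled two-sided p-values are computed as `erfc(|z|/√2)` (accurate in
  the far tail) and clamped to the smallest positive float when `erfc`
  underflows (|z| ≳ 38), keeping p strictly positive. Text reports print
  p < 1e-15 as `"< 1e-15"`; `report.json` keeps the exact value.
- I² and τ² are floored at 0 (so Q ≤ k−1 gives I² = 0, τ² = 0 and the
  random-effects pool collapses onto the fixed-effect pool exactly).
- HWE χ² terms with expected count 0 (monomorphic arms) contribute 0;
  the statistic is then 0 and p = 1, which is the correct degenerate
  limit. An exact conditional HWE test (enumeration of heterozygote
  counts given allele counts, in log space) is available via
  `method="exact"` for small arms where the 1-df asymptotics are doubtful.
- Egger regression is solved by explicit normal equations. A numerically
  exact linear fit (residual variance below 1e-24 relative to the
  response scale) is treated as zero-residual: a zero intercept then
  yields t = 0, p = 1 rather than 0/0 noise. A design with no spread in
  precision (all SEs equal) is rejected as degenerate.
- Leave-one-out re-applies the full model-selection rule within each
  reduced subset rather than freezing the full-data choice; re-selection
  is the conservative reading and costs nothing.

## The simulator

`simulate_table` draws control genotypes multinomially from HWE
proportions ((1−q)², 2q(1−q), q²) and case genotypes from the tilted
distribution p_g ∝ HWE_g(q)·ψ^g — the closed-form case-genotype law of a
logistic model with per-allele odds ratio ψ — so ψ is the true value the
allele-model pipeline should recover as n → ∞. Between-study
heterogeneity enters as log ψᵢ ~ Normal(log ψ, τ²); q is held fixed
across studies (the simplest model matching the DerSimonian–Laird
framework being tested). Substreams are keyed on (replicate, study index)
via `numpy` `SeedSequence` spawn keys, so a study's counts are invariant
to how many studies follow it and all output is reproducible from one
integer seed.

What the simulator does *not* emulate: linkage disequilibrium, covariates
or population stratification, genotyping error, selective reporting.
Passing calibration tests therefore show that the *estimators* are
correct and well-sized under the stated sampling model — not that real
published studies are free of those artefacts.

Default experiment sizes (chosen once as realistic for this design):
calibration uses the bundled table's seven arm sizes with q = 0.09 (the
pooled control effect-allele frequency of the bundled studies) over
1000 replicates; recovery uses 7 × 50,000/50,000 arms at q = 0.1 over
200 replicates; the Egger size experiment uses k = 10 studies of
100–2000 per arm over 1000 replicates. All run in seconds.

## Design notes

- Input is aggregate counts only (TSV/CSV, one study per row, header-keyed
  columns); genotype-file formats (VCF/PLINK) are out of scope.
- Counts in the bundled table are the published per-genotype cells; their
  row sums reproduce the published per-study and grand totals (1019/1030,
  812/762, 376/277, 448/452, 483/495, 388/389, 529/421; 4055 and 3826
  overall), which the test suite asserts.
- Only the additive allele model is implemented; the types keep the
  genotype counts intact so dominant/recessive contrasts could be added
  without reshaping the data model.
- The per-study HWE p-values printed alongside published tables often come
  from heterogeneous sources (different tests, different rounding); the
  screen therefore asserts its own χ² computation and treats any published
  per-study HWE annotations as informational.

## Limitations

- Woolf SEs and the normal approximation degrade for very sparse tables;
  the continuity correction keeps the pipeline total but small-sample
  exactness is not claimed.
- DerSimonian–Laird τ² is the classic moment estimator; REML/Paule–Mandel
  alternatives and Hartung–Knapp adjustment are not implemented.
- Egger's test at k = 7 has little power and is approximately sized;
  the size experiment bounds its miscalibration (±0.04 at α = 0.1) but
  non-significance is weak evidence of absence of bias.
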