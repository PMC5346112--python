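# Methods

## Scope and model

The package implements the consensus-median evaluation used in
semiquantitative sIgE proficiency testing. There is no reference value for
sIgE against whole-extract allergens — detection systems disagree by
factors of two to seven on some allergen sources — so the scheme scores
each laboratory against the median of its own manufacturer collective
rather than against a common truth. The quantities the pipeline computes
(pass rates, per-collective CVs, bias ratios) therefore measure
*within-system reproducibility* and *between-system offset*, never
trueness.

## Evaluation pipeline

**Outlier exclusion.** A concentration is excluded iff
`x > 1.2 · top_calibration` and a class iff `class > top_class + 0.5`.
Both comparisons are strict: a value exactly 20 % above the calibration
ceiling, or exactly half a class above the class ceiling, is kept. The
filter runs before everything else; excluded rows carry a reason string
and never touch any median or CV (verified by a dedicated test comparing
medians with and without the excluded rows).

**Collectives.** Grouping is per (analyte, sample); a manufacturer needs
at least `min_collective_size = 4` participants for its own collective,
all smaller groups pool into `"other"`. The `"other"` pool is exempt from
the size requirement.

**Consensus median and pass band.** The median uses the standard
sort-and-midpoint convention (even counts average the two central
values). An optional clinically-relevant range `[lo, hi]` can restrict
the values entering the median; it must be supplied explicitly by the
evaluator per analyte/sample and defaults to *no* restriction — the
scheme's own procedure for choosing this range is not published, and
silently auto-trimming would invent method. A participant's own value is
included in the consensus it is scored against (simple pooled medians).
Scoring: `deviation = 100·(x − m)/m`; pass iff `|deviation| ≤ 25`
(inclusive). The comparison carries an absolute epsilon of 1e-12
percentage points so that values which are exactly on the band boundary
in real arithmetic do not fail through floating-point rounding. A
consensus median ≤ 0 makes the group *unevaluable* (scoring suppressed),
never a failure.

**Class evaluation.** Classes are scored with the same relative ±25 %
band, by default against one pooled median over all participants of the
survey. The separate-median exception ("completely different range") is
operationalized as: the collective's class median differs from the median
of all other participants by ≥ 2 classes, its 10–90 percentile range does
not overlap theirs, and the collective is the minority side. The minority
condition is needed to make the rule well-posed: with two collectives of
disjoint ranges the first two conditions hold symmetrically for both, and
the majority is by construction the "general" range the scheme compares
against. All three parameters are configurable. A relative band on an
ordinal 0–6 scale is coarse at the low end (neighboring classes 1 and 2
differ by 50–100 %), which is why simulated class pass rates sit below
concentration pass rates; this mirrors the scheme's design, not a defect
of the implementation.

**Certificates.** A participant passes a survey when every evaluable
outcome passed ("all" policy); a participant with no evaluable outcome is
reported unevaluable, not failed.

## Dispersion metrics

CV is `100 · sd(n−1) / mean` on the linear kU/L scale. No log transform:
the characteristic CV collapse of saturated collectives (all members
reporting the ceiling → CV exactly 0) only appears on the linear scale,
and censored values are deliberately *included* in the CV. The
`saturated_fraction` (values within relative 1e-9 of or above the
ceiling) is reported next to every CV so a 0 % CV can be told apart from
genuine agreement. CVs above 100 % are reported uncapped. The quality
flag is strict: `cv > 20` flags, exactly 20 % does not.

Dilution recovery `diluted_median · factor / concentrated_median` equals
1 on noiseless uncensored pairs and exceeds 1 when the concentrated
parent is censored — a cheap saturation diagnostic.

Bias recovery: for each manufacturer, the geometric mean over shared
surveys of (collective median / pooled all-participant median), plus the
CV of those per-survey ratios as a constancy statistic. The geometric
mean is the natural estimator for a multiplicative, lognormal-noise
offset. Estimates are *relative to the pooled median*, which is itself
pulled by the biased collectives; ratios between manufacturers are the
invariant quantity and are what the tests assert on.

## Synthetic panels

Each lab's report is `min(T, c · b · ε)` with true level `c`, device bias
`b`, ceiling `T`, and `ε ~ Lognormal(μ, σ)` scaled to unit mean:
`σ = sqrt(ln(1 + cv²))`, `μ = −σ²/2`, so `noise_cv` is the exact CV of
the noise factor. Multiplicative lognormal noise keeps reports
nonnegative and makes dispersion scale with level, as interlaboratory
sIgE data does. Dilution samples use `c(parent)/factor` before bias and
noise. Classes are derived from the *reported* concentration via the
class scale. Injected transfer errors (rate, multiplier uniform in
[5, 30] by default) corrupt the reported number after the assay and
therefore bypass the saturation clamp — this is what makes values above
the calibration ceiling possible at all, and what the exclusion filter
exists to catch.

Default study conditions (`default_config`): 17 surveys over 2010–2014,
three allergen sources, five-sample panels with 1:10 dilutions, and six
devices — four major collectives (biases 0.8/3.0/0.5/1.2, noise CVs
15–25 %, 25–60 labs) mirroring the qualitative pattern of published
timelines (one system severalfold high, one low, two near consensus),
plus two below-threshold systems exercising the "other" pool. True
high-serum levels are drawn once per survey from 5–80 kU/L (and 1–40 for
the second serum), the range published timelines span. A 100 kU/L ceiling
and class ceiling 6 apply everywhere.

Determinism: one integer seed governs a study; each survey uses a
substream seeded by `(seed, crc32(survey_id))`, so adding, removing or
reordering surveys never changes the draws of the others, and identical
seeds give byte-identical CSVs. An optional log-bias random walk
(`bias_walk_sd`, default off) models slow calibration drift; it exists so
the constancy statistic has something to detect in tests.

What the simulator does **not** model: immunochemistry (epitope profiles,
cross-reactive carbohydrates, extract composition), correlated errors
between labs sharing a lot or an operator, non-lognormal heavy tails,
class-only reporters, and participation churn. Passing tests therefore
demonstrate that the *scoring machinery* is correct and that its
statistics behave as designed under the stated noise model — not that any
real scheme's published tables are reproduced (participant-level EQA data
is not public).

## Numerical and design choices

- **Class scale.** Only the 0.35 kU/L negativity cutoff is fixed by the
  evaluation rules; the remaining default boundaries are the conventional
  CAP ladder 0.35/0.7/3.5/17.5/50/100 (classes 1–6), configurable as a
  list of six cut points. Boundary membership is lower-inclusive
  (0.35 → class 1) because negativity is defined as *below* 0.35.
- **Percentiles** (box plots, divergence rule) use linear interpolation
  between order statistics, fixed so geometry tests are stable.
- **CV before/after exclusion.** Computed after outlier exclusion (the
  dispersion table takes the filtered results); callers can pass the
  unfiltered table to get the other convention.
- **Reader policy.** A row with one unreadable numeric field keeps its
  other valid value and is reported; rows violating invariants (negative
  concentration, no value at all) are dropped and reported with their
  file line number. Nothing is ever silently discarded.
- **Problem sizes.** The bundled study runs 17 surveys × 160 labs ×
  3 analytes × 4 evaluated samples ≈ 33 k results; bias-recovery checks
  use 2 devices × 50 labs × 10 surveys; oracle-equivalence tests sweep
  1000 randomized tables of 2–25 values. These sizes give stable
  statistics (bias recovered within a few percent) while the whole suite
  runs in well under a minute per module.

## Known limitations

- The ±25 % band applied to ordinal classes is the scheme's stated rule,
  but it behaves erratically below class 3; an absolute-distance band
  would be the obvious alternative and is a one-line configuration away
  (`band` on the class path).
- `recover_bias` assumes the pooled median is a stable reference; with
  few, similarly-biased collectives the estimates shift together (only
  between-manufacturer ratios are reliable).
- Timeline ordering uses the ISO `YYYY-MM` panel date; two surveys in the
  same month order by survey id.
- The CLI's `timeline` subcommand currently orders by survey id (the
  simulated ids sort chronologically); supplying explicit dates for
  arbitrary real ids requires the library API.
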