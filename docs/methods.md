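# Methods

This note records the models behind each module, the defaults and why they
were chosen, the numerical decisions, and the limits of what the synthetic
data can demonstrate.

## Survival (`lop.survival`)

Kaplan–Meier estimation and the log-rank test are delegated to lifelines;
`KMCurve` exposes the product-limit estimate at the distinct event times
with at-risk and event counts. The median is the smallest event time with
S(t) ≤ 0.5 and is explicitly undefined (None) when censoring keeps S above
0.5. Percent changes are reported raw, at one decimal, and as
half-away-from-zero rounded integers, since headline lifespan contrasts
are conventionally printed as whole percentages.

The maximal-lifespan quantile test pools the *observed* lifespans of both
groups (censored animals are excluded with a logged count — the design
assumes essentially fully observed aging cohorts), takes the empirical
quantile as the order statistic at ⌈q·n⌉ (1-indexed; determinate under
ties, no interpolation), and counts per group the animals with lifespan
strictly greater than the threshold — "still alive at the age at which
only 10% remain". The 2×2 table is tested with a two-sided Fisher exact
test (conservative; the sidedness choice matters only near the boundary).
With fewer than 10 pooled animals the pooled quantile is unstable and the
function refuses. Each group's own q-quantile lifespan and its percent
change are also reported; whether published "maximum lifespan increased by
X%" figures refer to exactly this summary is ambiguous, so the quantity is
exposed without asserting equivalence.

The cohort generator uses Gompertz mortality h(t) = rate·exp(shape·t) —
the standard two-parameter law for laboratory-rodent aging — with inverse-
CDF sampling, an exact exponential limit at shape = 0, and non-informative
censoring by independent uniform truncation of the death time. The default
shape 0.008/day corresponds to a mortality-rate doubling time of ~87 days;
group rates are solved from target medians in closed form. The mirror
cohort uses the four diet-by-genotype groups with sizes 108/105/97/102 and
medians 636/850/931/1050 days (intermediate-diet medians are plausible
interpolations; only the ad-libitum medians anchor published contrasts).

## Differential expression (`lop.diffexpr`)

The detection filter retains a probe if its summarized log2 value exceeds
a floor (default log2(64) ≈ 6) in at least one sample. This is a stand-in
operating on the summarized matrix: probe-level detection calls (MAS 5.0
Wilcoxon) require CEL-level data and are out of scope.

The moderated t follows the standard empirical-Bayes construction: with
per-probe variances s²_g on d residual df, marginally s²_g ~ s₀²·F(d, d₀);
matching the mean and variance of log s²_g (digamma/trigamma corrections,
Newton inversion of the trigamma function) gives closed-form (d₀, s₀²) —
deterministic, no optimizer. Under-dispersed variances give d₀ = ∞ and a
single pooled variance; `prior_df` can force the ordinary-t (d₀ = 0) or
fully pooled limits, which the tests use as oracles. p-values come from
the t distribution on d₀ + d df (normal when d₀ = ∞).

BH adjustment runs across **all retained probes before collapse** (the
FDR family is the tested probe sets). Collapse keeps the minimum-p probe
per gene, ties broken by larger |log2fc| then lexicographic probe id.
Classification applies FDR < 0.05 jointly with linear fold change > 1.5 or
< 0.67. A separate `significant` flag (FDR alone, no fold-change
condition) marks the genes excluded from enrichment backgrounds: the
canonical accounting (13,201 expressed − 365 differentially expressed =
12,836 background) is only coherent if "differentially expressed" for
background purposes ignores the fold-change dead zone, since the direction
lists sum to 305. The mirror expression study therefore plants 141 strong
up, 164 strong down (±2 log2, i.e. 4-fold) and 60 mild (±0.42 log2,
1.34-fold — significant but inside the dead zone) genes at residual SD
0.06, chosen so planted effects are recovered with probability ≈ 1 and no
null gene passes the joint rule. Note that BH step-up necessarily admits
~α·R false FDR-only discoveries among 24,840 null probes (~30 genes here),
so the computed background lands at ≈ 12,800, within half a percent of the
canonical count — an intrinsic property of FDR control, not a defect of
the generator.

## Set concordance (`lop.setcompare`)

Ranked lists order genes by descending signed fold change, ties broken by
gene id for determinism. The enrichment statistic is the tie-corrected
standardized rank-sum Z (positive = set members at higher scores);
p-values use exact enumeration when the smaller group has ≤ 10 members and
scores are tie-free, otherwise the normal approximation with continuity
and tie correction. Set genes absent from a list are dropped per
comparison (platforms differ across experiments) and reported via
`n_set_in_list`; a set covering the whole list, or missing entirely, is
explicitly "not evaluable". The screen tallies experiments with p < α and
sign matching the set's direction. The ranked-experiment generator shifts
member scores by direction·concordance·effect (effect = 1 SD); concordance
0 is an exchangeable null, and 0.8 gives essentially certain detection for
a 164-gene set in a 2,000-gene list — the tally calibration claims are
therefore about the screen's plumbing, not marginal power.

## Term overrepresentation (`lop.funcenrich`)

Annotations propagate to ancestors once at load time (true-path rule) so
term counts are well-defined before conditioning. The walk processes terms
children-before-parents (topological order of the child→parent DAG); when
a parent is tested, genes annotated to its raw-p-significant direct
children are removed from both k and K. Child significance uses raw
p < α — no FDR inside the walk, matching the published conditional
algorithm — while a BH q across tested terms is attached afterwards as a
separate reporting column. Terms with fewer than 3 background genes after
conditioning are skipped as untestable. Real ontology releases are out of
scope; version-dependent term counts cannot be reproduced, so the term
stage is validated by construction (propagation, monotonicity of
conditioning, planted-leaf recovery) rather than against published lists.

## Motif scanning (`lop.motif`)

Scores are probability sums: column score of base b is its pseudocounted,
background-weighted probability, so all entries are nonnegative and "80%
of the maximum score" is well defined (log-odds scores can be negative,
making fractional-of-maximum thresholds ill-posed). A match strictly
exceeds min_frac·maxScore ("exceeded" ⇒ ties excluded). Both strands are
scanned by default (minus-strand windows score against the
reverse-complement matrix and are reported at their forward start);
overlapping matches all count. Any window containing a masked base
(lowercase soft-masking or N, one convention for both) is ineligible.
`scanned_length` is the number of eligible window starts on the region —
identical on either strand because masking is strand-symmetric — so it
stays bounded by the region length and is the natural per-gene exposure
covariate. Dictionary assembly pools sources and filters motifs shorter
than 4 bases or with homopolymer consensus ("repetitive"); `build_pwm`
itself accepts any length so short toy motifs remain constructible.

## Motif enrichment (`lop.motifenrich`)

Per motif: logit P(member) = β₀ + β₁·count + s(scanned length), fit by
ridge-stabilized IRLS (ridge 1e-8, tolerance 1e-8, ≤ 100 iterations). The
smooth is a fixed-df natural cubic basis (df = 4, knots at quantiles of
the observed lengths) rather than penalized smoothing with data-driven df:
a fixed basis is deterministic and the reduction oracles (constant length
⇒ plain logistic GLM) are exact. Degenerate lengths shrink the basis
gracefully to a linear term or nothing. A constant count covariate is
flagged inestimable and excluded from the BH family; quasi-complete
separation (|η| > 30) is flagged and the penalized-fit p reported with a
warning. Two-sided p with the direction carried separately. Only expressed
genes enter — callers pass the background explicitly. Published per-motif
p-values depend on real mm10 promoter sequence and a proprietary
dictionary, neither shippable, so validation is by reduction oracles,
type-I calibration and planted recovery.

## Phenotypes (`lop.phenotype`)

HOMA-IR = glucose(mg/dl)·insulin(µU/ml)/405. RQ = VCO₂/VO₂. Tolerance
curves are 100·g(t)/g(0). Fold induction uses the standard ΔΔCt with the
sign convention 2^(−ΔΔCt), so lower treated Ct (more transcript) gives
fold > 1 — consistent with strongly induced detoxification genes showing
1000-fold induction; replicate Ct values are averaged per (sample, gene)
before ΔCt, and the reference gene is a per-run parameter, never inferred.

## Orchestration, IO and scale

All interchange formats are plain text (TSV/GMT/FASTA/JASPAR-style PFM
blocks) with `# key=value` headers carrying the seed and a configuration
hash; reruns are byte-identical and coordinates are 1-based inclusive.
The pipeline's default synthetic scale (3,000 genes, 13 ranked
experiments, 20 motifs over 400 promoters of 2 kb) keeps a full run in
seconds; the mirror specs reproduce the full probe bookkeeping (45,101
probes) when requested. Test simulations use hundreds of replicates at
modest n — enough for the calibration assertions' Monte-Carlo margins.

## What the synthetic data does not show

Gompertz cohorts with independent uniform censoring cannot validate
behaviour under informative censoring or cohort heterogeneity. The
expression generator is Gaussian and homoscedastic per study, so the
moderated t's advantage over the ordinary t under variance heterogeneity
is exercised only in the dedicated hierarchical-prior test. Promoters are
i.i.d. background with planted instances — no repeat structure, GC
heterogeneity or positional bias — so scanning is validated for
correctness, not for realism of match statistics. Passing tests show the
algorithms implement their definitions and recover planted truth under
the stated conditions; they say nothing about any particular real
dataset.
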