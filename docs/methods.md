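# Methods

This note documents the models, estimators and numerical choices behind
`dipackit`, what the synthetic-data generator does and does not emulate, and
the known limitations.

## Differentiation pattern classification

A gene's trajectory between two cell states A and B is summarized by its
position in the plane of log2 fold changes versus a fixed reference state
(PHH): x for A, y for B. Classification is a fixed decision table (README)
with one symmetric cut-off `t` on both axes, gated by a significance call on
the direct B-vs-A contrast.

Design choices, made where the design was genuinely open:

* **Change gating uses the direct B-vs-A contrast**, not the difference
  y − x of the two reference contrasts. The direct contrast provides a
  proper standard error for the transition itself; y − x compounds the
  errors of two contrasts that share the reference samples.
* **Cut-off default t = 1.0** (2-fold). The cut is a biological relevance
  threshold, not a significance threshold; it is configurable and exported
  alongside every classification so plots can draw the dotted lines actually
  used.
* **Genes with a significant transition that both start and end inside the
  reference window are assigned DPG0.** This keeps the eleven labels a
  total partition and preserves the reading of DPG0 as "no relevant
  deviation from the reference".
* **The full tested gene universe is classified**, not a pre-filtered DEG
  list: the no-change groups (DPG0/1/6) are themselves informative and serve
  as the enrichment background.
* `alpha_change` defaults to 0.05 with no minimum-effect requirement
  (`min_abs_change = 0`); both are configurable.

The DPG→supercluster map is fixed: SC1 = {7,8,9,10}, SC2 = {2,3,4,5},
SC3 = {0,1,6}. The supercluster asymmetry question — do downregulated genes
preferentially reach the reference window rather than overshoot it — is an
exact two-sided binomial test of the DPG7+8 count within SC1's moving genes
against p = 1/2, two-sided by summing all outcomes with point probability at
most that of the observed count.

The decision table satisfies, and the test suite asserts, an exact mirror
symmetry: negating both axes and swapping the change direction maps
2↔7, 3↔8, 4↔9, 5↔10, 1↔6 and fixes 0.

## Differential expression

The negative binomial is parameterized by mean μ and dispersion α with
variance μ + αμ². Size factors follow the median-of-ratios construction:
for genes positive in all m samples, s_j = median_g K_gj / (∏_j' K_gj')^(1/m),
rescaled to geometric mean 1. When no gene is positive everywhere the caller
must opt in to a positive-entry pseudo-reference.

Per gene, the Wald test uses:

* normalized group means m_A, m_B; log2FC = log2((m_B + c)/(m_A + c)) with
  pseudocount c = 0.5 for stability at zeros;
* a size-factor-aware moment estimator of dispersion. For K_j ~ NB(s_j μ, α)
  the within-group variance of K_j/s_j has expectation μ·mean(1/s_j) + αμ²,
  so α̂ = (v_pool − μ̂·mean(1/s))/μ̂², floored at 1e-8. Ignoring the
  mean(1/s) factor biases α̂ and the standard errors whenever library sizes
  are heterogeneous;
* heavy dispersion moderation: α̂ is shrunk 90% of the way toward the mean
  dispersion over expressed genes. With four replicates per group the
  per-gene estimate carries roughly six degrees of freedom; a Wald z built
  on so noisy a standard error behaves like a t statistic read off a normal
  table and rejects ≈ 7% at nominal 5%. Strong moderation (weight chosen in
  the empirical-Bayes spirit of limma-style prior degrees of freedom well
  above the residual six) restores calibration while keeping a 10% per-gene
  component for genuinely atypical genes. An untrimmed mean is used for the
  prior because the trimmed mean of the right-skewed dispersion estimates is
  biased low, which alone inflates the type-I error;
* delta-method variance Var(log2(m + c)) ≈ Var(m)/((m + c) ln2)², with
  Var(m) = (μ·mean(1/s) + αμ²)/n per group, and a two-sided normal p-value.

Calibration: on null simulations at the generator's default dispersion
(α = 0.05, n = 4 vs 4, 10,000 genes) the empirical fraction of p < 0.05 lies
within the 99% binomial envelope of 0.05 across independent seeds (the
acceptance suite checks one such simulation). At dispersions ≥ 0.2 the
normal approximation to the skewed log-mean at n = 4 leaves a residual
inflation of roughly half a percentage point — a documented limitation; an
exact NB test is out of scope.

Known property: the additive pseudocount makes log2FC exactly invariant to
rescaling one sample's counts only in the limit c → 0, because the
geometric-mean reference of the size factors shifts all normalized counts by
a global factor c_scale^(1/m) that an additive constant cannot cancel. At
c = 0.5 and typical counts the effect is ≲ 0.01 log2 units.

Benjamini–Hochberg adjustment is the classical step-up procedure
(statsmodels `fdr_bh`), order-preserving, validated in the tests against a
direct step-up implementation.

## Enrichment and GRN impact

Overrepresentation of a gene set in a DPG uses the one-sided upper-tail
hypergeometric p-value P(X ≥ overlap) on the universe of *classified* genes
— conditioning on tested genes avoids detection bias from unexpressed
annotation members. Gene-set members outside the universe are dropped during
harmonization. BH families are one collection × one DPG column; the
multiplicity scheme is a package choice and is documented rather than
inherited. The reported odds ratio is the sample cross-product (ad)/(bc)
with a Haldane 0.5 correction applied only when a cell is zero — conditional
maximum-likelihood estimators used by some tools will differ, so published
odds ratios are matched only approximately in re-analyses.

The union-enrichment question (a TF's targets versus the union of several
DPGs) is a two-sided Fisher exact test on the 2×2 table; a zero margin makes
the odds ratio undefined (NaN, warned) while the p-value is still returned.
One-sided Fisher and the hypergeometric tail are the same sum — the suite
asserts the identity to 1e-12 on random tables.

**GRN impact score — an explicit reconstruction.** No canonical formula
exists for "the influence of a TF within a DPG"; this package defines, and
documents as its own choice:

    score(target) = regulon_weight × |log2FC(B vs A)|,
    summary(TF)   = median over regulon ∩ DPG of score,

with TFs admitted to the ranking only when their regulon is
hypergeometrically overrepresented in the DPG (BH-adjusted p < α). The
transition contrast (not the endpoint contrast) supplies the fold change
because the score is meant to explain the *movement* of the DPG. The score
is monotone in edge confidence and effect size, carries log2 units, scales
linearly under global weight rescaling (leaving ranks unchanged), and the
median makes the summary robust to single outlier targets. Unweighted (plain
GMT) regulons default to weight 1. Absolute score values are not comparable
across studies that use different regulon resources.

## Canalicular kinetics

Traces are baseline-corrected (mean of the first `baseline_points` frames,
default 3, subtracted) and smoothed with a centered moving average of odd
width (default 3) whose window shrinks at the edges. Amplitude is the peak
of the corrected, smoothed trace, floored at 0. Half-time is the first
linear-interpolated crossing of amplitude/2; it is *undefined* (NaN, never
an error) when the amplitude is 0 or the half level is not reached inside
the observation window. Time-to-half-maximum was chosen over an exponential
fit because it is assumption-free; a least-squares fit of b + A(1 − e^{−kt})
is provided as a cross-check (`fit_exponential`, half-time ln2/k).

Practical accuracy notes, derived from the synthetic recovery experiments:

* the baseline window should cover only pre-onset frames — if the signal is
  already rising, the baseline absorbs part of the rise and biases both
  amplitude and half-time upward;
* the capture window should span several half-lives; at three half-lives the
  observed maximum under-represents A by 12.5% and the half-level crossing
  shifts accordingly. With five pre-onset frames, a 9-frame smoothing window
  and a well-saturated 60-frame window, the median relative half-time error
  at 5% multiplicative-scale noise is below 3%.

Group comparisons: Kruskal–Wallis across all groups, pairwise two-sided
Mann–Whitney with BH adjustment; the exact null distribution is used for
untied arms of ≤ 8 traces, the tie-corrected normal approximation otherwise.
Per-group n, median and IQR are reported, and traces with undefined
half-times are excluded with their count surfaced. Canalicular lumen areas
are consumed as a table (segmentation is out of scope); the equivalent
circular diameter 2·sqrt(area/π) is provided for comparison with in-vivo
calibers.

## Synthetic data

The generator emulates a four-group bulk RNA-seq design — iPSC, WT-HLC,
KO-HLC, PHH, four biological replicates each, ~20,000 genes by default —
with:

* NB counts at a single shared dispersion (default 0.05, a typical bulk
  value; the dataset's true dispersion profile is not published);
* base means log-uniform on (20, 2000) normalized counts;
* per-sample size factors log-uniform on (0.5, 2), exercising normalization;
* planted DPG blocks: group-mean log2 offsets of ±effect_size (default 4,
  far outside the default cut t = 1) or ±effect_size/2 for the
  "toward-but-short" shapes (DPG2/7), arranged so the noise-free offsets map
  exactly to the intended label. Default block sizes mirror the intervention
  analysis's published DPG sizes where printed (e.g. DPG8 = 453, DPG7 = 237,
  DPG10 = 342), with 100 for the unprinted DPG1/6;
* the iPSC group receives an independent ±effect_size offset per planted
  gene so all four populations are transcriptionally distinct (the planted
  truth refers to the WT→KO transition versus PHH);
* gene sets: one set per planted block with ≥ 80% of members inside the
  block, plus uniform decoys; optionally weighted, GMT-serializable;
* traces: b + A(1 − e^{−k(t−lag)}) on a regular grid over [0, 60] with
  Gaussian noise, optional lognormal per-trace parameter spread
  (`param_cv`), and an optional pre-onset hold (`t_lag`) emulating
  pre-stimulus acquisition frames.

What it does **not** emulate: gene–gene correlation, gene-specific
dispersion trends (mean–dispersion relationships), GC/length biases, batch
structure, single-cell zero inflation, outlier samples, photobleaching or
focus drift in traces. Passing recovery tests therefore demonstrate
correctness of the pipeline's logic and calibration of its statistics under
the stated model — not robustness to every artifact of real data.

Reproducibility: every generator is a pure function of its seed
(`numpy.random.default_rng`); the pipeline expands one global seed per stage
through a fixed counter scheme, and `run_all` writes numeric outputs at six
significant digits with a JSON manifest (config SHA-256, seed, library
versions) so identical configurations reproduce byte-identical bundles.

## Problem sizes

The shipped tests and the acceptance script run at desk scale: 2,000–10,000
genes, 500–2,000 planted genes, 200 traces, 20,000 permutation draws —
sizes chosen so the full suite completes in seconds while keeping every
statistical check's Monte-Carlo error well below its decision margin.
Dataset-derived published quantities (absolute DPG sizes, specific odds
ratios, PCA percentages) depend on the accession data and are not
reproduced here; the package recomputes their *statistical machinery* on
synthetic inputs with known truth.
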