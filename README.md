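# dipackit

Differentiation pattern clustering (DiPaC) of gene-expression trajectories,
with downstream gene-set overrepresentation, gene-regulatory-network (GRN)
impact scoring and bile-canalicular transport-kinetics quantification — plus
a synthetic-data generator with planted ground truth so the whole pipeline is
testable without any sequencing data.

## The problem

Hepatocyte-like cells (HLC) differentiated from induced pluripotent stem
cells (iPSC) are a candidate replacement for primary human hepatocytes (PHH)
in drug screening and liver disease models. Current differentiation
protocols, however, produce a *hybrid* state: individual HLC co-express
hepatocyte and intestinal gene programs, driven by intestinal master
regulators such as CDX2. Evaluating an intervention (for example a *CDX2*
knockout) requires asking, gene by gene: did expression move *toward* the
reference cell type, *away* from it, overshoot it, or not move at all — and
which regulators and functional programs dominate each class of behaviour?

`dipackit` answers this with a supervised, logic-based classification rather
than unsupervised clustering, so every gene's label has a fixed, auditable
meaning.

## The method

**DiPaC.** Each gene is placed in the plane of log2 fold changes versus the
reference state (PHH): `x = log2FC(A / PHH)`, `y = log2FC(B / PHH)`, where
(A, B) is either (iPSC, HLC) for differentiation or (WT-HLC, KO-HLC) for an
intervention. A change call from the direct B-vs-A contrast (`padj <
alpha_change`, direction by sign) gates the classification, and a symmetric
cut-off `t` (default 1.0 log2 units, i.e. 2-fold) on both axes carves the
plane into eleven differentiation pattern groups:

| change | region                 | DPG | reading                                |
|--------|------------------------|-----|----------------------------------------|
| none   | \|y\| ≤ t / y < −t / y > t | 0 / 1 / 6 | no relevant transition       |
| up     | x < −t, y < −t         | 2   | rising toward the reference window     |
| up     | x < −t, \|y\| ≤ t      | 3   | risen into the window                  |
| up     | x < −t, y > t          | 4   | overshot above it                      |
| up     | x ≥ −t, y > t          | 5   | induced although not below it          |
| down   | x > t, y > t           | 7   | falling toward the window              |
| down   | x > t, \|y\| ≤ t       | 8   | fallen into the window                 |
| down   | x > t, y < −t          | 9   | overshot below it                      |
| down   | x ≤ t, y < −t          | 10  | suppressed although not above it       |

DPGs aggregate into superclusters SC1 = {7–10} (down in B vs A), SC2 = {2–5}
(up), SC3 = {0, 1, 6} (no change). Whether downregulation preferentially
*reached* the reference window (DPG7+8) rather than overshooting it (DPG9+10)
is tested with an exact two-sided binomial test against p = 1/2.

**Differential expression.** A self-contained negative-binomial moments
model: median-of-ratios size factors, `log2FC = log2((m_B + c)/(m_A + c))`
on normalized group means (pseudocount c = 0.5), method-of-moments gene
dispersions heavily moderated toward the genome-wide mean, delta-method
standard errors, Wald normal p-values and Benjamini–Hochberg adjustment.
Any external DE tool's table can be substituted — DiPaC only consumes
(log2FC, padj) columns.

**Enrichment and GRN impact.** Per (gene set, DPG): one-sided hypergeometric
overrepresentation on the universe of classified genes, BH within each DPG
column; Fisher's exact test for DPG-union versus TF-target questions. The
GRN impact score of a TF in a DPG is the median over its regulon members in
that DPG of `weight × |log2FC(B vs A)|`, reported only for TFs whose regulon
is significantly overrepresented in the DPG.

**Canalicular kinetics.** Fluorescence traces of dye secretion into bile
canaliculi are summarized per trace by maximum amplitude (peak of the
baseline-corrected, smoothed signal) and half-time (first crossing of half
the amplitude, linearly interpolated) — for a saturating exponential
`A(1 − e^{−kt})` the half-time is ln2/k. Groups are compared with
Kruskal–Wallis and exact pairwise Mann–Whitney tests.

## Worked example

```bash
python examples/01_simulate_and_classify.py
```

simulates 4,000 genes × 16 samples with 60 genes planted per DPG and prints:

```
genes per differentiation pattern group:
dpg
0     3398
1       62
...
8       60
...
planted-label recovery: 98.8% of 600 genes
SC1 asymmetry: 120/241 favorable, exact binomial p = 1
```

Planted labels are recovered for ~99% of genes at realistic dispersion
(0.05) with four replicates per group; the balanced design puts equal
numbers in DPG7+8 and DPG9+10, so the asymmetry test is null (p = 1) — an
asymmetric design drives it toward 0. The other examples cover enrichment
and TF ranking (`02`), kinetics (`03`) and the serialized end-to-end bundle
(`04`). A thin CLI mirrors the stages: `dipackit run --config cfg.yaml`,
plus `deg`, `dipac`, `enrich`, `impact`, `kinetics`, `pca` and `synth`
subcommands.

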