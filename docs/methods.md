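# Methods

`metabocurate` re-implements, as a tested library, the analysis chain of an
untargeted positive-mode LC-MS plasma metabolomics study of dietary
supplementation with cocoa shell extract (CSE): animals are sampled at
baseline, day 4 and day 7 of supplementation, each sample injected in
triplicate alongside extraction blanks, and the aligned peak table is
curated, tested for differential abundance, explored chemometrically, and
interpreted through pathway and network enrichment.  This note documents the
models, the defaults and why, the numerical choices, and what the synthetic
validation does and does not establish.

## Peak-table curation

Raw input is a features x runs intensity matrix with missing cells meaning
*not detected* (never zero) plus a run design.  The chain, in order:

1. **Replicate collapsing.** Triplicate injections of one (subject,
   timepoint) sample are collapsed to their median, ignoring missing
   replicates; an all-missing triplicate stays missing.
2. **Blank filter.** A feature is removed when its maximum height across
   samples is *less than* `k` times its mean height in the extraction blanks
   (default `k = 3`).  Missing-in-blank counts as zero signal, so features
   absent from blanks always survive this step.
3. **Intensity filter.** Removed when the maximum sample height is less
   than `I_min` counts (default 1000).
4. **Identification filter.** Features without a library identification —
   operationally, no name and no InChIKey — are removed; spectral matching
   itself is outside this package's scope.
5. **Prevalence filter.** Removed unless detected in at least `n_min`
   samples of *some one* timepoint (default 3).  Counting happens on
   collapsed samples, not injections.
6. **Half-LLD imputation.** The limit of detection (LLD) of a metabolite is
   its minimum detected intensity over all retained samples; remaining
   missing cells are filled with LLD/2.  The LLD is computed globally
   (all groups) after the filters and before merging — the most
   reproducible choice where no window is prescribed.
7. **Adduct/duplicate merging.** Features sharing an identity key
   (InChIKey, else the (name, adduct) pair) are merged; the representative
   is the member with the highest overall median, merged cell values are the
   member-wise maximum (idempotent, preserves "height" semantics; the audit
   keeps member lists so sums can be recomputed).  Features with no usable
   identity never merge.

All three thresholds use strict "less than" for removal, so equality
retains.  Every step logs removal counts into an audit dictionary; the
blank and intensity filters provably commute (both depend only on
per-feature maxima and blank means), and tightening any threshold can only
shrink the survivor set — both are property-tested.

## Differential abundance

Only baseline and day 7 are compared; day 4 is carried for chemometrics but
excluded from inference (it is not distinguishable from baseline in this
design).  Per metabolite, values are log10-transformed (imputation
guarantees positivity; the base only shifts scale) and subjected to an
**exact two-sided Wilcoxon signed-rank test** on per-subject pairs: zero
differences are dropped, ties in |difference| are handled with average
ranks, and the null distribution is enumerated exactly (dynamic programme
over doubled ranks, conditional on the tie pattern) for n ≤ 25, with a
tie-corrected, continuity-corrected normal approximation above.  The
upstream description of the test as a "repeated/paired Mann–Whitney" is
read as this test, the standard paired nonparametric analogue.  P-values
are Benjamini–Hochberg adjusted across metabolites; significance is
`q ≤ α` with α = 0.05.

The effect size is the **signed fold change** of the group medians:

    FC = m_day7 / m_basal            if m_day7 ≥ m_basal
    FC = −(m_basal / m_day7)         otherwise

so |FC| ≥ 1 always and an exact tie reports +1.  This convention
reconciles the signs of every row of the published differential table.  A
Shapiro–Wilk screen per metabolite is reported as a diagnostic only; the
pipeline always proceeds nonparametrically.

**Subclass roll-up.** Metabolites are grouped by chemical family
(PubChem-style subclass; unannotated ones pool into "unknown"); each member
contributes one log10(m_day7/m_basal) ratio, the subclass test is a
signed-rank of those ratios against zero, BH-adjusted across subclasses.
Singleton subclasses report p = 1 and are flagged low-power.

### Recomputability of printed fold changes

The packaged differential table prints medians to 2–3 significant figures.
Recomputing FC from printed medians therefore reproduces the printed value
at one decimal only where the medians are large relative to their printing
precision (the five anchor rows used as acceptance targets do); rows with
day-7 medians near 0.02–0.05 recompute with large absolute deviations.  The
audit operation reports match counts and the worst mismatch instead of
pretending precision the source does not carry; *sign* agreement holds for
every row, including the four rows whose day-7 median truncates to 0.00
(checked by median ordering).

## Chemometrics

- **Scaling.** Each metabolite is z-scored across samples (typification)
  and divided by its maximum |z| to land in [−1, 1]; zero-variance
  metabolites are dropped with a warning.  This representation feeds the
  heatmap and Ward clustering.
- **Sphericity.** Bartlett's test on the metabolite correlation matrix,
  χ² = −(n−1−(2p+5)/6)·ln det R with p(p−1)/2 df; a singular correlation
  matrix (more metabolites than samples) returns p = 0, i.e. sphericity is
  firmly rejected.
- **PCA.** Unit-variance (correlation) PCA of samples — metabolites are
  standardised internally, as the R implementation the field uses does by
  default — via SVD.  Loadings are *standardized loadings*
  (eigenvectors scaled by singular values: variable–component correlations);
  scores are scaled so `scores @ loadings.T` reconstructs the standardised
  matrix exactly at full rank.  The first K = 2 columns (configurable) are
  **varimax-rotated** by Kaiser-normalised iterative pairwise rotations
  (convergence 1e-6); the same rotation is applied to the scores, so the
  reconstruction identity and per-metabolite communalities are preserved
  (the pairwise update is cross-checked in tests against an independent
  SVD-based rotation).  Component signs are fixed so each column's
  largest-|loading| entry is positive.  Influential metabolites are ranked
  by maximum |rotated loading| over the K components, ties broken by id.
- **Clustering.** Agglomerative Ward (minimum-variance, ward.D2 on
  Euclidean distances) on either axis, via `scipy.cluster.hierarchy`;
  merge heights are non-decreasing and the dendrogram-reordered matrix is
  exported as TSV.

Replicates are included in chemometrics (the scaled matrix is built from
the imputed replicate-level table restricted to curated metabolites), while
differential statistics run on replicate-collapsed samples.

## Bioavailability (three-set algebra)

"Detected in a group" means at least one *measured* (non-imputed) value in
that group — imputed cells encode non-detection by construction.  The three
sets {extract, plasma baseline, plasma day 7} are partitioned into the
seven exact regions; **bioavailable** compounds are the region present in
the extract and at day 7 but absent at baseline.  Percentages are reported
against both the union and each input set (published accounts mix the two
denominators).  An audit mode checks externally reported region counts for
joint consistency and flags violations without reconciling them — the
published counts themselves are not jointly consistent.

## Pathway enrichment

The compound **importance** within a pathway is relative betweenness
centrality: betweenness divided by the pathway's maximum; pathways without
topology, or where no node has positive betweenness (complete graphs), fall
back to uniform importance 1/K.  The **pathway impact** of a hit set is
Σ importance(hits) / Σ importance(all members).  Over-representation is the
upper-tail hypergeometric probability P(X ≥ k) for k hits in a pathway of
size K given n mapped input compounds in a universe of N (the library's
compound union; unmapped inputs are dropped and counted).  The
**enrichment ratio** is k/(K·n/N).  P-values are BH-adjusted across
pathways; zero-overlap pathways are kept at p = 1 so the correction sees
the whole family.  Impact carries no p-value of its own.

## Network diffusion

A layered undirected knowledge graph (pathway / module / enzyme / reaction
/ compound) is scored from the indicator vector b of input compounds by
solving the regularised-Laplacian system `(L + λI) s = b` with λ = 1.
Because Laplacian rows sum to zero, λ·Σs = |input| exactly — asserted at
1e-9 as a runtime invariant — and `(L + λI)` is an M-matrix, so scores are
non-negative and monotone in the input set.  Calibration comes from a
permutation null: the input set is redrawn uniformly from the compound
layer `niter = 100` times (the "iterations" of the upstream tool read as
Monte-Carlo permutations; the solve itself is direct) and
`p_emp(v) = (1 + #{null ≥ observed}) / (niter + 1)`, whose floor is
1/(niter+1) ≈ 0.0099 — smaller published node p-values cannot arise from
100 permutations and are not reproduced here.  Nodes are ranked by
ascending p, then descending score, then id (deterministic cuts); the top
`nlimit = 150` induce the reported subnetwork, with pathway-type nodes
listed separately.

## Synthetic studies

The generator emulates the study the analysis assumes, with defaults chosen
once to mirror the published design and printed summaries:

| parameter | default | basis |
| --- | --- | --- |
| subjects | 8 | unstated upstream; small-n exact-test granularity matches the printed minimum p ≈ 0.005 |
| timepoints x replicates | 3 x 3 | stated design (baseline/day 4/day 7, triplicate injections) |
| extraction blanks | 4 | typical batch practice |
| endogenous metabolites | 60 | desk-scale stand-in for 244 |
| extract-only compounds | 20 | stand-in for the extract-unique fraction |
| bioavailable spikes | 3 | the published three-compound finding |
| basal-only / day7-only | 12 / 3 | scaled from the published Venn regions (52 and 12 of 244) |
| affected (down / up) | 12 / 4 | ≈30% of metabolites change, decreases ≈3:1 over increases |
| effect ratios | log-uniform 1/150–1/2 (down), 2–20 (up) | brackets the printed fold-change distribution |
| intensity model | log-normal, baseline mean 10^3.8–10^5.2 | typical QTOF count scales |
| subject effect / replicate CV | 0.15 log10 / 15% | realistic biological and injection variability |
| detection floor | 500 counts | left-censoring below the 1000-count filter |
| blank contamination | 10% of endogenous features at ~100 counts | low-level background |

Missingness is purely left-censoring at the detection floor (matching the
half-LLD imputation rationale), not random dropout.  Day 4 applies effects
at quarter strength on the log scale, keeping it close to baseline as the
published chemometrics found.  Studies can plant one violation of each
curation rule (blank-ratio, intensity, identification, prevalence,
duplicate adducts), constructed so that each planted feature is removed by
exactly its intended filter; the truth manifest records the expected
removal counts, and membership flags are read off the emitted matrices so
the manifest is verifiable by direct inspection.

What passing on synthetic data does **not** show: the generator has no
retention-time drift, batch effects, correlated metabolite families, or
spectral ambiguity, and its sample sizes are desk-scale.  Raw-data-dependent
published figures (244/180 detected compounds, 51.3% PC1+PC2 variance,
84.8/91.8/68.0% detection rates, real pathway and diffusion p-values) are
therefore not asserted anywhere; the packaged tables are instead checked by
internal audits (ppm-error consistency; Venn count consistency flagging).

### A note on discrete p-values

With 8 subjects the exact signed-rank two-sided p-value is supported on 19
points (largest point mass 0.102).  Its null distribution is *sub-uniform*
(P(p ≤ α) ≤ α, with equality at achievable levels) — the property that
matters for error control, and the one the test suite asserts, along with
exact uniformity of the randomized p-value.  A literal Kolmogorov–Smirnov
test of the raw p-values against U(0,1) necessarily fails at these sample
sizes (the KS distance of the discrete null itself is 0.102): discreteness,
not miscalibration.

## Numerical choices

- Element masses are frozen IUPAC/CODATA monoisotopic values; +1 ions
  subtract one electron mass, so "+H" is exactly a proton; "[Cat]+" species
  (permanent cations) are the written formula minus one electron.  Vendor
  "calculated m/z" columns deviate from first principles by up to ~2e-5;
  recomputation of such columns is an audit, not a gate.
- Unicode minus ("−") is accepted everywhere a sign may occur (numbers and
  adduct strings); decimal points only.
- BH adjustment via `statsmodels.multipletests`; hypergeometric tail via
  `scipy.stats.hypergeom.sf(k−1, N, K, n)`; Ward via `scipy` linkage
  (`ward.D2` semantics); betweenness and Laplacians via `networkx`.
- Degenerate inputs: empty pathway files, inputs disjoint from the library
  universe or the graph's compound layer, nonpositive medians, K larger
  than the matrix rank, and edges to undeclared nodes are all hard errors
  with the offending entity named.
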