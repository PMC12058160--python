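# Methods

This note documents the models, the numerical choices, the defaults and
the known limitations of `methdriver`, stage by stage.

## Input contracts

All tables are tab-separated (gzip accepted by extension). The
expression matrix (genes × samples, log2 scale) and beta-value matrix
(CpG probes × samples, values in [0, 1]) must share sample identifiers
with the sample sheet (`sample_id`, `group ∈ {tumor, normal}`); the
pipeline operates on the lexicographically sorted intersection and
requires at least 5 tumor and 5 normal samples. Beta values outside
[−0.01, 1.01] abort the run (they indicate M-values or another wrong
scale); in-range values are clamped into [10⁻³, 1 − 10⁻³] because the
beta likelihood is undefined at exactly 0 or 1 — clamping rather than
dropping preserves the sample count. Duplicate gene rows are collapsed
to the row with the highest mean expression (deterministic, logged).
The probe manifest maps probes to genes one row per pair — a probe on a
bidirectional promoter legitimately maps to several genes, and each
pair is tested independently; no cross-gene arbitration is attempted.
As a BED alternative, the name field must encode
`probe_id|gene_symbol[|region_class]`, since BED reserves no columns
for the gene symbol or region class.

## Differential expression

The built-in test is a two-sided Wilcoxon rank-sum on log2 expression
(tumor vs normal) with Benjamini–Hochberg correction across all genes;
a gene is a DEG when FDR ≤ 0.05 and |log2FC| ≥ 1 (both configurable).
The exact permutation null is enumerated when both groups have ≤ 12
tie-free samples, otherwise the normal approximation is used.
Zero-variance genes get p = 1 and are logged, not dropped. A
nonparametric test was chosen deliberately: it needs no count-model
assumptions, and users with a dedicated DEA (DESeq2, limma, ...) can
load its table via `load_dea` instead — the rest of the pipeline only
consumes `gene, log2fc, p, fdr`.

## Gene regulatory network

Mutual information is estimated between each DEG and every gene after
equal-frequency discretization into `B = max(2, ⌊√n⌋)` bins; ties
straddling a bin boundary are collapsed onto one bin so identical
values always share a code (this keeps MI(X, X) maximal and makes the
MI of a constant gene exactly 0). The network is built on tumor
samples only (flag `tumor_only`): the regulatory state of interest is
the disease; mixing in normals injects a strong tumor/normal axis that
correlates all deregulated genes with each other. Per regulator, the
edge threshold is the (1 − α) quantile (α = 0.05) of the pooled null MI
obtained from `n_perm = 100` seeded permutations of the regulator's
values against all candidate targets; pooling across targets stabilizes
the quantile at moderate permutation counts. By construction ~α of
null edges survive; downstream scores must (and do) tolerate that
noise floor.

## Upstream-regulator score and mediator calling

For regulator g and process P with signature genes s(P) (each annotated
with the direction expected under process activation),

    z(g, P) = Σ_{i ∈ targets(g) ∩ s(P)} s_i / √|targets(g) ∩ s(P)| ,

where `s_i = +1` if sign(log2FC_i) matches the expected direction and
−1 otherwise; z = 0 on an empty intersection and targets absent from
the DEA table are skipped (logged). MI edge weights are kept in the
regulon but deliberately not used in z: the unweighted form is simple,
directly testable by hand, and insensitive to the MI scale. Exactly
two processes drive the pattern step — one cancer-growing
(proliferation) and one cancer-blocking (apoptosis); additional
signature processes are scored but ignored there. A gene is a putative
OCG when z_growing ≥ +t and z_blocking ≤ −t (t = 1 by default,
symmetric), a putative TSG in the mirrored case, otherwise not a
mediator. Because z is a normalized ±1 sum, t = 1 means "one
concordant target beyond noise, in σ units"; raising t trades
sensitivity for precision.

## Beta-mixture methylation model

Per CpG, tumor beta values x₁..xₙ (n ≥ 10 required) are modeled as a
K-component beta mixture, K ∈ {1, 2, 3}; K = 3 admits the richest
pattern (normal-like + hypo + hyper). Parameters are the component
mean μ_k ∈ (0, 1) and precision φ_k (α = μφ, β = (1 − μ)φ).

*Initialization* partitions the sorted values into K contiguous blocks
and moment-matches each block — deterministic, so a fixed seed is
sufficient for exact reproducibility (the `seed` argument is reserved
for randomized restarts). *E-step* responsibilities use the beta
densities in log space. *M-step*: the mixing weights update exactly;
for (μ_k, φ_k) a method-of-moments proposal from the
responsibility-weighted moments is evaluated against the current
parameters on the component's weighted log-likelihood — which depends
on the data only through (Σr·log x, Σr·log(1 − x), Σr), so the check is
O(1) — and is accepted only if it does not decrease it. Because every
accepted step improves the EM minorant, the observed log-likelihood is
non-decreasing at each iteration by construction (a generalized EM);
the suite asserts this at tolerance 10⁻⁸ for every fitted probe. At
convergence (gain < 10⁻⁶ or 500 iterations) each component is polished
by a safeguarded Newton ascent in (log α, log β) — the exact weighted
MLE — which can only increase the likelihood further. A pure moment
M-step would be marginally cheaper but does not guarantee monotonicity;
a full MLE M-step at every iteration is needlessly slow. Components
converging below 1% weight are pruned and the probe refitted with
K − 1. Model order minimizes BIC = −2ℓ + (3K − 1)·ln n. Cohort runs
batch all probes through one vectorized EM program (probes × samples ×
components), which is numerically equivalent to per-probe fitting.

Differential-methylation values are `dm_k = μ_k − mean(normal betas)`.
A component is hypomethylated when dm ≤ −0.10, hypermethylated when
dm ≥ +0.10 (`dm_min = 0.10`, the established beta-difference convention
in mixture-based methylation callers; configurable). Probe summary:
Hypo, Hyper, Dual (both directions present across patients), or None.
Mixtures are fitted on tumors only and normals only define the
reference mean, mirroring the disease/control asymmetry of the design.

## Functional CpG–gene pairs

For each probe with an abnormal component and each mapped gene
(promoter rows only by default — the "regular mode"), tumor samples
assigned by maximum responsibility to abnormal component(s) are
compared with samples assigned to normal-like component(s) on the
gene's expression (two-sided rank-sum); when no normal-like component
exists the comparison falls back to normal-tissue samples. Hard
assignment keeps the groups deterministic and auditable. Pairs with
fewer than 3 samples on either side are skipped (logged). BH runs
across all tested pairs; `assoc_fdr ≤ 0.05` defines the functional
pairs, and the full tested table is emitted alongside as the raw
mixture-layer output.

## Evidence integration and driver calling

Per mediator, functional CpGs are counted by state. Dual CpGs are
counted but never determine the gene state: the gene is Hypo only if it
has ≥1 hypo and 0 hyper functional CpGs (symmetrically for Hyper),
Mixed when both directions occur, Dual-only or None otherwise. The
evidence table maps (gene state, putative role) to Agreement_OCG /
Agreement_TSG / Conflicting / Mixed / NoEvidence; only agreement genes
enter the final driver set. Two deliberate generalizations: (i) Mixed
genes are excluded from drivers — requiring a consistent methylation
direction across a gene's CpGs extends the same-state rule used for the
evidence comparison to the driver call itself; (ii) a gene with only
dual CpGs yields NoEvidence — a dual state supports both directions at
once and is therefore reported (counted, plotted) but never counted as
agreement. The evidence categories partition the mediators exactly;
this conservation is asserted on every run.

## Evaluation

Against a census restricted to a stated gene universe: TP = predicted ∩
census, FP = predicted \ census, FN = census \ predicted; precision =
100·TP/(TP+FP), sensitivity = 100·TP/(TP+FN). The universe defaults to
all genes input to the DEA — the defensible cohort-specific choice
(these are the genes the method could have predicted); a custom
universe can be supplied. Fisher's exact test (two-sided, exact
hypergeometric) runs on [[TP, FP], [FN, neither]]; the reported odds
ratio is the sample (a·d)/(b·c) with the Haldane–Anscombe +0.5
correction on all cells when any cell is zero — closed-form and
oracle-testable, unlike the conditional-MLE odds ratio some Fisher
implementations report (values differ slightly for extreme tables).

## Synthetic cohorts

`simulate_cohort` generates the full input set plus a truth table.
Defaults: 30 tumor and 20 normal samples; 10 planted hypomethylated
OCGs and 10 hypermethylated TSGs among 200 null genes; methylation
shift δ = 0.4 beta units, expression shift Δ = 2 log2 units; 2 promoter
probes per gene; beta precision φ = 30; expression noise SD 0.5. A
fraction (0.7) of tumor samples carries each driver's aberration —
chosen so the mean log2FC (0.7·Δ = 1.4) clears the DEG cutoff and both
mixture groups (21 vs 9 of 30) exceed the 3-sample minimum of the
association test. The same abnormal samples carry the methylation and
the expression shift, matching the sample-level coupling the
association test assumes. Because the planted drivers model
independent aberration events, the abnormal subsets are drawn with a
cap on their pairwise overlap deviation (±max(2, 1.5 SD) around the
expected overlap): at 30 tumors, unconstrained subsets occasionally
overlap far from expectation, which would correlate two drivers'
expression programs — and hence their regulons — by small-sample
accident rather than by design. Each driver regulates 16 dedicated
signature genes per process (growing-process targets follow the
driver's deviation from baseline, blocking-process targets mirror it),
sized so the planted z ≈ 16/√32 ≈ 2.8 clears t = 1 with a wide margin
against the α-level false-edge noise of the permutation-thresholded
network; 20 uncoupled decoy signature genes per process keep the
signatures non-trivial in driver-free cohorts. Infeasible
configurations (abnormal fraction × tumors < 3) are rejected.

What the generator does *not* emulate: realistic 450K probe geography
and probe-type effects, tumor purity and cell-type composition,
copy-number confounding, correlated null genes, and count-level
expression noise. Passing tests therefore demonstrate the pipeline's
internal correctness and its behavior under the stated generative
model, not performance on real cohorts.

Defaults are sized so a full two-layer run on the default cohort takes
on the order of a minute on one CPU; the reduced cohorts used in
fast-running tests shrink gene counts, not the mechanism.

## Known limitations

- The rank-sum DEA ignores count overdispersion structure; import a
  dedicated DEA table when exact parity with count-model results
  matters.
- The URA score is an unweighted concordance z; regulons with very few
  signature targets are noisy, and the α-level false-edge floor of the
  network propagates into z (quantified above).
- Beta-mixture model order is capped at 3; more complex intra-tumor
  methylation heterogeneity is collapsed into the nearest state.
- Hard sample assignment discards assignment uncertainty near component
  boundaries; probes with heavily overlapping components can produce
  unstable groupings.
- The sample odds ratio with Haldane correction is reported, not the
  conditional-MLE odds ratio.
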