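# Methods

This note documents the models and procedures implemented in `degmeta`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic study conditions do and do not
demonstrate.

## Ingest and harmonization

Each study contributes one DEG table per tissue comparison (NAWM, active
lesion, or chronic active lesion vs control white matter). Fold changes
are stored on log2 scale. Published tables do not share a reporting
convention, so the source scale is declared per table (`fc_scale`):
linear fold changes convert as log2(x) for x > 0 and, for the common
sign-magnitude convention for down-regulation, −log2(|x|) for x < 0
(so a reported "−2.0" means two-fold down, log2FC = −1).

The default significance filter is the conjunction |log2FC| > 1 and
p < 0.05 (strict inequalities, matching the usual phrasing "log2 fold
change > |1|"). Three alternative modes encode per-study exceptions:
linear |FC| ≥ 2.5, nominal p < 0.025, and Benjamini–Hochberg adjusted
p < 0.05; these ship as a preset keyed by study and are overridable in
configuration. A record missing the field its filter mode requires is
excluded and counted, never silently kept, so
kept + removed + missing-field always equals the input count.

Within a study, a gene reported in several comparisons keeps the record
with the largest |log2FC|. Exact-magnitude ties with opposite signs have
no principled winner; they are resolved deterministically by comparison
priority CAL > AL > NAWM > other (later lesion stages carry the larger
lists) and flagged, trading silent arbitrariness for reproducibility.
Genes are keyed by Entrez id downstream; symbols are display-only, and
the symbol→id map is a local two-column table with manual overrides
taking precedence.

## Vote-count ranking

For each gene the per-study merged lists are tallied into: the modal
fold-change direction, the number of lists agreeing with it (`n_agree`),
the sample total and mean log2FC over exactly those agreeing lists, and
the number of lists containing the gene at all. A gene up in three lists
and down in one therefore counts as agreeing in three; only an exact
up/down tie makes it *inconsistent* (n_agree = 0). This majority rule is
a design choice: it lets the tally report both a meaningful agreement
count for mostly-consistent genes and a separate inconsistent category,
mirroring how published rankings present both.

Ranking is a descending lexicographic sort on (n_agree, n_samples_agree,
|mean_fc_agree|) — the three criteria in order of relevance — with
remaining ties broken by ascending Entrez id so output files are
byte-reproducible. "Samples" means tissue samples by default; a
`samples_unit="donors"` switch uses donor counts where records carry
them, since studies report both and the choice is not obvious a priori.

The overlap profile counts genes per agreement level k; the headline
statistic is `total_multi`, the number of genes with a consistent
direction in at least two lists.

## Co-expression connectivity (WGCNA-lite)

The null model's sampling weights are per-gene connectivity scores from
a weighted co-expression network built on an expression matrix that
serves as the gene universe:

* Pearson correlation between gene rows (≥ 3 samples; zero-variance rows
  are an error);
* soft thresholding: unsigned adjacency a = |cor|^β (signed
  ((1+cor)/2)^β available); β is the smallest candidate power (default
  scan 1..20) whose scale-free topology fit reaches R² ≥ 0.8, where the
  fit regresses log10 p(k) on log10 k over 10 connectivity bins and is
  sign-corrected (negated for a positive slope). If no power reaches the
  target the best power is used with a warning; degenerate inputs (e.g.
  an identity correlation, where every power yields zero connectivity)
  score −1 and take the same warning path rather than erroring.
* topological overlap: TOMᵢⱼ = (ℓᵢⱼ + aᵢⱼ)/(min(kᵢ,kⱼ) + 1 − aᵢⱼ) with
  ℓᵢⱼ the shared-neighbour product sum and kᵢ the adjacency row sum;
* connectivity kᵢ = Σⱼ≠ᵢ TOMᵢⱼ (TOM row sum). This, rather than the
  adjacency row sum, is the default because the weighting is explicitly
  TOM-based; the adjacency basis is available as a config alternative.

Numerical notes. The shared-neighbour product is computed with
non-optimized `einsum` so the optional row-blocked evaluation is
bit-identical to the single-pass one (BLAS matmuls are not: their
accumulation order depends on the operand shape). Adjacency matrices are
symmetrized exactly ((A+Aᵀ)/2) after a 1e−10 tolerance check to absorb
correlation round-off. One caution on intuition: raising a
shared-neighbour weight aᵢᵤ raises ℓᵢⱼ but also kᵢ, so TOMᵢⱼ is only
guaranteed monotone in shared-neighbour weights while the *other* gene
supplies min(k); the property test asserts exactly that regime.

Genes that appear in DEG lists but not in the expression universe
receive the universe's median connectivity (and are flagged): dropping
them would shrink the sampling frame asymmetrically relative to the
observed lists.

## Monte Carlo overlap null

Given observed list sizes, each iteration draws one same-sized gene set
per study from the universe, independently across studies, without
replacement within a list. Weighted sampling draws genes with
probability proportional to connectivity via Gumbel-top-k keys
(log wᵢ + Gumbel noise, take the top s), which is distributionally
identical to drawing genes one at a time with renormalized
probabilities but vectorizes across iterations. Per iteration the
number of genes present in ≥ 2 lists is recorded (and per exact level
k); summaries are the mean, SD, per-level means and 95% intervals taken
as empirical 2.5/97.5 percentiles of the integer counts.

The null records gene *identities* only — fold-change direction is not
simulated by default — while the observed statistic counts
direction-consistent genes. The test is therefore conservative: the
null counts every co-occurrence the observed statistic would split into
consistent and inconsistent halves. A `simulate_directions` option
attaches independent random signs per list and counts modal-direction
overlap instead, for sensitivity analyses.

The p-value uses the add-one permutation convention
p = (exceedances + 1)/(iterations + 1), so it is never zero; when no
draw reaches the observation the result is flagged as a bound and
rendered "< 1/iterations" (e.g. "< 0.0001" at 10,000). Weighted and
uniform runs in a comparison share the same Gumbel key stream (matched
seeds), so their mean difference is not noise-dominated. Identical
configurations (including seed) reproduce bit-identical nulls.

An exhaustive enumerator over all subset combinations serves as the
independent oracle for tiny universes (≤ 8 genes, ≤ 3 lists) in the test
suite; no closed-form p-value is attempted for realistic sizes.

## PPI subnetworks and hubs

The interaction graph is a STRING-style edge list thresholded at a
combined score of 400 (medium confidence; configurable — the threshold
used by any given published analysis is rarely stated). MCODE follows
the canonical description: vertex weight = density of the highest k-core
of the node's closed neighbourhood × that core's k (nodes under the
degree cutoff weigh 0); seeds in decreasing weight order (ties by node
id); breadth-first expansion admitting unassigned neighbours with
weight ≥ seed × (1 − node score cutoff) up to the depth limit; a node
joins at most one cluster. Clusters lacking a k-core at the configured
k are discarded; haircut (default on, as in the reference
implementation) trims the cluster to its 2-core; fluff (default off)
adds neighbours whose closed-neighbourhood density exceeds the density
cutoff. Default parameters: degree cutoff 2, node density cutoff 0.3,
node score cutoff 0.2, k-core 4, max depth 100.

Betweenness centrality is normalized per connected component by
(n−1)(n−2)/2, so a component's central node can reach 1 regardless of
the rest of the graph. Candidate hubs are nodes with normalized
betweenness > 0.5; the scope is the whole multi-study network by default
(a per-cluster scope is available for sensitivity), and each cluster's
main hub is its member with maximal betweenness, ties to the lower node
id.

## Perturbation evidence

Classification is a pure truth table over 5 perturbation classes × 3
outcomes: reduced activity (knockout, knockdown, inhibiting treatment)
improving the disease model, or increased activity (overexpression,
activating treatment) worsening it, is *detrimental* evidence; the
converse pairings are *beneficial*; no model effect is *no-effect*. Net
per-gene calls are majority-based, with equal nonzero detrimental and
beneficial counts reported as *mixed* and only-no-effect as *none*; raw
counts are always reported alongside, so unbalanced mixed evidence is
never hidden behind a single label.

## Synthetic study conditions

The generator emulates, at desk scale, the data situation the pipeline
is designed for. Defaults: a 2,000-gene universe in 50 samples; 8
co-expression modules; 9 studies; 50 planted genes, each present in any
given list with probability 0.6 and a fully consistent direction;
background list members drawn uniformly with 50:50 random directions;
all records drawn to pass the default filter (|log2FC| > 1, p < 0.05).

*Expression.* Gene g in module m is √(ρₘ)·l_g·fₘ + √(1−ρₘl_g²)·ε with
standard normal factor and noise, per-gene loadings l ~ U(0.9, 1.1), so
within-module correlation is ρₘ·lᵢ·lⱼ in closed form and across-module
correlation is 0. Module sizes grow geometrically (ratio 1.25) and
strengths fall linearly (factors 1.35 → 0.85 around the configured
level, clipped at 0.95): equal-size, equal-strength blocks would give a
bimodal connectivity distribution that never passes the scale-free fit,
whereas this heterogeneity — like real transcriptomes' uneven modules —
yields fits of R² ≈ 0.81–0.91 with chosen powers around 8–13 while the
pair-weighted within-module correlation stays in [0.6, 0.8] at the 0.7
default.

*Study lists.* Sizes are drawn uniformly from 20–40 genes. This is
deliberately small relative to the universe, and smaller than published
lists scaled proportionally, for a quantitative reason: the observed
statistic counts direction-consistent multi-study genes while the null
counts identity overlap only, so background co-occurrence (half of which
is direction-consistent by chance) works against the planted signal.
With ~30 planted genes present per list, chance identity-overlap must
stay well below the ~50-gene planted contribution even under the
weighted null, whose mean is inflated by the connectivity weight
dispersion (measured factor E[w²]/E[w]² ≈ 1.5) — which the 20–40 range
achieves with a comfortable margin (null mean ≈ 23–32, SD ≈ 4, observed
≈ 50). The configured planted-set size intentionally exceeds the
minimum list size; the generator warns about this regime and realized
list sizes equal max(drawn size, planted genes present), so the
presence probability is honored exactly and the null always uses
realized sizes.

*PPI.* Planted complexes are Erdős–Rényi-dense blocks (intra-edge
probability 0.9) over disjoint gene subsets, sizes 12/14/16 by default,
with background wiring (probability 0.05) on every pair involving a
background gene. Distinct complexes are not wired directly to each
other: under seeded expansion with a seed-relative weight threshold, a
single edge between two equal-density complexes merges them into one
cluster, so direct inter-complex edges would make recovery fail for
reasons unrelated to the detector's quality. Even so, recovery is not
guaranteed: the expansion threshold is relative to the complex's
max-weight node, and when that maximum is an outlier the complex's
low-degree tail is clipped (best-match Jaccard dips to ~0.7 on a
minority of seeds). The default sizes are the most robust of the ranges
examined.

*Perturbations.* Each gene receives 1–3 experiments generated as the
inverse of the classification truth table for its assigned true effect,
so tallying must recover that effect exactly.

What passing these conditions does *not* show: real DEG lists are
direction-correlated in their background (shared biology, shared
platforms), list sizes span two orders of magnitude, expression modules
are not clean latent-factor blocks, and published PPI networks carry
score-dependent ascertainment structure. The synthetic conditions test
the machinery — calibration of the null, correctness of the statistics,
recovery of a known signal — not the field-realism of any particular
published dataset.

## Degenerate inputs and tie-breaking (summary)

* log2FC of exactly 0 tallies as "down"; records are expected to pass a
  fold-change filter first, which excludes the case.
* Empty gene-id map → configuration error; unmapped symbols are
  reported per study and excluded downstream.
* Correlation requires ≥ 3 samples and nonzero row variance.
* Soft-threshold scan with no power reaching the target warns and takes
  the best power; all-degenerate scans (identity correlation) resolve
  the same way.
* Weighted sampling requires strictly positive finite weights;
  connectivity weights of 0 are floored at a tiny positive value.
* MCODE seed order, cluster ordering, and all hub ties are broken by
  node id; ranking ties by Entrez id.
* Percentile CIs are computed with the "nearest" method so bounds are
  observed integer counts.

## Problem sizes used by the test suite and acceptance script

The full pipeline runs at the default conditions above with 10,000 null
iterations (~15 s). The calibration check uses 200 replicates of a
1,000-iteration null over a 600-gene universe with five lists of
100–140 genes — sizes chosen so the discrete overlap statistic is
fine-grained, because the add-one p-value is super-uniform by about one
point mass of the statistic and a coarse statistic would read as
spuriously non-uniform. Exhaustive-enumeration checks use universes of
≤ 8 genes and ≤ 3 lists; betweenness oracles use graphs of ≤ 12 nodes.
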