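# degmeta

Integrative prioritization of differential-expression gene (DEG) lists
from independent transcriptomic studies — built around the kind of
evidence available for multiple-sclerosis (MS) white-matter pathology,
where a dozen studies each publish a DEG list (lesion tissue vs control
white matter) but raw data are rarely available, so classical
meta-analysis of effect sizes is impossible.

The package is for computational biologists who need to turn a pile of
heterogeneous published gene lists into a ranked, statistically defended
candidate set:

1. **Ingest** per-study DEG tables, harmonize fold changes to log2 scale,
   apply per-study significance filters (the shared rule |log2FC| > 1 and
   p < 0.05, with study-specific exceptions), map symbols to Entrez ids
   and collapse each study to one record per gene (largest |log2FC|).
2. **Vote-count ranking**: genes are ordered by (i) the number of study
   lists reporting them with the same fold-change direction, (ii) the
   total samples behind those agreeing comparisons, (iii) the mean
   |log2FC| among them.
3. **Weighted Monte Carlo overlap null**: is the observed number of
   multi-study genes more than chance? Lists of the observed sizes are
   resampled 10,000 times from the gene universe — uniformly, and
   weighted by each gene's co-expression connectivity *k*ᵢ = Σⱼ TOMᵢⱼ
   (topological overlap from a WGCNA-style network built on an expression
   matrix standing in for the universe) — giving an empirical null for
   the count of genes in ≥ 2 lists and the p-value
   p = (exceedances + 1)/(iterations + 1), reported as "< 0.0001" when no
   null draw reaches the observation.
4. **Network stage**: multi-study genes are projected onto a STRING-style
   protein–protein interaction graph; MCODE clustering (degree cutoff 2,
   node density cutoff 0.3, node score cutoff 0.2, k-core 4, max depth
   100) extracts dense subnetworks and betweenness centrality calls hub
   genes (candidates: normalized betweenness > 0.5).
5. **Perturbation evidence**: published in-vivo perturbation experiments
   (knockout/knockdown/inhibition vs overexpression/activation in EAE
   models) are classified as detrimental / beneficial / no-effect per gene
   via a fixed truth table and tallied into net calls.

A first-class synthetic-data generator (`degmeta.synthetic_data`) emits
every input — block-correlated expression, study lists with a planted
consistently-deregulated gene set, a PPI graph with planted complexes, a
perturbation table with known effects — so the whole pipeline is testable
offline with known ground truth.

## Worked example

Run the full pipeline on the default synthetic study conditions (2,000
gene universe, 9 studies, 50 planted genes present per study with
probability 0.6):

```bash
$ degmeta demo --seed 1 --iterations 10000
observed multi-study genes : 50
weighted null              : mean 26.14 (SD 4.19), p < 0.0001
uniform null               : mean 18.41, p < 0.0001
precision at |planted|     : 1.0
```

Reading: 50 genes were reported with a consistent direction in ≥ 2 study
lists. Under the connectivity-weighted null, chance co-occurrence yields
only 26.1 such genes on average (the weighted null sits well above the
uniform null's 18.4 — co-expressed genes recur across resampled lists,
which is exactly why the weighted null is the harsher, more biologically
honest reference). None of 10,000 null draws reached 50, so the overlap
is significant at p < 0.0001, and all 50 planted genes occupy the top 50
ranks (precision 1.0).

The same run is available programmatically:

```python
from degmeta.pipeline import run_synthetic_study
from degmeta.synthetic_data import SynthesisConfig

res = run_synthetic_study(SynthesisConfig(seed=1), iterations=10_000)
res.ranked[:10]              # top-ranked GeneSupport records
res.test_weighted.format_p() # '< 0.0001'
```

`degmeta synth --seed 1 --out fixtures/` writes the complete fixture set
(expression TSV, per-study DEG TSVs, id map, PPI edge list, perturbation
table, manifest with ground truth) for use with external tools.

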