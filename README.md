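# immucluster

Immunogenomic analysis of bulk tumour transcriptomes, built for cohorts of
paediatric nervous system tumours and other low-infiltration cancers. The
package is aimed at computational biologists who want to classify tumour
immune microenvironments from RNA-seq without relying on deconvolution
signatures contaminated by tumour-cell expression, and to relate those
classes to immune-repertoire and mutation-burden readouts.

It implements, as tested library code with a CLI:

- **Tumour-clean immune genesets** — from purified cell-type reference
  panels, genes expressed above the per-population 75th percentile of
  median-centred, MAD-scaled expression, specific to immune over
  non-immune populations by ≥ 2 MAD units, free of tumour expression
  evidence, and assigned to one major immune cell type by ≥ 2 independent
  annotation sources.
- **ssGSEA consensus immune clustering** — per-sample enrichment
  `ES = Σ_i (P_in(i) − P_out(i))` with rank weights `(N − i)^0.25`,
  followed by consensus k-means (200 subsamples of 80% of samples,
  k = 2..8) with the consensus matrix `M_ij = co-clustered / co-sampled`
  and k selected by minimizing PAC, the fraction of `M_ij ∈ (0.1, 0.9)`;
  clusters are named Paediatric Inflamed / Myeloid Predominant / Immune
  Neutral / Immune Desert from their centroid profiles.
- **Immune read percentage** — a monotone calibration (3-parameter
  logistic, isotonic fallback) fitted on synthetic tumour–immune mixtures
  at known fractions, converting immune enrichment scores to percentages.
- **Repertoire analysis** — observed and asymptotic diversity (Chao1
  richness `S + ((n−1)/n) f₁²/(2f₂)`; Chao–Wang–Jost asymptotic Shannon
  entropy; unbiased inverse Simpson), clonal/polyclonal calls from ±2σ
  residuals of the diversity-versus-reads regression, IGH isotype
  composition, one-mismatch CDR3-octamer clustering and the gini index of
  clonal inequality.
- **Harmonized TMB** — padded (50 bp) interval intersection across capture
  designs, VAF ≥ 3% and non-synonymous filters, per-Mb rates, oncogenic
  pathway flags and strong/weak peptide-binder classification.
- **Synthetic data** — seeded generators for all of the above with planted
  ground truth (marker sets, cluster labels, immune fractions, clonality
  classes, in-region variant counts), so the whole pipeline is testable
  end to end without any external data.

## Worked example

Simulate a 240-sample cohort with four planted immune clusters
(10/30/43/17% design), score it with the planted immune cell-type
genesets, cluster, and name the clusters:

```python
import numpy as np
from immucluster.scoring import scale_scores, ssgsea_score
from immucluster.clustering import consensus_cluster, label_clusters
from immucluster.synthetic import simulate_reference_panel, simulate_cohort

panel = simulate_reference_panel(seed=11)
genesets = {ct: sorted(panel.truth_markers[ct]) for ct in panel.immune_columns}
cohort = simulate_cohort(panel, seed=1)

scores = ssgsea_score(np.log2(cohort.expression + 1.0), genesets)
z = scale_scores(scores)
res = consensus_cluster(z, k_range=range(2, 9), reps=200, seed=1)
print({k: round(v, 3) for k, v in res.pac.items()}, res.chosen_k)

named = label_clusters(res.assignments[res.chosen_k], z,
                       lymphoid_sets=["T", "B", "NK"],
                       myeloid_sets=["monocyte", "dendritic", "granulocyte"])
print(named.labels.value_counts().to_dict())
```

Output:

```
{2: 0.7, 3: 0.504, 4: 0.0, 5: 0.159, 6: 0.196, 7: 0.158, 8: 0.159} 4
{'Immune Neutral': 104, 'Myeloid Predominant': 72, 'Immune Desert': 41,
 'Paediatric Inflamed': 23}
```

PAC is minimized at k = 4 (0.0: the four-way split is perfectly stable
under resampling, while the two- and three-way splits are ambiguous), and
the named clusters recover the planted design: 43.3% Immune Neutral, 30.0%
Myeloid Predominant, 17.1% Immune Desert and 9.6% Paediatric Inflamed —
within one sample of the planted 10/30/43/17% prevalences.

The same steps are available from the shell:

```sh
immucluster simulate cohort --seed 1 --out sim/
immucluster score --expr sim/cohort.tsv --genesets catalog.gmt --out scores.tsv
immucluster cluster --scores scores.tsv --seed 1 --out clus/
immucluster label --scores scores.tsv --assignments clus/assignments.tsv --out labels.tsv
```

Other entry points: `immucluster derive-genesets`, `calibrate`,
`fraction`, `repertoire`, `tmb`, `pathways`, `binders`.

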