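# germomics

Multi-omics time-series analysis of bacterial spore germination.

When a dormant *Streptomyces coelicolor* spore re-awakens, its proteome and
transcriptome are rebuilt over a few hours. Measuring that process gives
three parallel replicate time courses over 13 sampling points (dormant
spores, then 0–5.5 h every 30 min): Sypro-Ruby-stained 2DE gels
(accumulated protein), pulse-radiolabeled 2DE gels (protein synthesis
rate; the dormant point cannot be labeled), and two-channel microarrays
whose sample sits in the α (Cy3) channel against a pooled all-time-points
reference in the β (Cy5) channel. `germomics` provides the full analysis
chain for such data, plus a synthetic-data generator with planted ground
truth so every stage is testable end to end:

* **Gel normalization** — loading correction; distribution-matching
  factors f_g = exp(M − m_g) from the stained gels, where m_g is gel g's
  mean log spot intensity and M the grand mean; transfer of those factors
  to the paired radiolabeled images; replicate CV reports.
* **Array normalization** — Log2Ratio = log2(α/β); per-array median/MAD
  centering; 0.02-quantile tail trimming; replicate averaging with
  Dixon's Q test (3–9 values) or Peirce's criterion (≥ 10, Gould's
  procedure); geometric-mean profiles; interpolation of single internal
  gaps; a first-quartile low-expression floor with a single-peak rescue.
* **PCA trend extraction** — row-standardized profiles, eigendecomposition
  of the time-domain covariance; the loadings are the principal kinetic
  trends and their eigenvalue shares the fraction of data variability each
  carries. Genes with Pearson p ≤ 0.05 and r > 0 against a loading
  "follow" that trend (p from t = r·√((n−2)/(1−r²))). Decompositions of
  different datasets are aligned over shared time points, including
  detection of a constant component-order shift — the signature of one
  dataset carrying an extra dominant trend such as stored-protein
  consumption.
* **Enrichment** — per-functional-group 2×2 chi-square of a selected gene
  set against the full set, with fold over-representation
  (n_subset/subset_size)/(n_full/full_size), over the packaged 27-group
  Sanger functional classification of the *S. coelicolor* genome.
* **Utilization** — α-channel absolute expression: per-gene median
  abundance, quartile + top-5 % partitioning, proteome-vs-quartile
  cross-tabulation, and time-resolved counts of highly expressed genes per
  functional group at a global quantile threshold.

## Worked example

```python
import numpy as np
from germomics import (SimulationConfig, simulate_transcriptome,
                       fabricate_annotation, normalize_arrays,
                       standardize_profiles, pca_decompose,
                       correlate_with_loading, enrich)

cfg = SimulationConfig(n_genes=1000, seed=42)
annot = fabricate_annotation(1000, seed=42)
matrix, truth = simulate_transcriptome(cfg, annot)

result = normalize_arrays(matrix)
print(f"kept {len(result.profiles)} of {cfg.n_genes} genes "
      f"({len(result.report.rescued)} rescued, "
      f"{result.report.interpolated_cells} cells interpolated)")

std = standardize_profiles(result.profiles, cfg.grid)
decomp = pca_decompose(std, 3)
print("variance fractions:", np.round(decomp.variance_fractions[:3], 3))

corr = correlate_with_loading(std, decomp, component=1, alpha=0.05)
followers = corr.index[corr["significant"]].tolist()
print(f"{len(followers)} genes follow PC1 "
      f"({100 * len(followers) / len(corr):.1f}% of analyzed)")
print(enrich(followers, corr.index.tolist(), annot)
      [["n_subset", "n_full", "fold", "p"]].head(3).round(3))
```

prints

```
kept 795 of 1000 genes (45 rescued, 4 cells interpolated)
variance fractions: [0.199 0.139 0.11 ]
151 genes follow PC1 (19.0% of analyzed)
                         n_subset  n_full   fold      p
group
Chaperones                      2       3  3.501  0.035
Fatty acid biosynthesis         5       9  2.918  0.005
Cell division                   1       3  1.751  0.528
```

The low-expression floor removed the quietest quarter of the genes (45
rescued by their single expression peak); the first three principal
components carry ~45 % of the variability of this noisy 1000-gene
simulation; 151 analyzed genes significantly follow the first kinetic
trend; and the enrichment table ranks functional groups by their fold
over-representation among those followers (with 1000 random genes, no
group is strongly enriched — the small-count rows also carry the
expected-count warning flag in the full table).

## Command line

Each stage is also a subcommand operating on TSV files:

```sh
germomics simulate --seed 1 --out-dir run/
germomics normalize-array --matrix run/transcriptome.tsv --out-dir run/
germomics pca --profiles run/profiles.tsv --out-dir run/
germomics utilization --matrix run/transcriptome.tsv --annot run/annotation.tsv --out-dir run/
germomics run-all --seed 1 --out-dir run/
```

`--config` points at a YAML file holding thresholds (correlation alpha,
trim quantile, filter quartile, utilization quantile) and the seed; any
flag overrides its config key.

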