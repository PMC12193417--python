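# echinodiv

Multi-marker morphological and genetic diversity analysis for barnyard grass
(*Echinochloa* spp.) populations — the troublesome, morphologically plastic
weed complex of rice paddies.  The package implements, as one tested and
reusable pipeline, the analysis workflow used in regional diversity surveys
of paddy-field weed populations:

* **Quantitative traits** — per-trait variation statistics (range, max, min,
  mean X̄, sample SD *s*, CV = 100·*s*/X̄) and the Shannon–Wiener diversity
  index H′ = −Σ Pᵢ ln Pᵢ over ten trait levels spanning X̄ ± 2*s* in 0.5*s*
  steps; Ward minimum-variance clustering of z-scored traits over Euclidean
  distances, cuttable at a height threshold (optionally on an SPSS-style
  0–25 rescaled axis).
* **DNA barcodes** (nuclear *ITS*; chloroplast *psbA*, *matK*, *trnL-F*) —
  variable-site detection with reference-anchored 1-based coordinates,
  haplotype grouping, Kimura 2-parameter distances
  d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q), Saitou–Nei neighbor-joining trees
  with column-resampled bootstrap supports, and multi-locus concatenation.
* **Dominant SCoT markers** (0/1 band matrices) — polymorphic-locus rates,
  polymorphism information content PIC = 1 − Σ pᵢ² per locus and primer,
  Simple Matching similarity, and UPGMA clustering cut at a dissimilarity
  threshold.
* **Herbicide multi-resistance** — fresh-weight inhibition relative to
  untreated controls, the <78 % resistance call, counts of distinct
  herbicide sites of action (SOAs), and Pearson trait–resistance
  correlation.
* **Cross-marker concordance** — Pearson correlation (with two-sided
  t-distribution p-values) between the integer cluster labels each marker
  system assigns, plus a relabeling-maximized diagnostic.
* **Synthetic studies** — a ground-truthed generator of complete studies
  (traits, alignments, bands, resistance) with group-structured archetypes,
  planted haplotypes and flip-noised band profiles, so every stage is
  testable without field data.

The intended users are weed scientists and population geneticists comparing
marker systems on collections of field populations.

## Worked example

```python
from echinodiv import barcode, scot, traits
from echinodiv.synth import reference_survey_config, simulate_study

study = simulate_study(reference_survey_config(seed=1))

summary, levels = traits.diversity_table(study.trait_table)
print(f"mean CV {summary.attrs['mean_cv']:.2f}%  mean H' {summary.attrs['mean_hprime']:.2f}")

its = barcode.barcode_cluster(study.alignments["ITS"])
print(f"ITS haplotype groups: {its.n_clusters}")

sim = scot.sm_similarity(study.band_matrix)
dend, bands = scot.scot_cluster(sim, threshold=0.3)
print(f"SCoT clusters: {bands.n_clusters}")

table2 = scot.primer_summary(study.band_matrix)
print(table2.loc[["SCoT20", "Mean", "Total"]].round(2))
```

prints

```
mean CV 37.47%  mean H' 1.92
ITS haplotype groups: 5
SCoT clusters: 5
        n_bands  n_polymorphic  polymorphism_rate  mean_band_frequency   PIC
SCoT20     15.0          14.00              93.33                 0.50  0.42
Mean       12.0          10.33              85.19                 0.56  0.43
Total      72.0          62.00              86.11                  NaN   NaN
```

The simulated 46-population study plants five population groups; the *ITS*
barcode recovers them exactly (groups are haplotype classes), the
dominant-marker UPGMA cut recovers them despite 2 % band-scoring noise, and
the trait summary lands near the aggregates reported for real surveys
(mean CV ≈ 44 %, mean H′ ≈ 1.7, total 72 bands of which 62 polymorphic).

The same analyses are available from the shell:

```sh
echinodiv simulate --seed 1 --out-dir study/
echinodiv scot --bands study/bands.csv --primer-map study/primer_map.csv --cut 0.3
echinodiv run --config run.yaml        # full pipeline, see RunConfig fields
```

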