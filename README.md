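# nutrinet

Analysis of gut-microbiome feature tables along a child-nutrition
gradient: WHO-style LMS z-scores and a cumulative nutritional index,
rank-normalized abundance profiling, ReBoot-validated Spearman
correlations, AH/BL/SM group comparisons, abundance-pattern clustering,
and co-occurrence networks with sliding-window topology trends — plus a
synthetic cohort generator with planted ground truth so every stage is
testable without sequencing data.

**Who it is for.** Researchers studying how gut microbial community
structure shifts with host phenotype severity (here, child malnutrition)
from shotgun-metagenome feature tables (genus/phylum counts, COGs,
CAZyme families, virulence factors), and anyone needing a compositional
co-occurrence pipeline with honest null calibration.

## The statistics at the core

**Nutritional index.** Each child's anthropometrics yield three LMS
z-scores against a growth reference — height-for-age (z₁), weight-for-age
(z₂) and weight-for-height (z₃) — via

    z = ((X/M)^L − 1) / (L·S),     → ln(X/M)/S as L → 0.

Their sum, the *cumulative nutritional index* z₁+z₂+z₃, is the severity
axis; it cuts the cohort into apparently healthy (AH, index > −6),
borderline (BL, −9 < index ≤ −6) and severely malnourished (SM, ≤ −9).

**ReBoot correlation significance.** Relative abundances are
compositional: closure alone induces spurious correlations. For a feature
pair (or feature-vs-index), ReBoot compares a bootstrap distribution of
the observed Spearman ρ against a permutation null in which the permuted
profile is pushed back through closure (each sample renormalized), so
purely compositional coupling is present in the null too:

    z = (mean_bootstrap − mean_null) / sd_null,   p = 2·Φ(−|z|),

with |z| > 1.97 ⇔ p < 0.05. Power uses the Fisher transform:
power = Φ(δ − z₁₋α/₂) + Φ(−δ − z₁₋α/₂), δ = atanh|ρ|·√(n−3).

**Networks and windows.** Feature pairs with ReBoot p < α become edges of
an undirected signed graph; graph statistics follow the Cytoscape
NetworkAnalyzer definitions (mean degree, characteristic path length over
connected pairs, clustering over degree-≥2 nodes, centralization,
density, degree heterogeneity). Samples sorted by index are scanned with
overlapping windows (20 samples, width 7, step 1 → 14 windows); each
window's network properties are correlated with the window's mean index
to trace how microbial interdependence changes along the gradient.

## Worked example

```python
import nutrinet as nn
from nutrinet.profiles import normalize_abundance, rank_normalize, core_features
from nutrinet.association import RebootParams, associate_with_index, association_frame
from nutrinet.networks import compute_window_series, window_trend

cohort = nn.generate_cohort(nn.SyntheticConfig(seed=7))
meta = cohort.metadata
comp = normalize_abundance(cohort.genus_counts,
                           meta.set_index("sample_id")["total_reads"])
core = core_features(comp)                      # >1% abundance in >=50% of samples
ranked = rank_normalize(comp.subset_features(core))

res = associate_with_index(ranked, meta.set_index("sample_id")["cumulative_index"],
                           comp.subset_features(core), RebootParams(seed=7))
print(association_frame(res).sort_values("rho").head(4).to_string(index=False))

series = compute_window_series(comp, meta, params=RebootParams(seed=7))
rho, p = window_trend(series)["avg_num_neighbors"]
print(f"windows: {len(series.records)}; avg-neighbors trend rho = {rho:.3f} (p = {p:.4f})")
```

Output:

```
      feature_id       rho  reboot_z  p_value    power direction
     g4_taxon_02 -0.679699 -2.818704 0.004822 0.927339  negative
neutral_taxon_01 -0.127820 -0.368842 0.712245 0.082740      none
neutral_taxon_11 -0.084211 -0.264461 0.791425 0.063988      none
neutral_taxon_03 -0.037594 -0.002695 0.997849 0.052759      none
windows: 14; avg-neighbors trend rho = -0.644 (p = 0.0129)
```

A planted gradient-negative genus (`g4_taxon_02`) is recovered with
ρ = −0.68 and ReBoot p < 0.005 while neutral taxa stay quiet, and the
sliding-window trend shows the average number of network neighbors
*falling* as nutrition improves (ρ = −0.64) — the interdependence
signature the hub coupling plants at the malnourished end.

The same analysis end to end, from the shell:

```bash
nutrinet run-all --seed 7 --out runs/demo     # simulate → score → ... → report
cat runs/demo/report.md
```

## Layout

```
src/nutrinet/
  nutrition.py    LMS z-scores, cumulative index, AH/BL/SM classification
  profiles.py     feature tables: hit filtering, normalization, ranking,
                  core detection, abundance-pattern clustering
  association.py  Spearman + ReBoot, power, ANOVA/KW/eta^2/Tukey-Kramer, BH-FDR
  networks.py     co-occurrence networks, graph properties, sliding windows
  synthetic.py    cohort generator with planted ground truth
  pipeline.py     run config, end-to-end orchestration, report
  cli.py          click CLI (simulate/zscore/profile/.../run-all)
docs/methods.md   model assumptions, parameter choices, limitations
```
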