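# Methods

This note documents the models, numerical conventions and design choices
behind nutrinet, and what the synthetic-data tests do and do not
demonstrate about real data.

## Nutritional scoring

Z-scores use the LMS parameterization: `z = ((X/M)^L − 1)/(L·S)`, with the
log-limit `ln(X/M)/S` taken when `|L| ≤ 1e−9`. The convergence of the
general form to the log form is O(L) (at X/M = 1.2, S = 0.1 the gap is
≈1.7e−3 at L = 0.01 and ≈1.7e−4 at L = 0.001), which is what the unit
tests assert. Reference rows are looked up by (sex, axis, key) with
linear interpolation of L, M and S between bracketing keys; lookups
outside the key span raise rather than extrapolate, because growth
references are only valid over their tabulated range.

The cumulative nutritional index is the exact sum z₁+z₂+z₃. Class
boundaries close downward — AH strictly above −6, BL on (−9, −6], SM at
or below −9 — so the three classes partition the real line; the source
inequalities leave the two boundary points undefined and this is the
self-consistent completion.

The bundled growth reference (`toy_growth_reference`) is a synthetic
stand-in shaped like an LMS table, not WHO data: smooth median curves,
axis-wise constant L and S of realistic magnitude, and
*median-consistency* (the weight-for-age median at each age equals the
weight-for-height median at that age's median height), so a child at the
median of every axis scores ≈0 on all three axes. Real WHO tables vary L
and S with age; any real LMS table in the documented TSV layout can be
plugged in instead.

## Synthetic cohort generator

Each taxon's latent log-abundance is Gaussian:

    latent(f, s) = base_f + dir_f · β · u_s + λ(u_s)·g_h(s) − λ(u_s)²/2 + ε,

where `u_s` is the sample's cumulative index rescaled to [−½, ½] over the
configured index range, `dir_f ∈ {+1, −1, 0}` marks planted
gradient-positive/negative/neutral roles, and `ε ~ N(0, latent_sd²)`.
Latents map to proportions by exponentiate-and-normalize (softmax
closure) and to counts by a Dirichlet-multinomial with concentration
`library_size/overdispersion` — the standard count-noise model for
metagenomes. Column sums equal the drawn library size exactly;
normalized tables divide by the *total* sequenced reads
(`library_size / 0.36`, emulating a realistic genus-level assignment
rate), so column sums of normalized tables are ≈0.36, below 1.

Parameter conventions that matter:

- **effect_size (β, default 2.0)** is the change in latent log-abundance
  across the *full* index range, i.e. planted taxa swing ≈`e^β`-fold from
  one end of the gradient to the other. Defining the slope per raw index
  unit instead would give e^±9.4 swings over the observed index span;
  closure distortion from such swings leaks monotone trends into every
  unplanted taxon and no correlation test survives that honestly. At the
  default, planted-taxon correlations with the index land around
  |ρ| ≈ 0.6–0.8 at n = 20, the magnitude range reported for
  gradient-associated genera in Prevotella-dominated child cohorts.
- **hub_coupling_slope (default 2.0)**: each hub h has a shared factor
  `g_h(s) ~ N(0,1)` with loading `λ(u) = slope·(u_high − u)`, rising from
  0 at the healthy end to the slope value at the malnourished end, so
  within-hub co-occurrence strengthens as nutrition falls. The
  `−λ²/2` term removes the log-normal mean `e^{λ²/2}`: without it, hub
  taxa's *expected* share inflates ~e² at the malnourished end and
  closure pushes spurious positive index-correlations into all other
  taxa (measured: neutral false-positive rate 0.146 versus 0.069 with
  the correction). Hubs plant co-occurrence, not abundance trends.
- **Roles are exclusive.** Hub members are their own planted role
  (2 hubs × 5 taxa by default), separate from the 5 gradient-positive,
  5 gradient-negative and 13 neutral taxa and the dominant
  Prevotella-like genus (mean share `dominant_fraction` = 0.35).
- **latent_sd (default 0.5)** sets the per-sample biological noise floor;
  **overdispersion (default 100)** inflates count variance beyond
  multinomial; **library sizes** are uniform on 100k–200k synthetic
  reads — normalization is scale-free, so desk-scale read counts carry
  the same structure as Mbp-scale metagenomes.

**Anthropometrics.** Heights invert the height-for-age LMS transform at a
target z₁; weights invert weight-for-height at the generated height. One
height and one weight determine all three scores against a fixed
reference, so only two scores are free — the generator therefore solves
the weight-for-height target numerically (Brent's method) so the three
recomputed scores sum *exactly* to the sample's target cumulative index,
and z₂ (weight-for-age) is implied. All stored scores round-trip through
`compute_z_scores` to machine precision. A three-way independent target
round-trip is over-determined and not attempted.

**What the generator does not emulate:** sequencing error, read-length
structure, taxon phylogeny (features are exchangeable apart from their
roles), multi-modal enterotype shifts, and covariates (age, diet) beyond
the single nutrition axis. Passing tests therefore demonstrate that the
*statistical machinery* behaves as claimed under a compositional
log-normal world — not that any particular biological finding would
replicate.

## Abundance profiling

Hit filtering uses strict `>` on identity, query coverage and (when set)
alignment length, matching the wording of the thresholds it implements
(65/70/75 for taxonomic hits, 65/90 for functional hits). Normalization
divides by the whole-metagenome read count, not the assigned-read count.
Ranking is ascending with average ranks for ties; Spearman statistics are
invariant to this orientation up to a global sign convention, which is
fixed package-wide. Core features must *strictly* exceed the abundance
floor (0.01) in at least `ceil(prevalence · n)` samples.

Pattern clustering uses average-linkage agglomeration on
`1 − Spearman(rows)`; the metric and linkage are configurable, chosen as
the least-committal match to "similar abundance patterns" across ranked
profiles. The tree is cut to a *requested* number of groups (4 for taxa,
7 for CAZyme families by default) — no automatic cut, since the group
counts come from inspection in the source analyses. Labels G1..Gk are
assigned by each group's alphabetically first member so the labelling is
deterministic; constant rows get zero correlation (distance 1) to
everything.

## Association testing

**ReBoot.** The null distribution permutes the focal feature's profile
across samples and renormalizes every sample's composition to its
pre-permutation sum, restoring closure so that compositional coupling is
present under the null; the score is
`z = (mean_bootstrap − mean_null)/sd_null` with a two-sided normal p.
The bootstrap ranks the observed sample once and resamples the rank
pairs (Pearson on resampled ranks). The alternative — re-ranking each
resample — attenuates the bootstrap mean by ≈8% at n = 20 through
duplicate-induced ties, which drags pooled null p-values visibly below
uniform; the rank-once convention keeps the null calibrated (measured
type-I 0.048 at nominal 0.05 over 500 null pairs; pooled null p-values
consistent with U(0,1) by KS at 2000 draws). For pairs, the
alphabetically first feature is the permuted one, making edges canonical
and the computation batchable per feature. Degenerate nulls (constant
features) raise; constant features are excluded from association scans
with a warning.

**Power** uses the two-sided arctanh formula
`Φ(δ − z_crit) + Φ(−δ − z_crit)`, `δ = atanh|ρ|·√(n−3)`; |ρ| = 1 maps to
power 1 by convention and ρ = 0 recovers α exactly. Several arctanh-based
variants circulate (one- vs two-sided, small-sample bias corrections) and
give visibly different values at n = 20, so power is reported
descriptively and never used as a decision gate.

**Group comparisons** run one-way ANOVA and tie-corrected Kruskal-Wallis
per feature, with η² = SS_between/SS_total and Tukey-Kramer post-hoc
pairs using the unequal-n standard error `√(MS_within/2·(1/nᵢ+1/nⱼ))`
against the studentized range with df = N − k at family-wise α = 0.05.
BH-FDR is applied across features separately within each test family
(parametric and non-parametric) — the conservative reading when the
correction family is unstated. Classes with fewer than 2 samples skip
the comparison with a warning rather than producing unstable F
statistics.

## Networks and windows

Edges require ReBoot p strictly below α (0.05 whole-cohort and windows,
0.01 within-class by default); no multiple-testing correction is applied
to edges by default — raw per-edge thresholds are the convention for
these co-occurrence networks (a BH mode can be applied downstream from
the stored per-pair statistics, which are retained for every pair). The node
set is the set of edge endpoints. Graph properties follow Cytoscape
NetworkAnalyzer: characteristic path length averages shortest paths over
connected ordered pairs (disconnected pairs excluded, not infinite, and
the connected-pair count is reported alongside since "shortest path" is
ambiguous in that tool's output); clustering averages over nodes of
degree ≥ 2; centralization is `(N/(N−2))·(max_deg/(N−1) − density)`,
undefined below 3 nodes; heterogeneity is the population CV of degrees.

Windows sort samples by ascending index (ties by sample id) and slide a
width-7 window by step 1 (20 samples → 14 windows). Per-property trends
are Spearman correlations against the windows' mean index, dropping
undefined windows pairwise and requiring ≥4 defined windows. Because
consecutive windows share 6 of 7 samples, trend p-values are
optimistically small under autocorrelation; the sign and magnitude of
the trend, not its nominal p, is the meaningful output — the Monte-Carlo
tests therefore assert sign consistency across replicates rather than
p-value thresholds.

## Numerical and reproducibility choices

- All randomness flows from integer seeds through numpy `SeedSequence`;
  per-feature and per-stage streams are spawned so results are invariant
  to unrelated configuration changes. Pipeline runs are byte-identical
  for identical configs; the manifest records the config SHA-256, seed
  and package version (no timestamps).
- Per-pair ReBoot statistics are independent of α, so edge sets are
  nested as α tightens.
- Problem sizes in the test-suite Monte-Carlos (500 null pairs at
  300/300 resamples; 50 recovery replicates at n = 60 with 200/200;
  50 trend replicates at 100/100) were chosen to keep each suite section
  in the seconds-to-a-minute range while leaving the binomial noise on
  the measured rates several times smaller than the margins being
  asserted.

## Known limitations

- ReBoot's normal-tail p is an approximation; the procedure is slightly
  conservative (type-I ≈ 0.048 at nominal 0.05 in our calibration).
- The permutation null renormalizes only the focal feature's
  displacement; trends induced through the *denominator* by other,
  strongly trending features are not nulled out — this is a property of
  the method, visible in the generator's need for mean-stationary hubs.
- Window trends inherit strong autocorrelation from 6/7 sample overlap.
- The toy growth reference supports the synthetic pipeline and tests;
  real scoring requires a real LMS table.
- Tukey-Kramer assumes ANOVA's variance homogeneity; with n = 20 split
  into three classes, both it and η² are descriptive rather than
  confirmatory.
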