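# Methods

This note documents the statistical models the package implements, the
design of the synthetic-data generators that provide ground truth, and the
numerical choices a user should know before trusting (or extending) the
results.

## Data model

A study consists of three aligned objects: a `FeatureTable` of integer ASV
counts (samples × taxa; empty samples are dropped with a logged count, all
relative-abundance views are derived on demand and no rarefaction is ever
applied by default), a rooted Newick phylogeny over the ASVs whose
patristic distances feed the phylogenetic null models, and a per-sample
metadata frame. Metadata derivations are fixed formulas: BMI is weight (g)
divided by forearm length (mm); a sample is *infected* exactly when a qPCR
Ct value is present; fungal load is carried in log10 space as
`(Ct − 22.04942) / −3.34789`, the exponent of the standard-curve relation
`load = 10^[(Ct − 22.04942)/−3.34789]`. Averages of loads are means of the
log10 values, and the output labels them as such. Missing metadata stays
missing; nothing is imputed.

## Assembly-process inference

For samples *k, l* the between-community mean nearest taxon distance is

    βMNTD(k,l) = ½ [ Σ_i f_ik · min_{j∈l} d_ij + Σ_j f_jl · min_{i∈k} d_ij ]

with *f* the relative abundances (presence/absence weights 1/richness are
available) and *d* patristic distances. βNTI standardizes the observed
βMNTD against a null built by shuffling taxon labels on the distance
matrix jointly for all samples — equivalent to shuffling tip labels — with
999 randomizations by default; the null mean and SD are retained for
audit, and pairs whose null has zero spread are flagged undefined, counted,
and excluded from classification. The implementation was cross-checked
against an independent R implementation (picante's `comdistnt` plus
`taxaShuffle`) and agrees to ~1e-15 on βMNTD and ρ ≈ 0.998 on βNTI.

The Raup–Crick index draws, per randomization, one null community per
sample that preserves its observed richness and read total: taxa enter by
weighted draws without replacement (weights = occurrence frequency across
all samples), each colonist keeps at least one read, and remaining reads
are assigned multinomially in proportion to mean relative abundance across
samples. RC rescales the rank of the observed Bray–Curtis value within the
null distribution to [−1, 1]. Identical samples give RC ≈ −1; RC is
*expected* to sit near −1 whenever observed turnover is weaker than
richness-constrained resampling produces — that is a feature of the index,
not a bias.

Classification thresholds are the standard ones (|βNTI| ≥ 2 for selection;
RC beyond ±0.95 for the dispersal categories). The published rule text
this convention descends from is internally inconsistent for homogenizing
dispersal ("RC < 0.95" overlaps the drift band "|RC| < 0.95"); the package
defaults to the standard reading RC < −0.95 → homogenizing dispersal and
exposes the literal variant via `rc_convention="as_printed"`. Pairs are
classified within host groups by default, mirroring per-species reporting;
`within_groups=False` adds cross-group pairs labeled "between". "Drift" is
the label used for the |RC| < 0.95, |βNTI| < 2 cell; the literature also
calls this "undominated".

## Sloan neutral model

The detection probability of a taxon with source-pool relative abundance
*p* is `1 − BetaCDF(d; Nmp, Nm(1−p))`. Only *m* is free: *N* is fixed at
the mean total reads per sink sample and the detection limit at d = 1/N —
the smallest relative abundance observable at that depth. *m* is fitted by
bounded scalar least squares on log m ∈ [log 1e−7, log 1e3]; R² is the
usual 1 − SSE/SST and may be negative when the neutral curve fits worse
than a constant. The 95% band is a Wilson score interval around the
predicted frequency with n = number of sink samples (`ci_method="fit"`
propagates a ±1.96 SE interval of the fitted m instead). ASVs absent from
the source pool cannot have p > 0; they are excluded from the fit and
reported as a separate count (they are exactly the candidates for an
"unknown source"). Category abundance shares are computed on sink relative
abundance, pooled and optionally per site from the pooled fit.

Recovery behavior: on data generated by the model's own sampler the fitted
m carries a modest upward bias (up to ~20–23% at the grid edges) that
comes from a deliberate model/generator mismatch — the generator detects a
taxon when its multinomial count is ≥ 1 (probability ≈ 1 − e^(−Nq) at
latent proportion q), while the fitted model uses the sharp threshold
q > 1/N. The bias is stable, monotone-preserving, and inside the ±25%
recovery band used by the tests; we keep the sharp-threshold form because
it is the standard formulation users will compare against.

## EM source tracking

Sink counts follow a multinomial mixture of pseudocount-smoothed (add-½)
empirical source profiles plus an unknown source. The E-step assigns reads
fractionally; the M-step updates α and the unknown profile γ₀. A fully
free γ₀ makes the model unidentifiable — it can imitate the sink itself
and absorb everything — so γ₀ is re-estimated only over taxa with zero raw
counts in every source; when no such taxa exist it stays fixed at uniform
and its weight collapses. The log-likelihood is asserted non-decreasing on
every run; 5 random restarts (seeded) guard against local optima. Source
profiles are *not* re-estimated: this is deliberately simpler than
published source-tracking estimators that model source noise, and it is
accurate at desk scale (mixture proportions recovered within ~0.005 at
depth 50,000). Multiple sinks are processed independently with per-sink
child seeds.

## Ordination statistics

PERMANOVA uses the distance-based partition SS_total = Σ_{i<j} d²_ij / N
and SS_within = Σ_g Σ_{i<j∈g} d²_ij / n_g, pseudo-F =
(SS_between/(a−1))/(SS_within/(N−a)), free label permutation (no strata),
999 permutations and the add-one p-value. The statistic matches
scikit-bio's PERMANOVA to 1e-9 and a hand-computed partition exactly; its
type-I error is ~0.05 over 500 structure-free simulations. Multi-factor
designs are run as sequential one-factor tests. Procrustes/PROTEST centres
and unit-scales both configurations, superimposes by SVD (reflection
allowed by default, Kabsch-constrained otherwise), and permutes rows of
the second configuration for p. NMDS minimizes Kruskal stress-1
(non-metric SMACOF, 20 seeded restarts, best kept). Bray–Curtis is
computed on relative abundances by default. Shannon diversity is reported
in nats.

## Co-occurrence networks

Taxa (typically genus-aggregated) are ranked by mean relative abundance;
the top 30 are retained and all pairwise Spearman correlations computed.
Edges require raw p < 0.05 and |ρ| ≥ 0.5 — no multiple-testing correction,
matching common practice for these descriptive networks; correlations can
be computed on raw counts (`use_relative=False`) to avoid compositional
closure when calibrating false-edge rates. Constant taxon vectors have
undefined rank correlations; their pairs are skipped and counted.
"Complexity" is reported as node and edge counts only.

## Synthetic-data generators

The generators encode the regimes the inference stages assume, so every
stage can be validated against known truth.

**Trees.** `gen_tree` builds a pure-birth topology and draws every branch
length i.i.d. Exponential(mean 1). The i.i.d. lengths (rather than a
birth-process clock) keep terminal branches short relative to typical
tip-to-tip paths, which is the regime in which a Brownian trait on the
tree retains phylogenetic signal at the tips — with clock lengths, sister
tips are nearly as far apart as random tips and no trait-based filter can
produce detectable phylogenetic clustering at a few hundred taxa.

**Filtered scenarios.** A niche trait evolves by Brownian motion
(increments ∼ Normal(0, branch length)), standardized to unit variance
across tips. Assembly is a colonization lottery under a deterministic
filter: each sample draws `richness` colonists without replacement with
probability ∝ exp(−(trait − optimum)²/(2σ²)), then assigns reads
multinomially ∝ envelope × lognormal(0, 0.5) noise. The lottery matters:
βNTI's signal lives entirely in the *unshared* taxa of a sample pair
(shared taxa contribute zero distance to both the observed and the null
βMNTD), so scenarios must combine strong filtering with high within-niche
turnover. Defaults: σ = 0.2 (strong filter), richness = n_taxa/5, shared
optimum at the median tip trait; the contrasting variant places two equal
sample blocks at the 25th and 75th trait percentiles. Detectability grows
with pool size; filtered-scenario analyses in the tests and acceptance
script run at 600 taxa, 12 samples, richness 120, depth 2,000, where the
homogeneous-selection fraction averages ≈ 0.8 across replicate trees
(roughly 0.5–1.0 tree to tree — single replicates are noisy, so recovery
is always assessed on pairs pooled over several replicate trees).

**Exchangeable null.** The same lottery with the filter removed: colonists
drawn ∝ pool abundance from a lognormal species-abundance distribution,
reads ∝ pool. Turnover is therefore of exactly the richness-constrained
kind the Raup–Crick null reconstructs and carries no phylogenetic
structure, making this the calibration scenario: βNTI tail rate ≈ 5%,
PERMANOVA type-I ≈ 5%, RC centred (slightly left of 0 — the null
"knows" the pooled occurrence frequencies, a small conservative offset).

**Neutral and source/sink scenarios.** The Sloan sampler draws per-taxon
latent proportions Beta(Nmp, Nm(1−p)), renormalizes, and samples reads
multinomially. Source/sink mixtures use Dirichlet(0.2)-distinct source
profiles, a sink multinomial from the α-mixture, and an optional unknown
spike on taxa absent from every source. Default scales are 300 taxa, 50
samples, 10,000 reads per sample.

What the generators do **not** emulate: sequencing error and chimeras,
taxonomy, compositional biases of extraction/PCR, spatial or temporal
autocorrelation among samples, and source profiles that drift between the
time of sourcing and sampling. Passing recovery tests therefore shows the
estimators are correct under their own assumptions at realistic scale —
not that those assumptions hold in any particular field data set.

## Pipeline, seeds, determinism

`run_pipeline` executes validate → diversity → assembly → neutral → source
tracking → network from one `RunConfig`; a failed stage is recorded and
independent later stages still run. Every stage derives a child seed from
the run seed via a CRC-tagged `SeedSequence`, so re-running any stage with
the same config is bit-reproducible; all thresholds and applied defaults
are echoed into the JSON report (schema version 1.0). Problem sizes in the
test-suite and acceptance script (replicate counts, 199–299 null
randomizations instead of the 999 default, 12–50 samples) were chosen as
the smallest scales at which the quantities above are stable; all defaults
inside the library remain at their documented values.

## Known limitations

- The RC index is reported under the standard sign convention; analyses
  that used the literal published rule text will differ for the
  homogenizing-dispersal category.
- The neutral fit's m inherits the ~20% detection-convention bias above;
  comparisons of m *between* data sets fitted the same way are unaffected.
- PERMANOVA has no strata/blocking and the multi-factor mode is
  sequential, not partial; covariate-adjusted ordination (db-RDA-style) is
  out of scope.
- The source tracker fixes source profiles at their empirical estimates;
  very shallow source tables will push shared-but-unseen taxa into the
  unknown component.
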