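# mycoassembly

Community-assembly inference for host-associated mycobiomes (and amplicon
communities generally). The package implements the ecological inference
chain used to ask how a skin (or other host-surface) fungal community is
assembled from its environmental reservoir:

- **Phylogenetic null models** — between-community mean nearest taxon
  distance (βMNTD), its standardized effect size **βNTI** against a
  tip-shuffle null, the abundance-based **Raup–Crick** index on Bray–Curtis
  dissimilarity, and the five-process classification: homogeneous selection
  (βNTI < −2), heterogeneous selection (βNTI > 2), homogenizing dispersal
  (RC < −0.95), dispersal limitation (RC > 0.95), and drift (otherwise).
- **Sloan neutral community model** — the occurrence frequency of a taxon
  across sink communities predicted from its source-pool relative abundance
  *p*, community size *N*, and migration rate *m* as
  `1 − BetaCDF(d; Nmp, Nm(1−p))`; taxa outside the 95% band are called
  over-/under-represented.
- **EM source tracking** — sink counts modeled as
  `Multinomial(N, Σ_k α_k γ_k + α_0 γ_0)` over known source profiles γ_k
  plus an unknown source γ_0; mixing proportions α estimated by
  expectation–maximization.
- **Ordination statistics** — Bray–Curtis distances, one-factor PERMANOVA
  (pseudo-F from the distance-based sum-of-squares partition, label
  permutation p), non-metric MDS, Procrustes/PROTEST concordance, alpha
  diversity, and UpSet-style shared/unique ASV partitions.
- **Co-occurrence networks** — Spearman correlation networks on the top-k
  most abundant taxa (p < 0.05, |ρ| ≥ 0.5 by default) with node/edge
  "complexity" counts per host group.
- **Synthetic data with known truth** — generators for habitat-filtered,
  exchangeable-null, Sloan-neutral, and source/sink-mixture communities,
  plus trees, traits, and field-style sample metadata (species, site,
  roost temperature, qPCR Ct → log10 *Pd* load, BMI = weight/forearm).

Everything is importable from Python; a thin `mycoassembly` CLI wraps the
same functions for shell use, and `examples/` holds one narrative script
per capability.

## Worked example

`examples/01_assembly_processes.py` generates communities assembled by
phylogenetically conserved habitat filtering toward one shared niche
optimum, then classifies every sample pair:

```text
 group  n_pairs  homogeneous_selection  heterogeneous_selection  homogenizing_dispersal  dispersal_limitation    drift  deterministic
colony       66               0.818182                      0.0                     0.0              0.166667 0.015152       0.818182

deterministic share (|betaNTI| >= 2): 0.82
```

82% of pairs show less phylogenetic turnover than the tip-shuffle null
allows (βNTI < −2) — the signature of homogeneous selection, which is the
truth the generator encoded. `examples/02_neutral_model.py` fits the Sloan
model to a sink generated with m = 0.1 and prints

```text
fitted m        : 0.1206   (generating value 0.1)
fit r^2         : 0.959
ASV categories  : {'neutral': 282, 'over': 13, 'under': 5}
```

and `examples/03_source_tracking.py` recovers a 0.42/0.28/0.30
two-source-plus-unknown mixture as 0.415/0.284/0.301.

The same analyses run from the shell:

```bash
mycoassembly simulate --scenario filtered_shared_optimum --n-taxa 300 \
    --n-samples 50 --seed 42 --out demo/
mycoassembly assembly --table demo/table.tsv --tree demo/tree.nwk \
    --meta meta.tsv --group species --reps 999 --seed 7
mycoassembly run --config run.yaml     # full pipeline, JSON report
```

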