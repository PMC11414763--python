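"""Synthetic communities, trees, metadata, and source/sink mixtures with
known ground truth.

Each generator emulates one generative regime the inference stages assume:

- ``null_exchangeable``: samples drawn i.i.d. from a shared Dirichlet pool
  with no phylogenetic structure — the calibration scenario where betaNTI
  should flag ~5% of pairs and PERMANOVA should hold its type-I error.
- ``filtered_shared_optimum`` / ``filtered_contrasting_optima``:
  phylogenetically conserved habitat filtering. A niche trait evolves on the
  tree by Brownian motion; a sample's expected abundance for a taxon decays
  as a Gaussian of the trait's distance to the sample's environmental
  optimum. A shared optimum yields homogeneous selection; two sample blocks
  with distant optima yield heterogeneous selection between blocks.
- ``neutral``: the Sloan beta-multinomial sampler — per-taxon latent
  proportions Beta(N m p, N m (1-p)) renormalized, then multinomial reads.
- ``source_sink``: sinks as multinomial draws from a convex mixture of
  Dirichlet-distinct source profiles, optionally with unknown-source mass on
  taxa absent from every source.

Defaults are desk-scale study conditions: 300 taxa, 50 samples, 10,000
reads per sample.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd
from skbio import TreeNode

from .tables_io import FeatureTable, ValidationError

__all__ = [
    "ScenarioSpec", "gen_tree", "brownian_traits", "gen_filtered_communities",
    "gen_exchangeable_communities", "gen_neutral_sink", "gen_source_sink",
    "gen_metadata", "generate_scenario",
]

SCENARIOS = (
    "neutral", "filtered_shared_optimum", "filtered_contrasting_optima",
    "null_exchangeable", "source_sink",
)


@dataclass
class ScenarioSpec:
    """Parameters of one synthetic study; ``seed`` is mandatory.

    ``sigma`` is the habitat-filter width in standardized trait units
    (traits are scaled to unit variance across tips); 0.2 is a strong
    filter, large sigma approaches no filtering. ``richness`` is the number
    of colonization events per filtered sample (default: one fifth of the
    taxon pool). ``m`` is the Sloan migration parameter; ``alphas`` the
    source mixing proportions.
    """

    scenario: str
    seed: int
    n_taxa: int = 300
    n_samples: int = 50
    depth: int = 10_000
    m: float = 0.1
    sigma: float = 0.2
    richness: int | None = None
    alphas: tuple = (0.6, 0.4)
    unknown_fraction: float = 0.0
    noise_sd: float = 0.5          # lognormal per-taxon abundance noise

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValidationError(f"unknown scenario {self.scenario!r}")
        if self.depth < 100:
            raise ValidationError("depth must be >= 100 reads")
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        if self.alphas is not None and abs(sum(self.alphas) - 1.0) > 1e-9:
            raise ValidationError("alphas must sum to 1")


# ---------------------------------------------------------------------------
# trees and traits
# ---------------------------------------------------------------------------

def gen_tree(n_taxa: int, seed: int) -> TreeNode:
    """Pure-birth topology with i.i.d. exponential branch lengths.

    Tips are labeled ASV_1..ASV_n. Branch lengths are drawn independently
    Exponential(mean 1) rather than taken from the birth-process clock, so
    terminal branches are short relative to typical tip-to-tip paths — the
    regime in which traits evolved on the tree carry usable phylogenetic
    signal at the tips. Deterministic under a fixed seed.
    """
    if n_taxa < 3:
        raise ValidationError("need at least 3 taxa")
    rng = random.Random(seed)
    taxa = dendropy.TaxonNamespace([f"ASV_{i + 1}" for i in range(n_taxa)])
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_taxa,
        taxon_namespace=taxa, rng=rng,
    )
    newick = tree.as_string(schema="newick", suppress_rooting=True)
    out = TreeNode.read([newick])
    blen_rng = np.random.default_rng(seed)
    for node in out.traverse(include_self=False):
        node.length = float(blen_rng.exponential(1.0))
    return out


def brownian_traits(tree: TreeNode, seed: int, standardize: bool = True) -> pd.Series:
    """One continuous trait evolved along the tree by Brownian motion.

    Increments are Normal(0, branch length); with ``standardize`` the tip
    values are centred and scaled to unit variance so filter widths are
    comparable across trees.
    """
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {id(tree): 0.0}
    for node in tree.preorder(include_self=False):
        parent_val = values[id(node.parent)]
        values[id(node)] = parent_val + rng.normal(0.0, np.sqrt(max(node.length, 0.0)))
    tips = pd.Series({t.name: values[id(t)] for t in tree.tips()})
    if standardize:
        tips = (tips - tips.mean()) / tips.std(ddof=0)
    return tips


# ---------------------------------------------------------------------------
# community generators
# ---------------------------------------------------------------------------

def _multinomial_table(expected: np.ndarray, depth: int, rng, sample_ids, asv_ids) -> FeatureTable:
    probs = expected / expected.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(depth, p) for p in probs])
    return FeatureTable(list(sample_ids), list(asv_ids), counts)


def gen_exchangeable_communities(spec: ScenarioSpec, asv_ids=None) -> tuple[FeatureTable, dict]:
    """Label-exchangeable null: i.i.d. multinomial samples from one shared
    lognormal species-abundance pool (no phylogenetic structure and no
    between-sample compositional heterogeneity beyond sampling noise) — the
    calibration regime in which betaNTI and Raup-Crick tails should fire at
    their nominal rates and PERMANOVA should hold its type-I error.

    Sampling is a trait-blind colonization lottery: each sample receives
    ``richness`` taxa drawn without replacement with probability
    proportional to pool abundance, and reads assigned multinomially from
    the pool restricted to the colonists. Turnover between samples is
    therefore of the same richness-constrained kind the Raup-Crick null
    reconstructs, and carries no phylogenetic structure at all."""
    rng = np.random.default_rng(spec.seed)
    if asv_ids is None:
        asv_ids = [f"ASV_{i + 1}" for i in range(spec.n_taxa)]
    n_taxa = len(asv_ids)
    pool = rng.lognormal(0.0, 1.0, n_taxa)
    pool /= pool.sum()
    richness = min(spec.richness or max(n_taxa // 3, 5), n_taxa)
    counts = np.zeros((spec.n_samples, n_taxa), dtype=np.int64)
    for s in range(spec.n_samples):
        chosen = rng.choice(n_taxa, size=richness, replace=False, p=pool)
        w = pool[chosen]
        counts[s, chosen] = rng.multinomial(spec.depth, w / w.sum())
    sample_ids = [f"S{i + 1}" for i in range(spec.n_samples)]
    table = FeatureTable(sample_ids, asv_ids, counts)
    return table, {"scenario": spec.scenario, "pool": pool.tolist(),
                   "richness": richness}


def gen_filtered_communities(tree: TreeNode, spec: ScenarioSpec) -> tuple[FeatureTable, dict]:
    """Habitat-filtered communities with phylogenetically conserved niches.

    Assembly is a colonization lottery under a deterministic filter: each
    sample receives ``richness`` colonization events drawn without
    replacement with probability proportional to the Gaussian habitat
    envelope exp(-(trait_i - optimum_s)^2 / (2 sigma^2)); colonists' expected
    abundances are the envelope times lognormal noise, and reads are
    multinomial at the requested depth. The lottery gives neighbouring
    samples high taxon turnover within the same clade neighbourhood, which
    is what makes selection detectable as reduced phylogenetic turnover.

    ``filtered_shared_optimum`` places every sample at the median tip trait;
    ``filtered_contrasting_optima`` splits samples into two equal blocks at
    the 25th and 75th trait percentiles.
    """
    if spec.scenario not in ("filtered_shared_optimum", "filtered_contrasting_optima"):
        raise ValidationError(f"not a filtered scenario: {spec.scenario}")
    if spec.sigma <= 0:
        raise ValidationError("sigma must be positive")
    rng = np.random.default_rng(spec.seed)
    traits = brownian_traits(tree, seed=spec.seed + 1)
    asv_ids = list(traits.index)
    tvals = traits.to_numpy()
    n_taxa = len(asv_ids)
    richness = spec.richness or max(n_taxa // 5, 10)

    if spec.scenario == "filtered_shared_optimum":
        optima = np.full(spec.n_samples, np.quantile(tvals, 0.5))
        blocks = ["A"] * spec.n_samples
    else:
        half = spec.n_samples // 2
        optima = np.concatenate([
            np.full(half, np.quantile(tvals, 0.25)),
            np.full(spec.n_samples - half, np.quantile(tvals, 0.75)),
        ])
        blocks = ["A"] * half + ["B"] * (spec.n_samples - half)

    counts = np.zeros((spec.n_samples, n_taxa), dtype=np.int64)
    for s in range(spec.n_samples):
        envelope = np.exp(-((tvals - optima[s]) ** 2) / (2 * spec.sigma ** 2))
        p_col = envelope / envelope.sum()
        chosen = rng.choice(n_taxa, size=min(richness, n_taxa), replace=False, p=p_col)
        w = envelope[chosen] * rng.lognormal(0.0, spec.noise_sd, chosen.size)
        counts[s, chosen] = rng.multinomial(spec.depth, w / w.sum())
    sample_ids = [f"S{i + 1}" for i in range(spec.n_samples)]
    table = FeatureTable(sample_ids, asv_ids, counts)
    truth = {
        "scenario": spec.scenario,
        "sigma": spec.sigma,
        "richness": richness,
        "optima": optima.tolist(),
        "blocks": blocks,
        "traits": traits.to_dict(),
    }
    return table, truth


def gen_neutral_sink(
    source_profile,
    m: float,
    n_eff: float,
    depth: int,
    n_samples: int,
    seed: int,
    asv_ids=None,
) -> FeatureTable:
    """Sloan-neutral sink communities sampled from a source pool.

    Per sample, each taxon's latent proportion is drawn Beta(N m p,
    N m (1 - p)); the vector is renormalized and reads drawn multinomially.
    """
    if m <= 0:
        raise ValidationError("migration parameter m must be positive")
    rng = np.random.default_rng(seed)
    p = np.asarray(source_profile, dtype=float)
    p = p / p.sum()
    p = np.clip(p, 1e-12, 1 - 1e-12)
    if asv_ids is None:
        asv_ids = [f"ASV_{i + 1}" for i in range(p.size)]
    nm = n_eff * m
    rows = []
    for _ in range(n_samples):
        latent = rng.beta(nm * p, nm * (1.0 - p))
        latent_sum = latent.sum()
        if latent_sum <= 0:
            latent = p
            latent_sum = 1.0
        rows.append(rng.multinomial(depth, latent / latent_sum))
    sample_ids = [f"S{i + 1}" for i in range(n_samples)]
    return FeatureTable(sample_ids, list(asv_ids), np.vstack(rows))


def gen_source_sink(
    n_sources: int,
    alphas,
    depth: int,
    seed: int,
    n_taxa: int = 300,
    n_source_samples: int = 10,
    unknown_fraction: float = 0.0,
    n_unknown_taxa: int = 50,
) -> tuple[dict, FeatureTable, np.ndarray, dict]:
    """Known-truth source/sink mixture.

    Returns (source tables by name, sink table with one sample, sink counts
    vector, truth record). Source profiles are Dirichlet-distinct over a
    shared taxon pool; the sink is multinomial from sum_k alpha_k gamma_k,
    with optional ``unknown_fraction`` of reads placed on ``n_unknown_taxa``
    taxa absent from every source.
    """
    alphas = np.asarray(alphas, dtype=float)
    if n_sources < 1 or len(alphas) != n_sources:
        raise ValidationError("need one alpha per source")
    if abs(alphas.sum() - 1.0) > 1e-9:
        raise ValidationError("alphas must sum to 1")
    rng = np.random.default_rng(seed)
    total_taxa = n_taxa + (n_unknown_taxa if unknown_fraction > 0 else 0)
    asv_ids = [f"ASV_{i + 1}" for i in range(total_taxa)]

    profiles = rng.dirichlet(np.full(n_taxa, 0.2), size=n_sources)
    gammas = np.zeros((n_sources, total_taxa))
    gammas[:, :n_taxa] = profiles
    sources = {}
    for k in range(n_sources):
        counts = np.vstack([
            rng.multinomial(depth, gammas[k]) for _ in range(n_source_samples)
        ])
        sources[f"source_{k + 1}"] = FeatureTable(
            [f"src{k + 1}_{i + 1}" for i in range(n_source_samples)], asv_ids, counts
        )

    mix = alphas @ gammas
    if unknown_fraction > 0:
        unknown_prof = np.zeros(total_taxa)
        unknown_prof[n_taxa:] = rng.dirichlet(np.full(n_unknown_taxa, 0.5))
        mix = (1 - unknown_fraction) * mix + unknown_fraction * unknown_prof
    sink_counts = rng.multinomial(depth, mix)
    sink = FeatureTable(["sink_1"], asv_ids, sink_counts[None, :])
    truth = {
        "alphas": alphas.tolist(),
        "unknown_fraction": unknown_fraction,
        "n_taxa": n_taxa,
        "depth": depth,
    }
    return sources, sink, sink_counts, truth


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------

_SPECIES = ["RHFE", "MULE", "RHPU", "MYPE", "PLAU"]
_SITE_TEMPS = {"cave_1": 8.0, "cave_2": 10.0, "cave_3": 7.0, "cave_4": 9.5, "cave_5": 11.0}


def gen_metadata(
    n_samples: int,
    seed: int,
    species=None,
    sites=None,
    infected_fraction: float = 0.3,
    n_environment: int = 0,
    temp_sd: float = 1.0,
) -> pd.DataFrame:
    """Per-sample covariates mirroring a multi-species cave survey.

    Species and site labels cycle over the provided pools; roost temperature
    is drawn around a per-site mean; an ``infected_fraction`` of bat samples
    receives a qPCR Ct value (uniform 20-35 cycles). Weight and forearm are
    drawn from plausible vespertilionid/rhinolophid ranges so BMI derives
    consistently. Environment samples carry site and temperature only.
    """
    rng = np.random.default_rng(seed)
    species = list(species or _SPECIES)
    sites = list(sites or _SITE_TEMPS)
    rows = []
    for i in range(n_samples):
        sp = species[i % len(species)]
        site = sites[i % len(sites)]
        forearm = rng.uniform(35.0, 60.0)
        weight = forearm * rng.uniform(0.25, 0.45)
        ct = rng.uniform(20.0, 35.0) if rng.random() < infected_fraction else np.nan
        rows.append({
            "sample_id": f"S{i + 1}",
            "species": sp,
            "site": site,
            "sample_type": "bat",
            "sex": "F" if rng.random() < 0.5 else "M",
            "forearm_mm": round(forearm, 1),
            "weight_g": round(weight, 1),
            "roost_temp_c": round(rng.normal(_SITE_TEMPS.get(site, 9.0), temp_sd), 2),
            "ct": round(ct, 2) if np.isfinite(ct) else np.nan,
        })
    for j in range(n_environment):
        site = sites[j % len(sites)]
        rows.append({
            "sample_id": f"E{j + 1}",
            "species": "ENV",
            "site": site,
            "sample_type": "environment",
            "sex": np.nan,
            "forearm_mm": np.nan,
            "weight_g": np.nan,
            "roost_temp_c": round(rng.normal(_SITE_TEMPS.get(site, 9.0), temp_sd), 2),
            "ct": np.nan,
        })
    from .tables_io import derive_sample_fields

    return derive_sample_fields(pd.DataFrame(rows).set_index("sample_id"))


# ---------------------------------------------------------------------------
# scenario dispatcher
# ---------------------------------------------------------------------------

def generate_scenario(spec: ScenarioSpec, out_dir=None):
    """Generate a full scenario (table, tree where applicable, truth record).

    With ``out_dir`` the table/tree/truth are written in the same TSV/Newick
    formats the readers consume, plus the truth record as JSON.
    """
    tree = None
    if spec.scenario in ("filtered_shared_optimum", "filtered_contrasting_optima"):
        tree = gen_tree(spec.n_taxa, spec.seed)
        table, truth = gen_filtered_communities(tree, spec)
    elif spec.scenario == "null_exchangeable":
        tree = gen_tree(spec.n_taxa, spec.seed)
        table, truth = gen_exchangeable_communities(spec)
    elif spec.scenario == "neutral":
        rng = np.random.default_rng(spec.seed)
        pool = rng.lognormal(0.0, 1.5, spec.n_taxa)
        table = gen_neutral_sink(
            pool / pool.sum(), spec.m, spec.depth, spec.depth,
            spec.n_samples, spec.seed + 1,
        )
        truth = {"scenario": "neutral", "m": spec.m,
                 "source_profile": (pool / pool.sum()).tolist()}
    elif spec.scenario == "source_sink":
        sources, sink, _, truth = gen_source_sink(
            len(spec.alphas), spec.alphas, spec.depth, spec.seed,
            n_taxa=spec.n_taxa, unknown_fraction=spec.unknown_fraction,
        )
        truth["scenario"] = "source_sink"
        table = _concat_tables(list(sources.values()) + [sink])
    else:  # pragma: no cover - guarded by ScenarioSpec
        raise ValidationError(spec.scenario)

    if out_dir is not None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.write_tsv(out / "table.tsv")
        if tree is not None:
            tree.write(str(out / "tree.nwk"))
        spec_record = asdict(spec)
        (out / "truth.json").write_text(
            json.dumps({"spec": spec_record, "truth": truth}, indent=2) + "\n"
        )
    return table, tree, truth


def _concat_tables(tables: list[FeatureTable]) -> FeatureTable:
    asv_ids = tables[0].asv_ids
    frames = [t.to_dataframe().reindex(columns=asv_ids, fill_value=0) for t in tables]
    return FeatureTable.from_dataframe(pd.concat(frames))
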