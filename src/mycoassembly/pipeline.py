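"""End-to-end orchestration: validate -> diversity -> assembly -> neutral ->
source tracking -> network, from one config, into one JSON report.

Stages are independent where the data allow: a failed stage is recorded in
the report and later stages that do not depend on it still run. Every seed,
permutation count, and threshold applied is echoed into the report, so two
runs with the same config produce identical numbers.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assembly_null, cooccurrence, diversity, neutral_model, source_tracking
from .tables_io import (
    FeatureTable, ValidationError, patristic_distances, read_feature_table,
    read_metadata, read_tree, validate_inputs,
)

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = "1.0"


@dataclass
class RunConfig:
    """All inputs, thresholds, and seeds of one pipeline run.

    Thresholds are recorded verbatim in the report: betaNTI selection bound
    (2), Raup-Crick bound (0.95), network |rho| >= 0.5 at alpha 0.05.
    """

    table_path: str
    metadata_path: str
    out_dir: str
    tree_path: str | None = None
    group_var: str = "species"
    sink_type: str = "bat"
    source_type: str = "environment"
    n_permutations: int = 999
    n_randomizations: int = 999
    seed: int = 1
    bnti_threshold: float = assembly_null.BNTI_THRESHOLD
    rc_threshold: float = assembly_null.RC_THRESHOLD
    rho_threshold: float = 0.5
    alpha: float = 0.05
    top_k: int = 30
    nmds_dimensions: int = 2
    stages: tuple = ("diversity", "assembly", "neutral", "sourcetrack", "network")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)


def _seed_for(base: int, stage: str) -> int:
    """Stable per-stage child seed below 2**31 (process-independent)."""
    tag = zlib.crc32(stage.encode()) % (2 ** 31)
    ss = np.random.SeedSequence([base, tag])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_pipeline(config: RunConfig) -> dict:
    """Run all configured stages; returns (and writes) the aggregated report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "stages": {},
    }

    # -- validation (always first; hard failure stops the run) -------------
    table = read_feature_table(config.table_path)
    meta = read_metadata(config.metadata_path)
    tree = None
    if "assembly" in config.stages and config.tree_path is None:
        raise ValidationError("assembly stage enabled but no tree supplied")
    if config.tree_path:
        tree = read_tree(config.tree_path)
    report["validation"] = validate_inputs(table, tree, meta)

    common = [s for s in table.sample_ids if s in meta.index]
    table = table.filter_samples(common)
    meta = meta.loc[common]
    groups = meta[config.group_var]
    is_sink = meta["sample_type"] == config.sink_type
    is_source = meta["sample_type"] == config.source_type
    bat_table = table.filter_samples(list(meta.index[is_sink]))
    bat_groups = groups[is_sink]

    def _stage(name, fn):
        if name not in config.stages:
            return
        t0 = time.perf_counter()
        try:
            result = fn()
            report["stages"][name] = {"status": "ok", **result}
        except Exception as exc:  # deliberately broad: later stages still run
            logger.exception("stage %s failed", name)
            report["stages"][name] = {"status": "failed", "error": str(exc)}
        finally:
            report["stages"].setdefault(name, {})["wall_seconds"] = round(
                time.perf_counter() - t0, 3
            )
            logger.info("stage %-12s %s", name,
                        report["stages"][name].get("status", "?"))

    # -- diversity ---------------------------------------------------------
    def diversity_stage():
        seed = _seed_for(config.seed, "diversity")
        alpha_df = pd.DataFrame({
            "shannon": [diversity.shannon(r) for r in bat_table.counts],
            "richness": [diversity.observed_richness(r) for r in bat_table.counts],
        }, index=bat_table.sample_ids)
        alpha_df.to_csv(out / "alpha_diversity.tsv", sep="\t", index_label="sample_id")
        dm = diversity.bray_curtis(bat_table)
        dm_df = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
        dm_df.to_csv(out / "bray_curtis.tsv", sep="\t")
        perma = diversity.permanova(dm, bat_groups, config.n_permutations, seed)
        coords, stress = diversity.nmds_embed(dm, config.nmds_dimensions, seed)
        coord_df = pd.DataFrame(
            coords, index=dm.ids,
            columns=[f"axis{i + 1}" for i in range(config.nmds_dimensions)],
        )
        with open(out / "nmds.tsv", "w") as fh:
            fh.write(f"# stress-1 = {stress:.6f}\n")
            coord_df.to_csv(fh, sep="\t", index_label="sample_id")
        part = diversity.shared_asv_partition(bat_table, bat_groups)
        result = {
            "alpha_mean_shannon": float(alpha_df["shannon"].mean()),
            "alpha_mean_richness": float(alpha_df["richness"].mean()),
            "permanova": asdict(perma),
            "nmds_stress": stress,
            "shared_asvs_all_groups": part.all_shared,
            "shared_fraction": part.shared_fraction,
            "unique_counts": part.unique_counts,
            "seed": seed,
        }
        if is_source.any() and is_sink.any():
            pooled = table
            type_groups = meta["sample_type"]
            dm_all = diversity.bray_curtis(pooled)
            perma_ts = diversity.permanova(
                dm_all, type_groups, config.n_permutations, seed + 1
            )
            result["permanova_bat_vs_environment"] = asdict(perma_ts)
        return result

    _stage("diversity", diversity_stage)

    # -- assembly null models ----------------------------------------------
    def assembly_stage():
        seed = _seed_for(config.seed, "assembly")
        dist = patristic_distances(tree, bat_table.asv_ids)
        bnti = assembly_null.beta_nti(
            bat_table, dist, config.n_randomizations, seed
        )
        rc = assembly_null.raup_crick_bray(
            bat_table, config.n_randomizations, seed + 1
        )
        rep = assembly_null.classify_processes(bnti, rc, bat_groups)
        rep.n_randomizations = config.n_randomizations
        rep.pairs.to_csv(out / "assembly_pairs.tsv", sep="\t", index=False)
        rep.fractions.to_csv(out / "assembly_fractions.tsv", sep="\t", index=False)
        pooled = rep.fractions[rep.fractions["group"] == "pooled"].iloc[0]
        return {
            "deterministic_fraction": float(pooled["deterministic"]),
            "process_fractions": {p: float(pooled[p]) for p in assembly_null.PROCESSES},
            "n_pairs": int(pooled["n_pairs"]),
            "n_undefined": rep.n_undefined,
            "n_randomizations": config.n_randomizations,
            "seed": seed,
        }

    _stage("assembly", assembly_stage)

    # -- neutral model -------------------------------------------------------
    def neutral_stage():
        if not is_source.any():
            raise ValidationError(f"no {config.source_type!r} samples for the source pool")
        source_table = table.filter_samples(list(meta.index[is_source]))
        summaries = {}
        for g in sorted(bat_groups.unique()):
            sink = table.filter_samples(list(meta.index[is_sink & (groups == g)]))
            try:
                fit = neutral_model.fit_neutral(
                    sink, source_table,
                    site_by_sample=meta.loc[sink.sample_ids, "site"],
                )
            except ValidationError as exc:
                summaries[g] = {"status": "skipped", "reason": str(exc)}
                continue
            fit.asv_records.to_csv(out / f"neutral_{g}.tsv", sep="\t", index=False)
            summaries[g] = {
                "m": fit.m, "n_eff": fit.n_eff, "nm": fit.nm, "r2": fit.r2,
                "category_counts": fit.category_counts,
                "abundance_shares": fit.abundance_shares,
            }
        (out / "neutral_summary.json").write_text(json.dumps(summaries, indent=2))
        return {"per_group": summaries}

    _stage("neutral", neutral_stage)

    # -- source tracking -----------------------------------------------------
    def sourcetrack_stage():
        if not is_source.any():
            raise ValidationError(f"no {config.source_type!r} samples to use as sources")
        seed = _seed_for(config.seed, "sourcetrack")
        src_group = meta.loc[is_source, "site"].astype(str)
        props = source_tracking.track_sinks(
            table, list(meta.index[is_sink]), src_group, seed=seed
        )
        props.to_csv(out / "source_proportions.tsv", sep="\t", index_label="sink_id")
        env_total = props.drop(columns="Unknown").sum(axis=1)
        by_species = env_total.groupby(bat_groups).mean()
        return {
            "environment_share_by_group": {k: float(v) for k, v in by_species.items()},
            "mean_unknown": float(props["Unknown"].mean()),
            "seed": seed,
        }

    _stage("sourcetrack", sourcetrack_stage)

    # -- co-occurrence network ----------------------------------------------
    def network_stage():
        summaries = {}
        for g in sorted(bat_groups.unique()):
            sub = table.filter_samples(list(meta.index[is_sink & (groups == g)]))
            if sub.n_samples < 5:
                summaries[g] = {"status": "skipped", "reason": "fewer than 5 samples"}
                continue
            net = cooccurrence.spearman_network(
                sub, config.top_k, config.rho_threshold, config.alpha, group=g
            )
            net.write_edges(out / f"network_{g}_edges.tsv")
            summaries[g] = {"nodes": net.nodes, "edges": net.edges}
        return {"per_group": summaries}

    _stage("network", network_stage)

    report["failed_stages"] = [
        k for k, v in report["stages"].items() if v.get("status") == "failed"
    ]
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
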