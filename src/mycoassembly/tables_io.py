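"""Feature tables, phylogenies, sample metadata, and per-sample scalar derivations.

The central containers are :class:`FeatureTable` (samples x ASVs integer counts),
an :class:`skbio.TreeNode` phylogeny with its patristic distance matrix, and a
pandas ``DataFrame`` of per-sample covariates produced by :func:`read_metadata`.
All downstream stages (diversity, null models, neutral fit, source tracking,
networks) consume these three objects.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio
from skbio import DistanceMatrix, TreeNode

logger = logging.getLogger(__name__)

# qPCR standard-curve constants for Pseudogymnoascus destructans load:
# Pd = 10^[(Ct - 22.04942) / -3.34789]
_PD_CT_INTERCEPT = 22.04942
_PD_CT_SLOPE = -3.34789


class ValidationError(ValueError):
    """An input violated a structural invariant (duplicate ids, bad counts, ...)."""


@dataclass
class FeatureTable:
    """Integer count matrix of samples (rows) by ASVs (columns).

    Invariants enforced at construction: unique identifiers, non-negative
    integer counts, and no empty (all-zero) samples — empty samples are
    dropped with a logged warning rather than kept silently.
    """

    sample_ids: list[str]
    asv_ids: list[str]
    counts: np.ndarray
    n_dropped_empty: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.sample_ids), len(self.asv_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.asv_ids)} ASVs"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.allclose(self.counts, rounded, atol=1e-9):
                bad = np.argwhere(~np.isclose(self.counts, rounded))[0]
                raise ValidationError(
                    f"non-integer count at sample {self.sample_ids[bad[0]]!r}, "
                    f"ASV {self.asv_ids[bad[1]]!r}"
                )
            self.counts = rounded.astype(np.int64)
        if (self.counts < 0).any():
            raise ValidationError("negative counts are not allowed")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample identifiers")
        if len(set(self.asv_ids)) != len(self.asv_ids):
            raise ValidationError("duplicate ASV identifiers")
        empty = self.counts.sum(axis=1) == 0
        if empty.any():
            dropped = [s for s, e in zip(self.sample_ids, empty) if e]
            logger.warning("dropping %d all-zero sample(s): %s", len(dropped), dropped)
            self.sample_ids = [s for s, e in zip(self.sample_ids, empty) if not e]
            self.counts = self.counts[~empty]
            self.n_dropped_empty = int(empty.sum())

    # -- views ------------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_asvs(self) -> int:
        return len(self.asv_ids)

    def relative_abundance(self) -> np.ndarray:
        """Row-normalized float view; each row sums to 1."""
        totals = self.counts.sum(axis=1, keepdims=True)
        return self.counts / totals

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.asv_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureTable":
        return cls(
            sample_ids=[str(s) for s in df.index],
            asv_ids=[str(a) for a in df.columns],
            counts=df.to_numpy(),
        )

    # -- subsetting --------------------------------------------------------

    def filter_samples(self, keep: list[str]) -> "FeatureTable":
        idx = [self.sample_ids.index(s) for s in keep]
        return FeatureTable(list(keep), list(self.asv_ids), self.counts[idx])

    def filter_asvs(self, keep: list[str]) -> "FeatureTable":
        pos = {a: j for j, a in enumerate(self.asv_ids)}
        idx = [pos[a] for a in keep]
        return FeatureTable(list(self.sample_ids), list(keep), self.counts[:, idx])

    def rarefy(self, depth: int, seed: int) -> "FeatureTable":
        """Subsample each sample to ``depth`` reads without replacement.

        Samples shallower than ``depth`` are dropped. Not applied anywhere by
        default; counts are stored raw and relative views derived on demand.
        """
        rng = np.random.default_rng(seed)
        keep_ids, rows = [], []
        for i, sid in enumerate(self.sample_ids):
            total = self.counts[i].sum()
            if total < depth:
                logger.warning("rarefy: dropping %s (depth %d < %d)", sid, total, depth)
                continue
            picks = rng.choice(
                np.repeat(np.arange(self.n_asvs), self.counts[i]), depth, replace=False
            )
            rows.append(np.bincount(picks, minlength=self.n_asvs))
            keep_ids.append(sid)
        return FeatureTable(keep_ids, list(self.asv_ids), np.array(rows, dtype=np.int64))

    # -- I/O ---------------------------------------------------------------

    def write_tsv(self, path, orientation: str = "samples") -> None:
        df = self.to_dataframe()
        if orientation == "asvs":
            df = df.T
            df.index.name = "#OTU ID"
        else:
            df.index.name = "sample_id"
        df.to_csv(path, sep="\t")


def read_feature_table(path, format: str = "tsv", orientation: str = "samples") -> FeatureTable:
    """Read a tab-separated count table.

    ``orientation='samples'`` expects samples as rows (canonical);
    ``'asvs'`` transposes ASV-major files such as BIOM-style TSV exports,
    whose ``#OTU ID`` header row is accepted (``format='biom_tsv'`` implies
    ASV-major orientation).
    """
    if format not in ("tsv", "biom_tsv"):
        raise ValueError(f"unknown format {format!r}")
    if format == "biom_tsv":
        orientation = "asvs"
    df = pd.read_csv(path, sep="\t", index_col=0, comment=None, skiprows=_comment_rows(path))
    df.index = df.index.astype(str)
    if orientation == "asvs":
        df = df.T
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = df.index[vals.isna()][0]
            raise ValidationError(f"non-numeric count at row {row!r}, column {col!r}")
        df[col] = vals
    return FeatureTable.from_dataframe(df)


def _comment_rows(path) -> list[int]:
    """Indices of leading '#'-comment lines, keeping a '#OTU ID' header row."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if line.startswith("#") and not line.startswith("#OTU ID"):
                rows.append(i)
            elif not line.startswith("#"):
                break
    return rows


# ---------------------------------------------------------------------------
# phylogeny
# ---------------------------------------------------------------------------

def read_tree(path) -> TreeNode:
    """Read a rooted Newick tree; missing branch lengths become 0."""
    if isinstance(path, os.PathLike):
        path = str(path)
    try:
        tree = TreeNode.read(path, format="newick")
    except Exception as exc:  # skbio raises several parse error types
        raise ValidationError(f"unparseable Newick in {path}: {exc}") from exc
    for node in tree.traverse(include_self=True):
        if node.length is None:
            node.length = 0.0
        elif node.length < 0:
            raise ValidationError(f"negative branch length at {node.name!r}")
    return tree


def patristic_distances(tree: TreeNode, ids: list[str] | None = None) -> DistanceMatrix:
    """All-pairs path-length (patristic) distance matrix over tips.

    If ``ids`` is given, checks that every id is a tip first, reporting the
    set difference before failing.
    """
    dm = tree.tip_tip_distances()
    if ids is not None:
        missing = set(ids) - set(dm.ids)
        if missing:
            raise ValidationError(
                f"{len(missing)} identifier(s) missing from tree tips: {sorted(missing)}"
            )
        dm = dm.filter(ids)
    return dm


# ---------------------------------------------------------------------------
# scalar derivations and sample metadata
# ---------------------------------------------------------------------------

def ct_to_pd_load(ct: float) -> float:
    """log10 Pd fungal load from a qPCR cycle-threshold value.

    Standard-curve form: load = 10^[(Ct - 22.04942) / -3.34789]; the value
    returned is the exponent, i.e. the load in log10 space. Strictly
    decreasing in Ct (later detection = less template).
    """
    if not np.isfinite(ct):
        raise ValidationError("Ct must be finite")
    return (ct - _PD_CT_INTERCEPT) / _PD_CT_SLOPE


def compute_bmi(weight: float, forearm: float) -> float:
    """Bat body mass index: weight (g) divided by forearm length (mm)."""
    if weight <= 0 or forearm <= 0:
        raise ValidationError("weight and forearm length must both be positive")
    return weight / forearm


METADATA_COLUMNS = [
    "sample_id", "species", "site", "sample_type", "sex",
    "forearm_mm", "weight_g", "roost_temp_c", "ct",
]


def derive_sample_fields(df: pd.DataFrame) -> pd.DataFrame:
    """Attach derived per-sample fields: bmi, pd_load_log10, infected.

    ``infected`` is True exactly when a Ct value is present (qPCR detection);
    ``bmi`` is present iff both weight and forearm are; missing fields stay
    as explicit NA, never imputed.
    """
    out = df.copy()
    w = pd.to_numeric(out.get("weight_g"), errors="coerce")
    f = pd.to_numeric(out.get("forearm_mm"), errors="coerce")
    if ((w <= 0) | (f <= 0)).any():
        raise ValidationError("non-positive weight or forearm length")
    out["bmi"] = w / f
    ct = pd.to_numeric(out.get("ct"), errors="coerce")
    out["pd_load_log10"] = (ct - _PD_CT_INTERCEPT) / _PD_CT_SLOPE
    out["infected"] = ct.notna()
    return out


def read_metadata(path) -> pd.DataFrame:
    """Read a per-sample metadata TSV (sample_id-indexed) with derived fields."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValidationError("metadata must have a 'sample_id' column")
    if df["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample identifiers in metadata")
    df = df.set_index("sample_id")
    return derive_sample_fields(df)


def write_metadata(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id")


def validate_inputs(
    table: FeatureTable,
    tree: TreeNode | None = None,
    metadata: pd.DataFrame | None = None,
) -> dict:
    """Cross-check table/tree/metadata identifier agreement.

    Returns a conformance report dict; raises :class:`ValidationError` only
    for table ASVs absent from the tree (phylogenetic stages would fail).
    """
    report: dict = {
        "n_samples": table.n_samples,
        "n_asvs": table.n_asvs,
        "n_dropped_empty_samples": table.n_dropped_empty,
    }
    if tree is not None:
        tips = {t.name for t in tree.tips()}
        missing = sorted(set(table.asv_ids) - tips)
        report["asvs_missing_from_tree"] = missing
        extra = sorted(tips - set(table.asv_ids))
        report["tree_tips_not_in_table"] = len(extra)
        if missing:
            raise ValidationError(
                f"{len(missing)} table ASV(s) missing from tree tips: {missing[:10]}"
            )
    if metadata is not None:
        unlabeled = sorted(set(table.sample_ids) - set(metadata.index))
        report["samples_missing_metadata"] = unlabeled
        if unlabeled:
            logger.warning("%d sample(s) lack metadata rows: %s", len(unlabeled), unlabeled[:10])
    return report
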