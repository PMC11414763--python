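"""Alpha/beta diversity, PERMANOVA, Procrustes, NMDS, and shared-ASV partitions.

PERMANOVA and the Procrustes permutation test (PROTEST) are implemented
directly on the distance-based sum-of-squares partition so the statistic,
permutation scheme, and seeding are fully specified; routine distance and
embedding steps go through scipy/scikit-learn.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from sklearn.manifold import MDS

from .tables_io import FeatureTable, ValidationError

__all__ = [
    "shannon", "observed_richness", "bray_curtis", "permanova",
    "procrustes_test", "shared_asv_partition", "nmds_embed",
    "PermanovaResult", "ProcrustesResult", "SharedAsvPartition",
]


def shannon(counts) -> float:
    """Shannon diversity H = -sum p_i ln p_i, in nats (natural log base)."""
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise ValidationError("negative counts")
    total = x.sum()
    if total <= 0:
        raise ValidationError("Shannon diversity undefined for an all-zero sample")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def observed_richness(counts) -> int:
    """Number of ASVs with count > 0."""
    return int((np.asarray(counts) > 0).sum())


def bray_curtis(table: FeatureTable, use_relative: bool = True) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between samples.

    d(k,l) = sum_i |x_ki - x_li| / sum_i (x_ki + x_li), computed on
    relative abundances by default.
    """
    if table.n_samples < 2:
        raise ValidationError("need at least 2 samples")
    data = table.relative_abundance() if use_relative else table.counts.astype(float)
    condensed = pdist(data, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=table.sample_ids)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p_value: float
    n_permutations: int
    df_between: int
    df_within: int


def _permanova_ss(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray):
    """(SS_total, SS_within) from squared distances and integer group labels."""
    n = d2.shape[0]
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        ss_within += d2[np.ix_(idx, idx)][np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss_total, ss_within


def permanova(
    dm: DistanceMatrix,
    grouping,
    n_permutations: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-factor PERMANOVA by free permutation of sample labels.

    pseudo-F = (SS_between/(a-1)) / (SS_within/(N-a)) with the distance-based
    partition SS_total = sum_{i<j} d_ij^2 / N and SS_within summed per group;
    p uses the add-one convention (1 + #{F_perm >= F_obs}) / (1 + n_perm).

    ``grouping`` maps sample id -> label (dict or pandas Series).
    """
    ids = list(dm.ids)
    if isinstance(grouping, pd.Series):
        grouping = grouping.to_dict()
    try:
        raw = np.array([grouping[s] for s in ids])
    except KeyError as exc:
        raise ValidationError(f"sample {exc.args[0]!r} missing from grouping") from exc
    groups, labels = np.unique(raw, return_inverse=True)
    a, n = len(groups), len(ids)
    if a < 2:
        raise ValidationError("need at least 2 groups")
    sizes = np.bincount(labels)
    if (sizes < 2).any():
        small = groups[sizes < 2]
        raise ValidationError(f"group(s) with fewer than 2 samples: {list(small)}")

    d2 = np.asarray(dm.data) ** 2
    glab = np.arange(a)
    ss_total, ss_within = _permanova_ss(d2, labels, glab)
    ss_between = ss_total - ss_within
    df_b, df_w = a - 1, n - a
    f_obs = (ss_between / df_b) / (ss_within / df_w)
    r2 = ss_between / ss_total

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        sst, ssw = _permanova_ss(d2, perm, glab)
        f_perm = ((sst - ssw) / df_b) / (ssw / df_w)
        if f_perm >= f_obs - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return PermanovaResult(float(f_obs), float(r2), float(p), n_permutations, df_b, df_w)


# ---------------------------------------------------------------------------
# Procrustes / PROTEST
# ---------------------------------------------------------------------------

@dataclass
class ProcrustesResult:
    m2: float
    p_value: float
    n_permutations: int
    allow_reflection: bool


def _procrustes_m2(a: np.ndarray, b: np.ndarray, allow_reflection: bool) -> float:
    """Residual M^2 after optimal translation, scaling, and rotation of b onto a.

    Both configurations are centred and scaled to unit root-mean-square before
    superposition, so M^2 is the symmetric PROTEST statistic in [0, 1]. With
    reflection disallowed the rotation is constrained to det = +1 (Kabsch).
    """
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    u, s, vt = np.linalg.svd(a.T @ b)
    if not allow_reflection and np.linalg.det(u @ vt) < 0:
        s = s.copy()
        s[-1] = -s[-1]
    return float(1.0 - s.sum() ** 2)


def procrustes_test(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    n_permutations: int = 999,
    seed: int | None = None,
    allow_reflection: bool = True,
) -> ProcrustesResult:
    """PROTEST: Procrustes M^2 with a row-permutation significance test.

    Rows of the two coordinate sets must correspond to the same samples in
    the same order. The null permutes rows of ``coords_b``; p is the add-one
    tail probability of a permuted M^2 at or below the observed one.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[0] != b.shape[0]:
        raise ValidationError("coordinate sets must be 2-D with matching row counts")
    if a.shape[0] < 3:
        raise ValidationError("need at least 3 matched rows")
    if a.shape[1] != b.shape[1]:
        k = min(a.shape[1], b.shape[1])
        a, b = a[:, :k], b[:, :k]

    m2_obs = _procrustes_m2(a, b, allow_reflection)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        m2_perm = _procrustes_m2(a, b[rng.permutation(b.shape[0])], allow_reflection)
        if m2_perm <= m2_obs + 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return ProcrustesResult(float(m2_obs), float(p), n_permutations, allow_reflection)


# ---------------------------------------------------------------------------
# shared/unique ASV partition (UpSet-style)
# ---------------------------------------------------------------------------

@dataclass
class SharedAsvPartition:
    """Exclusive intersection cells over per-group ASV incidence sets."""

    groups: list[str]
    cells: dict[frozenset, int]        # exclusive membership pattern -> size
    unique_counts: dict[str, int]      # ASVs found in exactly one group
    all_shared: int                    # ASVs found in every group
    union_size: int
    shared_fraction: float             # |intersection of all| / |union of all|


def shared_asv_partition(table: FeatureTable, grouping) -> SharedAsvPartition:
    """UpSet-style exclusive intersection sizes of per-group ASV sets.

    An ASV belongs to a group's set iff its summed count over that group's
    samples is > 0. Cell sizes are exclusive (each ASV counted in exactly the
    cell of groups that contain it) and therefore sum to the union size.
    """
    if isinstance(grouping, pd.Series):
        grouping = grouping.to_dict()
    missing = [s for s in table.sample_ids if s not in grouping]
    if missing:
        raise ValidationError(f"unlabeled sample(s): {missing[:10]}")
    labels = sorted({grouping[s] for s in table.sample_ids})
    incidence = {}
    for g in labels:
        rows = [i for i, s in enumerate(table.sample_ids) if grouping[s] == g]
        incidence[g] = table.counts[rows].sum(axis=0) > 0

    membership = np.array([incidence[g] for g in labels])  # groups x asvs
    cells: dict[frozenset, int] = {}
    present = membership.any(axis=0)
    for j in np.flatnonzero(present):
        key = frozenset(g for g, row in zip(labels, membership) if row[j])
        cells[key] = cells.get(key, 0) + 1
    union = int(present.sum())
    all_shared = cells.get(frozenset(labels), 0)
    unique = {g: cells.get(frozenset([g]), 0) for g in labels}
    return SharedAsvPartition(
        groups=labels,
        cells=cells,
        unique_counts=unique,
        all_shared=all_shared,
        union_size=union,
        shared_fraction=all_shared / union if union else 0.0,
    )


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

def nmds_embed(
    dm: DistanceMatrix,
    k: int = 2,
    seed: int | None = None,
    n_restarts: int = 20,
) -> tuple[np.ndarray, float]:
    """Non-metric MDS of a distance matrix; returns (coords, Kruskal stress-1).

    Runs ``n_restarts`` random initializations and keeps the lowest-stress
    configuration.
    """
    n = len(dm.ids)
    if k >= n:
        raise ValidationError(f"k={k} must be smaller than n={n} samples")
    mds = MDS(
        n_components=k,
        metric=False,
        dissimilarity="precomputed",
        n_init=n_restarts,
        random_state=seed,
        normalized_stress=True,
        max_iter=500,
        eps=1e-9,
    )
    coords = mds.fit_transform(np.asarray(dm.data))
    return coords, float(mds.stress_)
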