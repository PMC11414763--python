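"""Source attribution of sink communities by an EM multinomial mixture.

Each sink community's counts are modeled as Multinomial(N, sum_k alpha_k
gamma_k + alpha_0 gamma_0): a convex mixture of known source profiles
gamma_k (fixed at pseudocount-smoothed empirical frequencies) plus a free
"unknown source" profile gamma_0 that absorbs sink reads no candidate
source explains. EM alternates fractional read assignment (E-step) with
updates of the mixing proportions alpha and the unknown profile (M-step);
the log-likelihood is monotone non-decreasing by construction and asserted
on every run. This is a generic mixture formulation of microbial source
tracking, deliberately simpler than estimators that also re-estimate the
known source profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables_io import FeatureTable, ValidationError

__all__ = ["em_source_track", "track_sinks", "SourceEstimate"]

_SMOOTH = 0.5  # add-half pseudocount when smoothing source profiles


@dataclass
class SourceEstimate:
    sink_id: str
    source_names: list[str]
    proportions: np.ndarray          # len K known sources (+1 unknown if enabled)
    unknown: float | None            # alpha_0, or None when disabled
    log_likelihood: float
    ll_trace: list[float] = field(repr=False)
    iterations: int = 0
    converged: bool = True
    unknown_profile: np.ndarray | None = field(default=None, repr=False)

    def as_series(self) -> pd.Series:
        names = list(self.source_names)
        vals = list(self.proportions)
        if self.unknown is not None:
            names.append("Unknown")
            vals.append(self.unknown)
        return pd.Series(vals, index=names, name=self.sink_id)


def _source_profiles(source_tables, asv_ids):
    """Smoothed profiles plus the raw (pre-smoothing) support union."""
    names, profiles, raw = [], [], []
    pos = {a: j for j, a in enumerate(asv_ids)}
    for name, tbl in source_tables.items():
        counts = np.zeros(len(asv_ids))
        sub_pos = [pos[a] for a in tbl.asv_ids if a in pos]
        sub_cols = [j for j, a in enumerate(tbl.asv_ids) if a in pos]
        counts[sub_pos] = tbl.counts[:, sub_cols].sum(axis=0)
        raw.append(counts)
        prof = counts + _SMOOTH
        profiles.append(prof / prof.sum())
        names.append(str(name))
    support = np.vstack(raw).sum(axis=0) > 0
    return names, np.array(profiles), support


def _em_once(x, gammas, unknown_mask, rng, max_iter, tol):
    """One EM run from a random start; returns (alpha, gamma0, ll_trace, ...).

    ``unknown_mask``: boolean support of the unknown-source profile (taxa no
    source can explain), or None when the unknown source is disabled. The
    unknown profile is re-estimated each M-step but confined to that
    support, which keeps the mixture identifiable: a totally free profile
    could imitate the sink itself and absorb all reads.
    """
    unknown = unknown_mask is not None
    k = gammas.shape[0]
    n_comp = k + (1 if unknown else 0)
    alpha = rng.dirichlet(np.ones(n_comp))
    total = x.sum()

    if unknown:
        resid = np.where(unknown_mask, x / total, 0.0)
        if resid.sum() > 0:
            gamma0 = resid / resid.sum()
        else:  # no unexplained taxa: fixed uniform profile, alpha_0 -> ~0
            gamma0 = np.full(x.size, 1.0 / x.size)
            unknown_mask = None  # do not re-estimate
    else:
        gamma0 = None

    ll_trace = []
    prev = -np.inf
    for it in range(1, max_iter + 1):
        comps = np.vstack([gammas, gamma0[None, :]]) if unknown else gammas
        mix = alpha @ comps                               # per-taxon mixture prob
        mix = np.maximum(mix, 1e-300)
        ll = float((x * np.log(mix)).sum())
        ll_trace.append(ll)
        # responsibilities r[c, i] = alpha_c comps[c,i] / mix[i]
        r = alpha[:, None] * comps / mix[None, :]
        weighted = r * x[None, :]                         # expected reads per comp
        alpha = weighted.sum(axis=1) / total
        if unknown and unknown_mask is not None:
            w0 = np.where(unknown_mask, weighted[-1], 0.0)
            mass = w0.sum()
            if mass > 0:
                gamma0 = w0 / mass
        if abs(ll - prev) < tol:
            return alpha, gamma0, ll_trace, it, True
        prev = ll
    return alpha, gamma0, ll_trace, max_iter, False


def em_source_track(
    sink_counts,
    source_tables,
    sink_id: str = "sink",
    unknown: bool = True,
    max_iter: int = 2000,
    tol: float = 1e-8,
    seed: int | None = None,
    n_restarts: int = 5,
    asv_ids: list[str] | None = None,
) -> SourceEstimate:
    """Estimate mixing proportions of one sink over candidate sources.

    ``source_tables`` is a mapping source-name -> FeatureTable (samples of
    that source pooled into one smoothed profile) or an (K x T) array of
    profiles when ``asv_ids`` gives the shared taxon order. Runs
    ``n_restarts`` EM chains from random Dirichlet starts and keeps the
    highest-likelihood solution.
    """
    x = np.asarray(sink_counts, dtype=float)
    if x.sum() <= 0:
        raise ValidationError("sink has no reads")
    if (x < 0).any():
        raise ValidationError("negative sink counts")

    if isinstance(source_tables, dict):
        if asv_ids is None:
            raise ValidationError("asv_ids required with FeatureTable sources")
        names, gammas, support = _source_profiles(source_tables, asv_ids)
    else:
        gammas = np.asarray(source_tables, dtype=float)
        support = gammas.sum(axis=0) > 0
        gammas = gammas / gammas.sum(axis=1, keepdims=True)
        names = [f"source_{k + 1}" for k in range(gammas.shape[0])]
    if gammas.shape[1] != x.size:
        raise ValidationError("sink and sources must share one ASV universe")

    if not unknown and not support[x > 0].any():
        raise ValidationError(
            "sink has no overlap with any source and the unknown source is disabled"
        )
    unknown_mask = ~support if unknown else None

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(n_restarts, 1)):
        alpha, gamma0, trace, iters, conv = _em_once(
            x, gammas, unknown_mask, rng, max_iter, tol
        )
        diffs = np.diff(trace)
        assert (diffs >= -1e-6 * np.maximum(np.abs(trace[:-1]), 1.0)).all(), \
            "EM log-likelihood decreased"
        if best is None or trace[-1] > best[2][-1]:
            best = (alpha, gamma0, trace, iters, conv)
    alpha, gamma0, trace, iters, conv = best

    k = gammas.shape[0]
    return SourceEstimate(
        sink_id=sink_id,
        source_names=names,
        proportions=alpha[:k],
        unknown=float(alpha[k]) if unknown else None,
        log_likelihood=trace[-1],
        ll_trace=trace,
        iterations=iters,
        converged=conv,
        unknown_profile=gamma0,
    )


def track_sinks(
    table: FeatureTable,
    sink_ids: list[str],
    source_grouping,
    seed: int | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Run EM source tracking independently for each sink sample.

    ``source_grouping`` maps source sample id -> source name; all samples of
    a name are pooled into one profile. Returns a sinks x (sources...,
    Unknown) proportions DataFrame. Each sink gets a child seed so results
    are reproducible yet independent.
    """
    if isinstance(source_grouping, pd.Series):
        source_grouping = source_grouping.to_dict()
    groups: dict[str, list[str]] = {}
    for s, g in source_grouping.items():
        groups.setdefault(str(g), []).append(s)
    source_tables = {g: table.filter_samples(ss) for g, ss in sorted(groups.items())}

    ss = np.random.SeedSequence(seed)
    rows = []
    for sink, child in zip(sink_ids, ss.spawn(len(sink_ids))):
        x = table.counts[table.sample_ids.index(sink)]
        est = em_source_track(
            x, source_tables, sink_id=sink, asv_ids=table.asv_ids,
            seed=int(child.generate_state(1)[0] % (2 ** 31)), **kwargs,
        )
        rows.append(est.as_series())
    return pd.DataFrame(rows)
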