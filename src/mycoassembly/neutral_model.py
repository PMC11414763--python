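"""Sloan neutral community model: fit and per-ASV neutrality partition.

The model predicts the occurrence frequency of a taxon across local (sink)
communities from its mean relative abundance p in the source pool, the
effective community size N (reads per sample), and a migration parameter m.
At stationarity the local relative abundance of the taxon is Beta(N m p,
N m (1 - p)) distributed, so the probability of detecting it above a
detection limit d is 1 - BetaCDF(d; N m p, N m (1 - p)).

Only m is free; N is fixed from the data (mean total reads per sink sample)
and d = 1/N, the smallest detectable relative abundance at that depth.
ASVs whose observed sink occurrence falls outside 95% bounds around the
prediction are called over-/under-represented; the rest are neutral.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.proportion import proportion_confint

from .tables_io import FeatureTable, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["predict_frequency", "fit_neutral", "NeutralFitReport"]


def predict_frequency(p, m: float, n_eff: float, d: float):
    """Expected fraction of sink samples in which an ASV is detected.

    1 - BetaCDF(d; N m p, N m (1-p)) with N = n_eff reads, migration m,
    detection limit d (relative abundance). Non-decreasing in p.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValidationError("source relative abundance p must lie in (0, 1)")
    if m <= 0 or n_eff < 1 or not (0 < d < 1):
        raise ValidationError("require m > 0, n_eff >= 1, 0 < d < 1")
    nm = n_eff * m
    out = stats.beta.sf(d, nm * p, nm * (1.0 - p))
    return float(out) if out.ndim == 0 else out


@dataclass
class NeutralFitReport:
    """Fitted Sloan model with the per-ASV neutrality partition.

    ``asv_records`` columns: asv_id, p (mean source relative abundance),
    observed_freq, predicted_freq, lower, upper, category. ``r2`` is the
    generalized fit statistic 1 - SSE/SST and can be negative when the
    neutral prediction fits worse than the mean.
    """

    m: float
    n_eff: float
    nm: float
    r2: float
    detection_limit: float
    n_sink_samples: int
    asv_records: pd.DataFrame
    category_counts: dict
    abundance_shares: dict          # share of total sink abundance per category
    n_source_only_excluded: int     # source ASVs never seen in the sink universe
    n_sink_only: int                # sink ASVs absent from the source pool
    ci_method: str = "wilson"
    per_site_shares: pd.DataFrame | None = None


def _category(obs: np.ndarray, lower: np.ndarray, upper: np.ndarray) -> np.ndarray:
    cat = np.full(obs.shape, "neutral", dtype=object)
    cat[obs > upper] = "over"
    cat[obs < lower] = "under"
    return cat


def fit_neutral(
    sink_table: FeatureTable,
    source_table: FeatureTable,
    seed: int | None = None,
    ci_method: str = "wilson",
    site_by_sample: dict | pd.Series | None = None,
    min_shared_asvs: int = 10,
) -> NeutralFitReport:
    """Fit the neutral model of a sink metacommunity against a source pool.

    p is each ASV's mean relative abundance across source samples; observed
    frequency is the fraction of sink samples where the ASV has a positive
    count. m is fitted by least squares of observed on predicted frequency
    over ASVs present in both sink and source. 95% bounds are Wilson score
    intervals around the predicted frequency with n = number of sink samples
    (``ci_method='fit'`` instead propagates the +/-1.96 SE interval of the
    fitted m). ``site_by_sample`` adds per-site abundance-share summaries
    from the pooled fit.
    """
    if sink_table.n_samples < 5:
        raise ValidationError("need at least 5 sink samples")
    if source_table.n_samples < 1:
        raise ValidationError("need at least 1 source sample")

    universe = [a for a in sink_table.asv_ids if a in set(source_table.asv_ids)]
    sink_present = sink_table.counts.sum(axis=0) > 0
    sink_active = {a for a, keep in zip(sink_table.asv_ids, sink_present) if keep}
    shared = [a for a in universe if a in sink_active]
    n_sink_only = len(sink_active - set(source_table.asv_ids))
    if n_sink_only:
        logger.info(
            "%d sink ASV(s) absent from the source pool; excluded from the fit "
            "(candidate unknown-source taxa)", n_sink_only,
        )
    if len(shared) < min_shared_asvs:
        raise ValidationError(
            f"only {len(shared)} ASVs shared between sink and source "
            f"(need >= {min_shared_asvs})"
        )

    src_rel = source_table.filter_asvs(shared).relative_abundance()
    p = src_rel.mean(axis=0)
    # clip p strictly inside (0,1): a shared ASV can still have p == 0 rows
    eps = 1.0 / (source_table.counts.sum() + 1)
    p = np.clip(p, eps, 1 - eps)

    sink_sub = sink_table.filter_asvs(shared)
    n_sink = sink_table.n_samples
    obs_freq = (sink_sub.counts > 0).mean(axis=0)

    n_eff = float(sink_table.counts.sum(axis=1).mean())
    d = 1.0 / n_eff

    def sse(log_m: float) -> float:
        pred = predict_frequency(p, float(np.exp(log_m)), n_eff, d)
        return float(((obs_freq - pred) ** 2).sum())

    res = optimize.minimize_scalar(sse, bounds=(np.log(1e-7), np.log(1e3)), method="bounded")
    if not res.success:
        raise ValidationError(f"neutral fit failed: {res.message}; objective trace {res.x}")
    m = float(np.exp(res.x))
    if not (np.log(1e-7) + 1e-6 < res.x < np.log(1e3) - 1e-6):
        logger.warning("fitted m at the bound of the search interval (m=%.3g)", m)

    pred = predict_frequency(p, m, n_eff, d)
    sst = float(((obs_freq - obs_freq.mean()) ** 2).sum())
    r2 = 1.0 - res.fun / sst if sst > 0 else np.nan

    if ci_method == "wilson":
        lower, upper = proportion_confint(
            np.round(pred * n_sink), n_sink, alpha=0.05, method="wilson"
        )
    elif ci_method == "fit":
        # +/-1.96 SE on m via inverse curvature of the SSE profile
        h = 1e-4
        curv = (sse(res.x + h) - 2 * res.fun + sse(res.x - h)) / h ** 2
        sigma2 = res.fun / max(len(shared) - 1, 1)
        se_logm = np.sqrt(2 * sigma2 / max(curv, 1e-12))
        lower = predict_frequency(p, m * np.exp(-1.96 * se_logm), n_eff, d)
        upper = predict_frequency(p, m * np.exp(1.96 * se_logm), n_eff, d)
    else:
        raise ValidationError(f"unknown ci_method {ci_method!r}")

    cat = _category(obs_freq, lower, upper)
    records = pd.DataFrame({
        "asv_id": shared,
        "p": p,
        "observed_freq": obs_freq,
        "predicted_freq": pred,
        "lower": lower,
        "upper": upper,
        "category": cat,
    })
    counts = {c: int((cat == c).sum()) for c in ("neutral", "over", "under")}

    sink_rel_all = sink_table.relative_abundance()
    pos = {a: j for j, a in enumerate(sink_table.asv_ids)}
    idx = {c: [pos[a] for a, cc in zip(shared, cat) if cc == c]
           for c in ("neutral", "over", "under")}
    shares = {c: float(sink_rel_all[:, idx[c]].sum() / n_sink) for c in idx}

    per_site = None
    if site_by_sample is not None:
        if isinstance(site_by_sample, pd.Series):
            site_by_sample = site_by_sample.to_dict()
        site_rows = []
        for site in sorted({site_by_sample[s] for s in sink_table.sample_ids}):
            rows = [i for i, s in enumerate(sink_table.sample_ids)
                    if site_by_sample[s] == site]
            row = {"site": site, "n_samples": len(rows)}
            for c in idx:
                row[c] = float(sink_rel_all[np.ix_(rows, idx[c])].sum() / len(rows))
            site_rows.append(row)
        per_site = pd.DataFrame(site_rows)

    return NeutralFitReport(
        m=m, n_eff=n_eff, nm=m * n_eff, r2=float(r2), detection_limit=d,
        n_sink_samples=n_sink, asv_records=records, category_counts=counts,
        abundance_shares=shares,
        n_source_only_excluded=len(universe) - len(shared),
        n_sink_only=n_sink_only, ci_method=ci_method, per_site_shares=per_site,
    )
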