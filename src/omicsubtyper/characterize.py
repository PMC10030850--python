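"""Statistical characterization of clusters.

Survival: Kaplan-Meier product-limit curves per cluster and the G-group
log-rank test for OS/DFS endpoints. Differential features: per-feature
one-way ANOVA with Tukey HSD post-hoc pairwise tests and Benjamini-Hochberg
FDR; methylation runs through an sd filter, quantile normalization and a
log2 transform first. Mutation and copy-number enrichment: one-vs-rest
two-sided Fisher exact tests.

Note: moderated (empirical-Bayes) statistics are deliberately replaced by
ordinary per-feature F-tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import ClusterAssignment, OmicKind, OmicMatrix, SurvivalTable

BETA_LOG2_OFFSET = 1e-3  # avoids -inf at beta = 0


@dataclass
class KMResult:
    cluster: object
    times: np.ndarray  # event/censor times in ascending order
    survival: np.ndarray  # S(t) evaluated at `times`
    at_risk: np.ndarray
    median: float  # np.inf when never reaching 0.5 ("not reached")

    @property
    def median_reached(self) -> bool:
        return np.isfinite(self.median)


@dataclass
class DEResult:
    feature_id: str
    omic_kind: OmicKind
    statistic: float
    p: float
    q: float = np.nan
    pairwise: dict = field(default_factory=dict)  # (a, b) -> (mean_diff, adj_p)
    selected: bool = False


@dataclass
class EnrichmentResult:
    feature_id: str
    cluster: object
    contingency: np.ndarray  # [[altered_in, altered_out], [clean_in, clean_out]]
    p: float
    q: float = np.nan
    selected: bool = False


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


# -- survival ----------------------------------------------------------------


def km_estimate(surv: SurvivalTable, group) -> KMResult:
    """Product-limit estimate for one cluster; median = earliest time with
    S(t) <= 0.5, np.inf when the curve never drops that far."""
    sel = surv.cluster == group
    if not sel.any():
        raise ValueError(f"cluster {group!r} is empty")
    t, e = surv.time[sel], surv.event[sel]
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    tab = kmf.event_table
    times = tab.index.to_numpy(dtype=float)
    survival = kmf.survival_function_["KM_estimate"].to_numpy()
    at_risk = tab["at_risk"].to_numpy(dtype=float)
    below = survival <= 0.5
    median = float(times[below][0]) if below.any() else np.inf
    return KMResult(cluster=group, times=times, survival=survival, at_risk=at_risk, median=median)


def logrank_test(surv: SurvivalTable):
    """G-group log-rank test; returns (chi2 statistic, df, p)."""
    groups = np.unique(surv.cluster)
    if len(groups) < 2:
        raise ValueError("log-rank test requires at least 2 non-empty groups")
    res = multivariate_logrank_test(surv.time, surv.cluster, surv.event)
    return float(res.test_statistic), len(groups) - 1, float(res.p_value)


# -- differential features ---------------------------------------------------


def _group_indices(labels: ClusterAssignment):
    return {k: np.flatnonzero(labels.labels == k) for k in range(1, labels.K + 1)}


def _anova_f(values: np.ndarray, groups: dict) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized one-way ANOVA over feature columns.

    Degenerate features (zero between- and within-group variance) get F = 0,
    p = 1 so batch runs never crash.
    """
    n, p = values.shape
    G = len(groups)
    grand = values.mean(axis=0)
    ss_between = np.zeros(p)
    ss_within = np.zeros(p)
    for idx in groups.values():
        sub = values[idx]
        gm = sub.mean(axis=0)
        ss_between += len(idx) * (gm - grand) ** 2
        ss_within += ((sub - gm) ** 2).sum(axis=0)
    df_b, df_w = G - 1, n - G
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / df_b) / (ss_within / df_w)
    degenerate = ~np.isfinite(F)
    F[degenerate] = 0.0
    pvals = stats.f.sf(F, df_b, df_w)
    pvals[degenerate] = 1.0
    # zero spread entirely: declared convention F = 0, p = 1
    flat = (ss_between < 1e-300) & (ss_within < 1e-300)
    F[flat], pvals[flat] = 0.0, 1.0
    return F, pvals


def _tukey_pairs(col: np.ndarray, groups: dict) -> dict:
    """Tukey HSD adjusted p-values with the harmonic-mean group size
    (Tukey-Kramer) for unbalanced clusters."""
    keys = sorted(groups)
    G = len(keys)
    n = sum(len(groups[k]) for k in keys)
    df_w = n - G
    mse = sum(((col[groups[k]] - col[groups[k]].mean()) ** 2).sum() for k in keys) / df_w
    out = {}
    for i, a in enumerate(keys):
        for b in keys[i + 1 :]:
            na, nb = len(groups[a]), len(groups[b])
            diff = col[groups[a]].mean() - col[groups[b]].mean()
            se = np.sqrt(mse / 2 * (1 / na + 1 / nb))
            if se == 0:
                adj_p = 1.0 if diff == 0 else 0.0
            else:
                q = abs(diff) / se
                adj_p = float(stats.studentized_range.sf(q, G, df_w))
            out[(a, b)] = (float(diff), adj_p)
    return out


def anova_tukey_de(
    m: OmicMatrix, labels: ClusterAssignment, q_threshold: float = 0.05
) -> list[DEResult]:
    """Per-feature one-way ANOVA across clusters, BH across features, Tukey
    HSD pairwise tests computed for the selected (q <= threshold) features."""
    if labels.K < 2:
        raise ValueError("need at least 2 clusters")
    groups = _group_indices(labels)
    if any(len(idx) < 2 for idx in groups.values()):
        raise ValueError("every cluster needs >= 2 samples")
    if m.missing_mask.any():
        raise ValueError("matrix must be fully observed (impute first)")
    order = [m.sample_ids.index(s) for s in labels.sample_ids]
    values = m.values[order]
    F, pvals = _anova_f(values, groups)
    qvals = bh_adjust(pvals)
    results = []
    for j, fid in enumerate(m.feature_ids):
        selected = bool(qvals[j] <= q_threshold)
        pairwise = _tukey_pairs(values[:, j], groups) if selected else {}
        results.append(
            DEResult(
                feature_id=fid,
                omic_kind=m.kind,
                statistic=float(F[j]),
                p=float(pvals[j]),
                q=float(qvals[j]),
                pairwise=pairwise,
                selected=selected,
            )
        )
    return results


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Make every sample's (row's) value distribution identical: rank r gets
    the mean of the r-th order statistics across samples; ties averaged."""
    n, p = values.shape
    ref = np.sort(values, axis=1).mean(axis=0)
    out = np.empty_like(values, dtype=float)
    for i in range(n):
        ranks = stats.rankdata(values[i], method="average") - 1
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        out[i] = (ref[lo] + ref[hi]) / 2
    return out


def methylation_de(
    m: OmicMatrix,
    labels: ClusterAssignment,
    sd_min: float = 0.2,
    q_threshold: float = 0.05,
) -> list[DEResult]:
    """Probes with sd > sd_min are quantile normalized, log2 transformed
    (offset avoids -inf at 0) and compared across clusters with per-probe
    F-tests plus BH."""
    if m.kind is not OmicKind.F3_METHYLATION:
        raise ValueError("methylation_de requires an F3 matrix")
    if m.missing_mask.any():
        raise ValueError("matrix must be fully observed (impute first)")
    sd = m.values.std(axis=0, ddof=1)
    keep = np.flatnonzero(sd > sd_min)
    if keep.size == 0:
        import warnings

        warnings.warn("no probe passes the sd filter; empty result", stacklevel=2)
        return []
    sub = m.subset(feature_idx=keep)
    order = [sub.sample_ids.index(s) for s in labels.sample_ids]
    values = sub.values[order]
    values = quantile_normalize(values)
    values = np.log2(values + BETA_LOG2_OFFSET)
    groups = _group_indices(labels)
    F, pvals = _anova_f(values, groups)
    qvals = bh_adjust(pvals)
    return [
        DEResult(
            feature_id=fid,
            omic_kind=m.kind,
            statistic=float(F[j]),
            p=float(pvals[j]),
            q=float(qvals[j]),
            selected=bool(qvals[j] <= q_threshold),
        )
        for j, fid in enumerate(sub.feature_ids)
    ]


# -- enrichment --------------------------------------------------------------


def fisher_enrichment(
    binary: pd.DataFrame,
    labels: ClusterAssignment,
    q_threshold: float = 0.05,
    adjust: bool = True,
    p_threshold: float | None = None,
) -> list[EnrichmentResult]:
    """One-vs-rest two-sided Fisher exact tests per feature x cluster.

    ``binary`` is a features x samples 0/1 table. With ``adjust`` (default)
    BH runs pooled over all feature x cluster tests and selection uses
    q <= q_threshold; with ``adjust=False`` selection uses the raw
    p <= p_threshold (the copy-number convention).
    """
    missing = [s for s in labels.sample_ids if s not in binary.columns]
    if missing:
        raise ValueError(f"samples absent from binary matrix: {missing[:5]}")
    mat = binary[labels.sample_ids].to_numpy() != 0
    results = []
    for k in range(1, labels.K + 1):
        in_k = labels.labels == k
        if not in_k.any():
            raise ValueError(f"cluster {k} is empty")
        for gi, gene in enumerate(binary.index):
            altered = mat[gi]
            table = np.array(
                [
                    [int((altered & in_k).sum()), int((altered & ~in_k).sum())],
                    [int((~altered & in_k).sum()), int((~altered & ~in_k).sum())],
                ]
            )
            _, p = stats.fisher_exact(table, alternative="two-sided")
            results.append(
                EnrichmentResult(feature_id=str(gene), cluster=k, contingency=table, p=float(p))
            )
    pvals = np.array([r.p for r in results])
    if adjust:
        qvals = bh_adjust(pvals)
        for r, q in zip(results, qvals):
            r.q = float(q)
            r.selected = bool(q <= q_threshold)
    else:
        thr = 0.01 if p_threshold is None else p_threshold
        for r in results:
            r.selected = bool(r.p <= thr)
    return results


def cnv_binarize(segmean: pd.DataFrame, threshold: float = 0.3):
    """Split a cytoband x sample segment-mean table into gain/loss indicator
    tables; |segmean| >= threshold counts as altered (boundary inclusive)."""
    vals = segmean.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("segment means must be finite")
    gain = pd.DataFrame(vals >= threshold, index=segmean.index, columns=segmean.columns)
    loss = pd.DataFrame(vals <= -threshold, index=segmean.index, columns=segmean.columns)
    return gain, loss
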