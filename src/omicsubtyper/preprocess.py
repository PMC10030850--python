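"""Per-omic filtering, imputation, normalization and multi-omics stacking.

The entry point :func:`preprocess_omic` applies the per-kind recipe:

* F1 (mRNA): zero-filter -> top-variance selection -> min-max scaling
* F2 (miRNA): zero-filter -> min-max scaling
* F3 (methylation): probe blacklist -> sample filter -> probe filter ->
  KNN imputation -> top-variance selection (beta values need no scaling)
* F4 (protein): feature filter -> KNN imputation (level-4 data arrives
  normalized)

Dropping thresholds are strict-greater: a feature/sample with a bad-entry
fraction exactly at the threshold is retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import MultiOmicsStack, OmicKind, OmicMatrix


class EmptyResultError(ValueError):
    """All features or samples were removed by a filter."""


@dataclass
class PreprocessConfig:
    max_zero_fraction: float = 0.20
    max_missing_fraction: float = 0.10
    knn_k: int = 5
    top_n_variable: int = 2000
    # per-kind switches; defaults mirror the published recipe
    variance_select: dict = field(
        default_factory=lambda: {
            OmicKind.F1_MRNA: True,
            OmicKind.F2_MIRNA: False,
            OmicKind.F3_METHYLATION: True,
            OmicKind.F4_PROTEIN: False,
        }
    )
    normalize: dict = field(
        default_factory=lambda: {
            OmicKind.F1_MRNA: True,
            OmicKind.F2_MIRNA: True,
            OmicKind.F3_METHYLATION: False,
            OmicKind.F4_PROTEIN: False,
        }
    )

    def __post_init__(self) -> None:
        for name in ("max_zero_fraction", "max_missing_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        if self.top_n_variable < 1:
            raise ValueError("top_n_variable must be >= 1")


def filter_sparse_features(
    m: OmicMatrix, max_bad_fraction: float, criterion: str = "zero"
) -> OmicMatrix:
    """Drop features whose fraction of bad entries exceeds ``max_bad_fraction``.

    ``criterion`` is ``"zero"`` (zero expression counts; F1/F2) or
    ``"missing"``. Strictly-greater fractions are dropped; features exactly
    at the threshold are kept. Sample set and feature order are preserved.
    """
    if criterion not in ("zero", "missing"):
        raise ValueError("criterion must be 'zero' or 'missing'")
    if m.n_features == 0 or m.n_samples == 0:
        raise ValueError("matrix is empty")
    if criterion == "zero":
        if m.kind not in (OmicKind.F1_MRNA, OmicKind.F2_MIRNA):
            raise ValueError("zero-filter applies to F1/F2 expression matrices only")
        bad = (m.values == 0) & ~m.missing_mask
    else:
        bad = m.missing_mask
    frac = bad.sum(axis=0) / m.n_samples
    keep = np.flatnonzero(frac <= max_bad_fraction)
    if keep.size == 0:
        raise EmptyResultError("no features survive filter")
    return m.subset(feature_idx=keep)


def filter_sparse_samples(m: OmicMatrix, max_missing_fraction: float) -> OmicMatrix:
    """Drop samples with a missing-entry fraction strictly above the threshold."""
    if m.n_features == 0 or m.n_samples == 0:
        raise ValueError("matrix is empty")
    frac = m.missing_mask.sum(axis=1) / m.n_features
    keep = np.flatnonzero(frac <= max_missing_fraction)
    if keep.size == 0:
        raise EmptyResultError("no samples survive filter")
    return m.subset(sample_idx=keep)


def knn_impute(m: OmicMatrix, k: int = 5) -> OmicMatrix:
    """Impute missing entries as the unweighted mean of the ``k`` nearest
    samples (Euclidean distance over mutually observed coordinates) that
    observe the feature.

    Fallbacks: fewer than ``k`` eligible neighbours -> use all available;
    none -> the feature's global observed mean. Observed entries are left
    bit-identical.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if m.missing_mask.all():
        raise ValueError("matrix is fully missing; cannot impute")
    if not m.missing_mask.any():
        return m.subset()

    values = m.values.copy()
    mask = m.missing_mask
    obs = ~mask
    n = m.n_samples
    feat_means = np.array(
        [values[obs[:, j], j].mean() if obs[:, j].any() else np.nan for j in range(m.n_features)]
    )

    # pairwise distances over mutually observed coordinates
    dist = np.full((n, n), np.inf)
    for i in range(n):
        for l in range(i + 1, n):
            shared = obs[i] & obs[l]
            if shared.any():
                d = values[i, shared] - values[l, shared]
                dist[i, l] = dist[l, i] = float(np.sqrt(np.dot(d, d)))

    out = values.copy()
    for i in range(n):
        miss_j = np.flatnonzero(mask[i])
        if miss_j.size == 0:
            continue
        order = np.argsort(dist[i], kind="stable")
        for j in miss_j:
            donors = [l for l in order if l != i and obs[l, j] and np.isfinite(dist[i, l])]
            if donors:
                chosen = donors[:k]
                out[i, j] = float(np.mean(values[chosen, j]))
            else:
                out[i, j] = feat_means[j]
    if np.isnan(out).any():
        raise ValueError("imputation failed: feature with no observed values")
    return OmicMatrix(
        sample_ids=list(m.sample_ids),
        feature_ids=list(m.feature_ids),
        values=out,
        missing_mask=np.zeros_like(mask),
        kind=m.kind,
    )


def select_top_variable(m: OmicMatrix, n: int) -> OmicMatrix:
    """Keep the min(n, p) features with the largest sample standard deviation,
    ordered by decreasing sd; ties broken by feature-id lexicographic order."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if m.n_features == 0:
        raise ValueError("matrix is empty")
    vals = np.where(m.missing_mask, np.nan, m.values)
    with np.errstate(invalid="ignore"):
        sd = np.array([np.nanstd(vals[:, j], ddof=1) if (~m.missing_mask[:, j]).sum() > 1 else 0.0
                       for j in range(m.n_features)])
    order = sorted(range(m.n_features), key=lambda j: (-sd[j], m.feature_ids[j]))
    keep = order[: min(n, m.n_features)]
    return m.subset(feature_idx=np.array(keep))


@dataclass
class MinMaxStats:
    """Per-feature min/max remembered for transforming new samples."""

    feature_ids: list[str]
    minima: np.ndarray
    maxima: np.ndarray

    def transform(self, x: np.ndarray) -> np.ndarray:
        rng = self.maxima - self.minima
        safe = np.where(rng == 0, 1.0, rng)
        out = (x - self.minima) / safe
        return np.where(rng == 0, 0.0, out)


def minmax_normalize(m: OmicMatrix, return_stats: bool = False):
    """Scale each feature so min -> 0 and max -> 1; constant features map to 0."""
    if m.missing_mask.any():
        raise ValueError("minmax_normalize requires a fully observed matrix")
    mins = m.values.min(axis=0)
    maxs = m.values.max(axis=0)
    stats = MinMaxStats(list(m.feature_ids), mins, maxs)
    out = OmicMatrix(
        sample_ids=list(m.sample_ids),
        feature_ids=list(m.feature_ids),
        values=stats.transform(m.values),
        missing_mask=np.zeros_like(m.missing_mask),
        kind=m.kind,
    )
    return (out, stats) if return_stats else out


def stack_omics(ms: list[OmicMatrix]) -> MultiOmicsStack:
    """Concatenate processed omics column-wise over the sample intersection."""
    if not ms:
        raise ValueError("no matrices to stack")
    for m in ms:
        if m.missing_mask.any():
            raise ValueError(f"{m.kind.value} still has missing values; impute first")
    common = set(ms[0].sample_ids)
    for m in ms[1:]:
        common &= set(m.sample_ids)
    if not common:
        raise ValueError("empty sample intersection across omics")
    # deterministic order: first matrix's sample order restricted to the intersection
    sample_ids = [s for s in ms[0].sample_ids if s in common]

    blocks, provenance, offsets, feature_ids = [], [], {}, []
    pos = 0
    for m in ms:
        idx = [m.sample_ids.index(s) for s in sample_ids]
        blocks.append(m.values[idx])
        provenance.extend([m.kind] * m.n_features)
        offsets[m.kind] = (pos, pos + m.n_features)
        feature_ids.extend(f"{m.kind.value}:{f}" for f in m.feature_ids)
        pos += m.n_features
    return MultiOmicsStack(
        sample_ids=sample_ids,
        values=np.hstack(blocks),
        column_provenance=provenance,
        block_offsets=offsets,
        feature_ids=feature_ids,
    )


def preprocess_omic(
    m: OmicMatrix,
    cfg: PreprocessConfig | None = None,
    probe_blacklist: set[str] | None = None,
    return_stats: bool = False,
):
    """Apply the full per-kind preprocessing recipe (see module docstring).

    ``probe_blacklist`` removes listed F3 probes (X/Y/SNP/cross-hybridizing
    annotations are caller-supplied, never computed). Returns the processed
    matrix, with min-max stats as a second element when ``return_stats``.
    """
    cfg = cfg or PreprocessConfig()
    stats = None
    if m.kind in (OmicKind.F1_MRNA, OmicKind.F2_MIRNA):
        m = filter_sparse_features(m, cfg.max_zero_fraction, criterion="zero")
        if m.missing_mask.any():
            m = knn_impute(m, cfg.knn_k)
        if cfg.variance_select.get(m.kind, False):
            m = select_top_variable(m, cfg.top_n_variable)
        if cfg.normalize.get(m.kind, True):
            m, stats = minmax_normalize(m, return_stats=True)
    elif m.kind is OmicKind.F3_METHYLATION:
        if probe_blacklist:
            keep = [j for j, f in enumerate(m.feature_ids) if f not in probe_blacklist]
            if not keep:
                raise EmptyResultError("probe blacklist removed every feature")
            m = m.subset(feature_idx=np.array(keep))
        m = filter_sparse_samples(m, cfg.max_missing_fraction)
        m = filter_sparse_features(m, cfg.max_missing_fraction, criterion="missing")
        if m.missing_mask.any():
            m = knn_impute(m, cfg.knn_k)
        if cfg.variance_select.get(m.kind, True):
            m = select_top_variable(m, cfg.top_n_variable)
        if cfg.normalize.get(m.kind, False):
            m, stats = minmax_normalize(m, return_stats=True)
    elif m.kind is OmicKind.F4_PROTEIN:
        m = filter_sparse_features(m, cfg.max_missing_fraction, criterion="missing")
        if m.missing_mask.any():
            m = knn_impute(m, cfg.knn_k)
        if cfg.normalize.get(m.kind, False):
            m, stats = minmax_normalize(m, return_stats=True)
    else:  # pragma: no cover
        raise ValueError(f"unknown omic kind {m.kind}")
    return (m, stats) if return_stats else m
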