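"""Consensus K-means with PAC-based model selection.

For each K, the latent matrix is clustered on many without-replacement
subsamples; the consensus matrix records, per sample pair, the fraction of
co-sampled runs in which the pair co-clustered. The empirical CDF of the
off-diagonal co-sampled consensus entries yields the proportion of
ambiguously clustered pairs, PAC = CDF(u2) - CDF(u1); the K with the
smallest PAC (optionally excluding values flagged as reproducing a known
partition) is selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import (
    adjusted_rand_score,
    calinski_harabasz_score,
    silhouette_score,
)

from .types import ClusterAssignment, LatentMatrix


@dataclass
class ConsensusMatrix:
    sample_ids: list[str]
    cooccur: np.ndarray
    cosample: np.ndarray
    consensus: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        self.cooccur = np.asarray(self.cooccur, dtype=float)
        self.cosample = np.asarray(self.cosample, dtype=float)
        if self.cooccur.shape != (n, n) or self.cosample.shape != (n, n):
            raise ValueError("count matrices must be n x n")
        if self.consensus is None:
            with np.errstate(invalid="ignore", divide="ignore"):
                c = np.where(self.cosample > 0, self.cooccur / np.where(self.cosample > 0, self.cosample, 1), 0.0)
            self.consensus = c


@dataclass
class PACRecord:
    K: int
    pac: float
    consensus: ConsensusMatrix


@dataclass
class PACProfile:
    records: dict[int, PACRecord]
    u1: float = 0.1
    u2: float = 0.9


def consensus_kmeans(
    latent: LatentMatrix,
    K: int,
    n_resamples: int = 1000,
    subsample_fraction: float = 0.8,
    seed: int = 0,
    n_init: int = 1,
) -> ConsensusMatrix:
    """Accumulate co-clustering evidence over subsampled K-means runs.

    Each resample draws floor(n * fraction) samples without replacement and
    clusters them with a single k-means++ start (``n_init=1``), so local-optimum
    variability contributes to the measured ambiguity. Pairs never co-sampled
    get consensus 0 by convention but carry no evidence downstream.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    x = latent.values
    n = x.shape[0]
    m = int(np.floor(n * subsample_fraction))
    if K > m:
        raise ValueError(f"K={K} exceeds subsample size {m}")
    rng = np.random.default_rng(seed)
    cooccur = np.zeros((n, n))
    cosample = np.zeros((n, n))
    for _ in range(n_resamples):
        idx = rng.choice(n, size=m, replace=False)
        km_seed = int(rng.integers(0, 2**31 - 1))
        labels = KMeans(n_clusters=K, n_init=n_init, random_state=km_seed).fit_predict(x[idx])
        same = (labels[:, None] == labels[None, :]).astype(float)
        cosample[np.ix_(idx, idx)] += 1.0
        cooccur[np.ix_(idx, idx)] += same
    return ConsensusMatrix(sample_ids=list(latent.sample_ids), cooccur=cooccur, cosample=cosample)


def _eligible_entries(cm: ConsensusMatrix) -> np.ndarray:
    iu = np.triu_indices(len(cm.sample_ids), k=1)
    sampled = cm.cosample[iu] > 0
    if not sampled.any():
        raise ValueError("no co-sampled off-diagonal pairs")
    return cm.consensus[iu][sampled]


def empirical_cdf(cm: ConsensusMatrix):
    """Right-continuous empirical CDF of the off-diagonal co-sampled
    upper-triangle consensus entries: cdf(u) = fraction of entries <= u."""
    entries = np.sort(_eligible_entries(cm))
    n = entries.size

    def cdf(u: float) -> float:
        return float(np.searchsorted(entries, u, side="right")) / n

    return cdf


def compute_pac(cdf, u1: float = 0.1, u2: float = 0.9) -> float:
    if not (0 <= u1 < u2 <= 1):
        raise ValueError("require 0 <= u1 < u2 <= 1")
    return cdf(u2) - cdf(u1)


def build_pac_profile(
    latent: LatentMatrix,
    k_range=range(2, 11),
    n_resamples: int = 1000,
    subsample_fraction: float = 0.8,
    u1: float = 0.1,
    u2: float = 0.9,
    seed: int = 0,
    n_init: int = 1,
) -> PACProfile:
    ks = list(k_range)
    if not ks:
        raise ValueError("k_range must be non-empty")
    records = {}
    for K in ks:
        cm = consensus_kmeans(latent, K, n_resamples, subsample_fraction, seed=seed, n_init=n_init)
        pac = compute_pac(empirical_cdf(cm), u1, u2)
        records[K] = PACRecord(K=K, pac=pac, consensus=cm)
    return PACProfile(records=records, u1=u1, u2=u2)


def select_k(profile: PACProfile, excluded: set[int] | None = None) -> int:
    """Non-excluded K with minimal PAC; ties resolved towards smaller K."""
    excluded = excluded or set()
    eligible = [r for k, r in sorted(profile.records.items()) if k not in excluded]
    if not eligible:
        raise ValueError("all K values excluded")
    best = min(eligible, key=lambda r: (r.pac, r.K))
    return best.K


def flag_known_partition(labels: ClusterAssignment, known, threshold: float = 0.8) -> bool:
    """True when the clustering merely reproduces a known categorical partition
    (adjusted Rand index >= threshold). Single-category known labels -> False."""
    known = np.asarray(known)
    if known.shape != labels.labels.shape:
        raise ValueError("known labels must cover all clustered samples")
    if len(np.unique(known)) < 2:
        return False
    return adjusted_rand_score(known, labels.labels) >= threshold


def final_labels(cm: ConsensusMatrix, K: int, seed: int = 0) -> ClusterAssignment:
    """Cluster consensus-matrix rows with K-means to derive per-sample labels.

    Retries with a perturbed seed (max 10 attempts) if a cluster comes out
    empty. Labels are 1-based.
    """
    rng = np.random.default_rng(seed)
    for _ in range(10):
        km_seed = int(rng.integers(0, 2**31 - 1))
        raw = KMeans(n_clusters=K, n_init=10, random_state=km_seed).fit_predict(cm.consensus)
        if len(np.unique(raw)) == K:
            return ClusterAssignment(sample_ids=list(cm.sample_ids), labels=raw + 1, K=K)
    raise RuntimeError(f"could not produce {K} non-empty clusters in 10 attempts")


def cluster_quality(x: np.ndarray, labels: ClusterAssignment):
    """(silhouette coefficient, Calinski-Harabasz index) for a labelled matrix."""
    if labels.K < 2:
        raise ValueError("cluster quality requires K >= 2")
    y = labels.labels
    return (
        float(silhouette_score(x, y)),
        float(calinski_harabasz_score(x, y)),
    )
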