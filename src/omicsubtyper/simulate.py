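"""Seeded synthetic multi-omics datasets with known cluster structure.

Four omic blocks share one latent cluster assignment: expression blocks are
exponentiated Gaussians (non-negative, FPKM/RPKM-like), methylation is the
inverse-logit of shifted Gaussians (strictly inside (0, 1)), protein is
plain Gaussian. Cluster-specific signal features are disjoint across
clusters; missingness is injected completely at random. Clinical companions:
exponential survival with per-cluster hazards and tuned exponential
censoring, Bernoulli mutations with designated enriched genes, and
segment-mean tables with cluster-specific shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import OmicKind, OmicMatrix, SurvivalTable

PAPER_SCALE_WIDTHS = {
    OmicKind.F1_MRNA: 2000,
    OmicKind.F2_MIRNA: 407,
    OmicKind.F3_METHYLATION: 2000,
    OmicKind.F4_PROTEIN: 216,
}


@dataclass
class SimConfig:
    n_samples: int = 300
    n_clusters: int = 5
    block_widths: dict = field(
        default_factory=lambda: {
            OmicKind.F1_MRNA: 400,
            OmicKind.F2_MIRNA: 80,
            OmicKind.F3_METHYLATION: 400,
            OmicKind.F4_PROTEIN: 60,
        }
    )
    signal_features_per_cluster: int = 20
    effect_size: float = 3.0  # mean shift in within-cluster sd units
    missing_fraction: dict = field(
        default_factory=lambda: {
            OmicKind.F3_METHYLATION: 0.02,
            OmicKind.F4_PROTEIN: 0.02,
        }
    )
    cluster_proportions: tuple | None = None  # default: uniform
    censor_fraction: float = 0.3
    hazard_per_cluster: tuple | None = None  # default: geometric spread
    mutation_genes: int = 50
    enriched_genes_per_cluster: int = 2
    enriched_mutation_rate: float = 0.6
    background_mutation_rate: float = 0.05
    n_cytobands: int = 40
    altered_cytobands_per_cluster: int = 2
    cnv_shift: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < self.n_clusters:
            raise ValueError("need at least one sample per cluster")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        for frac in self.missing_fraction.values():
            if not 0 <= frac < 1:
                raise ValueError("missing fractions must lie in [0, 1)")
        if not 0 <= self.censor_fraction < 1:
            raise ValueError("censor_fraction must lie in [0, 1)")
        if self.cluster_proportions is not None:
            if len(self.cluster_proportions) != self.n_clusters:
                raise ValueError("one proportion per cluster required")
            if abs(sum(self.cluster_proportions) - 1.0) > 1e-9:
                raise ValueError("cluster proportions must sum to 1")
        if self.hazard_per_cluster is not None and any(
            h <= 0 for h in self.hazard_per_cluster
        ):
            raise ValueError("hazards must be positive")

    def proportions(self) -> np.ndarray:
        if self.cluster_proportions is not None:
            return np.asarray(self.cluster_proportions, dtype=float)
        return np.full(self.n_clusters, 1.0 / self.n_clusters)

    def hazards(self) -> np.ndarray:
        if self.hazard_per_cluster is not None:
            return np.asarray(self.hazard_per_cluster, dtype=float)
        return 0.02 * (2.0 ** np.arange(self.n_clusters))


def _inv_logit(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _signal_columns(width: int, n_clusters: int, per_cluster: int) -> list[np.ndarray]:
    """Disjoint signal-feature index blocks, one per cluster."""
    per = min(per_cluster, width // max(n_clusters, 1))
    return [np.arange(k * per, (k + 1) * per) for k in range(n_clusters)]


def simulate_multiomics(cfg: SimConfig):
    """Generate the four omic matrices plus the true cluster labels (1-based).

    Returns (dict of OmicKind -> OmicMatrix, labels array).
    """
    rng = np.random.default_rng(cfg.seed)
    n, K = cfg.n_samples, cfg.n_clusters
    labels = rng.choice(np.arange(1, K + 1), size=n, p=cfg.proportions())
    # guarantee every cluster occupied
    for k in range(1, K + 1):
        if not (labels == k).any():
            labels[rng.integers(0, n)] = k
    sample_ids = [f"S{i:04d}" for i in range(n)]

    omics = {}
    for kind, width in cfg.block_widths.items():
        z = rng.normal(size=(n, width))
        blocks = _signal_columns(width, K, cfg.signal_features_per_cluster)
        for k, cols in enumerate(blocks, start=1):
            z[np.ix_(labels == k, cols)] += cfg.effect_size
        if kind in (OmicKind.F1_MRNA, OmicKind.F2_MIRNA):
            vals = np.exp(z)
        elif kind is OmicKind.F3_METHYLATION:
            vals = _inv_logit(z)
        else:
            vals = z
        frac = cfg.missing_fraction.get(kind, 0.0)
        if frac > 0:
            miss = rng.random(vals.shape) < frac
            vals = np.where(miss, np.nan, vals)
        prefix = kind.value.split("_")[0]
        omics[kind] = OmicMatrix(
            sample_ids=list(sample_ids),
            feature_ids=[f"{prefix}_feat{j}" for j in range(width)],
            values=vals,
            kind=kind,
        )
    return omics, labels


def simulate_clinical(labels: np.ndarray, cfg: SimConfig):
    """Survival table(s), binary mutation matrix, and segment-mean matrix
    linked to the given cluster labels.

    Returns (dict endpoint -> SurvivalTable, mutations DataFrame genes x
    samples, segmeans DataFrame cytobands x samples).
    """
    rng = np.random.default_rng(cfg.seed + 1)
    n = len(labels)
    sample_ids = [f"S{i:04d}" for i in range(n)]
    hazards = cfg.hazards()

    surv = {}
    for endpoint in ("OS", "DFS"):
        lam = hazards[labels - 1]
        t_event = rng.exponential(1.0 / lam)
        if cfg.censor_fraction > 0:
            # P(censor before event) = mu / (lam + mu) = c  =>  mu = lam*c/(1-c)
            mu = lam * cfg.censor_fraction / (1.0 - cfg.censor_fraction)
            t_cens = rng.exponential(1.0 / mu)
        else:
            t_cens = np.full(n, np.inf)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        surv[endpoint] = SurvivalTable(
            sample_ids=list(sample_ids), time=time, event=event,
            cluster=labels.copy(), endpoint=endpoint,
        )

    genes = [f"gene{g}" for g in range(cfg.mutation_genes)]
    mut = (rng.random((cfg.mutation_genes, n)) < cfg.background_mutation_rate).astype(int)
    enriched: dict[int, list[int]] = {}
    g = 0
    for k in range(1, cfg.n_clusters + 1):
        rows = []
        for _ in range(cfg.enriched_genes_per_cluster):
            if g >= cfg.mutation_genes:
                break
            in_k = labels == k
            mut[g, in_k] = (rng.random(in_k.sum()) < cfg.enriched_mutation_rate).astype(int)
            rows.append(g)
            g += 1
        enriched[k] = rows
    mutations = pd.DataFrame(mut, index=genes, columns=sample_ids)
    mutations.attrs["enriched"] = {k: [genes[i] for i in v] for k, v in enriched.items()}

    bands = [f"cb{c}" for c in range(cfg.n_cytobands)]
    seg = rng.normal(scale=0.1, size=(cfg.n_cytobands, n))
    b = 0
    altered: dict[int, list[str]] = {}
    for k in range(1, cfg.n_clusters + 1):
        names = []
        for _ in range(cfg.altered_cytobands_per_cluster):
            if b >= cfg.n_cytobands:
                break
            sign = 1.0 if b % 2 == 0 else -1.0
            seg[b, labels == k] += sign * cfg.cnv_shift
            names.append(bands[b])
            b += 1
        altered[k] = names
    segmeans = pd.DataFrame(seg, index=bands, columns=sample_ids)
    segmeans.attrs["altered"] = altered
    return surv, mutations, segmeans
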