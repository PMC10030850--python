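"""Core data containers shared across the pipeline stages."""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class OmicKind(str, enum.Enum):
    """Molecular data modality of a feature table."""

    F1_MRNA = "F1_mrna"
    F2_MIRNA = "F2_mirna"
    F3_METHYLATION = "F3_methylation"
    F4_PROTEIN = "F4_protein"

    @classmethod
    def from_string(cls, s: str) -> "OmicKind":
        aliases = {
            "f1": cls.F1_MRNA,
            "f2": cls.F2_MIRNA,
            "f3": cls.F3_METHYLATION,
            "f4": cls.F4_PROTEIN,
        }
        key = s.strip().lower()
        if key in aliases:
            return aliases[key]
        for member in cls:
            if member.value.lower() == key or member.name.lower() == key:
                return member
        raise ValueError(f"unknown omic kind {s!r}")


@dataclass
class OmicMatrix:
    """One omic level's samples x features table with a missingness mask.

    ``values`` holds NaN at missing positions; ``missing_mask`` is the
    authoritative record of which entries are missing.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    kind: OmicKind
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.values.shape:
                raise ValueError("missing_mask shape mismatch")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids")
        self._check_value_range()

    def _check_value_range(self) -> None:
        obs = self.values[~self.missing_mask]
        if obs.size == 0:
            return
        if self.kind is OmicKind.F3_METHYLATION:
            if obs.min() < 0 or obs.max() > 1:
                raise ValueError("methylation beta values must lie in [0, 1]")
        elif self.kind in (OmicKind.F1_MRNA, OmicKind.F2_MIRNA):
            if obs.min() < 0:
                raise ValueError(f"{self.kind.value} values must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def subset(self, sample_idx=None, feature_idx=None) -> "OmicMatrix":
        """Return a copy restricted to the given positional indices."""
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        fi = np.arange(self.n_features) if feature_idx is None else np.asarray(feature_idx)
        return OmicMatrix(
            sample_ids=[self.sample_ids[i] for i in si],
            feature_ids=[self.feature_ids[j] for j in fi],
            values=self.values[np.ix_(si, fi)].copy(),
            missing_mask=self.missing_mask[np.ix_(si, fi)].copy(),
            kind=self.kind,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)
        return df.mask(pd.DataFrame(self.missing_mask, index=df.index, columns=df.columns))

    @classmethod
    def from_frame(cls, df: pd.DataFrame, kind: OmicKind) -> "OmicMatrix":
        return cls(
            sample_ids=[str(s) for s in df.index],
            feature_ids=[str(f) for f in df.columns],
            values=df.to_numpy(dtype=float),
            kind=kind,
        )


@dataclass
class MultiOmicsStack:
    """Column-wise concatenation of processed omics over shared samples."""

    sample_ids: list[str]
    values: np.ndarray
    column_provenance: list[OmicKind]
    block_offsets: dict[OmicKind, tuple[int, int]]
    feature_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.isnan(self.values).any():
            raise ValueError("stack must not contain missing values")
        if self.values.shape[1] != len(self.column_provenance):
            raise ValueError("column_provenance length mismatch")
        total = sum(stop - start for start, stop in self.block_offsets.values())
        if total != self.values.shape[1]:
            raise ValueError("block widths do not sum to total feature count")
        if not self.feature_ids:
            self.feature_ids = [f"col{i}" for i in range(self.values.shape[1])]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def block(self, kind: OmicKind) -> np.ndarray:
        start, stop = self.block_offsets[kind]
        return self.values[:, start:stop]


@dataclass
class LatentMatrix:
    """Reduced-dimension sample representation (AE bottleneck or PCA scores)."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.sample_ids):
            raise ValueError("row count must equal number of sample ids")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class ClusterAssignment:
    """Per-sample cluster labels in 1..K, every cluster non-empty."""

    sample_ids: list[str]
    labels: np.ndarray
    K: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.sample_ids),):
            raise ValueError("labels length mismatch")
        present = set(self.labels.tolist())
        if not present.issubset(set(range(1, self.K + 1))):
            raise ValueError(f"labels must lie in 1..{self.K}")
        if present != set(range(1, self.K + 1)):
            raise ValueError("every cluster must be non-empty")

    def to_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.sample_ids, name="cluster")


@dataclass
class SurvivalTable:
    """Per-sample time/event pairs for one endpoint plus cluster label."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray
    cluster: np.ndarray
    endpoint: str = "OS"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        self.cluster = np.asarray(self.cluster)
        n = len(self.sample_ids)
        if not (self.time.shape == self.event.shape == (n,)) or self.cluster.shape != (n,):
            raise ValueError("time/event/cluster must align with sample_ids")
        if (self.time < 0).any():
            raise ValueError("survival times must be non-negative")
        if self.endpoint not in ("OS", "DFS"):
            raise ValueError("endpoint must be OS or DFS")


def read_omic_tsv(path, kind: OmicKind, sep: str = "\t") -> OmicMatrix:
    """Read a samples x features table: first column sample id, header row of
    feature ids, empty string or NA for missing entries."""
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA", ""])
    return OmicMatrix.from_frame(df, kind)


def write_omic_tsv(m: OmicMatrix, path, sep: str = "\t") -> None:
    m.to_frame().to_csv(path, sep=sep, na_rep="NA", index_label="sample_id")
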