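"""Statistical-parameter physicochemical encoding of DNA sequences.

Each sequence of length L is read as its L-1 overlapping dinucleotides.
Every dinucleotide is summarised by five statistics of its K physicochemical
property values -- (min, max, mean, variance, sum) -- so a sequence becomes
a (L-1) x 5 feature vector laid out position-major. For the standard 81 bp
promoter window with K = 90 properties this is the 400-dimensional
descriptor the classifier is trained on.

Variance is population variance (denominator K) by default, so a constant
property row gives exactly 0; a flag switches to the sample form (K-1).
Property columns can optionally be z-scored across the 16 dinucleotides
before the statistics are taken, for tables that ship pre-normalised.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import DINUCLEOTIDES, DINUC_INDEX, LabeledDataset, PropertyTable

STAT_NAMES: tuple[str, ...] = ("min", "max", "mean", "var", "sum")


@dataclass
class DinucStatsMap:
    """Per-dinucleotide 5-vector (min, max, mean, var, sum) over K properties."""

    values: np.ndarray  # 16 x 5, rows in DINUCLEOTIDES order
    K: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (16, 5):
            raise ValueError(f"stats map must be 16 x 5, got {self.values.shape}")

    def vector(self, dinuc: str) -> np.ndarray:
        return self.values[DINUC_INDEX[dinuc]]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(DINUCLEOTIDES), columns=list(STAT_NAMES)
        )


@dataclass
class FeatureMatrix:
    """n_samples x d feature matrix with optional labels and feature ids.

    ``feature_ids`` name each column by position and statistic
    (``pos017_var`` = variance statistic of the dinucleotide starting at
    base 17, 1-based). Labels may be absent in prediction mode.
    """

    values: np.ndarray
    feature_ids: list[str]
    labels: np.ndarray | None = None
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if len(self.feature_ids) != self.values.shape[1]:
            raise ValueError("feature_ids length does not match column count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (self.values.shape[0],):
                raise ValueError("labels length does not match row count")
            if not np.isin(self.labels, (0, 1)).all():
                raise ValueError("labels must be binary 0/1")
        if self.sample_ids is not None and len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length does not match row count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def feature_id(position: int, stat: str) -> str:
    """Column name for the ``stat`` statistic at 1-based dinucleotide ``position``."""
    return f"pos{position:03d}_{stat}"


def compute_dinuc_stats(
    table: PropertyTable,
    standardize: bool = False,
    sample_variance: bool = False,
) -> DinucStatsMap:
    """Summarise each dinucleotide's K property values into its 5-vector.

    Parameters
    ----------
    table
        16 x K property table.
    standardize
        If True, z-score each property column across the 16 dinucleotides
        (population std; zero-spread columns are left centred at 0) before
        computing the statistics. Off by default.
    sample_variance
        Use the K-1 denominator instead of the population form K.
    """
    vals = table.values
    if standardize:
        mu = vals.mean(axis=0)
        sd = vals.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        vals = (vals - mu) / sd
    ddof = 1 if sample_variance else 0
    if ddof == 1 and table.K < 2:
        raise ValueError("sample variance requires K >= 2")
    stats = np.column_stack([
        vals.min(axis=1),
        vals.max(axis=1),
        vals.mean(axis=1),
        vals.var(axis=1, ddof=ddof),
        vals.sum(axis=1),
    ])
    return DinucStatsMap(stats, K=table.K)


def dinucleotides_of(seq: str) -> list[str]:
    """Overlapping dinucleotides of ``seq``: element i is seq[i:i+2], L-1 total."""
    seq = seq.upper()
    if len(seq) < 2:
        raise ValueError("sequence must have length >= 2")
    return [seq[i : i + 2] for i in range(len(seq) - 1)]


def encode_sequence(seq: str, stats: DinucStatsMap) -> np.ndarray:
    """Encode one sequence as the concatenated 5-vectors of its dinucleotides.

    Position i (1-based, i = 1..L-1) contributes coordinates 5(i-1)..5i-1 in
    (min, max, mean, var, sum) order; total length 5 (L-1).
    """
    dinucs = dinucleotides_of(seq)
    idx = [DINUC_INDEX[d] for d in dinucs]
    return stats.values[idx].ravel()


def encode_dataset(dataset: LabeledDataset, stats: DinucStatsMap) -> FeatureMatrix:
    """Encode every record of an equal-length dataset, preserving order."""
    if not dataset.records:
        raise ValueError("cannot encode an empty dataset")
    L = dataset.length  # raises on mixed lengths at construction
    rows = np.stack([encode_sequence(r.seq, stats) for r in dataset.records])
    ids = [feature_id(i, s) for i in range(1, L) for s in STAT_NAMES]
    has_labels = all(r.label is not None for r in dataset.records)
    labels = dataset.labels() if has_labels else None
    return FeatureMatrix(
        rows, feature_ids=ids, labels=labels,
        sample_ids=[r.id for r in dataset.records],
    )


# ---------------------------------------------------------------------------
# Feature-matrix TSV interchange (sample_id, label, then one column per id)
# ---------------------------------------------------------------------------

def write_feature_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    sample_ids = matrix.sample_ids or [f"s{i + 1:05d}" for i in range(matrix.n_samples)]
    df = pd.DataFrame(matrix.values, columns=matrix.feature_ids)
    df.insert(0, "label", matrix.labels if matrix.labels is not None else "")
    df.insert(0, "sample_id", sample_ids)
    df.to_csv(path, sep="\t", index=False)


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns or "label" not in df.columns:
        raise ValueError(f"{path}: feature matrix needs sample_id and label columns")
    sample_ids = df["sample_id"].astype(str).tolist()
    labels_col = df["label"]
    labels = None if labels_col.isna().all() else labels_col.to_numpy(dtype=int)
    feats = df.drop(columns=["sample_id", "label"])
    return FeatureMatrix(
        feats.to_numpy(dtype=float),
        feature_ids=[str(c) for c in feats.columns],
        labels=labels,
        sample_ids=sample_ids,
    )
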