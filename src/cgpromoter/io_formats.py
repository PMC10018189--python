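"""Sequence, property-table and dataset I/O.

Handles the three fixed-format inputs of the pipeline: FASTA sequence sets
(fixed length per dataset), dinucleotide physicochemical property tables
(16 dinucleotides x K numeric properties, TSV/CSV in either orientation),
and stratified train/independent splits with JSON manifests.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger("cgpromoter")

#: The 16 dinucleotides in canonical (lexicographic) order. Every property
#: table and stats map in the package is indexed in this order.
DINUCLEOTIDES: tuple[str, ...] = (
    "AA", "AC", "AG", "AT", "CA", "CC", "CG", "CT",
    "GA", "GC", "GG", "GT", "TA", "TC", "TG", "TT",
)
DINUC_INDEX: dict[str, int] = {d: i for i, d in enumerate(DINUCLEOTIDES)}

_VALID_BASES = frozenset("ACGT")


@dataclass
class SequenceRecord:
    """A single DNA sequence with an optional binary promoter label."""

    id: str
    seq: str
    label: int | None = None

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - _VALID_BASES
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-ACGT character(s) {sorted(bad)}"
            )
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"record {self.id!r}: label must be 0 or 1")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class PropertyTable:
    """16 x K matrix of dinucleotide physicochemical property values.

    Rows follow :data:`DINUCLEOTIDES` order; K >= 1 (the published
    C. glutamicum table has K = 90 properties).
    """

    values: np.ndarray
    property_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != 16:
            raise ValueError(
                f"property table must be 16 x K, got shape {self.values.shape}"
            )
        if self.values.shape[1] < 1:
            raise ValueError("property table needs at least one property (K >= 1)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("property table contains non-finite values")
        if self.property_names is not None and len(self.property_names) != self.K:
            raise ValueError("property_names length does not match K")

    @property
    def K(self) -> int:
        return self.values.shape[1]

    def row(self, dinuc: str) -> np.ndarray:
        return self.values[DINUC_INDEX[dinuc]]


@dataclass
class LabeledDataset:
    """An ordered collection of labeled, equal-length sequence records."""

    records: list[SequenceRecord]
    split_tag: str = "none"

    def __post_init__(self) -> None:
        if self.split_tag not in ("train", "independent", "none"):
            raise ValueError(f"unknown split_tag {self.split_tag!r}")
        lengths = {len(r) for r in self.records}
        if len(lengths) > 1:
            raise ValueError(f"mixed sequence lengths in dataset: {sorted(lengths)}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def length(self) -> int:
        """Common sequence length L (dataset must be non-empty)."""
        if not self.records:
            raise ValueError("empty dataset has no sequence length")
        return len(self.records[0])

    def class_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {0: 0, 1: 0}
        for r in self.records:
            if r.label is None:
                raise ValueError(f"record {r.id!r} is unlabeled")
            counts[r.label] += 1
        return counts

    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(
    path: str | Path,
    label: int | None = None,
    on_invalid: str = "abort",
) -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    Parameters
    ----------
    path
        FASTA file (multi-line entries allowed; case-insensitive).
    label
        Binary label applied to every record, or ``None`` for prediction
        mode.
    on_invalid
        ``"abort"`` (default) raises on the first record containing a
        non-ACGT character, naming the record; ``"drop"`` skips such
        records with a warning.
    """
    if on_invalid not in ("abort", "drop"):
        raise ValueError("on_invalid must be 'abort' or 'drop'")
    records: list[SequenceRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        rec_id = entry.id  # first whitespace token of the header
        try:
            records.append(SequenceRecord(rec_id, str(entry.seq), label))
        except ValueError:
            if on_invalid == "abort":
                raise
            logger.warning("dropping invalid record %r", rec_id)
    if not records:
        raise ValueError(f"no valid FASTA records in {path}")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    """Write records to FASTA (one line per sequence)."""
    bio = [_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta-2line")


# ---------------------------------------------------------------------------
# Property tables
# ---------------------------------------------------------------------------

def _detect_sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_property_table(path: str | Path) -> PropertyTable:
    """Read a dinucleotide property table from TSV/CSV, either orientation.

    Published tables ship both as 16 rows x K properties (dinucleotides as
    the row index) and as K rows x 16 columns (dinucleotides as the column
    header). The dinucleotide axis is auto-detected: a header or index
    containing at least 12 of the 16 dinucleotide tokens is taken as that
    axis. Output is always canonical 16 x K in :data:`DINUCLEOTIDES` order.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), index_col=0)

    def n_dinuc(tokens) -> int:
        return sum(str(t).strip().upper() in DINUC_INDEX for t in tokens)

    if n_dinuc(df.columns) >= 12:
        df = df.T  # dinucleotides were the column axis
    elif n_dinuc(df.index) < 12:
        raise ValueError(
            f"{path}: could not locate a dinucleotide axis "
            "(need >= 12 of the 16 dinucleotide tokens in header or index)"
        )

    df.index = [str(i).strip().upper() for i in df.index]
    seen = set(df.index)
    missing = [d for d in DINUCLEOTIDES if d not in seen]
    if missing:
        raise ValueError(f"{path}: missing dinucleotide {', '.join(missing)}")
    if len(df.index) != len(seen):
        dupes = sorted({d for d in df.index if list(df.index).count(d) > 1})
        raise ValueError(f"{path}: duplicate dinucleotide {', '.join(dupes)}")

    df = df.loc[list(DINUCLEOTIDES)]
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell in property table") from exc
    names = [str(c) for c in df.columns]
    return PropertyTable(values, property_names=names)


def write_property_table(table: PropertyTable, path: str | Path) -> None:
    path = Path(path)
    names = table.property_names or [f"prop_{j + 1:03d}" for j in range(table.K)]
    df = pd.DataFrame(table.values, index=list(DINUCLEOTIDES), columns=names)
    df.to_csv(path, sep=_detect_sep(path))


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

def split_dataset(
    dataset: LabeledDataset, ratio: float = 0.8, seed: int = 0
) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified train/independent split at ``ratio`` per class.

    Each class is shuffled and split independently, with floor rounding of
    the test share so any odd record per class goes to the training side
    (1000+1000 at ratio 0.8 gives 800+800 train, 200+200 independent).
    Deterministic for a given seed; the two parts partition the input.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    by_class: dict[int, list[int]] = {}
    for i, r in enumerate(dataset.records):
        if r.label is None:
            raise ValueError(f"record {r.id!r} is unlabeled; cannot split")
        by_class.setdefault(r.label, []).append(i)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in sorted(by_class):
        idx = np.array(by_class[cls])
        if len(idx) < 2:
            raise ValueError(f"class {cls} has fewer than 2 members")
        rng.shuffle(idx)
        # round before flooring so 1000 * 0.2 cannot land at 199.999...
        n_test = int(np.floor(round(len(idx) * (1.0 - ratio), 9)))
        test_idx.extend(idx[:n_test].tolist())
        train_idx.extend(idx[n_test:].tolist())
    train_idx.sort()
    test_idx.sort()
    train = LabeledDataset([dataset.records[i] for i in train_idx], "train")
    test = LabeledDataset([dataset.records[i] for i in test_idx], "independent")
    return train, test


def write_split_manifest(
    train: LabeledDataset, test: LabeledDataset, path: str | Path,
    seed: int | None = None, ratio: float | None = None,
) -> None:
    """Record the record ids of each part so a split is reproducible."""
    manifest = {
        "train": [r.id for r in train.records],
        "independent": [r.id for r in test.records],
        "seed": seed,
        "ratio": ratio,
    }
    Path(path).write_text(json.dumps(manifest, indent=1))


def apply_split_manifest(
    dataset: LabeledDataset, path: str | Path
) -> tuple[LabeledDataset, LabeledDataset]:
    """Re-apply a previously written split manifest to a dataset."""
    manifest = json.loads(Path(path).read_text())
    by_id = {r.id: r for r in dataset.records}
    missing = [i for part in ("train", "independent")
               for i in manifest[part] if i not in by_id]
    if missing:
        raise ValueError(f"manifest ids not in dataset: {missing[:5]}")
    train = LabeledDataset([by_id[i] for i in manifest["train"]], "train")
    test = LabeledDataset([by_id[i] for i in manifest["independent"]], "independent")
    return train, test
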