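"""Synthetic property tables and labeled promoter/background datasets.

Every pipeline stage is testable without external downloads: this module
fabricates (a) 16 x K dinucleotide property tables with controlled
per-dinucleotide location and spread, plus pathological variants (constant
rows, duplicated rows) that exercise encoder edge cases, and (b) labeled
sequence sets in which positives carry a planted consensus motif — a
sigma-70-style TATAAT box by default — with per-base Bernoulli corruption,
against an i.i.d. background model, emulating the promoter-versus-sliced-
genome-fragment contrast of real training data at desk scale.

All draws come from one seeded generator, so a spec reproduces its outputs
byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import (
    DINUCLEOTIDES,
    DINUC_INDEX,
    LabeledDataset,
    PropertyTable,
    SequenceRecord,
)

BASES = "ACGT"

#: Uniform background.
UNIFORM_FREQS: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
#: Background matching the ~53.8% GC content of the C. glutamicum genome.
CG_GENOME_FREQS: tuple[float, ...] = (0.231, 0.269, 0.269, 0.231)


@dataclass
class SyntheticSpec:
    """Parameters for one synthetic study: sequences and property table.

    Defaults give 200+200 sequences of 81 bp with a strongly planted
    (95% per-base match) TATAAT box at offset 60 — roughly the -10 element
    of a promoter window that ends shortly after the transcription start —
    and a 16 x 90 property table whose per-dinucleotide means are spread
    with standard deviation ``loc_spread`` around 0.
    """

    n_pos: int = 200
    n_neg: int = 200
    length: int = 81
    base_freqs: tuple[float, float, float, float] = UNIFORM_FREQS  # A,C,G,T
    motif: str = "TATAAT"
    motif_offset: int = 60  # 0-based start of the motif in each positive
    match_prob: float = 0.95
    K: int = 90
    loc_spread: float = 2.0   # sd of per-dinucleotide property means
    prop_scale: float = 1.0   # within-dinucleotide property sd
    constant_rows: tuple[str, ...] = ()       # dinucs forced to a constant row
    duplicate_rows: tuple[tuple[str, str], ...] = ()  # (src, dst) row copies
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 2:
            raise ValueError("length must be >= 2")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9 or min(self.base_freqs) < 0:
            raise ValueError("base_freqs must be nonnegative and sum to 1")
        if not 0.0 <= self.match_prob <= 1.0:
            raise ValueError("match_prob must be in [0, 1]")
        self.motif = self.motif.upper()
        if set(self.motif) - set(BASES):
            raise ValueError("motif must be over ACGT")
        if self.motif and self.motif_offset + len(self.motif) > self.length:
            raise ValueError("motif does not fit in the sequence length")
        if self.K < 1:
            raise ValueError("K must be >= 1")


def generate_property_table(spec: SyntheticSpec) -> PropertyTable:
    """Draw a 16 x K property table from the spec's location/scale model.

    Row i (dinucleotide i) is Normal(loc_i, prop_scale) with loc_i ~
    Normal(0, loc_spread), so dinucleotides differ in their property
    means by design — mirroring how real physicochemical descriptors
    separate AT-rich from GC-rich steps. ``constant_rows`` dinucleotides
    get all-equal rows (variance exactly 0 after encoding);
    ``duplicate_rows`` copies one dinucleotide's row onto another so the
    two encode identically.
    """
    rng = np.random.default_rng(spec.seed)
    locs = rng.normal(0.0, spec.loc_spread, size=16)
    values = rng.normal(locs[:, None], spec.prop_scale, size=(16, spec.K))
    for d in spec.constant_rows:
        values[DINUC_INDEX[d]] = locs[DINUC_INDEX[d]]
    for src, dst in spec.duplicate_rows:
        values[DINUC_INDEX[dst]] = values[DINUC_INDEX[src]]
    names = [f"prop_{j + 1:03d}" for j in range(spec.K)]
    return PropertyTable(values, property_names=names)


def _draw_background(rng: np.random.Generator, n: int, L: int, freqs) -> np.ndarray:
    return rng.choice(np.frombuffer(BASES.encode(), dtype=np.uint8),
                      size=(n, L), p=list(freqs))


def generate_dataset(spec: SyntheticSpec) -> LabeledDataset:
    """Generate labeled sequences: motif-bearing positives, pure background negatives.

    Positives start as background and then, independently at each motif
    column, receive the consensus base with probability ``match_prob``
    (otherwise the background base stays). With ``match_prob`` equal to a
    base's background frequency the planting is statistically invisible
    and positives match the null; with match_prob -> 1 every positive
    carries the exact consensus.
    """
    rng = np.random.default_rng(spec.seed + 1)  # decoupled from the table draw
    pos = _draw_background(rng, spec.n_pos, spec.length, spec.base_freqs)
    if spec.motif:
        plant = rng.random((spec.n_pos, len(spec.motif))) < spec.match_prob
        motif_codes = np.frombuffer(spec.motif.encode(), dtype=np.uint8)
        cols = slice(spec.motif_offset, spec.motif_offset + len(spec.motif))
        pos[:, cols] = np.where(plant, motif_codes[None, :], pos[:, cols])
    neg = _draw_background(rng, spec.n_neg, spec.length, spec.base_freqs)

    records = [
        SequenceRecord(f"pos_{i + 1:05d}", row.tobytes().decode(), 1)
        for i, row in enumerate(pos)
    ] + [
        SequenceRecord(f"neg_{i + 1:05d}", row.tobytes().decode(), 0)
        for i, row in enumerate(neg)
    ]
    return LabeledDataset(records)


def null_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """A spec with no planted signal: positives and negatives exchangeable."""
    return SyntheticSpec(motif="", seed=seed, **overrides)
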