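"""ANOVA + hierarchical-clustering feature selection.

Redundancy-aware filter for two-class feature matrices. Each feature gets a
one-way ANOVA F value (between-class over within-class variance). The
features themselves are then clustered agglomeratively; every merge whose
two children are both original features is a *first-level pair* — the two
most mutually similar columns. Within each pair only the member with the
larger F survives; features that never pair at the first level are
singletons and are kept outright. The retained count is therefore always
d - (number of pairs).

The linkage rule, distance metric and whether features are z-scored before
clustering are configuration axes (defaults: Ward linkage on Euclidean
distance over z-scored features); every report records them, because
different choices yield different pairings.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from scipy.spatial.distance import pdist

from .encoder import FeatureMatrix

logger = logging.getLogger("cgpromoter")

_LINKAGES = ("ward", "complete", "average", "single")
_METRICS = ("euclidean", "correlation")


@dataclass
class FValueVector:
    """Per-feature two-group ANOVA F values with their variance components."""

    F: np.ndarray
    ms_between: np.ndarray  # between-group mean square, df = 1
    ms_within: np.ndarray   # within-group mean square, df = n - 2

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if np.any(self.F[np.isfinite(self.F)] < 0):
            raise ValueError("F values must be nonnegative")

    def __len__(self) -> int:
        return len(self.F)


@dataclass
class LinkageConfig:
    """How features are clustered: linkage rule, metric, pre-scaling."""

    method: str = "ward"
    metric: str = "euclidean"
    scale: bool = True  # z-score each feature across samples first

    def __post_init__(self) -> None:
        if self.method not in _LINKAGES:
            raise ValueError(f"linkage must be one of {_LINKAGES}")
        if self.metric not in _METRICS:
            raise ValueError(f"metric must be one of {_METRICS}")
        if self.method == "ward" and self.metric != "euclidean":
            raise ValueError("Ward linkage requires the Euclidean metric")


@dataclass
class PairingResult:
    """First-level pairs and singletons; together they partition 0..d-1."""

    pairs: list[tuple[int, int]]
    singletons: list[int]
    linkage_config: LinkageConfig
    d: int

    def __post_init__(self) -> None:
        seen = [j for p in self.pairs for j in p] + list(self.singletons)
        if sorted(seen) != list(range(self.d)):
            raise ValueError("pairs and singletons do not partition the features")


@dataclass
class PairDecision:
    pair: tuple[int, int]
    f_values: tuple[float, float]
    winner: int
    tie_broken: bool = False


@dataclass
class SelectionResult:
    """Outcome of max-F retention over a pairing."""

    retained: list[int]
    removed: list[int]
    decisions: list[PairDecision]
    seed: int
    linkage_config: LinkageConfig
    feature_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if set(self.retained) & set(self.removed):
            raise ValueError("retained and removed overlap")


def anova_f(matrix: FeatureMatrix) -> FValueVector:
    """Two-group one-way ANOVA F value of every feature.

    F_j = MS_between / MS_within with degrees of freedom (1, n - 2).
    Degenerate features: if both mean squares are 0 (feature constant within
    each class and classes equal) F is set to 0 with a warning; if only the
    within-class mean square is 0 the feature separates the classes
    perfectly and F is the +inf sentinel, which outranks every finite F.
    """
    if matrix.labels is None:
        raise ValueError("ANOVA needs labels")
    y = matrix.labels
    n = len(y)
    n1 = int(y.sum())
    n0 = n - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present")
    if n0 < 2 or n1 < 2:
        raise ValueError("each class needs at least 2 samples (n >= 4)")
    X = matrix.values
    g0 = X[y == 0]
    g1 = X[y == 1]
    grand = X.mean(axis=0)
    ssb = n0 * (g0.mean(axis=0) - grand) ** 2 + n1 * (g1.mean(axis=0) - grand) ** 2
    ssw = ((g0 - g0.mean(axis=0)) ** 2).sum(axis=0) + (
        (g1 - g1.mean(axis=0)) ** 2
    ).sum(axis=0)
    msb = ssb / 1.0
    msw = ssw / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = msb / msw
    zero_both = (msw <= 0) & np.isclose(msb, 0.0)
    if zero_both.any():
        logger.warning(
            "%d constant feature(s) assigned F = 0: %s",
            int(zero_both.sum()), np.flatnonzero(zero_both)[:10].tolist(),
        )
    F = np.where(zero_both, 0.0, F)
    F = np.where((msw <= 0) & ~zero_both, np.inf, F)
    return FValueVector(F=F, ms_between=msb, ms_within=msw)


def _feature_distance_matrix(X: np.ndarray, config: LinkageConfig) -> np.ndarray:
    """Condensed pairwise distance between feature columns."""
    feats = X.T.copy()
    if config.scale:
        mu = feats.mean(axis=1, keepdims=True)
        sd = feats.std(axis=1, keepdims=True)
        sd = np.where(sd == 0, 1.0, sd)
        feats = (feats - mu) / sd
    return pdist(feats, metric=config.metric), feats


def first_level_pairs(
    matrix: FeatureMatrix, config: LinkageConfig | None = None
) -> PairingResult:
    """Agglomeratively cluster the feature columns and extract leaf-leaf merges.

    A first-level pair is a merge in the full linkage tree whose two
    children are both original features. Every other feature is a
    singleton. Pairs and singletons partition the d features, so at most
    floor(d/2) pairs exist.
    """
    config = config or LinkageConfig()
    d = matrix.n_features
    if d < 2:
        raise ValueError("need at least 2 features to cluster")
    dist, feats = _feature_distance_matrix(matrix.values, config)
    if not np.all(np.isfinite(dist)):
        raise ValueError("non-finite feature distances (constant column under "
                         "the correlation metric?)")
    Z = _scipy_linkage(dist, method=config.method)
    pairs: list[tuple[int, int]] = []
    paired: set[int] = set()
    for a, b in Z[:, :2].astype(int):
        if a < d and b < d:
            j, k = sorted((int(a), int(b)))
            pairs.append((j, k))
            paired.update((j, k))
    singletons = [j for j in range(d) if j not in paired]
    return PairingResult(pairs=pairs, singletons=singletons,
                         linkage_config=config, d=d)


def select_features(
    F: FValueVector, pairing: PairingResult, seed: int = 0
) -> SelectionResult:
    """Keep the larger-F member of each first-level pair plus all singletons.

    Exact F ties within a pair are broken by a seeded uniform coin so runs
    are reproducible; every tie-break is flagged in the decision record.
    """
    if len(F) != pairing.d:
        raise ValueError(
            f"F vector has {len(F)} entries but pairing covers {pairing.d} features"
        )
    rng = np.random.default_rng(seed)
    retained = list(pairing.singletons)
    removed: list[int] = []
    decisions: list[PairDecision] = []
    for j, k in pairing.pairs:
        fj, fk = F.F[j], F.F[k]
        tie = bool(fj == fk)  # +inf vs +inf is also a tie
        if tie:
            winner = j if rng.integers(2) == 0 else k
        else:
            winner = j if fj > fk else k
        loser = k if winner == j else j
        retained.append(winner)
        removed.append(loser)
        decisions.append(PairDecision((j, k), (float(fj), float(fk)), winner, tie))
    return SelectionResult(
        retained=sorted(retained), removed=sorted(removed),
        decisions=decisions, seed=seed, linkage_config=pairing.linkage_config,
    )


def apply_selection(matrix: FeatureMatrix, selection: SelectionResult) -> FeatureMatrix:
    """Subset a matrix to the retained columns, in retained-index order.

    If the selection recorded feature ids, the matrix columns must match
    them exactly — a permuted or different matrix is rejected rather than
    silently misaligned.
    """
    d = matrix.n_features
    if set(selection.retained) | set(selection.removed) != set(range(d)):
        raise ValueError(
            f"selection covers {len(selection.retained) + len(selection.removed)} "
            f"features but matrix has {d}"
        )
    if selection.feature_ids is not None and selection.feature_ids != matrix.feature_ids:
        raise ValueError("matrix feature_ids do not match the ones the selection "
                         "was computed on")
    cols = selection.retained
    return FeatureMatrix(
        matrix.values[:, cols],
        feature_ids=[matrix.feature_ids[j] for j in cols],
        labels=matrix.labels,
        sample_ids=matrix.sample_ids,
    )


def select_pipeline(
    matrix: FeatureMatrix, config: LinkageConfig | None = None, seed: int = 0
) -> tuple[FeatureMatrix, SelectionResult, FValueVector, PairingResult]:
    """Convenience: F values -> pairing -> retention -> column subset."""
    F = anova_f(matrix)
    pairing = first_level_pairs(matrix, config)
    selection = select_features(F, pairing, seed=seed)
    selection.feature_ids = list(matrix.feature_ids)
    reduced = apply_selection(matrix, selection)
    return reduced, selection, F, pairing


def write_selection_report(
    selection: SelectionResult, F: FValueVector, path: str | Path
) -> None:
    """JSON report: config, seed, per-pair decisions, retained feature ids."""
    ids = selection.feature_ids
    report = {
        "linkage_config": asdict(selection.linkage_config),
        "seed": selection.seed,
        "n_features": len(selection.retained) + len(selection.removed),
        "n_pairs": len(selection.decisions),
        "n_singletons": len(selection.retained) - len(selection.decisions),
        "n_retained": len(selection.retained),
        "pairs": [
            {
                "pair": list(dec.pair),
                "f_values": [_json_float(f) for f in dec.f_values],
                "winner": dec.winner,
                "tie_broken": dec.tie_broken,
            }
            for dec in selection.decisions
        ],
        "singletons": [j for j in selection.retained
                       if j not in {d.winner for d in selection.decisions}],
        "retained": selection.retained,
        "retained_feature_ids": [ids[j] for j in selection.retained] if ids else None,
    }
    Path(path).write_text(json.dumps(report, indent=1))


def _json_float(x: float) -> float | str:
    return "inf" if np.isinf(x) else float(x)
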