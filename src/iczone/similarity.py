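"""Feature normalization, the dissimilarity statistic, and best-match retrieval.

A prospective user is characterized by five quickly measurable values
(forces F1–F4 in newtons, anterior reach D1 in cm).  Each value A_i is
min–max normalized against the repository's per-feature bounds,

    a_i = (A_i - A_i_min) / (A_i_max - A_i_min),

clamping to [0, 1] outside the repository range.  The dissimilarity
between a repository entry b and the user u is the weighted mean absolute
difference of normalized features,

    sim(x) = sum_i w_i |a_ib - a_iu|,   sum_i w_i = 1 (equal by default),

so sim(x) = 0 means entirely similar and sim(x) = 1 entirely different.
:func:`match` ranks all repository entries by this statistic and returns
the closest one; the user may supply either raw measurements (normalized
internally) or an already-normalized vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

from .core_model import SimplifiedFeatures
from .errors import ValidationError
from .repository import FEATURE_NAMES, FeatureBounds, FeatureTable, compute_feature_bounds

#: equal feature weights — every quick measurement counts the same
EQUAL_WEIGHTS: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)


@dataclass(frozen=True)
class NormalizedFeatures:
    """Dimensionless five-feature vector, each component in [0, 1]."""

    f1: float
    f2: float
    f3: float
    f4: float
    d1: float

    def __post_init__(self) -> None:
        for name in FEATURE_NAMES:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"normalized {name} must lie in [0, 1], got {v}")

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.f1, self.f2, self.f3, self.f4, self.d1)


@dataclass(frozen=True)
class SimilarityResult:
    """Per-feature and total dissimilarity of one repository entry vs the user."""

    entry_id: str
    per_feature: Mapping[str, float]
    total: float

    def __post_init__(self) -> None:
        for name in FEATURE_NAMES:
            if name not in self.per_feature:
                raise ValidationError(f"per_feature missing {name!r}")


@dataclass(frozen=True)
class MatchOutcome:
    """Ranked similarity results; ``best`` is the closest repository entry.

    ``accepted`` is None when no threshold was given, otherwise whether
    the best total met it; the best entry is reported either way.
    """

    results: tuple[SimilarityResult, ...]
    best: SimilarityResult
    threshold: float | None = None
    accepted: bool | None = None


def normalize_feature(value: float, min_value: float, max_value: float) -> float:
    """Min–max normalize one raw value against repository bounds.

    Values outside [min, max] are clamped to [0, 1] with a warning, and a
    degenerate interval (max == min) maps every input to 0.
    """
    interval = max_value - min_value
    if interval < 0:
        raise ValidationError(f"bounds out of order: min {min_value} > max {max_value}")
    if interval == 0:
        warnings.warn(
            f"degenerate bounds (min == max == {min_value}); normalized value set to 0",
            stacklevel=2,
        )
        return 0.0
    a = (value - min_value) / interval
    if a < 0.0 or a > 1.0:
        warnings.warn(
            f"value {value} outside repository bounds [{min_value}, {max_value}]; "
            "clamping normalized value to [0, 1]",
            stacklevel=2,
        )
        a = min(max(a, 0.0), 1.0)
    return a


def normalize_features(features: SimplifiedFeatures, bounds: FeatureBounds) -> NormalizedFeatures:
    """Normalize all five raw features against the repository bounds."""
    return NormalizedFeatures(
        **{
            name: normalize_feature(
                getattr(features, name), bounds.minima[name], bounds.maxima[name]
            )
            for name in FEATURE_NAMES
        }
    )


def feature_similarity(a_b: float, a_u: float) -> float:
    """Per-feature dissimilarity |a_b - a_u| of two normalized values."""
    for v in (a_b, a_u):
        if not (0.0 <= v <= 1.0):
            raise ValidationError(f"normalized inputs must lie in [0, 1], got {v}")
    return abs(a_b - a_u)


def _check_weights(weights: Sequence[float] | None) -> tuple[float, ...]:
    if weights is None:
        return EQUAL_WEIGHTS
    w = tuple(float(x) for x in weights)
    if len(w) != 5 or any(x < 0 for x in w) or abs(sum(w) - 1.0) > 1e-9:
        raise ValidationError(
            f"weights must be five non-negative values summing to 1, got {weights!r}"
        )
    return w


def similarity(
    b: NormalizedFeatures,
    u: NormalizedFeatures,
    weights: Sequence[float] | None = None,
    entry_id: str = "",
) -> SimilarityResult:
    """Weighted mean absolute difference of two normalized feature vectors.

    With the default equal weights this is the plain mean over the five
    features; 0 marks identical vectors, 1 maximal dissimilarity.
    """
    w = _check_weights(weights)
    per = {
        name: feature_similarity(getattr(b, name), getattr(u, name)) for name in FEATURE_NAMES
    }
    total = sum(wi * per[name] for wi, name in zip(w, FEATURE_NAMES))
    return SimilarityResult(entry_id=entry_id, per_feature=per, total=total)


def match(
    table: FeatureTable,
    user: SimplifiedFeatures | NormalizedFeatures,
    weights: Sequence[float] | None = None,
    threshold: float | None = None,
) -> MatchOutcome:
    """Rank repository entries by dissimilarity to the user; best first.

    Raw user features are normalized against the table's own bounds; a
    pre-normalized vector is used as given.  Ties are broken by table
    order (stable sort).  With a ``threshold``, ``accepted`` reports
    whether the best total met it; the best entry is reported regardless.
    """
    if len(table) == 0:
        raise ValidationError("cannot match against an empty repository")
    if threshold is not None and not (0.0 <= threshold <= 1.0):
        raise ValidationError(f"threshold must lie in [0, 1], got {threshold}")
    bounds = compute_feature_bounds(table)
    if isinstance(user, NormalizedFeatures):
        u = user
    else:
        u = normalize_features(user, bounds)
    results = [
        similarity(normalize_features(f, bounds), u, weights=weights, entry_id=eid)
        for eid, f in table
    ]
    ranked = tuple(sorted(results, key=lambda r: r.total))  # stable: table order breaks ties
    best = ranked[0]
    accepted = None if threshold is None else bool(best.total <= threshold)
    return MatchOutcome(results=ranked, best=best, threshold=threshold, accepted=accepted)
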