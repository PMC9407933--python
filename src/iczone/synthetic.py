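"""Synthetic ICZ point clouds and the bundled worked-example worksheet.

Full laboratory characterization of a person's reach/strength space takes
hundreds of supervised force measurements, so the test suite (and any
desk-scale experiment) works on synthetic point clouds instead.  The
generator uses a separable phenomenological form

    F(alpha, z, r) = peak * ang(alpha) * hgt(z) * (1 - rho*r/reach)^p

with ``ang`` a linear angular falloff (fraction of the sagittal force
remaining at 60 degrees), ``hgt`` a linear height factor anchored at 1 at
shoulder height and ``elbow_ratio`` at elbow height, and a radial decay
that keeps a positive boundary force when the decay fraction rho < 1.
The form is an invention of this package: it is not a physiological
model, merely the simplest shape that is monotone in r, separable, and
lets every downstream stage be tested against closed forms.

:func:`example_worksheet` bundles a 12-subject feature table together
with one prospective user's raw and normalized features and the full
per-feature/total dissimilarity worksheet, used for regression tests and
the worked example in the README.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .core_model import (
    AnthropometricProfile,
    ICZModel,
    SimplifiedFeatures,
    StrengthSample,
)
from .errors import ValidationError
from .repository import FeatureTable
from .similarity import NormalizedFeatures

# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic spatial-strength characteristic.

    ``peak_force`` (N) is the force near the body axis at shoulder height;
    ``reach`` (cm) the maximum radius (per-ray overrides allowed);
    ``decay_fraction`` rho in (0, 1] sets how much of the radial decay is
    spent by full reach (rho = 1: force hits 0 exactly at the boundary);
    ``angular_falloff`` is the fraction of sagittal force left at 60 deg;
    ``elbow_ratio`` the elbow/shoulder force ratio; ``noise_sd`` (N) the
    measurement noise; ``seed`` makes generation reproducible.
    """

    profile: AnthropometricProfile
    peak_force: float
    reach: float
    reach_overrides: Mapping[tuple[float, float], float] | None = None
    decay_exponent: float = 1.0
    decay_fraction: float = 1.0
    angular_falloff: float = 0.85
    elbow_ratio: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.peak_force <= 0:
            raise ValidationError(f"peak_force must be positive, got {self.peak_force}")
        if self.reach <= 0:
            raise ValidationError(f"reach must be positive, got {self.reach}")
        if self.reach_overrides and any(v <= 0 for v in self.reach_overrides.values()):
            raise ValidationError("reach overrides must be positive")
        if self.decay_exponent < 1:
            raise ValidationError(f"decay_exponent must be >= 1, got {self.decay_exponent}")
        if not (0 < self.decay_fraction <= 1):
            raise ValidationError(f"decay_fraction must lie in (0, 1], got {self.decay_fraction}")
        if self.angular_falloff < 0:
            raise ValidationError(f"angular_falloff must be >= 0, got {self.angular_falloff}")
        if self.elbow_ratio <= 0:
            raise ValidationError(f"elbow_ratio must be positive, got {self.elbow_ratio}")
        if self.noise_sd < 0:
            raise ValidationError(f"noise_sd must be >= 0, got {self.noise_sd}")

    def reach_for(self, alpha: float, z: float) -> float:
        if self.reach_overrides:
            return float(self.reach_overrides.get((alpha, z), self.reach))
        return self.reach


def noiseless_force(spec: SyntheticSpec, alpha: float, z: float, r: float) -> float:
    """Closed-form force (N) of the generator without noise."""
    sh, el = spec.profile.shoulder_height, spec.profile.elbow_height
    ang = max(0.0, 1.0 + (spec.angular_falloff - 1.0) * abs(alpha) / 60.0)
    hgt = 1.0 + (spec.elbow_ratio - 1.0) * (sh - z) / (sh - el)
    radial = max(0.0, 1.0 - spec.decay_fraction * r / spec.reach_for(alpha, z))
    return max(0.0, spec.peak_force * ang * hgt * radial**spec.decay_exponent)


@dataclass(frozen=True)
class RaySampling:
    """Where the generator places its measurements.

    Defaults give 5 angles x 4 heights x 5 radii = 100 points, the scale
    of a realistic laboratory session.  ``zs=None`` spaces heights evenly
    from elbow to shoulder.
    """

    alphas: tuple[float, ...] = (-60.0, -30.0, 0.0, 30.0, 60.0)
    zs: tuple[float, ...] | None = None
    n_r: int = 5

    def __post_init__(self) -> None:
        if self.n_r < 3:
            raise ValidationError("need at least 3 radii per ray for interpolation")
        if not self.alphas:
            raise ValidationError("need at least one sampling angle")

    def heights(self, profile: AnthropometricProfile) -> tuple[float, ...]:
        if self.zs is not None:
            return self.zs
        return tuple(np.linspace(profile.elbow_height, profile.shoulder_height, 4))


def generate_icz(spec: SyntheticSpec, sampling: RaySampling | None = None) -> ICZModel:
    """Generate a synthetic measured point cloud; deterministic given the seed."""
    sampling = sampling or RaySampling()
    rng = np.random.default_rng(spec.seed)
    samples: list[StrengthSample] = []
    for alpha in sampling.alphas:
        for z in sampling.heights(spec.profile):
            reach = spec.reach_for(alpha, z)
            radii = np.linspace(reach / sampling.n_r, reach, sampling.n_r)
            for r in radii:
                f = noiseless_force(spec, alpha, float(z), float(r))
                if spec.noise_sd > 0:
                    f += rng.normal(0.0, spec.noise_sd)
                samples.append(
                    StrengthSample(alpha=alpha, z=float(z), r=float(r), force=max(0.0, f))
                )
    return ICZModel(profile=spec.profile, samples=tuple(samples))


def spec_for_features(
    target: SimplifiedFeatures, profile: AnthropometricProfile, **kwargs
) -> SyntheticSpec:
    """Tune a generator spec so the extracted features reproduce ``target``.

    Uses the linear radial decay (p = 1): peak = 2*F3 - F1 and
    rho = 2*(F3 - F1)/peak make the sagittal shoulder ray pass through F3
    at D1/2 and F1 at D1; the angular falloff and elbow ratio scale the
    other two rays.  Requires F3 > F1 (mid-reach stronger than full
    reach), which holds for any monotone-in-r characteristic.
    """
    if target.f3 <= target.f1:
        raise ValidationError(
            "cannot tune a monotone radial decay: need F3 (mid-reach) > F1 (full reach), "
            f"got F3={target.f3}, F1={target.f1}"
        )
    peak = 2.0 * target.f3 - target.f1
    rho = 2.0 * (target.f3 - target.f1) / peak
    return SyntheticSpec(
        profile=profile,
        peak_force=peak,
        reach=target.d1,
        decay_exponent=1.0,
        decay_fraction=rho,
        angular_falloff=target.f2 / target.f1,
        elbow_ratio=target.f4 / target.f1,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# bundled worked-example worksheet
# ---------------------------------------------------------------------------

#: example subject: 72-year-old, 84 kg, 175 cm tall (shoulder 139, elbow 109)
EXAMPLE_PROFILE = AnthropometricProfile(
    subject_id="example-user",
    body_height=175.0,
    shoulder_height=139.0,
    elbow_height=109.0,
    body_mass=84.0,
    age=72,
)

# 12 repository subjects: (F1 N, F2 N, F3 N, F4 N, D1 cm)
_REPO_ROWS: tuple[tuple[str, tuple[float, float, float, float, float]], ...] = (
    ("1", (62, 50, 125, 85, 71)),
    ("2", (82, 62, 154, 118, 54)),
    ("3", (64, 52, 170, 83, 66)),
    ("4", (63, 64, 90, 80, 67)),
    ("5", (66, 75, 94, 77, 55)),
    ("6", (27, 24, 49, 30, 70)),
    ("7", (88, 69, 150, 117, 68)),
    ("8", (87, 86, 115, 105, 58)),
    ("9", (87, 79, 167, 99, 57)),
    ("10", (105, 92, 223, 149, 65)),
    ("11", (81, 79, 102, 103, 68)),
    ("12", (57, 45, 141, 69, 67)),
)

_USER_RAW = (71.0, 57.0, 146.0, 110.0, 68.0)
_USER_NORMALIZED = (0.564, 0.485, 0.557, 0.739, 0.824)
_BOUNDS_MIN = (27.0, 24.0, 49.0, 30.0, 54.0)
_BOUNDS_MAX = (105.0, 92.0, 223.0, 149.0, 71.0)

# published per-feature dissimilarities sim(f1..f4), sim(d1) and totals sim(x)
_SIM_MATRIX: tuple[tuple[float, ...], ...] = (
    (0.115, 0.103, 0.120, 0.277, 0.176),
    (0.141, 0.074, 0.046, 0.000, 0.824),
    (0.090, 0.073, 0.138, 0.294, 0.118),
    (0.102, 0.103, 0.321, 0.319, 0.059),
    (0.064, 0.265, 0.298, 0.344, 0.765),
    (0.564, 0.485, 0.557, 0.739, 0.117),
    (0.218, 0.177, 0.023, 0.008, 0.000),
    (0.205, 0.427, 0.178, 0.109, 0.589),
    (0.205, 0.324, 0.121, 0.159, 0.648),
    (0.436, 0.515, 0.443, 0.261, 0.177),
    (0.128, 0.324, 0.252, 0.126, 0.000),
    (0.179, 0.176, 0.028, 0.411, 0.059),
)
_SIM_TOTALS = (0.158, 0.217, 0.143, 0.181, 0.347, 0.492, 0.085, 0.302, 0.291, 0.366, 0.166, 0.171)


@dataclass(frozen=True)
class ExampleWorksheet:
    """The worked dissimilarity worksheet: repository, user, reference numbers.

    ``sim_matrix``/``totals`` carry the reference per-feature and total
    dissimilarities (3 decimals) computed with the user's normalized
    vector as listed in ``user_normalized``; they serve as regression
    targets, not as inputs to any computation.
    """

    table: FeatureTable
    user: SimplifiedFeatures
    user_normalized: NormalizedFeatures
    bounds_min: tuple[float, ...]
    bounds_max: tuple[float, ...]
    sim_matrix: Mapping[str, tuple[float, ...]]
    totals: Mapping[str, float]

    @property
    def best_entry_id(self) -> str:
        return min(self.totals, key=lambda k: self.totals[k])


def example_worksheet() -> ExampleWorksheet:
    """Build the bundled 12-subject worksheet with its prospective user."""
    rows = tuple(
        (eid, SimplifiedFeatures(f1=v[0], f2=v[1], f3=v[2], f4=v[3], d1=v[4]))
        for eid, v in _REPO_ROWS
    )
    user = SimplifiedFeatures(*_USER_RAW, profile=EXAMPLE_PROFILE)
    user_norm = NormalizedFeatures(*_USER_NORMALIZED)
    ids = [eid for eid, _ in _REPO_ROWS]
    return ExampleWorksheet(
        table=FeatureTable(rows),
        user=user,
        user_normalized=user_norm,
        bounds_min=_BOUNDS_MIN,
        bounds_max=_BOUNDS_MAX,
        sim_matrix={eid: row for eid, row in zip(ids, _SIM_MATRIX)},
        totals={eid: t for eid, t in zip(ids, _SIM_TOTALS)},
    )
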