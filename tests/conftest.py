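"""Shared fixtures: reference profiles, closed-form fields, and oracles."""

from __future__ import annotations

import numpy as np
import pytest

import iczone as iz


@pytest.fixture
def profile() -> iz.AnthropometricProfile:
    """The example subject: 175 cm tall, shoulder 139 cm, elbow 109 cm."""
    return iz.AnthropometricProfile(
        subject_id="subject-a",
        body_height=175.0,
        shoulder_height=139.0,
        elbow_height=109.0,
        body_mass=84.0,
        age=72,
    )


@pytest.fixture
def linear_model(profile) -> iz.ICZModel:
    """Single-ray model with the closed-form force F(r) = 200*(1 - r/70) N."""
    samples = tuple(
        iz.StrengthSample(alpha=0.0, z=139.0, r=float(r), force=200.0 * (1 - r / 70.0))
        for r in range(10, 71, 10)
    )
    return iz.ICZModel(profile=profile, samples=samples)


@pytest.fixture
def linear_field(linear_model) -> iz.StrengthField:
    return iz.build_strength_field(linear_model)


@pytest.fixture
def worksheet() -> iz.ExampleWorksheet:
    return iz.example_worksheet()


def pava_nonincreasing(y) -> list[float]:
    """Reference pool-adjacent-violators projection onto non-increasing sequences.

    Independent of the implementation under test: plain block-merging on
    the negated sequence (non-decreasing PAVA), then negated back.
    """
    vals: list[float] = []
    wts: list[int] = []
    for v in [-float(u) for u in y]:
        vals.append(v)
        wts.append(1)
        while len(vals) > 1 and vals[-2] > vals[-1]:
            w = wts[-1] + wts[-2]
            merged = (vals[-1] * wts[-1] + vals[-2] * wts[-2]) / w
            vals = vals[:-2] + [merged]
            wts = wts[:-2] + [w]
    out: list[float] = []
    for v, w in zip(vals, wts):
        out.extend([-v] * w)
    return out


@pytest.fixture
def pava_oracle():
    return pava_nonincreasing


def random_synthetic_field(seed: int, noise_sd: float = 0.0) -> iz.StrengthField:
    """A seeded random strength field for property tests."""
    rng = np.random.default_rng(seed)
    prof = iz.AnthropometricProfile(
        subject_id=f"rand-{seed}",
        body_height=float(rng.uniform(150, 195)),
        shoulder_height=140.0,
        elbow_height=110.0,
        body_mass=float(rng.uniform(50, 110)),
    )
    spec = iz.SyntheticSpec(
        profile=prof,
        peak_force=float(rng.uniform(120, 280)),
        reach=float(rng.uniform(50, 80)),
        decay_exponent=float(rng.uniform(1.0, 2.5)),
        decay_fraction=float(rng.uniform(0.4, 1.0)),
        angular_falloff=float(rng.uniform(0.6, 1.0)),
        elbow_ratio=float(rng.uniform(0.7, 1.5)),
        noise_sd=noise_sd,
        seed=seed,
    )
    return iz.build_strength_field(iz.generate_icz(spec))


def random_feature_table(rng: np.random.Generator, n_rows: int) -> iz.FeatureTable:
    """A random but valid repository table."""
    rows = []
    for i in range(n_rows):
        rows.append(
            (
                f"e{i}",
                iz.SimplifiedFeatures(
                    f1=float(rng.uniform(20, 120)),
                    f2=float(rng.uniform(20, 100)),
                    f3=float(rng.uniform(40, 240)),
                    f4=float(rng.uniform(25, 160)),
                    d1=float(rng.uniform(50, 75)),
                ),
            )
        )
    return iz.FeatureTable(tuple(rows))
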