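"""Synthetic tap-test data emulating a two-class (healthy / HD) cohort.

The clinical dataset behind this kind of study is never released, so the
generator stands in for it: 20 subjects (10 healthy, 10 Huntington's
patients), each performing the three test modes (2, 3 and 5 on-screen
circles) many times.  The generative model is:

* a latent per-subject *severity* s in [0, 1] (healthy subjects s <= 0.1,
  patients s in [0.3, 1]) plus small per-subject random effects;
* reaction times lognormal, with the log-location increasing in severity
  (bradykinesia) and mildly in the number of objects (visual search);
* touch points scattered around the target centre with isotropic Gaussian
  error whose scale grows exponentially with severity (tremor), giving a
  Rayleigh — lognormal-ish — touch-error distance ``delta``;
* a capacity label on [0, 10] that decreases with log reaction time and,
  more strongly, with log touch error, plus Gaussian noise — the touch
  error is deliberately the more discriminative feature.

Everything is driven by one seed; the same config and seed reproduce the
dataset byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .records import TouchRecord, compute_delta, log_transform, write_records

MODES = (2, 3, 5)


class LayoutInfeasibleError(RuntimeError):
    """Rejection sampling could not place the requested circles."""


@dataclass(frozen=True)
class SubjectProfile:
    """Latent state of one simulated subject."""

    user_id: int
    is_sick: int
    severity: float            # 0 = fully healthy, 1 = most affected
    rt_effect: float = 0.0     # per-subject shift of the rt log-location
    touch_effect: float = 0.0  # per-subject shift of the touch-error log-scale

    def __post_init__(self) -> None:
        if self.is_sick == 0 and not (0.0 <= self.severity <= 0.1):
            raise ValueError("healthy subjects must have severity <= 0.1")
        if self.is_sick == 1 and not (0.3 <= self.severity <= 1.0):
            raise ValueError("sick subjects must have severity in [0.3, 1]")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-shape and distributional parameters of the simulator.

    The label is ``clip(10 - alpha_rt*z(log rt) - beta_delta*z(log delta)
    + eps, 0, 10)`` with z-scores taken against the fixed reference moments
    below (not against the realized sample), so every label can be
    recomputed exactly from its own record.  ``beta_delta > alpha_rt`` keeps
    the touch error the stronger predictor.
    """

    screen_width: int = 1080
    screen_height: int = 1920
    circle_radius: float = 60.0
    subjects_per_class: int = 10
    attempts_per_mode: int = 51

    # reaction time: log rt ~ N(rt_log_base + slope*s + mode_slope*(nC-2), rt_log_sd)
    rt_log_base: float = -0.7
    rt_severity_slope: float = 1.2
    rt_mode_slope: float = 0.10
    rt_log_sd: float = 0.55

    # touch error: sd of the isotropic Gaussian, pixels
    touch_sd_base: float = 4.5
    touch_severity_slope: float = 2.5   # log-scale slope: sd = base * exp(slope*s)

    # per-subject random effects (log-scale standard deviations)
    subject_rt_sd: float = 0.15
    subject_touch_sd: float = 0.15

    # capacity label
    alpha_rt: float = 1.0
    beta_delta: float = 2.0
    label_noise_sd: float = 0.2
    ref_log_rt: tuple[float, float] = (-1.0, 0.65)    # (mean, sd) reference moments
    ref_log_delta: tuple[float, float] = (1.3, 0.8)

    seed: int = 42

    def __post_init__(self) -> None:
        if self.beta_delta <= self.alpha_rt:
            raise ValueError("beta_delta must exceed alpha_rt (delta is the "
                             "stronger predictor by construction)")
        if self.ref_log_rt[1] <= 0 or self.ref_log_delta[1] <= 0:
            raise ValueError("reference standard deviations must be positive")

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        for key in ("ref_log_rt", "ref_log_delta"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def generate_layout(
    n_objects: int,
    screen: tuple[int, int] = (1080, 1920),
    radius: float = 60.0,
    seed: int | np.random.Generator = 0,
    max_rejections: int = 10_000,
) -> list[tuple[float, float]]:
    """Place ``n_objects`` non-overlapping circles fully on screen.

    Centres are drawn uniformly and rejected when any pair comes closer than
    one circle diameter; after ``max_rejections`` failed proposals the layout
    is declared infeasible.
    """
    w, h = screen
    if w < 2 * radius or h < 2 * radius:
        raise LayoutInfeasibleError(f"screen {screen} cannot hold a circle of radius {radius}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    centers: list[tuple[float, float]] = []
    rejections = 0
    while len(centers) < n_objects:
        cx = rng.uniform(radius, w - radius)
        cy = rng.uniform(radius, h - radius)
        if all(math.hypot(cx - x, cy - y) >= 2 * radius for x, y in centers):
            centers.append((cx, cy))
        else:
            rejections += 1
            if rejections >= max_rejections:
                raise LayoutInfeasibleError(
                    f"could not place {n_objects} circles of radius {radius} "
                    f"on {screen} after {max_rejections} rejected proposals"
                )
    return centers


def sample_attempt(
    profile: SubjectProfile,
    n_objects: int,
    config: GeneratorConfig = GeneratorConfig(),
    seed: int | np.random.Generator = 0,
) -> TouchRecord:
    """Simulate one tap attempt for the given subject and mode."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    centers = generate_layout(
        n_objects, (config.screen_width, config.screen_height), config.circle_radius, rng
    )
    target = centers[int(rng.integers(len(centers)))]

    mu_rt = (config.rt_log_base + config.rt_severity_slope * profile.severity
             + config.rt_mode_slope * (n_objects - 2) + profile.rt_effect)
    rt = float(np.exp(rng.normal(mu_rt, config.rt_log_sd)))

    sd_touch = config.touch_sd_base * math.exp(
        config.touch_severity_slope * profile.severity + profile.touch_effect
    )
    touch = target + rng.normal(0.0, sd_touch, size=2)
    touch = np.clip(touch, 0.0, [config.screen_width, config.screen_height])

    return TouchRecord(
        x=round(target[0]), y=round(target[1]),
        xt=round(float(touch[0]), 1), yt=round(float(touch[1]), 1),
        n_objects=n_objects, rt=max(rt, 1e-3),
        user_id=profile.user_id, is_sick=profile.is_sick,
    )


def label_capacity(
    rt: float,
    delta: float,
    config: GeneratorConfig = GeneratorConfig(),
    noise: float | np.random.Generator = 0.0,
) -> float:
    """Capacity label on [0, 10] from one attempt's features.

    ``noise`` is either a pre-drawn N(0, label_noise_sd) deviate or a
    Generator to draw it from; pass 0.0 for the noiseless label.
    """
    if rt <= 0 or delta < 0:
        raise ValueError("label_capacity requires rt > 0 and delta >= 0")
    if isinstance(noise, np.random.Generator):
        noise = float(noise.normal(0.0, config.label_noise_sd))
    m1, s1 = config.ref_log_rt
    m2, s2 = config.ref_log_delta
    z_rt = (log_transform(rt) - m1) / s1
    z_delta = (log_transform(delta) - m2) / s2
    raw = 10.0 - config.alpha_rt * z_rt - config.beta_delta * z_delta + noise
    return float(np.clip(raw, 0.0, 10.0))


def make_profiles(config: GeneratorConfig, rng: np.random.Generator) -> list[SubjectProfile]:
    profiles = []
    for uid in range(1, 2 * config.subjects_per_class + 1):
        sick = 1 if uid > config.subjects_per_class else 0
        severity = (rng.uniform(0.3, 1.0) if sick else rng.uniform(0.0, 0.1))
        profiles.append(SubjectProfile(
            user_id=uid, is_sick=sick, severity=float(severity),
            rt_effect=float(rng.normal(0.0, config.subject_rt_sd)),
            touch_effect=float(rng.normal(0.0, config.subject_touch_sd)),
        ))
    return profiles


def generate_dataset(
    config: GeneratorConfig = GeneratorConfig(),
) -> tuple[list[TouchRecord], list[float], pd.DataFrame]:
    """Full synthetic study: records, capacity labels, and the latent truth table.

    The default configuration yields 20 subjects and 3060 records
    (51 attempts in each of the three modes per subject).
    """
    rng = np.random.default_rng(config.seed)
    profiles = make_profiles(config, rng)
    records: list[TouchRecord] = []
    labels: list[float] = []
    for profile in profiles:
        for mode in MODES:
            for _ in range(config.attempts_per_mode):
                rec = sample_attempt(profile, mode, config, rng)
                records.append(rec)
                labels.append(label_capacity(rec.rt, rec.delta, config, noise=rng))
    truth = pd.DataFrame([asdict(p) for p in profiles])
    return records, labels, truth


def write_dataset(config: GeneratorConfig, data_path, truth_path=None) -> None:
    """Generate and write the dataset CSV (with TFC labels) and optional truth sidecar."""
    records, labels, truth = generate_dataset(config)
    write_records(data_path, records, tfc=labels)
    if truth_path is not None:
        truth.to_csv(truth_path, index=False)


def simulate_session(
    profile: SubjectProfile,
    config: GeneratorConfig = GeneratorConfig(),
    attempts_per_mode: int = 4,
    seed: int | np.random.Generator = 0,
    session_id: str = "1",
):
    """A single test sitting for one subject (for the two-session comparison)."""
    from .pipeline import Session

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    records = [
        sample_attempt(profile, mode, config, rng)
        for mode in MODES
        for _ in range(attempts_per_mode)
    ]
    return Session(session_id=session_id, records=tuple(records))
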