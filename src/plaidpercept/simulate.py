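"""Synthetic behavioral cohorts for the priming paradigm.

Each simulated rat performs two-alternative direction discrimination of
horizontal targets (0 vs 180 deg) preceded by a grating or plaid prime
drifting at one of 19 directions.  The probability of a correct choice is

    p(d) = (1 - lapse) * (base_accuracy + gain * b(d)) + lapse / 2

where d is the prime-target angular distance, b is a bias profile equal to
+1 at d = 0 (coherent), 0 at 90 (neutral) and -1 at 180 (incoherent), and
the gain is ``identity_gain`` or ``cross_gain`` depending on whether the
prime matches the target's stimulus class.  Contaminant too-fast and
ignored trials are injected at configurable rates with reaction times
outside the valid response window, so the validity filter can be exercised
with exact ground-truth counts.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .behavior import (
    DIST_GRID,
    EXTREME_DISTANCES,
    angular_distance,
    target_kind_for_group,
)

PRIME_DIRECTIONS = np.arange(0, 181, 10)
TARGET_DIRECTIONS = np.array([0.0, 180.0])


@dataclass(frozen=True)
class SimRatConfig:
    animal_id: str
    group: str  # "G" (grating targets) or "P" (plaid targets)
    base_accuracy: float = 0.75
    identity_gain: float = 0.15
    cross_gain: float = 0.15
    bias_shape: str = "sigmoid"
    bias_slope: float = 25.0  # degrees; sigmoid steepness over distance
    lapse_rate: float = 0.05
    too_fast_rate: float = 0.03
    ignored_rate: float = 0.05
    n_sessions: int = 10
    trials_per_session: int = 300
    seed: int = 0

    def __post_init__(self):
        target_kind_for_group(self.group)  # validates group label
        if not (0.5 < self.base_accuracy < 1.0):
            raise ValueError("base_accuracy must lie in (0.5, 1)")
        for name in ("lapse_rate", "too_fast_rate", "ignored_rate"):
            if not (0.0 <= getattr(self, name) <= 0.2):
                raise ValueError(f"{name} must lie in [0, 0.2]")
        if self.bias_shape not in ("sigmoid", "linear"):
            raise ValueError(f"unknown bias_shape {self.bias_shape!r}")
        gain = max(self.identity_gain, self.cross_gain)
        if self.base_accuracy + gain > 1.0:
            raise ValueError("base_accuracy + gain exceeds 1: inconsistent probabilities")
        if min(self.identity_gain, self.cross_gain) < 0:
            raise ValueError("gains must be nonnegative")


def bias_profile(distance, shape: str = "sigmoid", slope: float = 25.0):
    """Priming bias b(d): +1 at d=0, 0 at d=90, -1 at d=180.

    The sigmoid profile is a logistic in distance centered at 90 deg,
    normalized to hit +/-1 exactly at the endpoints; the linear profile is
    (90 - d) / 90.
    """
    d = np.asarray(distance, dtype=float)
    if shape == "linear":
        return (90.0 - d) / 90.0
    raw = 1.0 / (1.0 + np.exp((d - 90.0) / slope)) - 0.5
    norm = 1.0 / (1.0 + np.exp(-90.0 / slope)) - 0.5
    return raw / norm


def expected_accuracy(config: SimRatConfig, condition: str, distance=None):
    """Ground-truth accuracy at each angular distance for valid trials."""
    if distance is None:
        distance = DIST_GRID
    gain = config.identity_gain if condition == "identity" else config.cross_gain
    b = bias_profile(distance, config.bias_shape, config.bias_slope)
    p = config.base_accuracy + gain * b
    return (1.0 - config.lapse_rate) * p + config.lapse_rate / 2.0


def expected_priming_magnitude(config: SimRatConfig, condition: str) -> float:
    """Magnitude implied by the generator (mean |p(d) - p(90)| at extremes)."""
    acc = expected_accuracy(config, condition, EXTREME_DISTANCES)
    neutral = expected_accuracy(config, condition, np.array([90.0]))[0]
    return float(np.mean(np.abs(acc - neutral)))


def _simulate_animal(config: SimRatConfig) -> pd.DataFrame:
    rng = np.random.default_rng(config.seed)
    n = config.n_sessions * config.trials_per_session
    session = np.repeat(np.arange(1, config.n_sessions + 1), config.trials_per_session)
    target = rng.choice(TARGET_DIRECTIONS, size=n)
    prime_kind = rng.choice(["grating", "plaid"], size=n)
    prime_dir = rng.choice(PRIME_DIRECTIONS, size=n).astype(float)

    identity_kind = target_kind_for_group(config.group)
    gain = np.where(prime_kind == identity_kind, config.identity_gain, config.cross_gain)
    dist = angular_distance(prime_dir, target)
    p_correct = config.base_accuracy + gain * bias_profile(dist, config.bias_shape, config.bias_slope)
    p_correct = (1.0 - config.lapse_rate) * p_correct + config.lapse_rate / 2.0
    correct = rng.random(n) < p_correct

    # choice encodes the reported direction: right for 0 deg, left for 180 deg
    reported_right = np.where(target == 0.0, correct, ~correct)
    choice = np.where(reported_right, "right", "left")

    u = rng.random(n)
    too_fast = u < config.too_fast_rate
    ignored = ~too_fast & (u < config.too_fast_rate + config.ignored_rate)
    rt = rng.uniform(320.0, 980.0, size=n)
    rt[too_fast] = rng.uniform(50.0, 295.0, size=int(too_fast.sum()))
    rt[ignored] = rng.uniform(1005.0, 1800.0, size=int(ignored.sum()))

    return pd.DataFrame(
        {
            "animal_id": config.animal_id,
            "group": config.group,
            "session": session,
            "phase": "priming",
            "prime_kind": prime_kind,
            "prime_direction": prime_dir,
            "target_direction": target,
            "choice": choice,
            "reaction_time": rt,
            "correct": correct,
        }
    )


def simulate_cohort(configs: list[SimRatConfig]) -> tuple[pd.DataFrame, dict]:
    """Simulate a cohort of rats; returns (trial table, ground-truth record).

    The ground truth carries, per animal, the exact expected identity- and
    cross-priming curves and magnitudes (valid trials only) and the
    injected contaminant counts, plus the generator configs.
    """
    if not configs:
        raise ValueError("at least one rat config is required")
    ids = [c.animal_id for c in configs]
    if len(set(ids)) != len(ids):
        raise ValueError("animal ids must be unique")
    frames = []
    truth = {"animals": {}, "configs": [asdict(c) for c in configs]}
    for cfg in configs:
        df = _simulate_animal(cfg)
        frames.append(df)
        n_too_fast = int((df["reaction_time"] < 300.0).sum())
        n_ignored = int((df["reaction_time"] > 1000.0).sum())
        truth["animals"][cfg.animal_id] = {
            "group": cfg.group,
            "identity_curve": expected_accuracy(cfg, "identity").tolist(),
            "cross_curve": expected_accuracy(cfg, "cross").tolist(),
            "identity_magnitude": expected_priming_magnitude(cfg, "identity"),
            "cross_magnitude": expected_priming_magnitude(cfg, "cross"),
            "n_too_fast": n_too_fast,
            "n_ignored": n_ignored,
        }
    table = pd.concat(frames, ignore_index=True)
    return table, truth


def default_cohort(
    seed: int = 0,
    n_g: int = 11,
    n_p: int = 10,
    n_sessions: int = 10,
    trials_per_session: int = 300,
    **overrides,
) -> list[SimRatConfig]:
    """Study-condition cohort: G rats show identity priming only, P rats both.

    G-group rats prime strongly in the identity condition (gain 0.15) but
    barely in the cross condition (gain 0.02, a nearly flat curve); P-group
    rats prime equally in both conditions.
    """
    rng = np.random.default_rng(seed)
    configs = []
    for i in range(n_g):
        configs.append(
            SimRatConfig(
                animal_id=f"G{i + 1:02d}",
                group="G",
                identity_gain=0.15,
                cross_gain=0.02,
                n_sessions=n_sessions,
                trials_per_session=trials_per_session,
                seed=int(rng.integers(0, 2**31 - 1)),
                **overrides,
            )
        )
    for i in range(n_p):
        configs.append(
            SimRatConfig(
                animal_id=f"P{i + 1:02d}",
                group="P",
                identity_gain=0.15,
                cross_gain=0.15,
                n_sessions=n_sessions,
                trials_per_session=trials_per_session,
                seed=int(rng.integers(0, 2**31 - 1)),
                **overrides,
            )
        )
    return configs


def simulate_training_sessions(
    animal_id: str,
    group: str,
    n_sessions: int = 30,
    start_accuracy: float = 0.5,
    asymptote: float = 0.8,
    learning_rate: float = 0.15,
    trials_per_session: int = 300,
    seed: int = 0,
) -> pd.DataFrame:
    """Training-phase trials with an exponential learning ramp.

    Session accuracy follows asymptote - (asymptote - start) * exp(-rate*t),
    emulating acquisition of the discrimination before the priming phase.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for s in range(1, n_sessions + 1):
        p = asymptote - (asymptote - start_accuracy) * np.exp(-learning_rate * (s - 1))
        n = trials_per_session
        target = rng.choice(TARGET_DIRECTIONS, size=n)
        correct = rng.random(n) < p
        reported_right = np.where(target == 0.0, correct, ~correct)
        frames.append(
            pd.DataFrame(
                {
                    "animal_id": animal_id,
                    "group": group,
                    "session": s,
                    "phase": "training",
                    "prime_kind": "none",
                    "prime_direction": np.nan,
                    "target_direction": target,
                    "choice": np.where(reported_right, "right", "left"),
                    "reaction_time": rng.uniform(350.0, 3900.0, size=n),
                    "correct": correct,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_trials(table: pd.DataFrame, path) -> None:
    """Write a trial table to CSV; round-trips through behavior.read_trials."""
    from pathlib import Path

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
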