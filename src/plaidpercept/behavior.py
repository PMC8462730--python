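"""Behavioral pipeline: trial filtering, learning metrics, priming curves.

A priming trial pairs a briefly flashed prime (grating or plaid, drifting
at one of 19 directions from 0 to 180 deg in 10-deg steps) with a
horizontal target (0 or 180 deg) whose direction the rat reports.  The
priming curve is the accuracy as a function of the unsigned angular
distance between prime and target direction, pooled over both targets:
distance 0 is the coherent condition, 180 the incoherent one and 90
(vertical prime) the neutral reference.  The priming magnitude is the mean
absolute deviation of the four most-coherent and four most-incoherent
points from the neutral accuracy.  Group statistics come from a session
bootstrap: each animal's sessions are resampled with replacement, the
per-animal curves recomputed and averaged with equal animal weights, and
normal confidence intervals are built from the bootstrap SD (Bonferroni
correction over the 19 curve points; scalar magnitudes unadjusted).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DIST_GRID = np.arange(0, 181, 10)
N_DIST = len(DIST_GRID)
#: distances entering the priming-magnitude statistic (4 points per side)
EXTREME_DISTANCES = np.array([0, 10, 20, 30, 150, 160, 170, 180])

REQUIRED_COLUMNS = [
    "animal_id",
    "group",
    "session",
    "phase",
    "prime_kind",
    "prime_direction",
    "target_direction",
    "choice",
    "reaction_time",
    "correct",
]

#: valid response window (ms from target onset) in the priming phase
PRIMING_RT_WINDOW = (300.0, 1000.0)
#: training phase: 2 s stimulus + responses accepted up to 2 s after offset
TRAINING_RT_WINDOW = (300.0, 4000.0)

_CHOICE_FOR_TARGET = {0.0: "right", 180.0: "left"}


def target_kind_for_group(group: str) -> str:
    """Stimulus class of the target: gratings for the G group, plaids for P."""
    if group == "G":
        return "grating"
    if group == "P":
        return "plaid"
    raise ValueError(f"unknown group {group!r}")


def angular_distance(a, b):
    """Smallest unsigned angle (degrees, in [0, 180]) between two directions."""
    return np.abs((np.asarray(a, dtype=float) - np.asarray(b, dtype=float) + 180.0) % 360.0 - 180.0)


def read_trials(path) -> pd.DataFrame:
    """Read a trial table from CSV, deriving ``correct`` if absent."""
    df = pd.read_csv(path)
    if "correct" not in df.columns:
        df["correct"] = [
            _CHOICE_FOR_TARGET.get(t) == c
            for t, c in zip(df["target_direction"].astype(float), df["choice"])
        ]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table is missing columns: {missing}")
    df["correct"] = df["correct"].astype(bool)
    return df


@dataclass
class ExclusionReport:
    n_total: int
    n_valid: int
    n_too_fast: int
    n_ignored: int
    n_malformed: int

    def as_dict(self):
        return dict(self.__dict__)


def filter_trials(trials: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop too-fast, ignored and malformed trials.

    Priming phase: responses must fall in [300, 1000] ms from target onset
    (faster trials are aborted as "too fast", later ones or absent choices
    are "ignored").  Training phase: the same 300 ms lower bound, with the
    upper bound 2 s after offset of the 2 s stimulus.  Trials without a
    reaction time are counted as malformed.
    """
    rt = pd.to_numeric(trials["reaction_time"], errors="coerce")
    malformed = rt.isna()
    priming = trials["phase"] == "priming"
    lo = np.where(priming, PRIMING_RT_WINDOW[0], TRAINING_RT_WINDOW[0])
    hi = np.where(priming, PRIMING_RT_WINDOW[1], TRAINING_RT_WINDOW[1])
    too_fast = ~malformed & (rt < lo)
    ignored = ~malformed & ~too_fast & ((rt > hi) | (trials["choice"] == "none"))
    valid = ~(malformed | too_fast | ignored)
    report = ExclusionReport(
        n_total=len(trials),
        n_valid=int(valid.sum()),
        n_too_fast=int(too_fast.sum()),
        n_ignored=int(ignored.sum()),
        n_malformed=int(malformed.sum()),
    )
    return trials.loc[valid].copy(), report


# ---------------------------------------------------------------------------
# learning curves


@dataclass
class LearningMetrics:
    smoothed: np.ndarray
    criterion_session: int | None  # 1-based; None if criterion never reached
    asymptotic_performance: float | None


def learning_metrics(session_accuracies, criterion: float = 0.70, run_length: int = 4) -> LearningMetrics:
    """Moving-average learning curve, criterion session and asymptote.

    The smoothed curve applies a size-3 moving average with shrunk edge
    windows.  The criterion session is the first session opening a run of
    ``run_length`` consecutive sessions with raw accuracy >= ``criterion``;
    the asymptotic performance is the mean raw accuracy from that session
    onward.
    """
    acc = np.asarray(session_accuracies, dtype=float)
    if acc.size < run_length:
        raise ValueError(f"at least {run_length} sessions are required")
    smoothed = np.array([acc[max(0, i - 1): i + 2].mean() for i in range(acc.size)])
    above = acc >= criterion
    criterion_session = None
    for i in range(acc.size - run_length + 1):
        if above[i: i + run_length].all():
            criterion_session = i + 1
            break
    asymptote = None if criterion_session is None else float(acc[criterion_session - 1:].mean())
    return LearningMetrics(smoothed, criterion_session, asymptote)


# ---------------------------------------------------------------------------
# priming curves


@dataclass
class PrimingCurveResult:
    """19-point accuracy curve over prime-target angular distance."""

    diff_grid: np.ndarray
    accuracy: np.ndarray
    n_trials: np.ndarray
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    condition: str | None = None

    def to_frame(self):
        data = {
            "distance": self.diff_grid,
            "accuracy": self.accuracy,
            "n_trials": self.n_trials,
        }
        if self.ci_low is not None:
            data["ci_low"] = self.ci_low
            data["ci_high"] = self.ci_high
        if self.condition is not None:
            data["condition"] = self.condition
        return pd.DataFrame(data)


def _counts_by_distance(dist_idx, correct, weights_shape=N_DIST):
    n_corr = np.bincount(dist_idx, weights=correct, minlength=weights_shape)
    n_tot = np.bincount(dist_idx, minlength=weights_shape)
    return n_corr, n_tot


def _accuracy(n_corr, n_tot):
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_tot > 0, n_corr / np.maximum(n_tot, 1), np.nan)


def priming_curve(trials: pd.DataFrame, prime_kind: str | None = None, condition: str | None = None) -> PrimingCurveResult:
    """Accuracy vs prime-target angular distance for one animal's trials.

    Empty distance bins propagate as NaN, never as zero accuracy.
    """
    if prime_kind is not None:
        trials = trials[trials["prime_kind"] == prime_kind]
    dist = angular_distance(trials["prime_direction"], trials["target_direction"])
    dist_idx = np.rint(dist / 10.0).astype(int)
    if np.any((dist_idx < 0) | (dist_idx >= N_DIST)):
        raise ValueError("prime directions must lie on the 0-180 deg, 10-deg-step grid")
    n_corr, n_tot = _counts_by_distance(dist_idx, trials["correct"].to_numpy(dtype=float))
    return PrimingCurveResult(DIST_GRID.copy(), _accuracy(n_corr, n_tot), n_tot, condition=condition)


def priming_magnitude(curve: PrimingCurveResult) -> float:
    """Mean |accuracy - neutral accuracy| over the 8 extreme curve points.

    The neutral accuracy is the animal's own 90-deg bin.  Reported as a
    fraction (multiply by 100 for percentage points).
    """
    acc = dict(zip(curve.diff_grid, curve.accuracy))
    neutral = acc.get(90, np.nan)
    if np.isnan(neutral):
        raise ValueError("neutral (90 deg) bin is undefined")
    extremes = np.array([acc.get(d, np.nan) for d in EXTREME_DISTANCES])
    if np.isnan(extremes).all():
        raise ValueError("no extreme curve points are defined")
    return float(np.nanmean(np.abs(extremes - neutral)))


def _magnitude_from_curve_array(acc: np.ndarray) -> float:
    neutral = acc[9]  # 90 deg bin
    if np.isnan(neutral):
        return np.nan
    ext = acc[np.searchsorted(DIST_GRID, EXTREME_DISTANCES)]
    if np.isnan(ext).all():
        return np.nan
    return float(np.nanmean(np.abs(ext - neutral)))


# ---------------------------------------------------------------------------
# inclusion criterion and group bootstrap


def apply_inclusion_criterion(trials: pd.DataFrame, threshold: float = 0.05):
    """Keep animals whose identity-priming magnitude is at least ``threshold``.

    Returns (kept trials, excluded animal ids, per-animal magnitudes).
    """
    magnitudes = {}
    excluded = []
    for animal, sub in trials.groupby("animal_id"):
        kind = target_kind_for_group(sub["group"].iloc[0])
        mag = priming_magnitude(priming_curve(sub, prime_kind=kind))
        magnitudes[animal] = mag
        if mag < threshold:
            excluded.append(animal)
    kept = trials[~trials["animal_id"].isin(excluded)].copy()
    return kept, excluded, magnitudes


@dataclass(frozen=True)
class BootstrapConfig:
    n_reps: int = 50
    ci_level: float = 0.95
    bonferroni_m: int = N_DIST
    seed: int = 0

    def __post_init__(self):
        if self.n_reps < 2:
            raise ValueError("n_reps must be at least 2")


@dataclass
class MagnitudeEstimate:
    value: float
    ci_low: float
    ci_high: float
    bootstrap_sd: float


@dataclass
class GroupPrimingResult:
    group: str
    n_animals: int
    curves: dict  # condition -> PrimingCurveResult (group mean, Bonferroni CIs)
    magnitudes: dict  # condition -> MagnitudeEstimate
    magnitude_difference: MagnitudeEstimate  # identity - cross
    per_animal_magnitudes: dict  # condition -> {animal_id: magnitude}
    flags: list = field(default_factory=list)
    config: BootstrapConfig | None = None

    def summary(self):
        return {
            "group": self.group,
            "n_animals": self.n_animals,
            "magnitudes": {
                cond: {
                    "value": m.value,
                    "ci_low": m.ci_low,
                    "ci_high": m.ci_high,
                    "bootstrap_sd": m.bootstrap_sd,
                }
                for cond, m in self.magnitudes.items()
            },
            "magnitude_difference_identity_minus_cross": {
                "value": self.magnitude_difference.value,
                "ci_low": self.magnitude_difference.ci_low,
                "ci_high": self.magnitude_difference.ci_high,
            },
            "flags": list(self.flags),
        }


_CONDITIONS = ("identity", "cross")


def _animal_session_counts(sub: pd.DataFrame):
    """Per-session correct/total counts, shape (S, 2 conditions, 19 bins, 2)."""
    sessions = np.sort(sub["session"].unique())
    sess_idx = np.searchsorted(sessions, sub["session"].to_numpy())
    kind = target_kind_for_group(sub["group"].iloc[0])
    cond_idx = np.where(sub["prime_kind"].to_numpy() == kind, 0, 1)
    dist = angular_distance(sub["prime_direction"], sub["target_direction"])
    dist_idx = np.rint(dist / 10.0).astype(int)
    correct = sub["correct"].to_numpy(dtype=float)
    counts = np.zeros((len(sessions), 2, N_DIST, 2))
    np.add.at(counts, (sess_idx, cond_idx, dist_idx, 0), correct)
    np.add.at(counts, (sess_idx, cond_idx, dist_idx, 1), 1.0)
    return counts


def _curves_and_mags(counts_summed):
    """(2, 19) accuracy array and per-condition magnitudes from summed counts."""
    acc = _accuracy(counts_summed[..., 0], counts_summed[..., 1])
    mags = np.array([_magnitude_from_curve_array(acc[c]) for c in range(2)])
    return acc, mags


def bootstrap_group_curves(trials: pd.DataFrame, config: BootstrapConfig | None = None) -> GroupPrimingResult:
    """Group mean priming curves, magnitudes and bootstrap CIs for one group.

    Sessions are the resampling unit: in each replicate, every animal's
    sessions are drawn with replacement independently, the animal's
    identity- and cross-condition curves are recomputed from the resampled
    counts, and animals are averaged with equal weights.  Curve-point CIs
    use the Bonferroni-adjusted normal critical value; scalar magnitude CIs
    are unadjusted.  Normal CIs are reported raw and may exceed [0, 1].
    """
    if config is None:
        config = BootstrapConfig()
    groups = trials["group"].unique()
    if len(groups) != 1:
        raise ValueError("bootstrap_group_curves expects trials from a single group")
    group = str(groups[0])
    animals = sorted(trials["animal_id"].unique())
    if len(animals) < 2:
        raise ValueError("at least 2 animals are required")

    flags = []
    per_animal = []
    for animal in animals:
        counts = _animal_session_counts(trials[trials["animal_id"] == animal])
        if counts.shape[0] < 2:
            flags.append(f"animal {animal} has a single session: degenerate resampling")
        per_animal.append(counts)

    # point estimates (all sessions)
    point = [_curves_and_mags(c.sum(axis=0)) for c in per_animal]
    acc_point = np.stack([p[0] for p in point])
    mag_point = np.stack([p[1] for p in point])
    group_acc = np.nanmean(acc_point, axis=0)  # (2, 19)
    group_mag = np.nanmean(mag_point, axis=0)  # (2,)

    rng = np.random.default_rng(config.seed)
    boot_acc = np.empty((config.n_reps, 2, N_DIST))
    boot_mag = np.empty((config.n_reps, 2))
    for r in range(config.n_reps):
        accs = np.empty((len(animals), 2, N_DIST))
        mags = np.empty((len(animals), 2))
        for a, counts in enumerate(per_animal):
            s = counts.shape[0]
            resampled = counts[rng.integers(0, s, size=s)].sum(axis=0)
            accs[a], mags[a] = _curves_and_mags(resampled)
        boot_acc[r] = np.nanmean(accs, axis=0)
        boot_mag[r] = np.nanmean(mags, axis=0)

    alpha = 1.0 - config.ci_level
    z_curve = stats.norm.ppf(1.0 - alpha / (2.0 * config.bonferroni_m))
    z_scalar = stats.norm.ppf(1.0 - alpha / 2.0)
    acc_sd = np.nanstd(boot_acc, axis=0, ddof=1)
    mag_sd = np.nanstd(boot_mag, axis=0, ddof=1)
    diff_boot = boot_mag[:, 0] - boot_mag[:, 1]
    diff_sd = float(np.nanstd(diff_boot, ddof=1))
    diff_value = float(group_mag[0] - group_mag[1])

    n_tot = np.stack([c.sum(axis=0)[..., 1] for c in per_animal]).sum(axis=0)
    curves = {}
    magnitudes = {}
    per_animal_mags = {}
    for c, cond in enumerate(_CONDITIONS):
        curves[cond] = PrimingCurveResult(
            DIST_GRID.copy(),
            group_acc[c],
            n_tot[c].astype(int),
            ci_low=group_acc[c] - z_curve * acc_sd[c],
            ci_high=group_acc[c] + z_curve * acc_sd[c],
            condition=cond,
        )
        magnitudes[cond] = MagnitudeEstimate(
            value=float(group_mag[c]),
            ci_low=float(group_mag[c] - z_scalar * mag_sd[c]),
            ci_high=float(group_mag[c] + z_scalar * mag_sd[c]),
            bootstrap_sd=float(mag_sd[c]),
        )
        per_animal_mags[cond] = {a: float(mag_point[i, c]) for i, a in enumerate(animals)}

    return GroupPrimingResult(
        group=group,
        n_animals=len(animals),
        curves=curves,
        magnitudes=magnitudes,
        magnitude_difference=MagnitudeEstimate(
            value=diff_value,
            ci_low=diff_value - z_scalar * diff_sd,
            ci_high=diff_value + z_scalar * diff_sd,
            bootstrap_sd=diff_sd,
        ),
        per_animal_magnitudes=per_animal_mags,
        flags=flags,
        config=config,
    )


# ---------------------------------------------------------------------------
# group comparison


@dataclass
class GroupComparison:
    t_statistic: float
    p_value: float
    degenerate: bool = False


def group_comparison(metric_a, metric_b) -> GroupComparison:
    """Unpaired two-tailed pooled-variance t-test between two animal groups."""
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("at least 2 animals per group are required")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        if a.mean() == b.mean():
            return GroupComparison(0.0, 1.0, degenerate=True)
        sign = np.sign(a.mean() - b.mean())
        return GroupComparison(float(sign * np.inf), 0.0, degenerate=True)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return GroupComparison(float(t), float(p))
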