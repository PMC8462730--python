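"""Behavioral-pipeline tests: filtering, learning metrics, priming statistics."""

import numpy as np
import pandas as pd
import pytest

from plaidpercept import (
    BootstrapConfig,
    angular_distance,
    apply_inclusion_criterion,
    bootstrap_group_curves,
    filter_trials,
    group_comparison,
    learning_metrics,
    priming_curve,
    priming_magnitude,
    read_trials,
)
from plaidpercept.behavior import DIST_GRID, PrimingCurveResult


def _trial(phase="priming", rt=500.0, prime_dir=0.0, target=0.0, correct=True,
           prime_kind="grating", choice="right", animal="r1", group="G", session=1):
    return {
        "animal_id": animal, "group": group, "session": session, "phase": phase,
        "prime_kind": prime_kind, "prime_direction": prime_dir,
        "target_direction": target, "choice": choice,
        "reaction_time": rt, "correct": correct,
    }


class TestFilterTrials:
    def test_priming_window(self):
        df = pd.DataFrame([
            _trial(rt=250.0),          # too fast
            _trial(rt=1200.0),         # ignored
            _trial(rt=500.0),          # kept
            _trial(rt=300.0),          # boundary: kept (abort rule is rt < 300)
            _trial(rt=np.nan),         # malformed
            _trial(rt=700.0, choice="none"),  # no response -> ignored
        ])
        valid, report = filter_trials(df)
        assert report.as_dict() == {
            "n_total": 6, "n_valid": 2, "n_too_fast": 1, "n_ignored": 2, "n_malformed": 1,
        }
        assert sorted(valid["reaction_time"]) == [300.0, 500.0]

    def test_training_window_extends_to_two_seconds_after_offset(self):
        df = pd.DataFrame([
            _trial(phase="training", rt=3500.0, prime_kind="none"),  # kept
            _trial(phase="training", rt=4200.0, prime_kind="none"),  # ignored
            _trial(phase="training", rt=200.0, prime_kind="none"),   # too fast
        ])
        valid, report = filter_trials(df)
        assert (report.n_valid, report.n_too_fast, report.n_ignored) == (1, 1, 1)


class TestLearningMetrics:
    def test_criterion_and_asymptote(self):
        m = learning_metrics([0.60, 0.65, 0.72, 0.71, 0.73, 0.74])
        assert m.criterion_session == 3
        assert m.asymptotic_performance == pytest.approx(np.mean([0.72, 0.71, 0.73, 0.74]))

    def test_criterion_is_inclusive_at_70_percent(self):
        assert learning_metrics([0.69] * 6).criterion_session is None
        assert learning_metrics([0.70] * 4).criterion_session == 1

    def test_moving_average_shrinks_at_edges(self):
        m = learning_metrics([0.5, 0.6, 0.9, 0.8, 0.7])
        assert m.smoothed[0] == pytest.approx(np.mean([0.5, 0.6]))
        assert m.smoothed[2] == pytest.approx(np.mean([0.6, 0.9, 0.8]))
        assert m.smoothed[-1] == pytest.approx(np.mean([0.8, 0.7]))

    def test_too_few_sessions_rejected(self):
        with pytest.raises(ValueError):
            learning_metrics([0.7, 0.7])


class TestPrimingCurve:
    def test_distance_pooling(self):
        assert angular_distance(0.0, 0.0) == 0.0
        assert angular_distance(180.0, 180.0) == 0.0
        assert angular_distance(180.0, 0.0) == 180.0
        assert angular_distance(90.0, 0.0) == 90.0
        assert angular_distance(90.0, 180.0) == 90.0

    def test_curve_pools_both_targets(self):
        df = pd.DataFrame(
            [_trial(prime_dir=0.0, target=0.0, correct=True)] * 3
            + [_trial(prime_dir=180.0, target=180.0, correct=True)] * 2
            + [_trial(prime_dir=180.0, target=0.0, correct=False)] * 4
        )
        curve = priming_curve(df)
        assert curve.n_trials[0] == 5 and curve.accuracy[0] == 1.0
        assert curve.n_trials[-1] == 4 and curve.accuracy[-1] == 0.0

    def test_empty_bins_propagate_as_nan(self):
        df = pd.DataFrame([_trial(prime_dir=0.0, target=0.0)])
        curve = priming_curve(df)
        assert np.isnan(curve.accuracy[1:]).all()

    def test_invariant_to_target_relabeling(self, rng):
        rows = []
        for _ in range(400):
            prime = float(rng.choice(np.arange(0, 181, 10)))
            target = float(rng.choice([0.0, 180.0]))
            correct = bool(rng.random() < 0.75)
            rows.append(_trial(prime_dir=prime, target=target, correct=correct))
        df = pd.DataFrame(rows)
        flipped = df.copy()
        flipped["target_direction"] = 180.0 - flipped["target_direction"]
        flipped["prime_direction"] = 180.0 - flipped["prime_direction"]
        np.testing.assert_allclose(
            priming_curve(df).accuracy, priming_curve(flipped).accuracy, equal_nan=True
        )


class TestPrimingMagnitude:
    def _curve(self, acc):
        acc = np.asarray(acc, dtype=float)
        return PrimingCurveResult(DIST_GRID.copy(), acc, np.full(19, 10))

    def test_direct_arithmetic(self):
        acc = np.full(19, 0.7)
        acc[:4] = 0.9
        acc[-4:] = 0.5
        assert priming_magnitude(self._curve(acc)) == pytest.approx(0.2)

    def test_flat_curve_is_zero(self):
        assert priming_magnitude(self._curve(np.full(19, 0.8))) == 0.0

    def test_undefined_neutral_raises(self):
        acc = np.full(19, 0.8)
        acc[9] = np.nan
        with pytest.raises(ValueError):
            priming_magnitude(self._curve(acc))

    def test_inclusion_criterion_excludes_flat_animals(self, rng):
        # "flat" responds correctly on every trial (exactly zero modulation,
        # no sampling floor); "primed" carries a strong distance-dependent bias
        rows = []
        for animal, p_mod in (("flat", None), ("primed", 0.2)):
            for session in range(1, 4):
                for _ in range(600):
                    prime = float(rng.choice(np.arange(0, 181, 10)))
                    target = float(rng.choice([0.0, 180.0]))
                    d = angular_distance(prime, target)
                    if p_mod is None:
                        correct = True
                    else:
                        correct = bool(rng.random() < 0.75 + p_mod * (90.0 - d) / 90.0)
                    rows.append(_trial(prime_dir=prime, target=target, correct=correct,
                                       animal=animal, session=session))
        kept, excluded, mags = apply_inclusion_criterion(pd.DataFrame(rows), threshold=0.05)
        assert excluded == ["flat"]
        assert mags["flat"] == 0.0
        assert mags["primed"] > 0.1
        assert set(kept["animal_id"]) == {"primed"}


class TestBootstrap:
    def _cohort(self, rng, n_animals=3, n_sessions=4, modulate=0.15, noise=True):
        rows = []
        for a in range(n_animals):
            for s in range(1, n_sessions + 1):
                for _ in range(200):
                    prime = float(rng.choice(np.arange(0, 181, 10)))
                    kind = str(rng.choice(["grating", "plaid"]))
                    target = float(rng.choice([0.0, 180.0]))
                    d = angular_distance(prime, target)
                    p = 0.75 + modulate * (90.0 - d) / 90.0
                    correct = bool(rng.random() < p) if noise else (d < 90.0)
                    rows.append(_trial(prime_dir=prime, target=target, correct=correct,
                                       prime_kind=kind, animal=f"r{a}", session=s))
        return pd.DataFrame(rows)

    def test_deterministic_rat_gives_zero_width_ci(self, rng):
        df = self._cohort(rng, noise=False)
        res = bootstrap_group_curves(df, BootstrapConfig(n_reps=20, seed=0))
        for cond in ("identity", "cross"):
            c = res.curves[cond]
            width = c.ci_high - c.ci_low
            np.testing.assert_allclose(width[~np.isnan(width)], 0.0, atol=1e-12)

    def test_bonferroni_widens_curve_cis(self, rng):
        df = self._cohort(rng)
        wide = bootstrap_group_curves(df, BootstrapConfig(n_reps=30, bonferroni_m=19, seed=1))
        narrow = bootstrap_group_curves(df, BootstrapConfig(n_reps=30, bonferroni_m=1, seed=1))
        w_wide = wide.curves["identity"].ci_high - wide.curves["identity"].ci_low
        w_narrow = narrow.curves["identity"].ci_high - narrow.curves["identity"].ci_low
        mask = ~np.isnan(w_wide) & (w_narrow > 0)
        assert np.all(w_wide[mask] > w_narrow[mask])

    def test_bootstrap_sd_stable_across_seeds(self, rng):
        df = self._cohort(rng)
        sds = [
            bootstrap_group_curves(df, BootstrapConfig(n_reps=1000, seed=s))
            .magnitudes["identity"].bootstrap_sd
            for s in (1, 2)
        ]
        assert abs(sds[0] - sds[1]) / sds[0] < 0.10

    def test_single_session_animal_is_flagged(self, rng):
        df = self._cohort(rng, n_animals=2, n_sessions=1)
        res = bootstrap_group_curves(df, BootstrapConfig(n_reps=10, seed=0))
        assert any("single session" in f for f in res.flags)

    def test_mixed_groups_rejected(self, rng):
        df = self._cohort(rng, n_animals=2)
        df.loc[df["animal_id"] == "r0", "group"] = "P"
        with pytest.raises(ValueError):
            bootstrap_group_curves(df)


class TestGroupComparison:
    def test_identical_groups(self):
        res = group_comparison([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_textbook_pooled_t(self):
        # pooled s^2 = 4, t = -10 / (2 sqrt(2/3)) = -6.1237
        res = group_comparison([70.0, 72.0, 74.0], [80.0, 82.0, 84.0])
        assert res.t_statistic == pytest.approx(-6.123724, abs=1e-5)

    def test_degenerate_variance_flagged(self):
        res = group_comparison([1.0, 1.0], [1.0, 1.0])
        assert res.degenerate and res.p_value == 1.0


def test_read_trials_derives_correct_column(tmp_path):
    df = pd.DataFrame([
        _trial(target=0.0, choice="right"),
        _trial(target=0.0, choice="left"),
        _trial(target=180.0, choice="left"),
    ]).drop(columns=["correct"])
    path = tmp_path / "t.csv"
    df.to_csv(path, index=False)
    out = read_trials(path)
    assert out["correct"].tolist() == [True, False, True]
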