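"""Named, seeded scenario recipes bundling the simulations end to end.

Each scenario builds its population, trains the decision neuron, and
returns a JSON-serializable summary; with an output directory it also
writes the summary, a reproducibility manifest and CSV artifacts.  The
defaults pin the study conditions: 24 equispaced cells with k = 7 and 500
training samples per class for the small-population generalization runs;
1000 cells (80% component / 20% pattern, uniform preferred directions,
baseline 2 spikes/s, amplitudes N(8, 1), trial noise SD 2 spikes/s,
OSI ~ N(0.7, 0.1), DSI ~ N(0.6, 0.2), pattern plaid tuning broadened by
k/4) with 200 training samples per class for the mixed-population runs;
L2 lambda = 1 throughout.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .behavior import (
    BootstrapConfig,
    apply_inclusion_criterion,
    bootstrap_group_curves,
    filter_trials,
    group_comparison,
    read_trials,
)
from .pool import (
    evidence_curve,
    input_population_norms,
    pruning_profile,
    weight_norm,
)
from .populations import (
    PopulationConfig,
    StimulusKind,
    StimulusSpec,
    cells_to_frame,
    sample_population,
)
from .readout import (
    TrainingConfig,
    classification_accuracy,
    curve_divergence,
    generalization_curve,
    train_readout,
    training_responses,
)
from .simulate import default_cohort, simulate_cohort, write_trials

TEST_GRID_15 = np.arange(0.0, 360.0, 15.0)

_MOD = 2**31 - 1


def _sub_seed(seed: int, salt: int) -> int:
    """Deterministic child seed below 2**31."""
    return (int(seed) * 1_000_003 + salt) % _MOD


def _json_ready(obj):
    if isinstance(obj, dict):
        return {k: _json_ready(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_ready(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# small equispaced populations (generalization-curve scenarios)


def _small_population_run(
    seed: int,
    cell_class: str = "component",
    train_kind: str = "plaid",
    k: float = 7.0,
    n_train: int = 500,
    n_test: int = 500,
    noise_sd: float = 0.25,
    l2_lambda: float = 1.0,
):
    frac = 1.0 if cell_class == "component" else 0.0
    pop_cfg = PopulationConfig(
        n_cells=24,
        fraction_component=frac,
        pref_direction_scheme="equispaced",
        k=k,
        amplitude=1.0,
        baseline=0.1,
        trial_noise_sd=noise_sd,
        seed=_sub_seed(seed, 1),
    )
    cells = sample_population(pop_cfg)
    train = training_responses(cells, StimulusKind(train_kind), n_train, noise_sd, _sub_seed(seed, 2))
    model = train_readout(
        train,
        TrainingConfig(StimulusKind(train_kind), n_train, l2_lambda),
    )
    curves = {
        kind.value: generalization_curve(
            model, cells, kind, TEST_GRID_15, n_test, noise_sd, _sub_seed(seed, 3 + i)
        )
        for i, kind in enumerate((StimulusKind.PLAID, StimulusKind.GRATING))
    }
    plaid = curves["plaid"].prop_rightward
    # local maximum restricted to the open interval (60, 180) on the grid
    interior = (TEST_GRID_15 > 60.0) & (TEST_GRID_15 < 180.0)
    local_max_dir = float(TEST_GRID_15[interior][np.argmax(plaid[interior])])
    summary = {
        "cell_class": cell_class,
        "train_kind": train_kind,
        "k": k,
        "directions": TEST_GRID_15,
        "prop_rightward_plaid": plaid,
        "prop_rightward_grating": curves["grating"].prop_rightward,
        "weights": model.weights,
        "weight_pref_directions": [c.pref_direction for c in cells],
        "bias": model.bias,
        "divergence": curve_divergence(curves["plaid"], curves["grating"]),
        "prop_rightward_plaid_at_0_pct": float(plaid[0] * 100.0),
        "prop_rightward_plaid_at_60_pct": float(plaid[list(TEST_GRID_15).index(60.0)] * 100.0),
        "plaid_local_max_direction_60_180": local_max_dir,
    }
    return summary, {"cells": cells, "model": model, "curves": curves}


def scenario_fig4_component(seed: int, **overrides):
    return _small_population_run(seed, cell_class="component", train_kind="plaid", **overrides)[0]


def scenario_fig4_pattern(seed: int, **overrides):
    return _small_population_run(seed, cell_class="pattern", train_kind="plaid", **overrides)[0]


def scenario_s3_grating_trained(seed: int, **overrides):
    out = {}
    for cls in ("component", "pattern"):
        out[cls] = _small_population_run(seed, cell_class=cls, train_kind="grating", **overrides)[0]
    return out


def scenario_s2_sweep(seed: int, ks=(0.5, 1.0, 3.0, 5.0, 7.0, 9.0, 11.0), **overrides):
    """Tuning-width sweep: grating/plaid curve divergence as a function of k."""
    divergences = []
    for k in ks:
        summ = _small_population_run(seed, cell_class="component", train_kind="plaid", k=k, **overrides)[0]
        divergences.append(summ["divergence"])
    return {"k": list(ks), "divergence": divergences}


# ---------------------------------------------------------------------------
# mixed 1000-cell population (pruning scenarios)


def _mixed_population(seed: int, fraction_component=0.8, component_suppression=0.5,
                      pattern_suppression=1.0, n_cells=1000):
    cfg = PopulationConfig(
        n_cells=n_cells,
        fraction_component=fraction_component,
        pref_direction_scheme="uniform_random",
        amplitude_distribution=(8.0, 1.0),
        baseline=2.0,
        trial_noise_sd=2.0,
        osi_target=(0.7, 0.1),
        dsi_target=(0.6, 0.2),
        component_plaid_suppression=component_suppression,
        pattern_plaid_suppression=pattern_suppression,
        pattern_plaid_k_divisor=4.0,
        seed=_sub_seed(seed, 11),
    )
    return sample_population(cfg), cfg


def _pruning_run(seed: int, component_suppression=0.5, n_train=200, n_cells=1000, l2_lambda=1.0):
    cells, _ = _mixed_population(seed, component_suppression=component_suppression, n_cells=n_cells)
    noise_sd = 2.0
    out = {"component_suppression": component_suppression, "n_cells": n_cells}
    for i, kind in enumerate((StimulusKind.PLAID, StimulusKind.GRATING)):
        train = training_responses(cells, kind, n_train, noise_sd, _sub_seed(seed, 21 + i))
        model = train_readout(train, TrainingConfig(kind, n_train, l2_lambda))
        heldout = training_responses(cells, kind, n_train, noise_sd, _sub_seed(seed, 31 + i))
        profile = pruning_profile(model)
        fc, fp = profile.surviving_fraction_component, profile.surviving_fraction_pattern
        reversal = None
        for q, c, p in zip(profile.quantiles, fc, fp):
            if p >= c:
                reversal = float(round(q * 100.0))
                break
        out[kind.value] = {
            "training_accuracy_pct": classification_accuracy(model, train) * 100.0,
            "heldout_accuracy_pct": classification_accuracy(model, heldout) * 100.0,
            "pruning_pct": (profile.quantiles * 100.0).tolist(),
            "fraction_component": fc,
            "fraction_pattern": fp,
            "reversal_pruning_pct": reversal,
            "weight_norm": weight_norm(model),
        }
    return out


def scenario_fig5_suppression(seed: int, **overrides):
    return _pruning_run(seed, component_suppression=overrides.pop("component_suppression", 0.5), **overrides)


def scenario_s4_control(seed: int, **overrides):
    overrides.pop("component_suppression", None)
    return _pruning_run(seed, component_suppression=1.0, **overrides)


# ---------------------------------------------------------------------------
# pattern-only homeostatic-norm scenario


def scenario_fig6_homeostatic(seed: int, pattern_suppression=0.25, n_train=200,
                              n_cells=1000, l2_lambda=1.0, n_evidence_reps=200):
    cells, _ = _mixed_population(
        seed,
        fraction_component=0.0,
        pattern_suppression=pattern_suppression,
        n_cells=n_cells,
    )
    noise_sd = 2.0
    summary = {"pattern_suppression": pattern_suppression, "n_cells": n_cells}
    models = {}
    for i, kind in enumerate((StimulusKind.GRATING, StimulusKind.PLAID)):
        stimuli = [StimulusSpec(kind, 0.0), StimulusSpec(kind, 180.0)]
        summary[f"input_norm_{kind.value}"] = input_population_norms(
            cells, stimuli, n_train, noise_sd, _sub_seed(seed, 41 + i)
        )
        train = training_responses(cells, kind, n_train, noise_sd, _sub_seed(seed, 51 + i))
        model = train_readout(train, TrainingConfig(kind, n_train, l2_lambda))
        models[kind] = model
        summary[f"weight_norm_{kind.value}_trained"] = weight_norm(model)
    summary["weight_norm_ratio_plaid_over_grating"] = (
        summary["weight_norm_plaid_trained"] / summary["weight_norm_grating_trained"]
    )
    evidence = {}
    for train_kind, model in models.items():
        for j, test_kind in enumerate((StimulusKind.GRATING, StimulusKind.PLAID)):
            curve = evidence_curve(
                model, cells, test_kind, TEST_GRID_15, noise_sd,
                n_reps=n_evidence_reps, seed=_sub_seed(seed, 61 + j),
            )
            evidence[f"{train_kind.value}_trained_{test_kind.value}_tested"] = curve.weighted_input
    summary["evidence_curves"] = evidence
    summary["evidence_directions"] = TEST_GRID_15
    summary["max_abs_evidence_grating_trained_on_plaids"] = float(
        np.max(np.abs(evidence["grating_trained_plaid_tested"]))
    )
    summary["max_abs_evidence_grating_trained_on_gratings"] = float(
        np.max(np.abs(evidence["grating_trained_grating_tested"]))
    )
    summary["max_abs_evidence_plaid_trained_on_gratings"] = float(
        np.max(np.abs(evidence["plaid_trained_grating_tested"]))
    )
    summary["max_abs_evidence_plaid_trained_on_plaids"] = float(
        np.max(np.abs(evidence["plaid_trained_plaid_tested"]))
    )
    return summary


# ---------------------------------------------------------------------------
# behavioral scenarios


def scenario_behavior_synthetic(seed: int, out_dir=None, **cohort_overrides):
    configs = default_cohort(seed=_sub_seed(seed, 71), **cohort_overrides)
    table, truth = simulate_cohort(configs)
    summary = {
        "n_animals": len(configs),
        "n_trials": len(table),
        "expected_identity_magnitude_G": float(
            np.mean([a["identity_magnitude"] for a in truth["animals"].values() if a["group"] == "G"])
        ),
        "expected_cross_magnitude_G": float(
            np.mean([a["cross_magnitude"] for a in truth["animals"].values() if a["group"] == "G"])
        ),
        "expected_identity_magnitude_P": float(
            np.mean([a["identity_magnitude"] for a in truth["animals"].values() if a["group"] == "P"])
        ),
        "expected_cross_magnitude_P": float(
            np.mean([a["cross_magnitude"] for a in truth["animals"].values() if a["group"] == "P"])
        ),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_trials(table, out_dir / "trials.csv")
        with open(out_dir / "truth.json", "w") as fh:
            json.dump(_json_ready(truth), fh, indent=1)
    return summary


def scenario_behavior_analysis(seed: int, trials=None, bootstrap_reps=50,
                               inclusion_threshold=0.05, out_dir=None):
    """Full behavioral pipeline on a trial table (path or DataFrame)."""
    if trials is None:
        raise ValueError("behavior_analysis requires a 'trials' override (CSV path or DataFrame)")
    df = trials if hasattr(trials, "columns") else read_trials(trials)
    priming = df[df["phase"] == "priming"]
    valid, report = filter_trials(priming)
    kept, excluded, magnitudes = apply_inclusion_criterion(valid, inclusion_threshold)
    summary = {
        "exclusions": report.as_dict(),
        "excluded_animals": list(excluded),
        "per_animal_identity_magnitude": {k: float(v) for k, v in magnitudes.items()},
        "groups": {},
    }
    group_mags = {}
    for i, (group, sub) in enumerate(sorted(kept.groupby("group"))):
        result = bootstrap_group_curves(
            sub, BootstrapConfig(n_reps=bootstrap_reps, seed=_sub_seed(seed, 81 + i))
        )
        summary["groups"][group] = result.summary()
        group_mags[group] = list(result.per_animal_magnitudes["identity"].values())
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            for cond, curve in result.curves.items():
                curve.to_frame().to_csv(out_dir / f"curve_{group}_{cond}.csv", index=False)
    if len(group_mags) == 2:
        (ga, va), (gb, vb) = sorted(group_mags.items())
        cmp_res = group_comparison(va, vb)
        summary["identity_magnitude_comparison"] = {
            "groups": [ga, gb],
            "t_statistic": cmp_res.t_statistic,
            "p_value": cmp_res.p_value,
            "degenerate": cmp_res.degenerate,
        }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "behavior_summary.json", "w") as fh:
            json.dump(_json_ready(summary), fh, indent=1)
    return summary


# ---------------------------------------------------------------------------
# dispatch


SCENARIOS = {
    "fig4_component": scenario_fig4_component,
    "fig4_pattern": scenario_fig4_pattern,
    "s2_sweep": scenario_s2_sweep,
    "s3_grating_trained": scenario_s3_grating_trained,
    "fig5_suppression": scenario_fig5_suppression,
    "s4_control": scenario_s4_control,
    "fig6_homeostatic": scenario_fig6_homeostatic,
    "behavior_synthetic": scenario_behavior_synthetic,
    "behavior_analysis": scenario_behavior_analysis,
}


@dataclass(frozen=True)
class ScenarioConfig:
    scenario: str
    seed: int = 0
    overrides: dict = field(default_factory=dict)
    out_dir: str | None = None

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; choose from {sorted(SCENARIOS)}")


def run_scenario(config: ScenarioConfig) -> dict:
    """Run a named scenario; write summary + manifest when out_dir is set."""
    fn = SCENARIOS[config.scenario]
    kwargs = dict(config.overrides)
    if config.scenario in ("behavior_synthetic", "behavior_analysis"):
        kwargs.setdefault("out_dir", config.out_dir)
    summary = _json_ready(fn(config.seed, **kwargs))
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {
            "scenario": config.scenario,
            "seed": config.seed,
            "overrides": _json_ready({k: v for k, v in config.overrides.items() if not hasattr(v, "columns")}),
            "package_version": __version__,
        }
        manifest["config_hash"] = hashlib.sha256(
            json.dumps(manifest, sort_keys=True).encode()
        ).hexdigest()
        with open(out / f"{config.scenario}_summary.json", "w") as fh:
            json.dump(summary, fh, indent=1)
        with open(out / f"{config.scenario}_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
    return summary
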