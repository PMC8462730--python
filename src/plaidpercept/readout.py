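"""The decision neuron: an L2-regularized logistic readout of the population.

The model mirrors a downstream neuron that weights its sensory afferents,
sums, and passes the result through a sigmoid.  Training minimizes the sum
of per-trial cross-entropies plus ``lambda/2 * ||w||^2`` (bias unpenalized)
with a quasi-Newton full-batch optimizer, so results are deterministic for
a given training set.  The L2 term doubles as the homeostatic constraint on
total synaptic strength in the norm analyses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .populations import (
    CellClass,
    CellTuning,
    ResponseMatrix,
    StimulusKind,
    StimulusSpec,
    sample_responses,
)

RIGHTWARD_DEG = 0.0
LEFTWARD_DEG = 180.0


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainingConfig:
    train_stimulus_kind: StimulusKind = StimulusKind.PLAID
    n_train_samples_per_class: int = 500
    l2_lambda: float = 1.0
    optimizer_tol: float = 1e-8
    max_iter: int = 2000
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "train_stimulus_kind", StimulusKind(self.train_stimulus_kind))
        if self.l2_lambda < 0:
            raise ValueError("l2_lambda must be nonnegative")
        if self.n_train_samples_per_class < 1:
            raise ValueError("n_train_samples_per_class must be at least 1")


@dataclass
class ReadoutModel:
    """Trained decision neuron: weight per input cell plus a bias.

    Rightward (0 deg) is the positive class: ``predict_proba`` is the
    probability that a stimulus drifts rightward.
    """

    weights: np.ndarray
    bias: float
    cell_classes: list[CellClass]
    training_config: TrainingConfig | None = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 1:
            raise ValueError("weights must be 1-d")
        if len(self.cell_classes) != self.weights.size:
            raise ValueError("one class tag per weight is required")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")

    def decision_function(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.weights + self.bias

    def predict_proba(self, X) -> np.ndarray:
        return expit(self.decision_function(X))

    def predict_rightward(self, X) -> np.ndarray:
        return self.predict_proba(X) > 0.5

    def to_json(self, path):
        cfg = None
        if self.training_config is not None:
            cfg = asdict(self.training_config)
            cfg["train_stimulus_kind"] = self.training_config.train_stimulus_kind.value
        payload = {
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "cell_classes": [c.value for c in self.cell_classes],
            "training_config": cfg,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ReadoutModel":
        with open(path) as fh:
            payload = json.load(fh)
        cfg = payload.get("training_config")
        return cls(
            weights=np.array(payload["weights"], dtype=float),
            bias=float(payload["bias"]),
            cell_classes=[CellClass(c) for c in payload["cell_classes"]],
            training_config=TrainingConfig(**cfg) if cfg else None,
        )


@dataclass
class GeneralizationCurve:
    """Fraction of test trials classified rightward per stimulus direction."""

    directions: np.ndarray
    prop_rightward: np.ndarray
    stimulus_kind: StimulusKind
    n_test_reps: int

    def __post_init__(self):
        self.directions = np.asarray(self.directions, dtype=float)
        self.prop_rightward = np.asarray(self.prop_rightward, dtype=float)
        if self.directions.shape != self.prop_rightward.shape:
            raise ValueError("directions and prop_rightward must align")
        if np.any((self.prop_rightward < 0) | (self.prop_rightward > 1)):
            raise ValueError("proportions must lie in [0, 1]")
        if np.any(np.diff(self.directions) <= 0):
            raise ValueError("direction grid must be strictly increasing")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "direction": self.directions,
                "stimulus_kind": self.stimulus_kind.value,
                "prop_rightward": self.prop_rightward,
                "n": self.n_test_reps,
            }
        )


def _cost_grad(params, X, y, lam):
    w, b = params[:-1], params[-1]
    z = X @ w + b
    s = 2.0 * y - 1.0
    cost = np.logaddexp(0.0, -s * z).sum() + 0.5 * lam * w @ w
    p = expit(z)
    gw = X.T @ (p - y) + lam * w
    gb = (p - y).sum()
    return cost, np.append(gw, gb)


def train_readout(responses: ResponseMatrix, config: TrainingConfig) -> ReadoutModel:
    """Fit the logistic decision neuron on 0-vs-180 degree responses.

    Requires a balanced two-class training set labeled by stimulus
    direction (0 deg = rightward = positive class).  Raises
    :class:`ConvergenceError` if the gradient norm at the optimum exceeds
    the configured tolerance (relative to the cost scale).
    """
    dirs = np.array([s.direction for s in responses.stimuli])
    present = set(np.unique(dirs))
    if present != {RIGHTWARD_DEG, LEFTWARD_DEG}:
        raise ValueError(f"training stimuli must be exactly {{0, 180}} deg, got {sorted(present)}")
    y = (dirs == RIGHTWARD_DEG).astype(float)
    if y.sum() * 2 != y.size:
        raise ValueError("training classes must be balanced")

    X = responses.values
    lam = config.l2_lambda
    x0 = np.zeros(X.shape[1] + 1)
    res = minimize(
        _cost_grad,
        x0,
        args=(X, y, lam),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": config.max_iter, "gtol": config.optimizer_tol, "ftol": 1e-14},
    )
    gnorm = float(np.max(np.abs(res.jac)))
    # scale-aware check: the optimizer may stop on ftol with gradient still
    # tiny relative to the cost surface
    if gnorm > max(config.optimizer_tol, 1e-6 * max(1.0, abs(res.fun))):
        raise ConvergenceError(
            f"readout training did not converge: grad_inf={gnorm:.3g}, "
            f"cost={res.fun:.6g}, iters={res.nit}, message={res.message}"
        )
    return ReadoutModel(
        weights=res.x[:-1],
        bias=float(res.x[-1]),
        cell_classes=list(responses.cell_classes),
        training_config=config,
    )


def training_responses(
    cells: list[CellTuning],
    kind: StimulusKind,
    n_per_class: int,
    noise_sd: float,
    seed: int,
    cross_angle: float = 120.0,
) -> ResponseMatrix:
    """Noisy responses to the two training stimuli (0 and 180 deg)."""
    stimuli = [
        StimulusSpec(kind, RIGHTWARD_DEG, cross_angle),
        StimulusSpec(kind, LEFTWARD_DEG, cross_angle),
    ]
    return sample_responses(cells, stimuli, n_per_class, noise_sd, seed)


def classification_accuracy(model: ReadoutModel, responses: ResponseMatrix) -> float:
    """Fraction of trials whose hard classification matches the stimulus."""
    y = np.array([s.direction == RIGHTWARD_DEG for s in responses.stimuli])
    return float(np.mean(model.predict_rightward(responses.values) == y))


def generalization_curve(
    model: ReadoutModel,
    cells: list[CellTuning],
    stimulus_kind: StimulusKind,
    direction_grid,
    n_test_reps: int = 500,
    noise_sd: float = 0.25,
    seed: int = 0,
    cross_angle: float = 120.0,
) -> GeneralizationCurve:
    """Fraction classified rightward per direction, over noisy test trials."""
    direction_grid = np.asarray(direction_grid, dtype=float)
    if direction_grid.size == 0:
        raise ValueError("direction grid must be non-empty")
    if len(cells) != model.weights.size:
        raise ValueError("model and population sizes differ")
    stimuli = [StimulusSpec(stimulus_kind, d, cross_angle) for d in direction_grid]
    resp = sample_responses(cells, stimuli, n_test_reps, noise_sd, seed)
    hard = model.predict_rightward(resp.values)
    props = hard.reshape(len(stimuli), n_test_reps).mean(axis=1)
    return GeneralizationCurve(direction_grid, props, StimulusKind(stimulus_kind), n_test_reps)


def curve_divergence(curve_a: GeneralizationCurve, curve_b: GeneralizationCurve) -> float:
    """Mean absolute difference between two curves on the same grid."""
    if not np.array_equal(curve_a.directions, curve_b.directions):
        raise ValueError("curves must share the same direction grid")
    return float(np.mean(np.abs(curve_a.prop_rightward - curve_b.prop_rightward)))
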