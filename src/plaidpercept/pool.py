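"""Decoding-pool pruning and homeostatic input/weight-norm analyses.

Pruning models a sparsity constraint on the decision neuron's connectivity:
weights with the smallest magnitudes are zeroed, and the class composition
of the surviving pool (the cells with nonzero influence) is tracked as the
constraint tightens.  The norm analyses quantify how L2 regularization
re-scales the learned weights when cross-orientation suppression weakens
the input population vectors for one stimulus kind.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .populations import (
    CellClass,
    CellTuning,
    StimulusKind,
    StimulusSpec,
    sample_responses,
)
from .readout import ReadoutModel


@dataclass
class PruningProfile:
    quantiles: np.ndarray
    surviving_fraction_component: np.ndarray
    surviving_fraction_pattern: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "quantile": self.quantiles,
                "fraction_component": self.surviving_fraction_component,
                "fraction_pattern": self.surviving_fraction_pattern,
            }
        )


@dataclass
class EvidenceCurve:
    """Mean pre-sigmoid activation (weights . response + bias) per direction."""

    directions: np.ndarray
    weighted_input: np.ndarray
    train_kind: StimulusKind
    test_kind: StimulusKind

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "direction": self.directions,
                "weighted_input": self.weighted_input,
                "train_kind": self.train_kind.value,
                "test_kind": self.test_kind.value,
            }
        )


def prune_by_quantile(model: ReadoutModel, quantile: float) -> ReadoutModel:
    """Zero the weights below the given magnitude quantile.

    Rank-based: the floor(q * n) smallest |w| are zeroed (stable sort, so
    among exact ties the earlier index is pruned first), which pins the
    survivor count at ceil((1 - q) * n) and coincides with thresholding at
    the empirical quantile for untied weights.
    """
    if not (0.0 <= quantile < 1.0):
        raise ValueError("quantile must lie in [0, 1)")
    w = model.weights.copy()
    n_prune = int(np.floor(quantile * w.size))
    if n_prune:
        order = np.argsort(np.abs(w), kind="stable")
        w[order[:n_prune]] = 0.0
    return ReadoutModel(
        weights=w,
        bias=model.bias,
        cell_classes=list(model.cell_classes),
        training_config=model.training_config,
    )


def class_fractions(model: ReadoutModel) -> tuple[float, float]:
    """(fraction_component, fraction_pattern) among nonzero-weight inputs."""
    alive = model.weights != 0.0
    n_alive = int(alive.sum())
    if n_alive == 0:
        raise ValueError("decoding pool is empty: all weights are zero")
    classes = np.array([c is CellClass.COMPONENT for c in model.cell_classes])
    n_comp = int(np.count_nonzero(classes & alive))
    return n_comp / n_alive, (n_alive - n_comp) / n_alive


def pruning_profile(model: ReadoutModel, quantiles=None) -> PruningProfile:
    """Surviving class fractions across a grid of pruning quantiles."""
    if quantiles is None:
        quantiles = np.arange(0.0, 0.91, 0.1)
    quantiles = np.asarray(quantiles, dtype=float)
    comp, patt = [], []
    for q in quantiles:
        fc, fp = class_fractions(prune_by_quantile(model, q))
        comp.append(fc)
        patt.append(fp)
    return PruningProfile(quantiles, np.array(comp), np.array(patt))


def input_population_norms(
    cells: list[CellTuning],
    stimuli: list[StimulusSpec],
    n_reps: int,
    noise_sd: float,
    seed: int,
) -> float:
    """Mean Euclidean norm of the population response vectors to ``stimuli``."""
    if not cells:
        raise ValueError("population must be non-empty")
    resp = sample_responses(cells, stimuli, n_reps, noise_sd, seed)
    return float(np.mean(np.linalg.norm(resp.values, axis=1)))


def evidence_curve(
    model: ReadoutModel,
    cells: list[CellTuning],
    test_kind: StimulusKind,
    direction_grid,
    noise_sd: float,
    n_reps: int = 200,
    seed: int = 0,
    cross_angle: float = 120.0,
) -> EvidenceCurve:
    """Trial-mean weighted input to the decision neuron per test direction."""
    if len(cells) != model.weights.size:
        raise ValueError("model and population sizes differ")
    direction_grid = np.asarray(direction_grid, dtype=float)
    stimuli = [StimulusSpec(test_kind, d, cross_angle) for d in direction_grid]
    resp = sample_responses(cells, stimuli, n_reps, noise_sd, seed)
    logits = model.decision_function(resp.values)
    mean_logits = logits.reshape(len(stimuli), n_reps).mean(axis=1)
    train_kind = (
        model.training_config.train_stimulus_kind
        if model.training_config is not None
        else StimulusKind(test_kind)
    )
    return EvidenceCurve(direction_grid, mean_logits, train_kind, StimulusKind(test_kind))


def weight_norm(model: ReadoutModel) -> float:
    """L2 norm of the weight vector, bias excluded."""
    return float(np.linalg.norm(model.weights))
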