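"""Simulated direction-tuned populations of component and pattern cells.

Tuning curves are Von Mises functions of stimulus direction,
``f(theta) = baseline + A * exp(k * (cos(theta - pref) - 1))``,
normalized so the peak equals the amplitude ``A`` regardless of the
concentration ``k`` (FWHM = 2*arccos(1 - ln2/k)).  A *component* cell
responds to the local direction of each constituent grating of a plaid, so
its plaid tuning is the superimposed pair of lobes separated by the plaid
cross-angle.  A *pattern* cell responds to the global direction and (by
construction) has identical grating and plaid tuning, optionally broadened
(``plaid_k_divisor``) and suppressed (``plaid_suppression``) to emulate
imperfect cross-angle invariance and cross-orientation suppression.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq


class StimulusKind(str, enum.Enum):
    GRATING = "grating"
    PLAID = "plaid"


class CellClass(str, enum.Enum):
    COMPONENT = "component"
    PATTERN = "pattern"


class CalibrationError(ValueError):
    """Raised when an OSI/DSI target is unattainable.

    Carries ``max_achievable``, the largest index value the cell geometry
    permits for the infeasible target.
    """

    def __init__(self, message: str, max_achievable: float):
        super().__init__(message)
        self.max_achievable = max_achievable


@dataclass(frozen=True)
class StimulusSpec:
    """A drifting grating or plaid, identified by its global direction.

    ``direction`` is in degrees, normalized to [0, 360).  ``cross_angle``
    (degrees, in (0, 180]) is the separation between the two constituent
    gratings' drift directions and is ignored for gratings.
    """

    kind: StimulusKind
    direction: float
    cross_angle: float = 120.0

    def __post_init__(self):
        object.__setattr__(self, "kind", StimulusKind(self.kind))
        object.__setattr__(self, "direction", float(self.direction) % 360.0)
        if not (0.0 < self.cross_angle <= 180.0):
            raise ValueError(f"cross_angle must lie in (0, 180], got {self.cross_angle}")


@dataclass(frozen=True)
class CellTuning:
    """Direction-tuning parameterization of one simulated neuron.

    ``anti_pref_amplitude`` adds a secondary lobe at pref+180 deg used to
    set the direction selectivity index independently of the tuning width.
    """

    cell_class: CellClass
    pref_direction: float
    k: float
    amplitude: float = 1.0
    baseline: float = 0.0
    anti_pref_amplitude: float = 0.0
    plaid_k_divisor: float = 1.0
    plaid_suppression: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "cell_class", CellClass(self.cell_class))
        object.__setattr__(self, "pref_direction", float(self.pref_direction) % 360.0)
        if not self.k > 0:
            raise ValueError(f"concentration k must be positive, got {self.k}")
        if self.amplitude < 0 or self.baseline < 0:
            raise ValueError("amplitude and baseline must be nonnegative")
        if not (0.0 <= self.plaid_suppression <= 1.0):
            raise ValueError("plaid_suppression must lie in [0, 1]")
        if not (0.0 <= self.anti_pref_amplitude <= self.amplitude):
            raise ValueError("anti_pref_amplitude must lie in [0, amplitude]")
        if self.plaid_k_divisor <= 0:
            raise ValueError("plaid_k_divisor must be positive")


@dataclass(frozen=True)
class PopulationConfig:
    """Recipe for sampling a population of :class:`CellTuning`.

    Either a fixed concentration ``k`` is given (all cells identical width,
    as in the 24-cell equispaced simulations) or per-cell widths are
    calibrated so the population OSI/DSI follow the target Gaussians
    ``osi_target``/``dsi_target`` (mean, sd).  Amplitudes are either the
    fixed ``amplitude`` or drawn from ``amplitude_distribution`` (mean, sd)
    truncated at zero.
    """

    n_cells: int
    fraction_component: float = 1.0
    pref_direction_scheme: str = "equispaced"  # or "uniform_random"
    k: float | None = None
    amplitude: float = 1.0
    amplitude_distribution: tuple[float, float] | None = None
    baseline: float = 0.0
    trial_noise_sd: float = 0.25
    osi_target: tuple[float, float] | None = None
    dsi_target: tuple[float, float] | None = None
    component_plaid_suppression: float = 1.0
    pattern_plaid_suppression: float = 1.0
    pattern_plaid_k_divisor: float = 1.0
    selectivity_method: str = "vector"
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 2:
            raise ValueError("n_cells must be at least 2")
        if not (0.0 <= self.fraction_component <= 1.0):
            raise ValueError("fraction_component must lie in [0, 1]")
        if self.trial_noise_sd < 0:
            raise ValueError("trial_noise_sd must be nonnegative")
        if self.pref_direction_scheme not in ("equispaced", "uniform_random"):
            raise ValueError(f"unknown scheme {self.pref_direction_scheme!r}")
        if self.k is None and self.osi_target is None:
            raise ValueError("either a fixed k or an osi_target must be given")


@dataclass
class ResponseMatrix:
    """Trials x cells array of (possibly noisy) responses."""

    values: np.ndarray
    stimuli: list[StimulusSpec]
    cell_classes: list[CellClass]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-d trials x cells array")
        if len(self.stimuli) != self.values.shape[0]:
            raise ValueError("one stimulus label per trial is required")
        if len(self.cell_classes) != self.values.shape[1]:
            raise ValueError("one class tag per cell is required")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def to_frame(self):
        """Long-format DataFrame (trial, cell, stimulus_kind, direction, value)."""
        import pandas as pd

        n_t, n_c = self.values.shape
        return pd.DataFrame(
            {
                "trial": np.repeat(np.arange(n_t), n_c),
                "cell": np.tile(np.arange(n_c), n_t),
                "stimulus_kind": np.repeat([s.kind.value for s in self.stimuli], n_c),
                "direction": np.repeat([s.direction for s in self.stimuli], n_c),
                "value": self.values.ravel(),
            }
        )


# ---------------------------------------------------------------------------
# tuning functions


def _lobe(delta_deg, k):
    """Peak-normalized Von Mises lobe exp(k*(cos(delta) - 1))."""
    return np.exp(k * (np.cos(np.deg2rad(delta_deg)) - 1.0))


def _evoked_grating(cell: CellTuning, direction, k=None):
    k = cell.k if k is None else k
    d = np.asarray(direction, dtype=float) - cell.pref_direction
    return cell.amplitude * _lobe(d, k) + cell.anti_pref_amplitude * _lobe(d - 180.0, k)


def grating_tuning(cell: CellTuning, direction):
    """Noise-free response of ``cell`` to a grating drifting at ``direction``."""
    return cell.baseline + _evoked_grating(cell, direction)


def plaid_tuning(cell: CellTuning, stimulus: StimulusSpec):
    """Noise-free response of ``cell`` to a drifting plaid.

    Component cells see the two constituent gratings (lobes at the global
    direction +/- half the cross-angle); pattern cells see the global
    direction, with their grating tuning broadened by ``plaid_k_divisor``.
    Cross-orientation suppression scales the above-baseline response.
    """
    if StimulusKind(stimulus.kind) is not StimulusKind.PLAID:
        raise ValueError("plaid_tuning requires a plaid stimulus")
    d = stimulus.direction
    half = stimulus.cross_angle / 2.0
    if cell.cell_class is CellClass.COMPONENT:
        evoked = _evoked_grating(cell, d - half) + _evoked_grating(cell, d + half)
        s = cell.plaid_suppression
    else:
        evoked = _evoked_grating(cell, d, k=cell.k / cell.plaid_k_divisor)
        s = cell.plaid_suppression
    return cell.baseline + s * evoked


def response(cell: CellTuning, stimulus: StimulusSpec):
    """Noise-free response to either stimulus kind."""
    if StimulusKind(stimulus.kind) is StimulusKind.GRATING:
        return grating_tuning(cell, stimulus.direction)
    return plaid_tuning(cell, stimulus)


def von_mises_fwhm(k: float) -> float:
    """Closed-form FWHM (degrees) of a zero-baseline Von Mises lobe.

    Valid for k > ln2/2 (narrower than the full circle); returns 360 for
    flatter lobes that never fall below half the peak.
    """
    c = 1.0 - math.log(2.0) / k
    if c <= -1.0:
        return 360.0
    return 2.0 * math.degrees(math.acos(c))


def measure_fwhm(k: float, n_grid: int = 720001) -> float:
    """FWHM of exp(k*(cos(theta)-1)) measured numerically on a fine grid.

    Independent of :func:`von_mises_fwhm`: locates the half-maximum crossing
    by bisection on the sampled curve.
    """
    theta = np.linspace(0.0, 180.0, n_grid)
    f = _lobe(theta, k)
    above = f >= 0.5
    if above.all():
        return 360.0
    idx = int(np.argmin(above))  # first sample below half max
    lo, hi = theta[idx - 1], theta[idx]
    half_width = brentq(lambda t: _lobe(t, k) - 0.5, lo, hi, xtol=1e-10)
    return 2.0 * half_width


# ---------------------------------------------------------------------------
# selectivity indices and width calibration


def compute_osi_dsi(cell: CellTuning, method: str = "ratio") -> tuple[float, float]:
    """Orientation and direction selectivity indices of the grating tuning.

    Both forms are standard in the rodent visual cortex literature and are
    computed on the evoked (above-baseline) noise-free tuning:

    - ``"ratio"``: OSI = (R_pref - R_orth) / (R_pref + R_orth) with R_orth
      the mean evoked response at pref +/- 90 deg; DSI likewise with R_null
      at pref + 180 deg.
    - ``"vector"``: global indices from the normalized Fourier moments of
      the full tuning curve (1 - circular variance at the second and first
      harmonic, respectively); these characterize the whole curve rather
      than three sample points and sit lower than the ratio form at equal
      tuning width.

    A flat but active cell (amplitude 0, baseline > 0) has OSI = DSI = 0;
    a cell with zero total response has undefined indices.
    """
    p = cell.pref_direction
    if cell.amplitude + cell.anti_pref_amplitude == 0.0:
        if cell.baseline > 0:
            return 0.0, 0.0
        raise ValueError("zero total response: selectivity indices undefined")
    if method == "ratio":
        r_pref = float(_evoked_grating(cell, p))
        r_orth = float(_evoked_grating(cell, p + 90.0) + _evoked_grating(cell, p - 90.0)) / 2.0
        r_null = float(_evoked_grating(cell, p + 180.0))
        osi = (r_pref - r_orth) / (r_pref + r_orth)
        dsi = (r_pref - r_null) / (r_pref + r_null)
        return osi, dsi
    if method == "vector":
        theta = np.arange(0.0, 360.0, 1.0)
        f = _evoked_grating(cell, theta)
        rad = np.deg2rad(theta)
        total = f.sum()
        osi = float(np.abs((f * np.exp(2j * rad)).sum()) / total)
        dsi = float(np.abs((f * np.exp(1j * rad)).sum()) / total)
        return osi, dsi
    raise ValueError(f"unknown selectivity method {method!r}")


def _anti_ratio_for_dsi(k: float, dsi: float) -> float:
    """Anti-preferred amplitude ratio r = A_anti/A giving the target DSI at k.

    From the evoked responses R_pref = A(1 + r*E), R_null = A(E + r) with
    E = exp(-2k): solving (R_pref - R_null)/(R_pref + R_null) = dsi gives a
    closed form; negative r signals an unattainable target at this k.
    """
    e = math.exp(-2.0 * k)
    num = (1.0 - e) - dsi * (1.0 + e)
    den = (1.0 - e) + dsi * (1.0 + e)
    return num / den


def _osi_at(k: float, r: float) -> float:
    e2 = math.exp(-2.0 * k)
    e1 = math.exp(-k)
    r_pref = 1.0 + r * e2
    r_orth = (1.0 + r) * e1
    return (r_pref - r_orth) / (r_pref + r_orth)


_K_MAX = 60.0
_K_MAX_VECTOR = 500.0


def _calibrate_ratio(osi_target, dsi_target, tol, clamp):
    def osi_err(k):
        r = max(_anti_ratio_for_dsi(k, dsi_target), 0.0)
        return _osi_at(k, r) - osi_target

    lo, hi = 1e-8, _K_MAX
    if osi_err(hi) < 0.0:
        max_osi = _osi_at(hi, max(_anti_ratio_for_dsi(hi, dsi_target), 0.0))
        if not clamp:
            raise CalibrationError(
                f"osi_target {osi_target} unattainable (max {max_osi:.4f})", max_osi
            )
        k = hi
    else:
        k = brentq(osi_err, lo, hi, xtol=tol)
    r = _anti_ratio_for_dsi(k, dsi_target)
    if r < 0.0:
        e = math.exp(-2.0 * k)
        max_dsi = (1.0 - e) / (1.0 + e)
        if not clamp:
            raise CalibrationError(
                f"dsi_target {dsi_target} unattainable at k={k:.3f} (max {max_dsi:.4f})",
                max_dsi,
            )
        r = 0.0
    return k, r


def _calibrate_vector(osi_target, dsi_target, tol, clamp):
    from scipy.special import ive

    # for the lobe + anti-lobe tuning, the second-harmonic moment is
    # I2(k)/I0(k) independent of the anti-lobe ratio r, and the first
    # harmonic is (1-r)/(1+r) * I1(k)/I0(k): k and r decouple.
    def osi_err(k):
        return ive(2, k) / ive(0, k) - osi_target

    lo, hi = 1e-8, _K_MAX_VECTOR
    if osi_err(hi) < 0.0:
        max_osi = float(ive(2, hi) / ive(0, hi))
        if not clamp:
            raise CalibrationError(
                f"osi_target {osi_target} unattainable (max {max_osi:.4f})", max_osi
            )
        k = hi
    else:
        k = brentq(osi_err, lo, hi, xtol=tol)
    r1 = float(ive(1, k) / ive(0, k))
    if dsi_target > r1:
        if not clamp:
            raise CalibrationError(
                f"dsi_target {dsi_target} unattainable at k={k:.3f} (max {r1:.4f})", r1
            )
        return k, 0.0
    r = (r1 - dsi_target) / (r1 + dsi_target)
    return k, r


def calibrate_k(
    osi_target: float,
    dsi_target: float,
    amplitude: float = 1.0,
    baseline: float = 0.0,
    tol: float = 1e-6,
    clamp: bool = False,
    method: str = "vector",
) -> tuple[float, float]:
    """Solve for (k, anti_pref_amplitude) hitting the OSI and DSI targets.

    The anti-preferred lobe ratio follows in closed form from the DSI
    target; the concentration k is found by bisection on the resulting OSI
    (monotone in k).  ``method`` selects the index definition (see
    :func:`compute_osi_dsi`); the round trip
    ``compute_osi_dsi(calibrate_k(o, d, method=m), method=m) == (o, d)``
    holds for both.  The indices are invariant to amplitude/baseline
    scaling; ``amplitude`` only sets the returned lobe amplitude's units.
    With ``clamp=True``, unattainable targets are replaced by the closest
    achievable value instead of raising :class:`CalibrationError`.
    """
    if not (0.0 < osi_target < 1.0):
        raise ValueError("osi_target must lie in (0, 1)")
    if not (0.0 <= dsi_target < 1.0):
        raise ValueError("dsi_target must lie in [0, 1)")
    if method == "ratio":
        k, r = _calibrate_ratio(osi_target, dsi_target, tol, clamp)
    elif method == "vector":
        k, r = _calibrate_vector(osi_target, dsi_target, tol, clamp)
    else:
        raise ValueError(f"unknown selectivity method {method!r}")
    return k, r * amplitude


# ---------------------------------------------------------------------------
# sampling


def sample_population(config: PopulationConfig) -> list[CellTuning]:
    """Draw a seeded population of cells according to ``config``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    n_comp = int(round(config.fraction_component * n))

    if config.pref_direction_scheme == "equispaced":
        prefs = np.arange(n) * (360.0 / n)
    else:
        prefs = rng.uniform(0.0, 360.0, size=n)

    if config.amplitude_distribution is not None:
        mu, sd = config.amplitude_distribution
        amps = np.clip(rng.normal(mu, sd, size=n), 0.0, None)
    else:
        amps = np.full(n, config.amplitude)

    if config.k is not None:
        ks = np.full(n, float(config.k))
        antis = np.zeros(n)
    else:
        o_mu, o_sd = config.osi_target
        d_mu, d_sd = config.dsi_target if config.dsi_target is not None else (0.9, 0.0)
        osis = np.clip(rng.normal(o_mu, o_sd, size=n), 0.01, 0.99)
        dsis = np.clip(rng.normal(d_mu, d_sd, size=n), 0.0, 0.99)
        ks = np.empty(n)
        antis = np.empty(n)
        for i in range(n):
            ks[i], ratio_amp = calibrate_k(
                osis[i], dsis[i], amplitude=1.0, clamp=True, method=config.selectivity_method
            )
            antis[i] = ratio_amp  # ratio; scaled by per-cell amplitude below

    cells = []
    for i in range(n):
        cls = CellClass.COMPONENT if i < n_comp else CellClass.PATTERN
        if cls is CellClass.COMPONENT:
            suppression, divisor = config.component_plaid_suppression, 1.0
        else:
            suppression = config.pattern_plaid_suppression
            divisor = config.pattern_plaid_k_divisor
        cells.append(
            CellTuning(
                cell_class=cls,
                pref_direction=prefs[i],
                k=ks[i],
                amplitude=amps[i],
                baseline=config.baseline,
                anti_pref_amplitude=antis[i] * amps[i],
                plaid_suppression=suppression,
                plaid_k_divisor=divisor,
            )
        )
    return cells


def tuning_matrix(cells: list[CellTuning], stimuli: list[StimulusSpec]) -> np.ndarray:
    """Noise-free stimuli x cells response matrix."""
    return np.array([[response(c, s) for c in cells] for s in stimuli], dtype=float)


def sample_responses(
    cells: list[CellTuning],
    stimuli: list[StimulusSpec],
    n_reps: int,
    noise_sd: float,
    seed: int,
    noise: str = "gaussian",
    clip_negative: bool = False,
) -> ResponseMatrix:
    """Sample ``n_reps`` noisy population responses per stimulus.

    Trials are stimulus-major: the first ``n_reps`` rows belong to
    ``stimuli[0]``.  Gaussian noise (the default) leaves negative samples
    untruncated unless ``clip_negative``; ``noise="poisson"`` draws spike
    counts with the tuning value as the rate (clipped at zero).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    means = tuning_matrix(cells, stimuli)
    tiled = np.repeat(means, n_reps, axis=0)
    if noise == "gaussian":
        values = tiled + rng.normal(0.0, noise_sd, size=tiled.shape) if noise_sd > 0 else tiled.copy()
    elif noise == "poisson":
        values = rng.poisson(np.clip(tiled, 0.0, None)).astype(float)
    else:
        raise ValueError(f"unknown noise model {noise!r}")
    if clip_negative:
        np.clip(values, 0.0, None, out=values)
    trial_stimuli = [s for s in stimuli for _ in range(n_reps)]
    return ResponseMatrix(values, trial_stimuli, [c.cell_class for c in cells])


# ---------------------------------------------------------------------------
# serialization

_CELL_FIELDS = [
    "cell_class",
    "pref_direction",
    "k",
    "amplitude",
    "baseline",
    "anti_pref_amplitude",
    "plaid_k_divisor",
    "plaid_suppression",
]


def cells_to_frame(cells: list[CellTuning]):
    import pandas as pd

    return pd.DataFrame(
        [
            {f: (getattr(c, f).value if f == "cell_class" else getattr(c, f)) for f in _CELL_FIELDS}
            for c in cells
        ]
    )


def cells_from_frame(df) -> list[CellTuning]:
    return [CellTuning(**{f: row[f] for f in _CELL_FIELDS}) for _, row in df.iterrows()]
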