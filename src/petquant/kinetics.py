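"""One- and two-tissue compartment models with fixed fractional blood volume.

The measured PET concentration is modelled as

    C_model(t) = (1 - vB) * C_tissue(t) + vB * C_wholeblood(t)

with vB fixed (5% by default, following standard practice for this tracer
class) and ``C_tissue`` the convolution of the metabolite-corrected
parent-plasma input with the model impulse response:

    1TCM:  h(t) = K1 * exp(-k2 t)
    2TCM:  h(t) = K1/(a1 - a2) * [(k3 + k4 - a2) e^{-a2 t} + (a1 - k3 - k4) e^{-a1 t}]

where a1/a2 are the eigen-rates of the two-tissue system.  The convolution
is evaluated analytically against the closed-form fitted input
(:meth:`petquant.input_function.InputFunction.convolve_exp`), so the forward
model is exact on the non-uniform frame grid.

Rate constants are per minute (K1 in mL/cm3/min), times in seconds
internally.  The total distribution volume is ``VT = K1/k2`` (1TCM) or
``VT = K1/k2 * (1 + k3/k4)`` (2TCM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .errors import DegenerateInputError, FitError, ValidationError
from .input_function import InputFunction
from .tac import FrameSchedule, TimeActivityCurve


@dataclass
class CompartmentParams:
    """Micro-parameters of a 1TCM or 2TCM, per-minute rates."""

    model: str  # "1tcm" | "2tcm"
    k1: float  # mL/cm3/min
    k2: float  # 1/min
    k3: float | None = None  # 1/min (2TCM)
    k4: float | None = None  # 1/min (2TCM)
    vb: float = 0.05

    def __post_init__(self):
        if self.model not in ("1tcm", "2tcm"):
            raise ValidationError(f"unknown model {self.model!r}")
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValidationError("K1 and k2 must be positive")
        if not 0 <= self.vb <= 1:
            raise ValidationError("vB must lie in [0, 1]")
        if self.model == "2tcm":
            if self.k3 is None or self.k4 is None:
                raise ValidationError("2TCM requires k3 and k4")
            if self.k3 < 0:
                raise ValidationError("k3 must be >= 0")
            if self.k4 <= 0:
                if self.k3 > 0:
                    raise ValidationError(
                        "k4 = 0 with k3 > 0 is an irreversible model (unsupported)"
                    )
                raise ValidationError("k4 must be positive")

    @property
    def vt(self) -> float:
        return vt_from_params(self)


def vt_from_params(params: CompartmentParams) -> float:
    """Total distribution volume from micro-parameters."""
    if params.k2 == 0:
        raise ValidationError("VT undefined for k2 = 0")
    if params.model == "1tcm":
        return params.k1 / params.k2
    if params.k4 == 0:
        raise ValidationError("VT undefined for k4 = 0")
    return params.k1 / params.k2 * (1.0 + params.k3 / params.k4)


def _impulse_terms(params: CompartmentParams) -> tuple[np.ndarray, np.ndarray]:
    """(weights, rates) of the tissue impulse response, per-minute units."""
    if params.model == "1tcm":
        return np.array([params.k1]), np.array([params.k2])
    k2, k3, k4 = params.k2, params.k3, params.k4
    s = k2 + k3 + k4
    disc = np.sqrt(max(s * s - 4.0 * k2 * k4, 0.0))
    a1 = (s + disc) / 2.0
    a2 = (s - disc) / 2.0
    if disc < 1e-12:  # coincident eigen-rates: nudge apart (measure-zero case)
        a1 += 5e-13
        a2 -= 5e-13
        disc = a1 - a2
    w1 = params.k1 * (a1 - k3 - k4) / disc
    w2 = params.k1 * (k3 + k4 - a2) / disc
    return np.array([w1, w2]), np.array([a1, a2])


def simulate_tissue(
    params: CompartmentParams,
    input_function: InputFunction,
    schedule: FrameSchedule,
) -> TimeActivityCurve:
    """Forward model evaluated at the frame midpoints.

    Returns the blood-volume-corrected model TAC
    ``(1 - vB) * C_tissue + vB * C_wholeblood`` in the input's concentration
    units, decay-corrected by convention.
    """
    t = schedule.midpoints
    weights, rates = _impulse_terms(params)
    tissue = np.zeros_like(t)
    for w, a in zip(weights, rates):
        # per-minute -> per-second: theta_s = w/60, alpha_s = a/60
        tissue += (w / 60.0) * input_function.convolve_exp(a / 60.0, t)
    blood = input_function.value(t, "whole_blood")
    activity = (1.0 - params.vb) * tissue + params.vb * blood
    return TimeActivityCurve(schedule, activity, label=f"sim:{params.model}")


def aic(rss: float, n_frames: int, n_free: int) -> float:
    """Akaike information criterion ``n ln(rss/n) + 2k`` for LS fits."""
    if n_frames <= n_free:
        raise ValidationError("need more frames than free parameters")
    if rss < 0:
        raise ValidationError("rss must be non-negative")
    if rss == 0:
        warnings.warn("rss = 0: AIC is -inf", stacklevel=2)
        return -np.inf
    return n_frames * np.log(rss / n_frames) + 2.0 * n_free


@dataclass
class CompartmentFit:
    """Result of a compartment-model fit."""

    params: CompartmentParams
    rss: float
    n_frames: int
    n_free: int
    aic: float
    vt: float
    fitted: np.ndarray


_STARTS = {
    "1tcm": [(0.3, 0.1), (0.1, 0.02), (0.8, 0.3)],
    "2tcm": [
        (0.3, 0.15, 0.05, 0.02),
        (0.1, 0.05, 0.02, 0.005),
        (0.6, 0.3, 0.1, 0.05),
    ],
}


def fit_compartment(
    tac: TimeActivityCurve,
    input_function: InputFunction,
    model: str = "2tcm",
    vb: float = 0.05,
    weights=None,
    n_starts: int = 3,
    random_state: int = 0,
    min_frames: int = 10,
) -> CompartmentFit:
    """Bounded weighted least-squares fit of a 1TCM or 2TCM.

    Bounds are K1 in (0, 2] mL/cm3/min and k2..k4 in (0, 1] 1/min; vB is
    fixed.  ``weights`` may be ``None`` (uniform), ``"duration"``
    (frame-duration weights) or an explicit array.  Multi-start with
    ``n_starts`` dispersed starting points (seed-jittered beyond the built-in
    list) guards against local minima.
    """
    if model not in ("1tcm", "2tcm"):
        raise ValidationError(f"unknown model {model!r}")
    y = tac.activity
    if tac.schedule.n_frames < min_frames:
        raise ValidationError(f"need >= {min_frames} frames, got {tac.schedule.n_frames}")
    if not np.any(y > 0):
        raise DegenerateInputError("degenerate TAC: no positive activity")
    if weights is None:
        w = np.ones_like(y)
    elif isinstance(weights, str) and weights == "duration":
        w = tac.schedule.durations / tac.schedule.durations.mean()
    else:
        w = np.asarray(weights, dtype=float)
    sw = np.sqrt(w)

    n_free = 2 if model == "1tcm" else 4
    lower = np.full(n_free, 1e-6)
    upper = np.array([2.0] + [1.0] * (n_free - 1))

    def make_params(x) -> CompartmentParams:
        if model == "1tcm":
            return CompartmentParams("1tcm", x[0], x[1], vb=vb)
        return CompartmentParams("2tcm", x[0], x[1], x[2], x[3], vb=vb)

    schedule = tac.schedule

    def residual(x):
        sim = simulate_tissue(make_params(x), input_function, schedule)
        return sw * (sim.activity - y)

    rng = np.random.default_rng(random_state)
    starts = [np.asarray(s, dtype=float) for s in _STARTS[model]]
    while len(starts) < n_starts:
        starts.append(starts[0] * np.exp(rng.normal(0.0, 0.7, size=n_free)))
    best = None
    failures = []
    for x0 in starts[:n_starts]:
        x0 = np.clip(x0, lower * 1.01, upper * 0.99)
        try:
            res = least_squares(
                residual,
                x0,
                bounds=(lower, upper),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                max_nfev=2000,
            )
        except Exception as exc:  # pragma: no cover - defensive
            failures.append(str(exc))
            continue
        if res.status > 0 and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FitError(f"all {model} starts failed: {failures}", best=failures)
    params = make_params(best.x)
    rss = float(2 * best.cost)
    score = aic(rss, schedule.n_frames, n_free) if rss > 0 else -np.inf
    fitted = simulate_tissue(params, input_function, schedule).activity
    return CompartmentFit(
        params=params,
        rss=rss,
        n_frames=schedule.n_frames,
        n_free=n_free,
        aic=score,
        vt=params.vt,
        fitted=fitted,
    )


@dataclass
class ModelSelection:
    selected: str
    delta_aic: float  # AIC(2TCM) - AIC(1TCM); negative favours 2TCM


def select_model(fit_1tcm: CompartmentFit, fit_2tcm: CompartmentFit) -> ModelSelection:
    """AIC model selection; ties resolve to the more parsimonious 1TCM."""
    delta = fit_2tcm.aic - fit_1tcm.aic
    return ModelSelection("2tcm" if delta < 0 else "1tcm", float(delta))


class CompartmentModel(BaseEstimator):
    """Scikit-learn style estimator wrapping :func:`fit_compartment`.

    Parameters
    ----------
    model : {"1tcm", "2tcm"}
    vb : float
        Fixed fractional blood volume.
    weights : None, "duration" or array
    n_starts, random_state : multi-start control.

    After :meth:`fit`, the micro-parameters are available as ``k1_``, ``k2_``
    (plus ``k3_``, ``k4_`` for the 2TCM), with ``vt_``, ``rss_``, ``aic_``
    and the full :class:`CompartmentFit` as ``result_``.
    """

    def __init__(self, model="2tcm", vb=0.05, weights=None, n_starts=3, random_state=0):
        self.model = model
        self.vb = vb
        self.weights = weights
        self.n_starts = n_starts
        self.random_state = random_state

    def fit(self, tac: TimeActivityCurve, input_function: InputFunction):
        result = fit_compartment(
            tac,
            input_function,
            model=self.model,
            vb=self.vb,
            weights=self.weights,
            n_starts=self.n_starts,
            random_state=self.random_state,
        )
        self.result_ = result
        self.k1_ = result.params.k1
        self.k2_ = result.params.k2
        self.k3_ = result.params.k3
        self.k4_ = result.params.k4
        self.vt_ = result.vt
        self.rss_ = result.rss
        self.aic_ = result.aic
        self.input_function_ = input_function
        self.schedule_ = tac.schedule
        return self

    def predict(self, schedule: FrameSchedule | None = None) -> np.ndarray:
        """Model TAC at the midpoints of ``schedule`` (default: fitted grid)."""
        if not hasattr(self, "result_"):
            raise ValidationError("estimator is not fitted")
        schedule = schedule if schedule is not None else self.schedule_
        return simulate_tissue(self.result_.params, self.input_function_, schedule).activity
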