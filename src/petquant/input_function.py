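"""Arterial input function: blood/plasma curve fits and metabolite correction.

The arterial model is the conventional one for manually sampled bolus data:
a linear rise from zero at injection to the peak, followed by a
tri-exponential decay, fitted separately to whole-blood and total-plasma
samples.  The parent (unmetabolised) fraction of plasma activity is a
mono-exponential anchored at 1 at injection, so the metabolite-corrected
parent-plasma input is ``Cp(t) = plasma(t) * exp(-k_m t)``.

Because every piece is an exponential or a linear ramp times an exponential,
the running integral of ``Cp`` and its convolution with ``exp(-alpha t)``
(needed by the compartment models and by the Logan x-axis) have closed forms;
:meth:`InputFunction.convolve_exp` evaluates them exactly and stably, with no
quadrature grid.

All times are seconds, all rates 1/s, concentrations kBq/mL.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares, nnls

from .errors import DegenerateInputError, FitError, ValidationError
from .tac import TimeActivityCurve


# --------------------------------------------------------------------------
# data model
# --------------------------------------------------------------------------

@dataclass
class ArterialSamples:
    """Manual arterial samples: whole blood, total plasma, parent fraction.

    Parent fractions are measured on a (usually sparser) subset of times,
    ``pf_time_s``.
    """

    time_s: np.ndarray
    whole_blood: np.ndarray
    total_plasma: np.ndarray
    pf_time_s: np.ndarray
    parent_fraction: np.ndarray

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.whole_blood = np.asarray(self.whole_blood, dtype=float)
        self.total_plasma = np.asarray(self.total_plasma, dtype=float)
        self.pf_time_s = np.asarray(self.pf_time_s, dtype=float)
        self.parent_fraction = np.asarray(self.parent_fraction, dtype=float)
        if np.any(np.diff(self.time_s) <= 0) or np.any(np.diff(self.pf_time_s) <= 0):
            raise ValidationError("sample times must be strictly increasing")
        if np.any(self.whole_blood < 0) or np.any(self.total_plasma < 0):
            raise ValidationError("concentrations must be non-negative")
        if np.any((self.parent_fraction < 0) | (self.parent_fraction > 1)):
            raise ValidationError("parent fractions must lie in [0, 1]")


@dataclass
class TriExpCurve:
    """Linear rise to the peak, tri-exponential decay after it.

    The curve is continuous at the peak by construction: the peak value is
    the sum of the amplitudes, and the rise is the chord from ``(0, 0)``.
    Rates are stored sorted in descending order.
    """

    peak_time: float
    amplitudes: np.ndarray
    rates: np.ndarray
    rss: float = 0.0

    def __post_init__(self):
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.peak_time <= 0:
            raise ValidationError("peak_time must be positive")
        if np.any(self.amplitudes < 0):
            raise ValidationError("amplitudes must be non-negative")
        if np.any(self.rates <= 0):
            raise ValidationError("rates must be positive")
        order = np.argsort(self.rates)[::-1]
        self.rates = self.rates[order]
        self.amplitudes = self.amplitudes[order]

    @property
    def peak_value(self) -> float:
        return float(self.amplitudes.sum())

    def value(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        tt = np.atleast_1d(t)
        rise = np.clip(tt / self.peak_time, 0.0, 1.0) * self.peak_value
        dt = np.maximum(tt - self.peak_time, 0.0)
        decay = np.sum(
            self.amplitudes[:, None] * np.exp(-self.rates[:, None] * dt[None, :]), axis=0
        )
        out = np.where(tt < self.peak_time, rise, decay)
        out = np.where(tt < 0, 0.0, out)
        return out if t.ndim else float(out[0])

    __call__ = value


@dataclass
class MonoExpParentFraction:
    """Parent fraction ``exp(-k_m t)``, anchored at 1 at injection."""

    rate: float  # 1/s

    def __post_init__(self):
        if self.rate < 0:
            raise ValidationError("parent-fraction rate must be >= 0")

    def value(self, t) -> np.ndarray:
        return np.exp(-self.rate * np.maximum(np.asarray(t, dtype=float), 0.0))

    __call__ = value


# --------------------------------------------------------------------------
# stable segment integrals (internal)
# --------------------------------------------------------------------------

def _exprel(x: np.ndarray) -> np.ndarray:
    """expm1(x)/x with the x -> 0 limit of 1."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    nz = np.abs(x) > 1e-14
    out[nz] = np.expm1(x[nz]) / x[nz]
    return out


def _int_exp_seg(u0, u1, mu: float, alpha: float, tau) -> np.ndarray:
    """``int_{u0}^{u1} exp(-mu*u) * exp(-alpha*(tau-u)) du``, elementwise.

    Anchored so that every exponent evaluated is <= 0 (u0 <= u1 <= tau).
    """
    u0 = np.asarray(u0, dtype=float)
    u1 = np.asarray(u1, dtype=float)
    tau = np.asarray(tau, dtype=float)
    kappa = alpha - mu
    d = u1 - u0
    lo = np.exp(-mu * u0 - alpha * (tau - u0)) * d * _exprel(kappa * d)
    hi = np.exp(-mu * u1 - alpha * (tau - u1)) * d * _exprel(-kappa * d)
    return np.where(kappa * d > 0, hi, lo)


def _int_ramp_exp(U, km: float, alpha: float, tau) -> np.ndarray:
    """``int_0^U u * exp(-km*u) * exp(-alpha*(tau-u)) du``, elementwise (U <= tau)."""
    U = np.asarray(U, dtype=float)
    tau = np.asarray(tau, dtype=float)
    kappa = alpha - km
    z = kappa * U
    small = np.abs(z) < 1e-4
    # series of int_0^U u e^{kappa u} du = U^2 (1/2 + z/3 + z^2/8 + z^3/30 + ...)
    poly = U**2 * (0.5 + z / 3.0 + z**2 / 8.0 + z**3 / 30.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        exact = (np.exp(z - alpha * tau) * (z - 1.0) + np.exp(-alpha * tau)) / np.where(
            small, 1.0, kappa**2
        )
    return np.where(small, np.exp(-alpha * tau) * poly, exact)


# --------------------------------------------------------------------------
# input function
# --------------------------------------------------------------------------

@dataclass
class InputFunction:
    """Fitted arterial curves plus delay and plasma-free-fraction metadata.

    ``delay`` (s) is the time shift of the blood-sampling clock relative to
    the PET clock: a positive delay means the input reaches the brain later,
    and all curve evaluations are shifted accordingly.  ``pff`` (plasma free
    fraction) is bookkeeping only and never scales VT.
    """

    whole_blood: TriExpCurve
    plasma: TriExpCurve
    parent_fraction: MonoExpParentFraction
    delay: float = 0.0
    pff: float | None = None

    # -- evaluation --------------------------------------------------------
    def value(self, t, component: str = "parent_plasma") -> np.ndarray:
        t = np.asarray(t, dtype=float)
        u = t - self.delay
        if component == "whole_blood":
            out = self.whole_blood.value(u)
        elif component == "total_plasma":
            out = self.plasma.value(u)
        elif component == "parent_plasma":
            out = self.plasma.value(u) * self.parent_fraction.value(u)
        else:
            raise ValidationError(f"unknown component {component!r}")
        return out

    def convolve_exp(self, alpha: float, t) -> np.ndarray:
        """``int_0^t Cp(s) * exp(-alpha*(t-s)) ds`` for the parent-plasma input.

        Exact closed form over the rise/decay segments of the fitted curves;
        ``alpha = 0`` gives the running integral of the input.  ``alpha`` is
        in 1/s, ``t`` in s, the result in kBq*s/mL.
        """
        t = np.asarray(t, dtype=float)
        tau = np.atleast_1d(t) - self.delay  # time since input onset
        tp = self.plasma.peak_time
        km = self.parent_fraction.rate
        pos = tau > 0
        out = np.zeros_like(tau)
        if np.any(pos):
            tpos = tau[pos]
            # rise segment u in [0, min(tau, tp)]: (P/tp) * u * e^{-km u}
            U = np.minimum(tpos, tp)
            c1 = self.plasma.peak_value / tp
            acc = c1 * _int_ramp_exp(U, km, alpha, tpos)
            # decay segments u in [tp, tau]: sum_i b_i e^{-mu_i u}
            late = tpos > tp
            if np.any(late):
                tl = tpos[late]
                contrib = np.zeros_like(tl)
                for a_i, lam_i in zip(self.plasma.amplitudes, self.plasma.rates):
                    mu = lam_i + km
                    b = a_i * np.exp(lam_i * tp)
                    contrib += b * _int_exp_seg(tp, tl, mu, alpha, tl)
                acc[late] += contrib
            out[pos] = acc
        return out if t.ndim else float(out[0])

    def integral(self, t) -> np.ndarray:
        """Running integral of the parent-plasma input, kBq*s/mL."""
        return self.convolve_exp(0.0, t)

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        def curve(c: TriExpCurve) -> dict:
            return {
                "peak_time": c.peak_time,
                "amplitudes": c.amplitudes.tolist(),
                "rates": c.rates.tolist(),
            }

        return {
            "whole_blood": curve(self.whole_blood),
            "plasma": curve(self.plasma),
            "parent_fraction_rate": self.parent_fraction.rate,
            "delay": self.delay,
            "pff": self.pff,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InputFunction":
        def curve(c: dict) -> TriExpCurve:
            return TriExpCurve(c["peak_time"], np.array(c["amplitudes"]), np.array(c["rates"]))

        return cls(
            whole_blood=curve(d["whole_blood"]),
            plasma=curve(d["plasma"]),
            parent_fraction=MonoExpParentFraction(d["parent_fraction_rate"]),
            delay=float(d.get("delay", 0.0)),
            pff=d.get("pff"),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "InputFunction":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def evaluate_input(input_function: InputFunction, t, component: str = "parent_plasma"):
    """Functional wrapper around :meth:`InputFunction.value`."""
    return input_function.value(t, component)


def integral_input(input_function: InputFunction, t):
    """Functional wrapper around :meth:`InputFunction.integral`."""
    return input_function.integral(t)


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

def _nnls_amplitudes(dt: np.ndarray, y: np.ndarray, rates: np.ndarray):
    basis = np.exp(-np.outer(dt, rates))
    amps, _ = nnls(basis, y)
    rss = float(np.sum((basis @ amps - y) ** 2))
    return amps, rss


def fit_triexponential(times, concentrations, min_post_peak: int = 8) -> TriExpCurve:
    """Fit the linear-rise / tri-exponential-decay model to arterial samples.

    The peak is taken at the maximum sample; the tri-exponential is fitted to
    the samples from the peak onward by constrained least squares (amplitudes
    >= 0, rates > 0), seeded by a rate-grid search with non-negative linear
    amplitude solves and polished by a bounded Levenberg-Marquardt run.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(concentrations, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValidationError("times and concentrations must be congruent 1-D arrays")
    if y.max(initial=0.0) <= 0:
        raise DegenerateInputError("degenerate input: no positive concentrations")
    ipk = int(np.argmax(y))
    tp = float(t[ipk])
    t_post, y_post = t[ipk:], y[ipk:]
    if t_post.size < min_post_peak:
        raise ValidationError(
            f"need >= {min_post_peak} post-peak samples, got {t_post.size}"
        )
    dt = t_post - tp
    span = float(dt[-1]) if dt[-1] > 0 else 1.0

    # coarse tail-rate estimate from the last third (log-linear)
    tail = slice(max(1, dt.size - max(3, dt.size // 3)), None)
    yt = np.maximum(y_post[tail], y_post.max() * 1e-9)
    slope = np.polyfit(dt[tail], np.log(yt), 1)[0]
    lam_slow = max(-slope, 0.05 / span)

    seeds = []
    for spread in ((25.0, 5.0, 1.0), (100.0, 10.0, 1.0), (8.0, 3.0, 1.0), (50.0, 4.0, 0.5)):
        seeds.append(lam_slow * np.asarray(spread))
    seeds.append(np.array([20.0, 4.0, 0.4]) / span)

    best = None
    for rates0 in seeds:
        amps0, rss0 = _nnls_amplitudes(dt, y_post, rates0)
        if best is None or rss0 < best[2]:
            best = (amps0, rates0, rss0)

    def residual(x):
        amps, lograte = x[:3], x[3:]
        return np.exp(-np.outer(dt, np.exp(lograte))) @ amps - y_post

    attempts = sorted(
        [(best[0], best[1])]
        + [(_nnls_amplitudes(dt, y_post, r)[0], r) for r in seeds[:3]],
        key=lambda ar: float(np.sum((np.exp(-np.outer(dt, ar[1])) @ ar[0] - y_post) ** 2)),
    )
    solution = None
    for amps0, rates0 in attempts[:3]:
        x0 = np.concatenate([np.maximum(amps0, y_post.max() * 1e-8), np.log(rates0)])
        res = least_squares(
            residual,
            x0,
            bounds=(
                np.concatenate([np.zeros(3), np.full(3, np.log(1e-8 / span))]),
                np.concatenate([np.full(3, np.inf), np.full(3, np.log(1e4 / span))]),
            ),
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
            max_nfev=4000,
        )
        if res.status > 0 and (solution is None or res.cost < solution.cost):
            solution = res
    if solution is None:
        raise FitError("tri-exponential fit did not converge", best=best)
    amps = solution.x[:3]
    rates = np.exp(solution.x[3:])
    # degenerate/duplicated components: keep them but guard identical rates
    rates = rates + np.arange(3) * 1e-15
    return TriExpCurve(tp, amps, rates, rss=float(2 * solution.cost))


def fit_parent_fraction(times, fractions) -> MonoExpParentFraction:
    """Least-squares mono-exponential parent fraction with f(0) fixed at 1."""
    t = np.asarray(times, dtype=float)
    f = np.asarray(fractions, dtype=float)
    if t.size < 3:
        raise ValidationError("need >= 3 parent-fraction measurements")
    if np.any((f < 0) | (f > 1)):
        raise ValidationError("parent fractions must lie in [0, 1]")
    # log-linear start, bounded non-linear polish
    k0 = max(-np.polyfit(t, np.log(np.maximum(f, 1e-12)), 1)[0], 0.0)
    res = least_squares(
        lambda k: np.exp(-k[0] * t) - f,
        [max(k0, 1e-12)],
        bounds=([0.0], [np.inf]),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
    )
    k_hat = float(res.x[0])
    # a metabolite-free subject is exactly k = 0; keep that limit clean
    if np.sum((1.0 - f) ** 2) <= 2.0 * res.cost:
        k_hat = 0.0
    return MonoExpParentFraction(k_hat)


def fit_input_function(samples: ArterialSamples, pff: float | None = None) -> InputFunction:
    """Fit whole-blood, plasma and parent-fraction curves from arterial samples."""
    wb = fit_triexponential(samples.time_s, samples.whole_blood)
    pl = fit_triexponential(samples.time_s, samples.total_plasma)
    pf = fit_parent_fraction(samples.pf_time_s, samples.parent_fraction)
    return InputFunction(whole_blood=wb, plasma=pl, parent_fraction=pf, delay=0.0, pff=pff)


def estimate_delay(
    input_function: InputFunction,
    composite_tac: TimeActivityCurve,
    search_s: tuple[float, float] = (-30.0, 30.0),
    step_s: float = 0.5,
    fit_window_s: float = 300.0,
) -> float:
    """Estimate the PET-vs-blood clock shift from the composite cortical TAC.

    Grid search over candidate delays; for each, a one-tissue compartment
    model is fitted to the first ``fit_window_s`` of the composite TAC with
    frame-duration weights, and the delay minimising the weighted residual is
    returned.  A flat objective (degenerate TAC) returns 0 with a warning.
    """
    from .kinetics import fit_compartment  # local import to avoid a cycle

    mask = composite_tac.midpoints <= fit_window_s
    if mask.sum() < 6:
        raise ValidationError("composite TAC must sample the first 5 min densely")
    early_activity = composite_tac.activity[mask]
    if np.ptp(early_activity) <= 1e-9 * max(np.abs(early_activity).max(), 1e-300):
        warnings.warn("degenerate (contrast-free) composite TAC; returning delay 0", stacklevel=2)
        return 0.0
    early = TimeActivityCurve(
        composite_tac.schedule.subset(mask),
        composite_tac.activity[mask],
        decay_corrected=composite_tac.decay_corrected,
        label=composite_tac.label,
    )
    deltas = np.arange(search_s[0], search_s[1] + step_s / 2, step_s)
    objective = np.full(deltas.size, np.inf)
    for i, d in enumerate(deltas):
        shifted = replace(input_function, delay=input_function.delay + float(d))
        try:
            fit = fit_compartment(
                early, shifted, model="1tcm", weights="duration", n_starts=1, min_frames=4
            )
        except FitError:
            continue
        objective[i] = fit.rss
    finite = np.isfinite(objective)
    if not np.any(finite) or np.ptp(objective[finite]) <= 1e-6 * objective[finite].max():
        warnings.warn("flat delay objective; returning 0", stacklevel=2)
        return 0.0
    return float(deltas[int(np.argmin(objective))])
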