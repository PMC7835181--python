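"""Whole-body dosimetry: organ curve models, cumulated activities, GI model.

Organ time-activity curves (fraction of injected activity, *not*
decay-corrected) are described by one of three half-time-parameterised
forms, with ``c`` the exponential constant (ln 2 by default; configurable
to the rounded 0.69 for literal replication of half-time tables):

* ``biexp``:           A1 e^{-c t / tau_e1} + A2 e^{-c t / tau_e2}
* ``uptake_washout``:  A1 (1 - e^{-c t / tau_u1}) e^{-c t / tau_e1} + A2 e^{-c t / tau_e2}
* ``uptake_plateau``:  A1 (1 - e^{-c t / tau_u1}) + A2 e^{-c t / tau_e2}

The normalized cumulated activity (NCA, a.k.a. residence time, MBq*h/MBq)
is the 0..infinity integral of such a fit, the frame trapezoid plus a
physical-decay tail for organs without a satisfactory fit, or the ICRP-30
serial gastrointestinal chain (small intestine -> upper -> lower large
intestine, biological transfer coefficients 6 / 1.8 / 1 per day) driven by
the fraction of injected activity entering the small intestine.  Organ
absorbed doses are a contraction of NCAs with a user-supplied S-value
matrix; the effective dose applies the ICRP-60 tissue weighting factors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, nnls
from sklearn.base import BaseEstimator

from .errors import FitError, StateError, ValidationError
from .tac import F18_HALF_LIFE_MIN, TimeActivityCurve, cumulative_integral

LN2 = math.log(2.0)

#: Organ -> curve form used in the whole-body analysis.  Organs not listed
#: (gallbladder wall, testes, urinary bladder) have no satisfactory curve
#: model and use the trapezoid method; GI-tract organs use the chain model.
ORGAN_FORMS: dict[str, str] = {
    "heart_wall": "biexp",
    "kidneys": "biexp",
    "lungs": "biexp",
    "spleen": "biexp",
    "thyroid": "biexp",
    "brain": "uptake_washout",
    "liver": "uptake_washout",
    "red_marrow": "uptake_washout",
    "remainder": "uptake_plateau",
}

#: ICRP-60 (1991) tissue weighting factors; they sum to 1.
ICRP60_WEIGHTS: dict[str, float] = {
    "gonads": 0.20,
    "red_marrow": 0.12,
    "colon": 0.12,
    "lung": 0.12,
    "stomach": 0.12,
    "bladder": 0.05,
    "breast": 0.05,
    "liver": 0.05,
    "oesophagus": 0.05,
    "thyroid": 0.05,
    "skin": 0.01,
    "bone_surface": 0.01,
    "remainder": 0.05,
}


def _physical_decay_constant_per_hour(half_life_min: float) -> float:
    return LN2 / (half_life_min / 60.0)


@dataclass
class OrganCurveModel:
    """One fitted organ TAC model (times in hours, values fraction injected)."""

    form: str  # "biexp" | "uptake_washout" | "uptake_plateau"
    a1: float
    a2: float
    tau_e1: float | None = None  # excretion half-time, h
    tau_e2: float | None = None  # excretion half-time, h
    tau_u1: float | None = None  # uptake half-time, h
    log2_constant: float = LN2
    rss: float = 0.0

    def __post_init__(self):
        if self.form not in ("biexp", "uptake_washout", "uptake_plateau"):
            raise ValidationError(f"unknown organ curve form {self.form!r}")
        if self.a1 < 0 or self.a2 < 0:
            raise ValidationError("scaling parameters must be non-negative")
        needed = {
            "biexp": ("tau_e1", "tau_e2"),
            "uptake_washout": ("tau_u1", "tau_e1", "tau_e2"),
            "uptake_plateau": ("tau_u1", "tau_e2"),
        }[self.form]
        for name in needed:
            value = getattr(self, name)
            if value is None or value <= 0:
                raise ValidationError(f"{self.form} requires {name} > 0")

    def value(self, t_h) -> np.ndarray:
        t = np.asarray(t_h, dtype=float)
        c = self.log2_constant
        e2 = self.a2 * np.exp(-c * t / self.tau_e2)
        if self.form == "biexp":
            out = self.a1 * np.exp(-c * t / self.tau_e1) + e2
        elif self.form == "uptake_washout":
            out = self.a1 * (1.0 - np.exp(-c * t / self.tau_u1)) * np.exp(
                -c * t / self.tau_e1
            ) + e2
        else:
            out = self.a1 * (1.0 - np.exp(-c * t / self.tau_u1)) + e2
        return out if t.ndim else float(out)

    __call__ = value


@dataclass
class NCARecord:
    """Normalized cumulated activity of one source organ, MBq*h/MBq."""

    organ: str
    nca: float
    method: str  # "analytic" | "trapezoid" | "gi_model"

    def __post_init__(self):
        if self.nca < 0:
            raise ValidationError("NCA must be non-negative")
        bound = F18_HALF_LIFE_MIN / 60.0 / LN2  # total-decay bound, h
        if self.nca > bound * 1.001:
            warnings.warn(
                f"NCA {self.nca:.4g} for {self.organ!r} exceeds the total-decay "
                f"bound {bound:.4g} h",
                stacklevel=2,
            )


class OrganCurve(BaseEstimator):
    """Constrained least-squares fit of one organ curve form.

    ``fit(t_hours, fraction)`` searches a coarse half-time grid with
    non-negative linear amplitude solves, polishes by bounded least squares,
    and exposes ``a1_``, ``a2_``, ``tau_e1_``, ``tau_e2_``, ``tau_u1_``,
    ``rss_`` and the :class:`OrganCurveModel` as ``model_``.
    """

    _TAU_GRID = (0.05, 0.15, 0.4, 0.9, 1.5, 1.83, 2.5)
    _TAU_U_GRID = (0.02, 0.08, 0.2, 0.6)

    def __init__(self, form: str = "biexp", log2_constant: float = LN2):
        self.form = form
        self.log2_constant = log2_constant

    def _basis(self, t, taus):
        c = self.log2_constant
        if self.form == "biexp":
            te1, te2 = taus
            b1 = np.exp(-c * t / te1)
        elif self.form == "uptake_washout":
            tu, te1, te2 = taus
            b1 = (1.0 - np.exp(-c * t / tu)) * np.exp(-c * t / te1)
        else:
            tu, te2 = taus
            b1 = 1.0 - np.exp(-c * t / tu)
        b2 = np.exp(-c * t / te2)
        return np.stack([b1, b2], axis=1)

    def fit(self, t_hours, fraction):
        t = np.asarray(t_hours, dtype=float)
        y = np.asarray(fraction, dtype=float)
        if t.size < 5:
            raise ValidationError("need >= 5 time points for an organ curve fit")
        if np.any(y < 0):
            raise ValidationError("organ activity fractions must be non-negative")

        if self.form == "biexp":
            grids = [(a, b) for a in self._TAU_GRID for b in self._TAU_GRID if b < a]
        elif self.form == "uptake_washout":
            grids = [
                (u, a, b)
                for u in self._TAU_U_GRID
                for a in self._TAU_GRID
                for b in self._TAU_GRID
                if b < a
            ]
        else:
            grids = [(u, b) for u in self._TAU_U_GRID for b in self._TAU_GRID]

        best = None
        for taus in grids:
            amps, rss = nnls(self._basis(t, taus), y)
            if best is None or rss**2 < best[2]:
                best = (amps, np.asarray(taus, dtype=float), rss**2)
        amps0, taus0, _ = best
        n_tau = taus0.size

        def residual(x):
            return self._basis(t, np.exp(x[2 : 2 + n_tau])) @ x[:2] - y

        x0 = np.concatenate([np.maximum(amps0, max(y.max(), 1e-12) * 1e-6), np.log(taus0)])
        sol = least_squares(
            residual,
            x0,
            bounds=(
                np.concatenate([np.zeros(2), np.full(n_tau, np.log(1e-3))]),
                np.concatenate([np.full(2, np.inf), np.full(n_tau, np.log(1e2))]),
            ),
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
            max_nfev=5000,
        )
        if sol.status <= 0:
            raise FitError(
                f"{self.form} organ fit did not converge; consider nca_trapezoid",
                best=sol.x,
            )
        taus = np.exp(sol.x[2:])
        kwargs = {"a1": float(sol.x[0]), "a2": float(sol.x[1])}
        if self.form == "biexp":
            kwargs.update(tau_e1=float(taus[0]), tau_e2=float(taus[1]))
        elif self.form == "uptake_washout":
            kwargs.update(tau_u1=float(taus[0]), tau_e1=float(taus[1]), tau_e2=float(taus[2]))
        else:
            kwargs.update(tau_u1=float(taus[0]), tau_e2=float(taus[1]))
        self.model_ = OrganCurveModel(
            form=self.form, log2_constant=self.log2_constant, rss=float(2 * sol.cost), **kwargs
        )
        self.a1_ = self.model_.a1
        self.a2_ = self.model_.a2
        self.tau_e1_ = self.model_.tau_e1
        self.tau_e2_ = self.model_.tau_e2
        self.tau_u1_ = self.model_.tau_u1
        self.rss_ = self.model_.rss
        return self

    def predict(self, t_hours) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise ValidationError("estimator is not fitted")
        return self.model_.value(np.asarray(t_hours, dtype=float))


def fit_organ_curve(
    tac: TimeActivityCurve, form: str, log2_constant: float = LN2
) -> OrganCurveModel:
    """Fit an organ curve form to a whole-body TAC (fraction injected, physical)."""
    if tac.decay_corrected:
        raise StateError("organ TACs must not be decay-corrected")
    est = OrganCurve(form=form, log2_constant=log2_constant)
    est.fit(tac.midpoints / 3600.0, tac.activity)
    return est.model_


def nca_analytic(model: OrganCurveModel, organ: str = "") -> NCARecord:
    """Closed-form 0..infinity integral of a fitted organ curve, MBq*h/MBq."""
    c = model.log2_constant
    total = model.a2 * model.tau_e2 / c
    if model.form == "biexp":
        total += model.a1 * model.tau_e1 / c
    elif model.form == "uptake_washout":
        te, tu = model.tau_e1, model.tau_u1
        total += model.a1 * (te / c - te * tu / (c * (te + tu)))
    else:  # uptake_plateau
        if model.a1 > 0:
            raise ValidationError(
                "uptake_plateau with A1 > 0 has a divergent integral; use "
                "nca_trapezoid on the physical TAC instead"
            )
    return NCARecord(organ=organ, nca=float(total), method="analytic")


def nca_trapezoid(
    tac: TimeActivityCurve, organ: str = "", half_life_min: float = F18_HALF_LIFE_MIN
) -> NCARecord:
    """Trapezoid NCA with a physical-decay tail beyond the last sample.

    The tail assumes no further biological excretion (conservative):
    ``A_last * T_half / ln 2`` from the last midpoint onward.
    """
    if tac.decay_corrected:
        raise StateError("trapezoid NCA requires a physical (not decay-corrected) TAC")
    last_mid = float(tac.midpoints[-1])
    base_h = cumulative_integral(tac, last_mid) / 3600.0
    tail_h = float(tac.activity[-1]) * (half_life_min / 60.0) / LN2
    return NCARecord(organ=organ, nca=float(base_h + max(tail_h, 0.0)), method="trapezoid")


@dataclass
class GIModelParams:
    """ICRP-30 gastrointestinal chain parameters.

    ``f_si`` is the fraction of injected activity entering the small
    intestine; biological transfer coefficients are per day (defaults
    6, 1.8 and 1 for SI, ULI and LLI); physical decay from the half-life.
    """

    f_si: float
    lambda_si: float = 6.0  # 1/day
    lambda_uli: float = 1.8  # 1/day
    lambda_lli: float = 1.0  # 1/day
    half_life_min: float = F18_HALF_LIFE_MIN

    def __post_init__(self):
        if not 0.0 <= self.f_si <= 1.0:
            raise ValidationError("f_si must lie in [0, 1]")
        if min(self.lambda_si, self.lambda_uli, self.lambda_lli) <= 0:
            raise ValidationError("biological transfer coefficients must be positive")
        if self.half_life_min <= 0:
            raise ValidationError("half-life must be positive")


def gi_tract_nca(params: GIModelParams | float) -> dict[str, NCARecord]:
    """NCAs of the ICRP-30 serial GI chain, MBq*h/MBq.

    A bolus of ``f_si`` enters the small intestine at t = 0 (the stomach
    compartment is bypassed for an intravenous tracer excreted via bile) and
    moves through SI -> ULI -> LLI with first-order biological transfer under
    physical decay.  Closed forms:

        SI  = f / (l_SI + l_p)
        ULI = f l_SI / [(l_SI + l_p)(l_ULI + l_p)]
        LLI = f l_SI l_ULI / [(l_SI + l_p)(l_ULI + l_p)(l_LLI + l_p)]
    """
    if not isinstance(params, GIModelParams):
        params = GIModelParams(f_si=float(params))
    lam_p = LN2 / (params.half_life_min / 60.0 / 24.0)  # 1/day
    d_si = params.lambda_si + lam_p
    d_uli = params.lambda_uli + lam_p
    d_lli = params.lambda_lli + lam_p
    si = params.f_si / d_si
    uli = params.f_si * params.lambda_si / (d_si * d_uli)
    lli = params.f_si * params.lambda_si * params.lambda_uli / (d_si * d_uli * d_lli)
    to_hours = 24.0
    return {
        "small_intestine": NCARecord("small_intestine", si * to_hours, "gi_model"),
        "upper_large_intestine": NCARecord("upper_large_intestine", uli * to_hours, "gi_model"),
        "lower_large_intestine": NCARecord("lower_large_intestine", lli * to_hours, "gi_model"),
    }


def remainder_tac(
    total_body: TimeActivityCurve, source_organs: dict[str, TimeActivityCurve]
) -> TimeActivityCurve:
    """Remainder = total body minus all source organs, floored at zero."""
    for name, tac in source_organs.items():
        if not np.array_equal(tac.schedule.start, total_body.schedule.start):
            raise ValidationError(f"schedule mismatch for source organ {name!r}")
    total = total_body.activity.copy()
    for tac in source_organs.values():
        total -= tac.activity
    n_neg = int(np.sum(total < 0))
    if n_neg:
        warnings.warn(f"remainder negative in {n_neg} frames; floored at 0", stacklevel=2)
        total = np.maximum(total, 0.0)
    return TimeActivityCurve(
        total_body.schedule,
        total,
        decay_corrected=total_body.decay_corrected,
        label="remainder",
        units=total_body.units,
    )


def effective_dose(
    organ_doses: dict[str, float], weights: dict[str, float] | None = None
) -> float:
    """ICRP-60 effective dose, uSv/MBq, from organ doses in uGy/MBq.

    Weighted tissues missing from ``organ_doses`` fall back to the
    ``"remainder"`` dose when present; otherwise the gaps are reported.
    """
    weights = ICRP60_WEIGHTS if weights is None else weights
    missing = [t for t in weights if t not in organ_doses and t != "remainder"]
    remainder = organ_doses.get("remainder")
    if missing and remainder is None:
        raise ValidationError(f"missing organ doses without remainder fallback: {missing}")
    total = 0.0
    for tissue, w in weights.items():
        total += w * float(organ_doses.get(tissue, remainder))
    return total


def read_s_matrix(path) -> pd.DataFrame:
    """S-value matrix: rows target organs, columns source organs, uGy/(MBq*h)."""
    return pd.read_csv(path, sep=None, engine="python", index_col=0)


def organ_doses_from_nca(
    ncas: dict[str, NCARecord | float], s_matrix: pd.DataFrame
) -> pd.Series:
    """Target doses ``D_T = sum_S NCA_S * S(T <- S)``, uGy/MBq."""
    values = {
        organ: (rec.nca if isinstance(rec, NCARecord) else float(rec))
        for organ, rec in ncas.items()
    }
    missing = [o for o in values if o not in s_matrix.columns]
    if missing:
        raise ValidationError(f"S-matrix lacks source columns: {missing}")
    vec = pd.Series(values)
    return s_matrix[vec.index] @ vec
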