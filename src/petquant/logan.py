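"""Logan graphical analysis of reversible tracer kinetics.

For a reversible tracer the transformed coordinates

    x_i = int_0^{t_i} Cp dtau / C_T(t_i)        (min)
    y_i = int_0^{t_i} C_T dtau / C_T(t_i)       (min)

become linear for t_i >= t* with slope VT.  The tissue integral uses the
frame-midpoint trapezoid rule (which bridges any acquisition gap linearly,
so the coffee-break protocol needs no special casing); the plasma integral
is the closed form of the fitted input.  t* defaults to 40 min: the first
included point is the first frame midpoint at or after t*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .errors import DegenerateInputError, ValidationError
from .input_function import InputFunction
from .tac import DynamicVolume, TimeActivityCurve, cumulative_integral


@dataclass
class LoganPoints:
    """Transformed Logan coordinates (minutes) at the usable frame midpoints."""

    x: np.ndarray
    y: np.ndarray
    t_mid_s: np.ndarray
    n_dropped: int = 0


@dataclass
class LoganFit:
    vt: float
    intercept: float  # min; diagnostic only
    t_star: float  # min
    n_points: int
    r_squared: float
    n_dropped: int = 0


@dataclass(frozen=True)
class AcquisitionWindow:
    """Disjoint, ordered acquisition segments in minutes.

    Full scan: ``[(0, 120)]``; coffee-break: ``[(0, 60), (90, 120)]``;
    truncated: ``[(0, X)]``.
    """

    segments: tuple[tuple[float, float], ...]

    def __post_init__(self):
        segs = tuple((float(a), float(b)) for a, b in self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise ValidationError("window needs at least one segment")
        last_end = -np.inf
        for a, b in segs:
            if b <= a:
                raise ValidationError(f"empty segment ({a}, {b})")
            if a < last_end:
                raise ValidationError("segments must be disjoint and ordered")
            last_end = b

    @classmethod
    def parse(cls, spec: str) -> "AcquisitionWindow":
        """Parse ``"0-120"`` or ``"0-60,90-120"`` (minutes)."""
        segs = []
        for token in spec.split(","):
            a, _, b = token.partition("-")
            segs.append((float(a), float(b)))
        return cls(tuple(segs))

    @property
    def label(self) -> str:
        return "/".join(f"{a:g}-{b:g}" for a, b in self.segments)


def logan_transform(tac: TimeActivityCurve, input_function: InputFunction) -> LoganPoints:
    """Logan coordinates at every frame midpoint with positive tissue value."""
    t = tac.midpoints
    ct = tac.activity
    keep = ct > 0
    n_dropped = int((~keep).sum())
    if not np.any(keep):
        raise DegenerateInputError("no frames with positive tissue activity")
    tk = t[keep]
    x = input_function.integral(tk) / 60.0 / ct[keep]
    y = cumulative_integral(tac, tk) / 60.0 / ct[keep]
    return LoganPoints(x=x, y=y, t_mid_s=tk, n_dropped=n_dropped)


def fit_logan(points: LoganPoints, t_star: float = 40.0) -> LoganFit:
    """OLS line through the Logan points with midpoint >= t* (minutes)."""
    mask = points.t_mid_s / 60.0 >= t_star - 1e-9
    if mask.sum() < 3:
        raise ValidationError(
            f"need >= 3 Logan points at/after t* = {t_star} min, got {int(mask.sum())}"
        )
    x, y = points.x[mask], points.y[mask]
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return LoganFit(
        vt=float(slope),
        intercept=float(intercept),
        t_star=float(t_star),
        n_points=int(mask.sum()),
        r_squared=r2,
        n_dropped=points.n_dropped,
    )


def logan_vt(
    tac: TimeActivityCurve, input_function: InputFunction, t_star: float = 40.0
) -> LoganFit:
    """Transform and fit in one call."""
    return fit_logan(logan_transform(tac, input_function), t_star=t_star)


class LoganVT(BaseEstimator):
    """Scikit-learn style estimator for the Logan graphical VT.

    After :meth:`fit`, exposes ``vt_``, ``intercept_``, ``r_squared_``,
    ``n_points_`` and the full :class:`LoganFit` as ``result_``.
    """

    def __init__(self, t_star: float = 40.0):
        self.t_star = t_star

    def fit(self, tac: TimeActivityCurve, input_function: InputFunction):
        result = logan_vt(tac, input_function, t_star=self.t_star)
        self.result_ = result
        self.vt_ = result.vt
        self.intercept_ = result.intercept
        self.r_squared_ = result.r_squared
        self.n_points_ = result.n_points
        return self


def apply_window(tac: TimeActivityCurve, window: AcquisitionWindow) -> TimeActivityCurve:
    """Keep only the frames fully inside the window's segments.

    Downstream integrals bridge any resulting gap linearly between the last
    retained midpoint before the gap and the first after it.
    """
    start, end = tac.schedule.start, tac.schedule.end
    keep = np.zeros(tac.schedule.n_frames, dtype=bool)
    for a, b in window.segments:
        keep |= (start >= a * 60.0 - 1e-6) & (end <= b * 60.0 + 1e-6)
    if not np.any(keep):
        raise ValidationError(f"window {window.label} retains no frames")
    return TimeActivityCurve(
        tac.schedule.subset(keep),
        tac.activity[keep],
        decay_corrected=tac.decay_corrected,
        reference_time=tac.reference_time,
        label=tac.label,
        units=tac.units,
    )


def voxelwise_logan(
    volume: DynamicVolume,
    input_function: InputFunction,
    t_star: float = 40.0,
) -> tuple[np.ndarray, float]:
    """Per-voxel Logan VT map.

    Voxels with non-positive tissue activity at any included midpoint are set
    to NaN.  Returns ``(vt_map, nan_fraction)``.
    """
    t = volume.schedule.midpoints
    late = t / 60.0 >= t_star - 1e-9
    if late.sum() < 3:
        raise ValidationError(f"need >= 3 frame midpoints at/after t* = {t_star} min")
    flat = volume.data.reshape(-1, t.size)
    # trapezoid cumulative integral anchored at (0, 0), vectorised over voxels
    nodes = np.concatenate([[0.0], t])
    seg = np.diff(nodes)
    vals = np.concatenate([np.zeros((flat.shape[0], 1)), flat], axis=1)
    cum = np.cumsum((vals[:, :-1] + vals[:, 1:]) / 2.0 * seg[None, :], axis=1)
    inp = input_function.integral(t[late]) / 60.0

    ct = flat[:, late]
    valid = np.all(ct > 0, axis=1)
    vt = np.full(flat.shape[0], np.nan)
    if np.any(valid):
        c = ct[valid]
        x = inp[None, :] / c
        y = cum[valid][:, late] / 60.0 / c
        xm = x.mean(axis=1, keepdims=True)
        ym = y.mean(axis=1, keepdims=True)
        denom = np.sum((x - xm) ** 2, axis=1)
        good = denom > 0
        slope = np.full(c.shape[0], np.nan)
        slope[good] = np.sum((x - xm) * (y - ym), axis=1)[good] / denom[good]
        vt[valid] = slope
    vt_map = vt.reshape(volume.data.shape[:3])
    return vt_map, float(np.isnan(vt_map).mean())


def time_stability_table(
    test_retest_sets,
    cohort_sets,
    windows,
    t_star: float = 40.0,
    full_window: AcquisitionWindow | None = None,
):
    """Time-stability summary of the Logan VT over reduced acquisition windows.

    Parameters
    ----------
    test_retest_sets : iterable of dicts
        Each with keys ``"test"`` and ``"retest"``, each value a tuple
        ``(tacs, input_function)`` where ``tacs`` maps region -> TAC with
        full-schedule coverage.
    cohort_sets : iterable of ``(tacs, input_function)``
        Single-scan datasets used for the bias-vs-full-scan column.
    windows : iterable of :class:`AcquisitionWindow`
    full_window : reference window (defaults to the full span of the first
        cohort schedule); its row reports no bias.

    Returns a DataFrame indexed by window label with pooled (region x
    subject) TRV and bias statistics in percent: mean, SD and range.
    """
    import pandas as pd

    from .reliability import trv as trv_pct

    test_retest_sets = list(test_retest_sets)
    cohort_sets = list(cohort_sets)
    windows = list(windows)
    if full_window is None:
        any_tac = next(iter(cohort_sets[0][0].values()))
        full_window = AcquisitionWindow(((0.0, any_tac.schedule.duration / 60.0),))

    def window_vts(tacs, inp, window):
        return {
            region: logan_vt(apply_window(tac, window), inp, t_star=t_star).vt
            for region, tac in tacs.items()
        }

    full_vts = [window_vts(tacs, inp, full_window) for tacs, inp in cohort_sets]

    rows = []
    for window in windows:
        trvs = []
        for pair in test_retest_sets:
            vt_t = window_vts(*pair["test"], window)
            vt_r = window_vts(*pair["retest"], window)
            trvs.extend(trv_pct(vt_t[r], vt_r[r]) for r in vt_t)
        is_full = window.segments == full_window.segments
        biases = []
        if not is_full:
            for (tacs, inp), ref in zip(cohort_sets, full_vts):
                vt_w = window_vts(tacs, inp, window)
                biases.extend(100.0 * (vt_w[r] - ref[r]) / ref[r] for r in vt_w)
        trvs = np.asarray(trvs, dtype=float)
        biases = np.asarray(biases, dtype=float)

        def stats(v):
            if v.size == 0:
                return (np.nan, np.nan, np.nan, np.nan)
            sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
            return (float(v.mean()), sd, float(v.min()), float(v.max()))

        rows.append(
            {
                "window": window.label,
                **dict(zip(("trv_mean", "trv_sd", "trv_min", "trv_max"), stats(trvs))),
                **dict(zip(("bias_mean", "bias_sd", "bias_min", "bias_max"), stats(biases))),
            }
        )
    return pd.DataFrame(rows).set_index("window")
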