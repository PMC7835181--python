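"""Test-retest, reliability and method-agreement statistics.

Definitions (all sample statistics use the n-1 denominator):

* TRV  = 2 (VT_test - VT_retest) / (VT_test + VT_retest), in percent (signed)
* aTRV = |TRV|
* ICC  = (BSMSS - WSMSS) / (BSMSS + WSMSS), the one-way random-effects form
  with BSMSS the between-subject mean square (k * sum over subject means,
  n - 1 df) and WSMSS the within-subject mean square (n (k - 1) df, k = 2
  repeated measurements); ranges over [-1, 1]
* %COV = sample SD / mean x 100
* Bland-Altman: bias = mean(a - b), SD, limits of agreement bias +- 1.96 SD
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError


def trv(vt_test, vt_retest):
    """Signed test-retest variability in percent."""
    a = np.asarray(vt_test, dtype=float)
    b = np.asarray(vt_retest, dtype=float)
    s = a + b
    if np.any(s <= 0):
        raise ValidationError("pair sums must be positive")
    out = 200.0 * (a - b) / s
    return out if out.ndim else float(out)


def atrv(vt_test, vt_retest):
    """Absolute test-retest variability in percent."""
    return np.abs(trv(vt_test, vt_retest))


def icc(test_values, retest_values) -> float:
    """One-way random-effects intra-class correlation for paired measurements."""
    a = np.asarray(test_values, dtype=float)
    b = np.asarray(retest_values, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("test and retest must be congruent 1-D arrays")
    n = a.size
    if n < 2:
        raise ValidationError("need >= 2 subjects")
    x = np.stack([a, b], axis=1)  # n subjects x k=2 measurements
    k = 2
    subj_means = x.mean(axis=1)
    grand = x.mean()
    bsmss = k * np.sum((subj_means - grand) ** 2) / (n - 1)
    wsmss = np.sum((x - subj_means[:, None]) ** 2) / (n * (k - 1))
    total = bsmss + wsmss
    if total == 0:
        raise ValidationError("zero total variance: ICC undefined")
    return float((bsmss - wsmss) / total)


def cov_percent(values) -> float:
    """Coefficient of variation in percent (sample SD / mean x 100)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValidationError("need >= 2 values")
    m = v.mean()
    if m <= 0:
        raise ValidationError("mean must be positive")
    return float(np.std(v, ddof=1) / m * 100.0)


@dataclass
class BlandAltman:
    bias: float
    sd: float
    loa_low: float
    loa_high: float


def bland_altman(values_a, values_b) -> BlandAltman:
    """Bland-Altman agreement of paired measurements (differences a - b)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("inputs must be congruent 1-D arrays")
    if a.size < 2:
        raise ValidationError("need >= 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(np.std(d, ddof=1))
    return BlandAltman(bias=bias, sd=sd, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd)


def summarize_test_retest(pairs: pd.DataFrame) -> pd.DataFrame:
    """Per-region TRV/aTRV (averaged over subjects) and ICC.

    ``pairs`` must have columns ``subject, region, vt_test, vt_retest``.
    """
    for col in ("subject", "region", "vt_test", "vt_retest"):
        if col not in pairs.columns:
            raise ValidationError(f"missing column {col!r}")
    rows = []
    for region, grp in pairs.groupby("region", sort=False):
        t = grp["vt_test"].to_numpy(dtype=float)
        r = grp["vt_retest"].to_numpy(dtype=float)
        rows.append(
            {
                "region": region,
                "trv_pct": float(np.mean(trv(t, r))),
                "atrv_pct": float(np.mean(atrv(t, r))),
                "icc": icc(t, r),
                "n_subjects": int(grp.shape[0]),
            }
        )
    return pd.DataFrame(rows).set_index("region")
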