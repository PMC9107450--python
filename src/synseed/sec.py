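"""Size-exclusion chromatography (SEC) fraction profiling.

An SEC run elutes a pooled lysate into sequential fractions (collected
range typically #18–#56 at 0.8 ml/fraction); an analyte is assayed per
fraction.  The quantities of interest are the percent-of-total profile
(each fraction's share of the summed signal over the collected range),
the peak fractions, the apparent molecular weight at a fraction from a
marker calibration (log-linear in elution position), and per-fraction
group comparisons of replicate percent profiles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from synseed.stats import GroupTestResult, group_compare

__all__ = [
    "FractionProfile",
    "CalibrationCurve",
    "percent_of_total",
    "peak_fractions",
    "mw_at_fraction",
    "compare_profiles",
]


class FractionProfile:
    """Per-fraction analyte amounts for one sample.

    Amounts must be non-negative; the fraction index is kept sorted.
    """

    def __init__(self, amounts, analyte: str = "",
                 fraction_volume_ml: float = 0.8):
        s = pd.Series(amounts, dtype=float).sort_index()
        if (s < 0).any():
            raise ValueError("fraction amounts must be >= 0")
        self.amounts = s
        self.analyte = analyte
        self.fraction_volume_ml = fraction_volume_ml

    @property
    def fractions(self) -> np.ndarray:
        return self.amounts.index.to_numpy()


class CalibrationCurve:
    """Molecular-weight markers: (fraction index, kDa) points.

    Later-eluting fractions contain smaller species, so MW must be strictly
    decreasing with fraction index.  Interpolation is linear in log10(MW);
    queries outside the marker range are refused (no extrapolation).
    """

    def __init__(self, markers):
        pts = sorted((float(f), float(mw)) for f, mw in markers)
        if len(pts) < 2:
            raise ValueError("need >= 2 calibration markers")
        fr = np.array([p[0] for p in pts])
        mw = np.array([p[1] for p in pts])
        if np.any(mw <= 0):
            raise ValueError("marker MW must be positive")
        if np.any(np.diff(mw) >= 0):
            raise ValueError("MW must strictly decrease with fraction index")
        self.fractions = fr
        self.mw_kda = mw


def percent_of_total(profile: FractionProfile | pd.Series) -> pd.Series:
    """Each fraction's percent of the summed signal over the collected range.

    Sums to 100 and is invariant to rescaling the raw amounts.
    """
    amounts = profile.amounts if isinstance(profile, FractionProfile) \
        else pd.Series(profile, dtype=float).sort_index()
    total = amounts.sum()
    if total <= 0:
        raise ValueError("percent of total undefined for an all-zero profile")
    return 100.0 * amounts / total


def peak_fractions(profile: FractionProfile | pd.Series, window: int = 1) -> list:
    """Interior local maxima of a fraction profile.

    A fraction is a peak when its amount is strictly greater than every
    neighbour within ``window`` fractions on both sides; a flat plateau is
    reported once at its lowest fraction index.  Endpoints are never peaks.
    """
    amounts = profile.amounts if isinstance(profile, FractionProfile) \
        else pd.Series(profile, dtype=float).sort_index()
    if amounts.size < 3:
        raise ValueError("need >= 3 fractions")
    if window < 1:
        raise ValueError("window must be >= 1")
    y = amounts.to_numpy()
    idx = amounts.index.to_numpy()
    peaks = []
    i = 1
    n = y.size
    while i < n - 1:
        # extent of a plateau starting at i
        j = i
        while j + 1 < n and y[j + 1] == y[i]:
            j += 1
        if j == n - 1:      # plateau runs to the boundary
            break
        lo = max(0, i - window)
        hi = min(n, j + 1 + window)
        neighbours = np.concatenate([y[lo:i], y[j + 1:hi]])
        if neighbours.size and np.all(y[i] > neighbours):
            peaks.append(idx[i])
        i = j + 1
    return peaks


def mw_at_fraction(cal: CalibrationCurve, fraction: float) -> float:
    """Apparent molecular weight (kDa) at a fraction, log-linear in MW."""
    if fraction < cal.fractions[0] or fraction > cal.fractions[-1]:
        raise ValueError(
            f"fraction {fraction} outside the calibrated range "
            f"[{cal.fractions[0]:g}, {cal.fractions[-1]:g}]; "
            "extrapolation is not supported")
    logmw = np.interp(fraction, cal.fractions, np.log10(cal.mw_kda))
    return float(10.0**logmw)


def compare_profiles(profiles: dict[str, list], m_tests: int | None = None,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Per-fraction group comparison of replicate SEC profiles.

    ``profiles`` maps group label -> list of replicate profiles (Series or
    FractionProfile).  Raw amounts are first converted to percent-of-total
    (profiles are always compared on the percent scale), then each fraction
    is tested across groups via :func:`synseed.stats.group_compare` with a
    Bonferroni family over the number of fractions (override with
    ``m_tests``).  With a single replicate per group the output is
    descriptive only (mean per group, no test).
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 groups")
    pct: dict[str, list[pd.Series]] = {
        g: [percent_of_total(p) for p in reps] for g, reps in profiles.items()
    }
    fractions = None
    for reps in pct.values():
        for s in reps:
            f = tuple(s.index)
            if fractions is None:
                fractions = f
            elif f != fractions:
                raise ValueError("all profiles must share one fraction range")

    testable = all(len(reps) >= 2 for reps in pct.values())
    m = m_tests if m_tests is not None else len(fractions)
    rows = []
    for k, frac in enumerate(fractions):
        row: dict = {"fraction": frac}
        vals, grps = [], []
        for g, reps in pct.items():
            x = [s.iloc[k] for s in reps]
            row[f"mean_pct[{g}]"] = float(np.mean(x))
            vals.extend(x)
            grps.extend([g] * len(x))
        if testable:
            res: GroupTestResult = group_compare(vals, grps, m_tests=m,
                                                 alpha=alpha)
            row.update(test=res.test, p_value=res.p_value,
                       significant=res.significant,
                       alpha_corrected=res.alpha_corrected)
        rows.append(row)
    return pd.DataFrame(rows).set_index("fraction")
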