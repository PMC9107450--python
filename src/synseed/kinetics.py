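"""Scoring of RT-QuIC (seeded-amplification) plate runs.

A run is a set of ThT fluorescence time series, one per well, on a shared
time grid (typically a reading every 30 min for 60 h).  Scoring follows the
standard brain-lysate protocol:

* **threshold** — mean of the pooled first 10 cycles of *all* wells on the
  plate plus 25 sample standard deviations of that same pool (one threshold
  per plate);
* **t_cross** — earliest grid time at which a well's fluorescence reaches
  the threshold;
* **PAR** (protein aggregation rate) — 1 / t_cross in 1/h, 0 for wells that
  never cross;
* **MaxFL** — mean fluorescence over the last 10 cycles (the reaction
  plateau);
* a biological sample is the mean of its replicate wells and is called
  positive when at least half of its replicates crossed.

Reproducibility across runs is summarized as intra-batch and inter-batch
coefficients of variation (CV%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PlateRun",
    "WellKinetics",
    "SampleResult",
    "BatchCV",
    "load_plate",
    "compute_threshold",
    "analyze_well",
    "aggregate_sample",
    "score_plate",
    "cv_percent",
]


@dataclass
class PlateRun:
    """One plate-reader export: a shared time grid, per-well series, layout.

    ``layout`` is indexed by well id with columns ``sample_id``, ``group``,
    ``replicate`` and optionally ``batch``.
    """

    times: np.ndarray
    wells: dict[str, np.ndarray]
    layout: pd.DataFrame

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size < 20:
            raise ValueError("time grid must have >= 20 points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time grid must be strictly increasing")
        for wid, series in self.wells.items():
            series = np.asarray(series, dtype=float)
            if series.size != self.times.size:
                raise ValueError(
                    f"well {wid}: series length {series.size} does not match "
                    f"the {self.times.size}-point grid")
            self.wells[wid] = series
            if wid not in self.layout.index:
                raise ValueError(f"well {wid} missing from layout")

    @property
    def n_wells(self) -> int:
        return len(self.wells)


def load_plate(curves_path, layout_path) -> PlateRun:
    """Read the wide curves CSV and layout CSV into a :class:`PlateRun`.

    The curves file has a ``well`` column followed by hour-stamped columns
    ``t_0``, ``t_0.5``, ...; the layout file maps each well to
    ``sample_id, group, replicate`` (and optionally ``batch``).
    """
    curves = pd.read_csv(curves_path)
    if "well" not in curves.columns:
        raise ValueError("curves file must contain a 'well' column")
    tcols = [c for c in curves.columns if c.startswith("t_")]
    if len(set(tcols)) != len(tcols):
        raise ValueError("duplicated time columns in curves file")
    try:
        times = np.array([float(c[2:]) for c in tcols])
    except ValueError:
        raise ValueError("duplicated or non-numeric time columns in curves "
                         f"file: {tcols[:5]}...") from None
    if np.unique(times).size != times.size:
        raise ValueError("duplicated time columns in curves file")

    layout = pd.read_csv(layout_path)
    required = {"well", "sample_id", "group", "replicate"}
    missing = required - set(layout.columns)
    if missing:
        raise ValueError(f"layout file missing columns: {sorted(missing)}")
    layout = layout.set_index("well")

    wells: dict[str, np.ndarray] = {}
    for _, row in curves.iterrows():
        wid = str(row["well"])
        vals = pd.to_numeric(row[tcols], errors="coerce").to_numpy(dtype=float)
        if np.any(~np.isfinite(vals)):
            bad = [tcols[i] for i in np.nonzero(~np.isfinite(vals))[0][:3]]
            raise ValueError(f"well {wid}: non-numeric readings in columns {bad}")
        if wid not in layout.index:
            raise ValueError(f"well {wid} present in curves but missing from layout")
        wells[wid] = vals
    return PlateRun(times=times, wells=wells, layout=layout)


@dataclass(frozen=True)
class WellKinetics:
    """Per-well scoring result."""

    well: str
    threshold: float
    t_cross: float | None
    par: float                      # 1/h; 0 when no crossing
    maxfl: float
    positive: bool
    invalid_baseline: bool = False  # already above threshold at cycle 1


@dataclass(frozen=True)
class SampleResult:
    """Replicate-aggregated result for one biological sample."""

    sample_id: str
    par_mean: float
    maxfl_mean: float
    n_replicates: int
    n_positive_replicates: int
    positive: bool
    unevaluable: bool = False


@dataclass(frozen=True)
class BatchCV:
    scope: str        # "intra-batch" | "inter-batch"
    statistic: str    # "PAR" | "MaxFL"
    cv_percent: float | None
    n: int


def compute_threshold(plate: PlateRun, n_baseline: int = 10,
                      k_sd: float = 25.0) -> float:
    """Plate-wide positivity threshold.

    Pools the first ``n_baseline`` readings of every well and returns
    ``mean + k_sd * SD`` of that pool (sample SD, ddof=1).  A zero-variance
    pool is legal and returns the pooled mean.
    """
    if n_baseline < 1:
        raise ValueError("n_baseline must be >= 1")
    for wid, series in plate.wells.items():
        if series.size < n_baseline:
            raise ValueError(f"well {wid} has fewer than {n_baseline} readings")
    pool = np.concatenate([s[:n_baseline] for s in plate.wells.values()])
    if pool.size < 2:
        raise ValueError("need at least 2 pooled baseline readings")
    return float(pool.mean() + k_sd * pool.std(ddof=1))


def analyze_well(series, times, threshold: float, well: str = "",
                 tail_cycles: int = 10, interpolate: bool = False) -> WellKinetics:
    """Score one well against a plate threshold.

    ``t_cross`` is the earliest grid time with F >= threshold (assay
    resolution is the read cycle, so no interpolation by default; with
    ``interpolate=True`` the crossing is linearly interpolated between the
    bracketing cycles).  A well already at or above threshold at the first
    cycle is flagged ``invalid_baseline`` and carries no kinetic values.
    """
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    if series.size != times.size:
        raise ValueError("series and time grid lengths differ")
    if tail_cycles < 1 or tail_cycles > series.size:
        raise ValueError("tail_cycles out of range")

    maxfl = float(series[-tail_cycles:].mean())
    above = series >= threshold
    if above[0]:
        warnings.warn(f"well {well or '?'} above threshold at the first cycle; "
                      "flagged invalid-baseline", stacklevel=2)
        return WellKinetics(well, threshold, None, 0.0, maxfl, False,
                            invalid_baseline=True)
    if not above.any():
        return WellKinetics(well, threshold, None, 0.0, maxfl, False)

    i = int(np.argmax(above))
    if interpolate and series[i] > threshold:
        f0, f1 = series[i - 1], series[i]
        t_cross = times[i - 1] + (threshold - f0) / (f1 - f0) * (times[i] - times[i - 1])
    else:
        t_cross = times[i]
    t_cross = float(t_cross)
    return WellKinetics(well, threshold, t_cross, 1.0 / t_cross, maxfl, True)


def aggregate_sample(wells: list[WellKinetics], sample_id: str = "",
                     min_positive_fraction: float = 0.5,
                     negative_par: str = "zero") -> SampleResult:
    """Aggregate replicate wells into one biological-sample result.

    Invalid-baseline wells are excluded.  ``negative_par='zero'`` lets
    non-crossing wells contribute PAR = 0 to the mean (so negative samples
    average to zero rate); ``'exclude'`` averages over crossing wells only.
    The sample is positive when the positive-replicate fraction is
    >= ``min_positive_fraction`` (a tie at exactly half counts as positive).
    """
    if not wells:
        raise ValueError("need at least one well")
    valid = [w for w in wells if not w.invalid_baseline]
    if not valid:
        return SampleResult(sample_id, float("nan"), float("nan"),
                            0, 0, False, unevaluable=True)
    n_pos = sum(w.positive for w in valid)
    if negative_par == "zero":
        pars = [w.par for w in valid]
    elif negative_par == "exclude":
        pars = [w.par for w in valid if w.positive] or [0.0]
    else:
        raise ValueError("negative_par must be 'zero' or 'exclude'")
    par_mean = float(np.mean(pars))
    maxfl_mean = float(np.mean([w.maxfl for w in valid]))
    positive = n_pos / len(valid) >= min_positive_fraction
    return SampleResult(sample_id, par_mean, maxfl_mean,
                        len(valid), n_pos, positive)


def score_plate(plate: PlateRun, n_baseline: int = 10, k_sd: float = 25.0,
                tail_cycles: int = 10, min_positive_fraction: float = 0.5,
                interpolate: bool = False,
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """End-to-end scoring: threshold, per-well kinetics, per-sample results.

    Returns (well_table, sample_table) as DataFrames ready for export.
    """
    threshold = compute_threshold(plate, n_baseline=n_baseline, k_sd=k_sd)
    per_well: dict[str, WellKinetics] = {}
    for wid, series in plate.wells.items():
        per_well[wid] = analyze_well(series, plate.times, threshold, well=wid,
                                     tail_cycles=tail_cycles,
                                     interpolate=interpolate)

    well_rows = [{
        "well": wk.well,
        "sample_id": plate.layout.loc[wk.well, "sample_id"],
        "group": plate.layout.loc[wk.well, "group"],
        "threshold": wk.threshold,
        "t_cross_h": wk.t_cross,
        "PAR_per_h": wk.par,
        "MaxFL_AU": wk.maxfl,
        "positive": wk.positive,
        "invalid_baseline": wk.invalid_baseline,
    } for wk in per_well.values()]
    well_df = pd.DataFrame(well_rows)

    sample_rows = []
    for sid, grp in well_df.groupby("sample_id", sort=False):
        res = aggregate_sample([per_well[w] for w in grp["well"]], sample_id=sid,
                               min_positive_fraction=min_positive_fraction)
        sample_rows.append({
            "sample_id": sid,
            "group": grp["group"].iloc[0],
            "PAR_mean_per_h": res.par_mean,
            "MaxFL_mean_AU": res.maxfl_mean,
            "n_replicates": res.n_replicates,
            "n_positive_replicates": res.n_positive_replicates,
            "positive": res.positive,
            "unevaluable": res.unevaluable,
        })
    return well_df, pd.DataFrame(sample_rows)


def cv_percent(values, scope: str = "intra-batch",
               statistic: str = "PAR") -> BatchCV:
    """Coefficient of variation, 100 * sample SD / mean.

    Intra-batch CV pools replicate wells within one run; inter-batch CV
    pools per-run sample means across runs.  A zero mean (flat negative
    wells can average to 0) makes the CV undefined; it is reported as
    ``None`` with a warning rather than an error, since negative controls
    legitimately produce near-zero means and wildly inflated CVs.
    """
    values = np.asarray(list(values), dtype=float)
    if values.size < 2:
        raise ValueError("CV needs at least 2 values")
    mean = values.mean()
    if mean == 0:
        warnings.warn("CV undefined for zero mean; reporting None", stacklevel=2)
        return BatchCV(scope, statistic, None, values.size)
    cv = 100.0 * values.std(ddof=1) / mean
    return BatchCV(scope, statistic, float(cv), values.size)
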