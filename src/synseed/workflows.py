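"""End-to-end convenience workflows combining the generator and the scorers."""

from __future__ import annotations

import pandas as pd

from synseed import datasets, kinetics, simulate
from synseed.simulate import GroupPreset

__all__ = ["ad_positivity_experiment", "cohort_composition_percentages"]


def _ad_positive_preset() -> GroupPreset:
    # AD lysates with detectable seeding: sigmoidal curves whose plateau sits
    # far above the 25-SD threshold and whose midpoint stays well inside the
    # 60 h read window.
    return GroupPreset(
        group_label="AD seeding-positive",
        means={"baseline": 10_000.0, "amplitude": 80_000.0, "rate_k": 0.5,
               "midpoint_t50": 32.0, "noise_sd": 400.0},
        sds={"amplitude": 8_000.0, "midpoint_t50": 3.0},
    )


def _ad_negative_preset() -> GroupPreset:
    return GroupPreset(
        group_label="AD seeding-negative",
        means={"baseline": 10_000.0, "amplitude": 0.0, "rate_k": 0.5,
               "midpoint_t50": 32.0, "noise_sd": 400.0},
    )


def ad_positivity_experiment(rng_seed: int = 0) -> dict:
    """Score a synthetic AD sample set end to end and report percent positive.

    Builds the AD assay design (43 biological samples in triplicate, of which
    19 carry seeding-competent sigmoidal kinetics and 24 are flat negatives),
    computes the plate threshold, per-well kinetics and per-sample positivity,
    and returns the positivity rate.
    """
    counts = datasets.rtquic_design_counts()
    n_pos = counts["ad_seeding_positive"]
    n_total = counts["ad_total"]
    plate, truth = simulate.simulate_plate(
        [(_ad_positive_preset(), n_pos),
         (_ad_negative_preset(), n_total - n_pos)],
        replicates_per_sample=counts["replicates"],
        rng_seed=rng_seed,
        multi_plate=True,
    )
    well_df, sample_df = kinetics.score_plate(plate)
    n_called = int(sample_df["positive"].sum())
    return {
        "n_samples": len(sample_df),
        "n_positive": n_called,
        "percent_positive": 100.0 * n_called / len(sample_df),
        "well_table": well_df,
        "sample_table": sample_df,
        "truth": truth,
    }


def cohort_composition_percentages() -> pd.Series:
    """Percent of AD-cohort cases without and with Lewy-body co-pathology."""
    counts = datasets.ad_cohort_counts()
    by_group = counts.groupby("group")["n"].sum()
    return 100.0 * by_group / by_group.sum()
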