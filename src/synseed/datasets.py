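"""Small built-in reference tables.

These are printed summary inputs (cohort composition, assay design counts),
not measurements; they let bookkeeping quantities be recomputed without any
external download.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["ad_cohort_counts", "rtquic_design_counts"]


def ad_cohort_counts() -> pd.DataFrame:
    """Composition of the 469-case autopsy-confirmed AD cohort.

    Cases are split by Lewy-body co-pathology (AD vs AD+LB) and APOE4
    carriage.  Returns one row per subgroup with case counts.
    """
    return pd.DataFrame([
        {"group": "AD", "apoe4": "carrier-", "n": 80},
        {"group": "AD", "apoe4": "carrier+", "n": 134},
        {"group": "AD+LB", "apoe4": "carrier-", "n": 78},
        {"group": "AD+LB", "apoe4": "carrier+", "n": 177},
    ])


def rtquic_design_counts() -> dict[str, int]:
    """Seeding-assay sample-set sizes: brain lysates assayed in triplicate.

    ``ad_total`` AD samples of which ``ad_seeding_positive`` showed seeding
    activity; plus the AD+LB, LBD and control set sizes.
    """
    return {
        "ad_total": 43,
        "ad_seeding_positive": 19,
        "adlb_total": 47,
        "lbd_total": 18,
        "control_total": 16,
        "replicates": 3,
    }
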