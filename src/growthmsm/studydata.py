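"""Published descriptive counts of the motivating pediatric HIV cohort.

The individual-level data of the motivating cohort (four HIV-exposure
groups followed from birth to five years in Cameroon) are not public;
what is public are the descriptive counts: group sizes, sex ratio,
deaths, and how many children ever experienced each form of growth
retardation.  This module reconstructs a child-level table carrying
exactly those margins so that :func:`growthmsm.pipeline.describe_cohort`
can recompute every published percentage from counts.

The table is *synthetic at the child level* (which particular child
carries which flag is arbitrary); only the counts are real.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["DESCRIPTIVE_COUNTS", "study_descriptive_children"]

#: published margins: group sizes, overall and per-index counts
DESCRIPTIVE_COUNTS = {
    "n": 611,
    "group_sizes": {"HI": 69, "HIL": 141, "HEU": 205, "HUU": 196},
    "n_female": 323,
    "n_deceased": 66,
    # ever-malnourished: (n assessed, n ever) overall and among deceased
    "underweight": {"assessed": 607, "ever": 168,
                    "deceased_assessed": 62, "deceased_ever": 32},
    "stunted": {"assessed": 605, "ever": 369,
                "deceased_assessed": 60, "deceased_ever": 38},
    "wasted": {"assessed": 605, "ever": 256,
               "deceased_assessed": 60, "deceased_ever": 16},
}


def study_descriptive_children(counts=None):
    """Child-level table reproducing the published descriptive margins."""
    c = counts or DESCRIPTIVE_COUNTS
    n = c["n"]
    groups = np.repeat(list(c["group_sizes"]), list(c["group_sizes"].values()))
    df = pd.DataFrame({"child_id": np.arange(n), "group": groups})
    df["sex"] = np.where(np.arange(n) < c["n_female"], "female", "male")
    n_dec = c["n_deceased"]
    df["deceased"] = np.arange(n) < n_dec

    def ever_flags(spec):
        col = np.full(n, np.nan, dtype=object)
        dec = np.arange(n_dec)
        alive = np.arange(n_dec, n)
        col[dec[:spec["deceased_ever"]]] = True
        col[dec[spec["deceased_ever"]:spec["deceased_assessed"]]] = False
        n_alive_assessed = spec["assessed"] - spec["deceased_assessed"]
        n_alive_ever = spec["ever"] - spec["deceased_ever"]
        col[alive[:n_alive_ever]] = True
        col[alive[n_alive_ever:n_alive_assessed]] = False
        return col

    df["ever_underweight"] = ever_flags(c["underweight"])
    df["ever_stunted"] = ever_flags(c["stunted"])
    df["ever_wasted"] = ever_flags(c["wasted"])
    return df
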