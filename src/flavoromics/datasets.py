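"""Packaged reference data.

The shipped table lists the 27 odor-scorable volatiles of three commercial
dried jujube cultivars — Huizao (HZ), Hamazao 1 (HMZ) and Qiyuexian (QYX) —
with their odor-detection thresholds in water (µg/kg), odor descriptors,
per-cultivar relative contents (percent of total volatile signal) and the
published ROAV scores for cross-checking.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io_core import (
    ThresholdLibrary,
    ThresholdRecord,
    VolatileEntry,
    VolatileProfile,
)

JUJUBE_GROUPS = ("HZ", "HMZ", "QYX")


def _table() -> pd.DataFrame:
    with resources.files("flavoromics.data").joinpath("jujube_voc_table.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_jujube_voc_table() -> tuple[list[VolatileProfile], ThresholdLibrary]:
    """Volatile profiles and odor-threshold library of the three cultivars."""
    df = _table()
    profiles = [
        VolatileProfile(
            g,
            tuple(
                VolatileEntry(row["compound"], row["category"], float(row[g]))
                for _, row in df.iterrows()
            ),
        )
        for g in JUJUBE_GROUPS
    ]
    library = ThresholdLibrary.from_records(
        ThresholdRecord(
            compound_id=row["compound"],
            threshold=float(row["threshold_ug_per_kg"]),
            odor_type=row["odor_type"],
            source="literature (water matrix)",
        )
        for _, row in df.iterrows()
    )
    return profiles, library


def load_jujube_roav_reference() -> pd.DataFrame:
    """Published ROAV scores (columns ``HZ``, ``HMZ``, ``QYX``) indexed by compound.

    Intended for validation against :func:`flavoromics.roav.compute_roav`
    output; the published scores are rounded to 2-3 decimals.
    """
    df = _table()
    out = df[["compound", "roav_HZ", "roav_HMZ", "roav_QYX"]].set_index("compound")
    out.columns = list(JUJUBE_GROUPS)
    return out
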