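"""Seeded generators for every input kind the pipeline consumes.

The defaults emulate a three-cultivar x three-biological-replicate dried
jujube study: a 454-compound intensity matrix with a 15-class composition,
a 66-volatile relative-content table over 7 categories, and 5-level HPLC
standard series on the 0.05-1.0 mg/mL grid.  Replicate noise is
multiplicative lognormal (intensities are positive and right-skewed;
additive Gaussian noise would allow negatives and distort fold changes) with
a default 10% coefficient of variation.  Every generator is deterministic
given its seed, and each returns the ground truth needed for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_core import (
    VOC_CATEGORIES,
    IntensityMatrix,
    ThresholdLibrary,
    ThresholdRecord,
    ValidationError,
    VolatileEntry,
    VolatileProfile,
)

#: 15-class metabolite composition of a dried-jujube panel (454 compounds):
#: lipids, amino acids, flavonoids, alkaloids, organic acids, nucleotides,
#: phenolic acids, terpenoids, saccharides, vitamins, alcohols, tannins,
#: coumarins, steroids, other.
DEFAULT_CLASS_COUNTS: dict[str, int] = {
    "lipids": 83,
    "amino acids and derivatives": 56,
    "flavonoids": 53,
    "alkaloids": 50,
    "organic acids": 44,
    "phenolic acids": 34,
    "nucleotides and derivatives": 31,
    "terpenoids": 30,
    "saccharides": 20,
    "others": 18,
    "vitamins": 13,
    "alcohols": 7,
    "tannins": 7,
    "coumarins": 6,
    "steroids": 2,
}

DEFAULT_GROUPS = (("HZ", 3), ("HMZ", 3), ("QYX", 3))


@dataclass(frozen=True)
class PlantedEffect:
    compound_id: str
    group_id: str  # group whose abundance is shifted
    log2_effect: float  # multiplicative shift, log2 scale


@dataclass
class SyntheticDesign:
    """Design of a synthetic intensity dataset; defaults mirror the
    3-cultivar x 3-replicate, 454-compound study layout."""

    groups: tuple[tuple[str, int], ...] = DEFAULT_GROUPS
    n_compounds: int = 454
    class_proportions: Mapping[str, float] | None = None  # None -> 454-panel mix
    planted_effects: tuple[PlantedEffect, ...] = ()
    noise_cv: float = 0.1  # within-group biological coefficient of variation
    baseline_log_mean: float = 11.0  # lognormal location (~6e4 median intensity)
    baseline_log_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv <= 0:
            raise ValidationError("noise_cv must be > 0")
        if self.n_compounds < 1:
            raise ValidationError("n_compounds must be >= 1")
        for g, n in self.groups:
            if n < 2:
                raise ValidationError(f"group {g!r} needs >= 2 replicates, got {n}")
        if self.class_proportions is not None:
            total = sum(self.class_proportions.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(f"class proportions sum to {total}, expected 1")


def _class_labels(design: SyntheticDesign) -> list[str]:
    if design.class_proportions is None:
        total = sum(DEFAULT_CLASS_COUNTS.values())
        props = {k: v / total for k, v in DEFAULT_CLASS_COUNTS.items()}
    else:
        props = dict(design.class_proportions)
    labels: list[str] = []
    classes = list(props)
    counts = [int(round(props[c] * design.n_compounds)) for c in classes]
    # round-off: pad/trim on the largest class
    diff = design.n_compounds - sum(counts)
    counts[int(np.argmax(counts))] += diff
    for c, k in zip(classes, counts):
        labels.extend([c] * max(k, 0))
    return labels[: design.n_compounds]


def generate_intensity_dataset(
    design: SyntheticDesign | None = None,
) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Synthesize an intensity matrix plus its ground-truth effect table.

    Baselines are lognormal per compound; each planted effect multiplies one
    group's baseline by 2**log2_effect; replicates add lognormal noise with
    the design's CV.  The ground-truth frame has columns
    ``compound_id, group_id, log2_effect``.
    """
    design = design or SyntheticDesign()
    rng = np.random.default_rng(design.seed)
    compounds = [f"M{i + 1:04d}" for i in range(design.n_compounds)]
    classes = dict(zip(compounds, _class_labels(design)))
    index = {c: i for i, c in enumerate(compounds)}
    for eff in design.planted_effects:
        if eff.compound_id not in index:
            raise ValidationError(f"planted compound {eff.compound_id!r} not in matrix")
        if eff.group_id not in {g for g, _ in design.groups}:
            raise ValidationError(f"planted group {eff.group_id!r} not in design")

    baselines = rng.lognormal(design.baseline_log_mean, design.baseline_log_sd,
                              size=design.n_compounds)
    # group-level expected abundance, planted effects applied multiplicatively
    group_means = {g: baselines.copy() for g, _ in design.groups}
    for eff in design.planted_effects:
        group_means[eff.group_id][index[eff.compound_id]] *= 2.0 ** eff.log2_effect

    # lognormal noise with E[noise]=1 and CV = noise_cv
    sigma2 = np.log1p(design.noise_cv**2)
    sigma = np.sqrt(sigma2)
    columns: dict[str, np.ndarray] = {}
    groups: dict[str, str] = {}
    for g, n_rep in design.groups:
        for r in range(1, n_rep + 1):
            noise = rng.lognormal(-sigma2 / 2, sigma, size=design.n_compounds)
            sample = f"{g}_{r}"
            columns[sample] = group_means[g] * noise
            groups[sample] = g
    values = pd.DataFrame(columns, index=compounds)
    truth = pd.DataFrame(
        [(e.compound_id, e.group_id, e.log2_effect) for e in design.planted_effects],
        columns=["compound_id", "group_id", "log2_effect"],
    )
    return IntensityMatrix(values, groups, classes), truth


def generate_voc_profiles(
    n_compounds: int = 66,
    groups: Sequence[str] = ("HZ", "HMZ", "QYX"),
    threshold_range: tuple[float, float] = (0.05, 10_000.0),
    seed: int = 0,
    dirichlet_alpha: float = 0.5,
) -> tuple[list[VolatileProfile], ThresholdLibrary]:
    """Synthesize per-group volatile profiles plus a threshold library.

    Relative contents are Dirichlet-distributed (summing to 100% per group);
    the default concentration 0.5 yields the sparse, dominance-heavy
    compositions typical of real volatile tables.  Thresholds are
    log-uniform over ``threshold_range`` (µg/kg).
    """
    if n_compounds < 2:
        raise ValidationError("need >= 2 compounds")
    lo, hi = threshold_range
    if lo <= 0 or hi <= lo:
        raise ValidationError("threshold_range must satisfy 0 < lo < hi")
    rng = np.random.default_rng(seed)
    compounds = [f"VOC{i + 1:03d}" for i in range(n_compounds)]
    categories = rng.choice(VOC_CATEGORIES, size=n_compounds)
    thresholds = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_compounds))
    profiles = []
    for g in groups:
        contents = 100.0 * rng.dirichlet(np.full(n_compounds, dirichlet_alpha))
        # guard the <=100 invariant against float round-up
        contents *= 100.0 / max(contents.sum(), 100.0)
        entries = tuple(
            VolatileEntry(c, cat, float(v))
            for c, cat, v in zip(compounds, categories, contents)
        )
        profiles.append(VolatileProfile(str(g), entries))
    library = ThresholdLibrary.from_records(
        ThresholdRecord(c, float(t), odor_type="synthetic", source="synthetic")
        for c, t in zip(compounds, thresholds)
    )
    return profiles, library


#: the conventional 5-level external-standard grid, mg/mL
CALIBRATION_LEVELS = (0.05, 0.1, 0.25, 0.5, 1.0)


def generate_calibration(
    analytes: Sequence[str],
    slope_range: tuple[float, float] = (50.0, 200.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    levels: Sequence[float] = CALIBRATION_LEVELS,
):
    """Synthesize standard series with known slope/intercept.

    Returns ``(series_list, truths)`` where truths maps analyte ->
    (slope, intercept).  Responses are slope*level + intercept + N(0, noise_sd).
    """
    from .quantify import CalibrationSeries  # local import avoids cycle

    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    series_list, truths = [], {}
    for analyte in analytes:
        slope = float(rng.uniform(*slope_range))
        intercept = float(rng.normal(0.0, 0.5))
        responses = [slope * c + intercept + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
                     for c in levels]
        series_list.append(CalibrationSeries(analyte, tuple(zip(levels, responses))))
        truths[analyte] = (slope, intercept)
    return series_list, truths
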