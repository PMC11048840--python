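"""Relative odor activity value (ROAV) aroma scoring.

A volatile's contribution to perceived aroma depends on both its abundance
and its odor-detection threshold.  ROAV rescales the odor activity ratio
C_i / T_i (relative content over threshold) so the strongest contributor in a
profile — the *reference compound* — scores exactly 100:

    ROAV_i = 100 * (C_i / C_max) * (T_max / T_i)

where C_max and T_max belong to the reference compound, chosen per profile as
the argmax of C / T.  Compounds scoring above 1 are conventionally called the
*key* aroma compounds, those between 0.1 and 1 aroma *modifiers*, and the
rest negligible.

ROAV is invariant to rescaling all contents by a common positive factor and
to the unit of the thresholds, because only the ratios C_i/C_max and T_max/T_i
enter the formula.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_core import (
    PipelineConfig,
    ThresholdLibrary,
    ValidationError,
    VolatileProfile,
    normalize_compound_id,
)

AROMA_CLASSES = ("key", "modifier", "negligible")


@dataclass(frozen=True)
class RoavRow:
    compound_id: str
    relative_content: float  # percent
    threshold: float  # µg/kg
    roav: float
    aroma_class: str
    odor_type: str


@dataclass(frozen=True)
class RoavTable:
    group_id: str
    reference_compound: str
    rows: tuple[RoavRow, ...]
    excluded: tuple[str, ...]  # compounds lacking a threshold record

    def row(self, compound_id: str) -> RoavRow:
        key = normalize_compound_id(compound_id)
        for r in self.rows:
            if normalize_compound_id(r.compound_id) == key:
                return r
        raise KeyError(compound_id)

    def by_class(self, aroma_class: str) -> list[RoavRow]:
        return [r for r in self.rows if r.aroma_class == aroma_class]


def reference_compound(profile: VolatileProfile, library: ThresholdLibrary) -> str:
    """The compound with the greatest aroma contribution: argmax of C / T.

    Only compounds present in both the profile and the threshold library with
    content > 0 are candidates; ties break lexicographically on compound id
    so the choice is deterministic.
    """
    best_id: str | None = None
    best_ratio = -1.0
    for entry in profile.entries:
        rec = library.get(entry.compound_id)
        if rec is None or entry.relative_content <= 0:
            continue
        ratio = entry.relative_content / rec.threshold
        if ratio > best_ratio or (ratio == best_ratio and entry.compound_id < (best_id or "")):
            best_id, best_ratio = entry.compound_id, ratio
    if best_id is None:
        raise ValidationError(
            f"profile {profile.group_id!r}: no compound with a threshold and content > 0"
        )
    return best_id


def classify_aroma(roav: float, config: PipelineConfig | None = None) -> str:
    """key (ROAV > 1), modifier (0.1 <= ROAV <= 1, both ends inclusive) or
    negligible, at the configured cutoffs."""
    cfg = config or PipelineConfig()
    if roav < 0:
        raise ValidationError(f"ROAV must be >= 0, got {roav}")
    if roav > cfg.roav_key_cutoff:
        return "key"
    if roav >= cfg.roav_modifier_cutoff:
        return "modifier"
    return "negligible"


def compute_roav(
    profile: VolatileProfile,
    library: ThresholdLibrary,
    config: PipelineConfig | None = None,
) -> RoavTable:
    """Score every thresholded compound of a profile; see the module docstring.

    Compounds without a threshold record are listed in ``excluded`` rather
    than silently dropped.  Zero-content compounds score 0 (the formula is
    linear in C_i).  The reference compound scores exactly 100.
    """
    cfg = config or PipelineConfig()
    ref_id = reference_compound(profile, library)
    ref_rec = library.get(ref_id)
    assert ref_rec is not None
    c_max = profile.contents()[normalize_compound_id(ref_id)]
    t_max = ref_rec.threshold

    rows: list[RoavRow] = []
    excluded: list[str] = []
    for entry in profile.entries:
        rec = library.get(entry.compound_id)
        if rec is None:
            excluded.append(entry.compound_id)
            continue
        if normalize_compound_id(entry.compound_id) == normalize_compound_id(ref_id):
            score = 100.0  # exact by construction; avoids float round-off
        else:
            score = 100.0 * (entry.relative_content / c_max) * (t_max / rec.threshold)
        rows.append(
            RoavRow(
                compound_id=entry.compound_id,
                relative_content=entry.relative_content,
                threshold=rec.threshold,
                roav=score,
                aroma_class=classify_aroma(score, cfg),
                odor_type=rec.odor_type,
            )
        )
    return RoavTable(
        group_id=profile.group_id,
        reference_compound=ref_id,
        rows=tuple(rows),
        excluded=tuple(excluded),
    )


def category_composition(profile: VolatileProfile) -> dict[str, float]:
    """Percent of the profile total contributed by each compound category.

    The percents are normalized to the profile's own total, so they sum to
    100 even for partial profiles.
    """
    if not profile.entries:
        raise ValidationError("empty profile")
    total = sum(e.relative_content for e in profile.entries)
    if total <= 0:
        raise ValidationError(f"profile {profile.group_id!r} has zero total content")
    sums: dict[str, float] = {}
    for e in profile.entries:
        sums[e.category] = sums.get(e.category, 0.0) + e.relative_content
    return {cat: 100.0 * v / total for cat, v in sums.items()}
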