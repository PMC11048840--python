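"""Shared data model, tabular readers/writers, and pipeline configuration.

All tabular formats are plain TSV/CSV (sniffed by file extension, decimal
point only).  Relative contents of volatiles are stored as *percents* of the
total volatile signal, the convention used in published GC-MS profile tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

VOC_CATEGORIES = ("acid", "alcohol", "aldehyde", "alkene", "ester", "ketone", "other")

#: tolerance on the "percents sum to <= 100" profile invariant; profiles may be
#: partial subsets of a full table, so only the upper bound is checked.
_PERCENT_SUM_TOL = 1e-6


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def normalize_compound_id(compound: str) -> str:
    """Case-insensitive compound key; punctuation is preserved.

    Hyphens and parentheses carry chemical meaning (isomer and position
    labels such as ``(E)-2-Nonenal``), so only surrounding whitespace and
    letter case are normalized.
    """
    return compound.strip().casefold()


@dataclass(frozen=True)
class VolatileEntry:
    compound_id: str
    category: str
    relative_content: float  # percent of total volatile signal

    def __post_init__(self) -> None:
        if self.category not in VOC_CATEGORIES:
            raise ValidationError(
                f"unknown category {self.category!r} for {self.compound_id!r}; "
                f"expected one of {VOC_CATEGORIES}"
            )
        if not math.isfinite(self.relative_content) or self.relative_content < 0:
            raise ValidationError(
                f"relative content of {self.compound_id!r} must be finite and >= 0, "
                f"got {self.relative_content}"
            )


@dataclass(frozen=True)
class VolatileProfile:
    """Per-group relative contents of named volatile compounds."""

    group_id: str
    entries: tuple[VolatileEntry, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        seen: set[str] = set()
        total = 0.0
        for e in self.entries:
            key = normalize_compound_id(e.compound_id)
            if key in seen:
                raise ValidationError(
                    f"duplicate compound {e.compound_id!r} in profile {self.group_id!r}"
                )
            seen.add(key)
            total += e.relative_content
        if total > 100.0 + _PERCENT_SUM_TOL:
            raise ValidationError(
                f"relative contents in profile {self.group_id!r} sum to {total:.6f} > 100"
            )

    def contents(self) -> dict[str, float]:
        """Map normalized compound id -> relative content (percent)."""
        return {normalize_compound_id(e.compound_id): e.relative_content for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class ThresholdRecord:
    compound_id: str
    threshold: float  # µg/kg, odor detection threshold in water
    odor_type: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.threshold) and self.threshold > 0):
            raise ValidationError(
                f"odor threshold of {self.compound_id!r} must be > 0, got {self.threshold}"
            )


@dataclass(frozen=True)
class ThresholdLibrary:
    """Compound -> odor threshold (µg/kg in water) and odor type."""

    records: Mapping[str, ThresholdRecord]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", dict(self.records))

    @classmethod
    def from_records(cls, records: Iterable[ThresholdRecord]) -> "ThresholdLibrary":
        out: dict[str, ThresholdRecord] = {}
        for rec in records:
            key = normalize_compound_id(rec.compound_id)
            if key in out:
                raise ValidationError(f"duplicate threshold record for {rec.compound_id!r}")
            out[key] = rec
        return cls(out)

    def get(self, compound_id: str) -> ThresholdRecord | None:
        return self.records.get(normalize_compound_id(compound_id))

    def __contains__(self, compound_id: str) -> bool:
        return normalize_compound_id(compound_id) in self.records

    def __len__(self) -> int:
        return len(self.records)


class IntensityMatrix:
    """Compounds x samples abundance matrix with group labels and classes.

    Thin wrapper around a :class:`pandas.DataFrame` (rows = compounds,
    columns = samples) carrying a sample -> group map and per-compound class
    labels.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        groups: Mapping[str, str],
        classes: Mapping[str, str] | None = None,
    ) -> None:
        if values.index.duplicated().any():
            dup = values.index[values.index.duplicated()][0]
            raise ValidationError(f"duplicate compound_id {dup!r}")
        if values.columns.duplicated().any():
            dup = values.columns[values.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample_id {dup!r}")
        arr = values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValidationError("non-finite abundance in matrix")
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative abundance {arr[i, j]} for compound "
                f"{values.index[i]!r}, sample {values.columns[j]!r}"
            )
        missing = [s for s in values.columns if s not in groups]
        if missing:
            raise ValidationError(f"samples without group label: {missing}")
        self.values = values.astype(float)
        self.groups = {s: groups[s] for s in values.columns}
        self.classes = dict(classes or {})

    # -- convenience accessors -------------------------------------------------
    @property
    def compounds(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def group_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.groups[s], None)
        return list(seen)

    def samples_of(self, group_id: str) -> list[str]:
        return [s for s in self.samples if self.groups[s] == group_id]

    def subset_groups(self, group_ids: Sequence[str]) -> "IntensityMatrix":
        cols = [s for s in self.samples if self.groups[s] in set(group_ids)]
        if not cols:
            raise ValidationError(f"no samples in groups {list(group_ids)}")
        return IntensityMatrix(self.values[cols], self.groups, self.classes)

    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class PathwayAnnotation:
    """pathway_id -> (name, member compound ids); membership is a set."""

    pathways: Mapping[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        clean: dict[str, tuple[str, frozenset[str]]] = {}
        for pid, (name, members) in dict(self.pathways).items():
            members = frozenset(normalize_compound_id(m) for m in members)
            if not members:
                raise ValidationError(f"pathway {pid!r} has no members")
            clean[pid] = (name, members)
        object.__setattr__(self, "pathways", clean)

    def __len__(self) -> int:
        return len(self.pathways)


@dataclass
class PipelineConfig:
    """Tunable knobs shared by every stage, with field defaults matching the
    conventions of the workflow (VIP > 1, |log2FC| > 1, ROAV cutoffs 1 / 0.1,
    200 permutation replicates)."""

    scaling_method: str = "unit_variance"  # unit_variance | pareto | none
    cv_folds: int = 7
    n_permutations: int = 200
    rng_seed: int = 0
    vip_cutoff: float = 1.0
    log2fc_cutoff: float = 1.0
    roav_key_cutoff: float = 1.0
    roav_modifier_cutoff: float = 0.1
    fdr_method: str = "benjamini_hochberg"  # benjamini_hochberg | none
    epsilon_fc: float = 1e-9

    def __post_init__(self) -> None:
        if self.scaling_method not in ("unit_variance", "pareto", "none"):
            raise ValidationError(f"unknown scaling_method {self.scaling_method!r}")
        if self.fdr_method not in ("benjamini_hochberg", "none"):
            raise ValidationError(f"unknown fdr_method {self.fdr_method!r}")
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")
        if not (0 < self.roav_modifier_cutoff < self.roav_key_cutoff):
            raise ValidationError("require 0 < roav_modifier_cutoff < roav_key_cutoff")
        if self.epsilon_fc <= 0:
            raise ValidationError("epsilon_fc must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}  # noqa: C416
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def replace(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _sep_for(path: str | Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def _parse_number(value, context: str) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"non-numeric value {value!r} at {context}") from None


def read_volatile_table(path: str | Path, dialect: str = "wide") -> list[VolatileProfile]:
    """Read a volatile relative-content table into one profile per group.

    ``wide``: columns ``compound[,category],<group1>,<group2>,...``
    ``long``: columns ``compound[,category],group,relative_content``
    A missing category column defaults every compound to ``other``.
    """
    if dialect not in ("wide", "long"):
        raise ValidationError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    df.columns = [str(c).strip() for c in df.columns]
    if "compound" not in df.columns:
        raise ValidationError(f"{path}: missing 'compound' column")
    has_cat = "category" in df.columns

    def category_of(row) -> str:
        if not has_cat:
            return "other"
        cat = str(row["category"]).strip().lower()
        return cat if cat in VOC_CATEGORIES else "other"

    profiles: list[VolatileProfile] = []
    if dialect == "wide":
        group_cols = [c for c in df.columns if c not in ("compound", "category")]
        seen: set[str] = set()
        for rownum, row in enumerate(df.itertuples(index=False), start=2):
            key = normalize_compound_id(getattr(row, "compound"))
            if key in seen:
                raise ValidationError(f"duplicate compound {getattr(row, 'compound')!r}")
            seen.add(key)
        for g in group_cols:
            entries = [
                VolatileEntry(
                    str(row["compound"]).strip(),
                    category_of(row),
                    _parse_number(row[g], f"row {i + 2}, column {g!r}"),
                )
                for i, (_, row) in enumerate(df.iterrows())
            ]
            profiles.append(VolatileProfile(g, tuple(entries)))
    else:
        for col in ("group", "relative_content"):
            if col not in df.columns:
                raise ValidationError(f"{path}: long dialect requires column {col!r}")
        for g, sub in df.groupby("group", sort=False):
            entries = [
                VolatileEntry(
                    str(row["compound"]).strip(),
                    category_of(row),
                    _parse_number(row["relative_content"], f"row {i + 2}"),
                )
                for i, (_, row) in enumerate(sub.iterrows())
            ]
            profiles.append(VolatileProfile(str(g), tuple(entries)))
    return profiles


def write_volatile_table(profiles: Sequence[VolatileProfile], path: str | Path) -> None:
    """Write profiles in the wide dialect (one content column per group)."""
    if not profiles:
        raise ValidationError("no profiles to write")
    base = profiles[0]
    cols: dict[str, list] = {
        "compound": [e.compound_id for e in base.entries],
        "category": [e.category for e in base.entries],
    }
    for p in profiles:
        contents = p.contents()
        cols[p.group_id] = [
            contents.get(normalize_compound_id(e.compound_id), 0.0) for e in base.entries
        ]
    pd.DataFrame(cols).to_csv(path, sep=_sep_for(path), index=False, float_format="%.17g")


def read_threshold_library(path: str | Path) -> tuple[ThresholdLibrary, int]:
    """Read ``compound,threshold_ug_per_kg[,odor_type[,source]]``.

    Rows with a missing threshold cell are skipped; the number skipped is
    returned alongside the library.  A non-positive threshold is an error.
    """
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    df.columns = [str(c).strip() for c in df.columns]
    for col in ("compound", "threshold_ug_per_kg"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    records, warnings = [], 0
    for i, row in df.iterrows():
        cell = row["threshold_ug_per_kg"]
        if cell is None or (isinstance(cell, float) and math.isnan(cell)) or str(cell).strip() == "":
            warnings += 1
            continue
        thr = _parse_number(str(cell).replace(",", ""), f"row {i + 2}")
        records.append(
            ThresholdRecord(
                compound_id=str(row["compound"]).strip(),
                threshold=thr,
                odor_type=str(row.get("odor_type", "") or ""),
                source=str(row.get("source", "") or ""),
            )
        )
    return ThresholdLibrary.from_records(records), warnings


def read_intensity_matrix(path: str | Path, group_map: Mapping[str, str] | None = None) -> IntensityMatrix:
    """Read a wide compounds-x-samples matrix.

    First column is ``compound_id``, an optional ``class`` column carries
    compound classes, remaining columns are samples.  Sample -> group mapping
    comes either from a ``#groups`` second header line (same delimiter) or
    from an explicit ``group_map``.
    """
    sep = _sep_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        second = fh.readline().rstrip("\n")
    inline_groups: dict[str, str] | None = None
    skip = [1] if second.startswith("#groups") else []
    if skip:
        head_cells = header.split(sep)
        group_cells = second.split(sep)
        if len(group_cells) != len(head_cells):
            raise ValidationError(f"{path}: '#groups' line has {len(group_cells)} cells, header has {len(head_cells)}")
        inline_groups = dict(zip(head_cells[1:], group_cells[1:]))
    df = pd.read_csv(path, sep=sep, skiprows=skip, index_col=0)
    df.index = df.index.astype(str)
    classes: dict[str, str] = {}
    if "class" in df.columns:
        classes = {normalize_compound_id(c): str(v) for c, v in df["class"].items()}
        df = df.drop(columns=["class"])
        if inline_groups is not None:
            inline_groups.pop("class", None)
    groups = dict(group_map or {})
    if inline_groups:
        groups = {**inline_groups, **groups}
    if not groups:
        raise ValidationError(f"{path}: no sample -> group mapping ('#groups' line or group_map)")
    if df.isna().any().any():
        raise ValidationError(f"{path}: ragged or missing cells in matrix")
    return IntensityMatrix(df, groups, classes)


def write_intensity_matrix(matrix: IntensityMatrix, path: str | Path) -> None:
    sep = _sep_for(path)
    with open(path, "w") as fh:
        fh.write("compound_id" + sep + sep.join(matrix.samples) + "\n")
        fh.write("#groups" + sep + sep.join(matrix.groups[s] for s in matrix.samples) + "\n")
        matrix.values.to_csv(fh, sep=sep, header=False, float_format="%.17g")


def read_gmt(path: str | Path) -> PathwayAnnotation:
    """Read a GMT pathway file: ``pathway_id<TAB>name<TAB>member...``."""
    pathways: dict[str, tuple[str, frozenset[str]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValidationError(f"{path}:{lineno}: GMT line needs id, name, >=1 member")
        pid, name, *members = parts
        if pid in pathways:
            raise ValidationError(f"{path}:{lineno}: duplicate pathway {pid!r}")
        pathways[pid] = (name, frozenset(m for m in members if m.strip()))
    return PathwayAnnotation(pathways)
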