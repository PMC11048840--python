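"""Differential-metabolite selection by VIP and log2 fold change.

For a pairwise contrast "A vs B" (A is the numerator) each compound gets a
log2 fold change of group-mean abundances and a VIP score from a two-group
OPLS-DA fitted on that contrast alone.  A compound is called *up* when
VIP > 1 and log2FC > 1, *down* when VIP > 1 and log2FC < -1, and not
significant otherwise — a conjunction, so a large fold change with a weak
VIP (or vice versa) is not called.  No p-value enters the rule.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .chemometrics import OPLSDA
from .io_core import (
    IntensityMatrix,
    PipelineConfig,
    ValidationError,
    normalize_compound_id,
)

CALLS = ("up", "down", "not_significant")


@dataclass(frozen=True)
class DifferentialRow:
    compound_id: str
    class_label: str
    mean_a: float
    mean_b: float
    log2fc: float
    vip: float
    call: str


@dataclass(frozen=True)
class DifferentialTable:
    contrast: tuple[str, str]  # (numerator group, denominator group)
    rows: tuple[DifferentialRow, ...]

    @property
    def n_up(self) -> int:
        return sum(r.call == "up" for r in self.rows)

    @property
    def n_down(self) -> int:
        return sum(r.call == "down" for r in self.rows)

    def selected(self) -> set[str]:
        """Compound ids called in either direction (volcano/enrichment input)."""
        return {r.compound_id for r in self.rows if r.call != "not_significant"}


def log2_fold_change(mean_a: float, mean_b: float, epsilon: float = 0.0) -> float:
    """log2((mean_a + eps) / (mean_b + eps)); eps guards zero means."""
    if mean_a < 0 or mean_b < 0:
        raise ValidationError("group means must be >= 0")
    if epsilon < 0:
        raise ValidationError("epsilon must be >= 0")
    if epsilon == 0 and (mean_a == 0 or mean_b == 0):
        raise ValidationError("zero mean with epsilon 0: fold change undefined")
    return math.log2((mean_a + epsilon) / (mean_b + epsilon))


def _call(log2fc: float, vip: float, cfg: PipelineConfig) -> str:
    if vip > cfg.vip_cutoff and log2fc > cfg.log2fc_cutoff:
        return "up"
    if vip > cfg.vip_cutoff and log2fc < -cfg.log2fc_cutoff:
        return "down"
    return "not_significant"


def call_differential(
    matrix: IntensityMatrix,
    contrast: tuple[str, str],
    config: PipelineConfig | None = None,
) -> DifferentialTable:
    """Select differential compounds for one pairwise contrast.

    VIP comes from an OPLS-DA fitted on the two contrast groups only (not a
    global model); fold changes use raw group means, with epsilon
    ``epsilon_fc x global median abundance`` applied only when a mean is zero.
    """
    cfg = config or PipelineConfig()
    group_a, group_b = contrast
    for g in contrast:
        n = len(matrix.samples_of(g))
        if n == 0:
            raise ValidationError(f"group {g!r} not present in matrix")
        if n < 2:
            raise ValidationError(f"group {g!r} has {n} sample(s); need >= 2")
    sub = matrix.subset_groups(contrast)
    labels = [sub.groups[s] for s in sub.samples]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # LOO fallback / variance drops
        model = OPLSDA(
            n_orthogonal=1,
            scaling=cfg.scaling_method,
            cv_folds=cfg.cv_folds,
            positive_label=group_a,
            compute_q2=False,
        ).fit(sub, labels)
    vips = model.vip_scores()

    cols_a = matrix.samples_of(group_a)
    cols_b = matrix.samples_of(group_b)
    means_a = matrix.values[cols_a].mean(axis=1)
    means_b = matrix.values[cols_b].mean(axis=1)
    global_median = float(np.median(matrix.values.to_numpy()))
    eps_abs = cfg.epsilon_fc * max(global_median, 1.0)

    rows = []
    for compound in matrix.compounds:
        ma, mb = float(means_a[compound]), float(means_b[compound])
        eps = eps_abs if (ma == 0 or mb == 0) else 0.0
        lfc = log2_fold_change(ma, mb, eps) if (ma + eps > 0 and mb + eps > 0) else 0.0
        v = vips.get(compound, 0.0)  # zero-variance compounds carry no VIP
        rows.append(
            DifferentialRow(
                compound_id=compound,
                class_label=matrix.classes.get(
                    normalize_compound_id(compound), matrix.classes.get(compound, "")
                ),
                mean_a=ma,
                mean_b=mb,
                log2fc=lfc,
                vip=v,
                call=_call(lfc, v, cfg),
            )
        )
    return DifferentialTable(contrast=(group_a, group_b), rows=tuple(rows))


def volcano_coordinates(table: DifferentialTable) -> list[tuple[str, float, float, str]]:
    """(compound, x=log2FC, y=VIP, call) points for a volcano-style plot."""
    return [(r.compound_id, r.log2fc, r.vip, r.call) for r in table.rows]
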