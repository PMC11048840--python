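"""Pathway over-representation analysis (ORA).

Given a selected compound set and a background, each pathway is scored with
the upper-tail hypergeometric probability of drawing at least the observed
overlap: with background size N, K background compounds in the pathway and a
selection of size n,

    p = P[X >= k],  X ~ Hypergeometric(N, K, n).

Benjamini-Hochberg q-values are reported across the tested pathways, but the
conventional significance flag uses the raw p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_core import (
    PathwayAnnotation,
    PipelineConfig,
    ValidationError,
    normalize_compound_id,
)


@dataclass(frozen=True)
class EnrichmentRow:
    pathway_id: str
    name: str
    n_background_in_pathway: int  # K
    n_selected: int  # n
    n_overlap: int  # k
    p_value: float
    q_value: float


@dataclass(frozen=True)
class EnrichmentResult:
    rows: tuple[EnrichmentRow, ...]
    background_size: int
    selected_size: int

    def significant(self, alpha: float = 0.05) -> list[EnrichmentRow]:
        return [r for r in self.rows if r.p_value < alpha]


def enrich(
    selected: set[str],
    background: set[str],
    annotation: PathwayAnnotation,
    config: PipelineConfig | None = None,
) -> EnrichmentResult:
    """Hypergeometric ORA of ``selected`` against ``background``.

    Pathways with no member in the background are skipped.  Compound ids are
    matched after normalization (case-insensitive, whitespace-trimmed).
    """
    cfg = config or PipelineConfig()
    if not background:
        raise ValidationError("background set is empty")
    sel = {normalize_compound_id(c) for c in selected}
    bg = {normalize_compound_id(c) for c in background}
    offenders = sorted(sel - bg)
    if offenders:
        raise ValidationError(f"selected compounds not in background: {offenders}")

    N, n = len(bg), len(sel)
    rows: list[EnrichmentRow] = []
    pvals: list[float] = []
    for pid in sorted(annotation.pathways):
        name, members = annotation.pathways[pid]
        in_bg = members & bg
        K = len(in_bg)
        if K == 0:
            continue
        k = len(in_bg & sel)
        # P[X >= k] via the survival function at k-1
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        p = min(max(p, 0.0), 1.0)
        rows.append(EnrichmentRow(pid, name, K, n, k, p, q_value=1.0))
        pvals.append(p)

    if rows and cfg.fdr_method == "benjamini_hochberg":
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
        rows = [
            EnrichmentRow(r.pathway_id, r.name, r.n_background_in_pathway,
                          r.n_selected, r.n_overlap, r.p_value, float(q))
            for r, q in zip(rows, qvals)
        ]
    return EnrichmentResult(tuple(rows), background_size=N, selected_size=n)


def rank_pathways(result: EnrichmentResult, top_n: int = 20) -> list[EnrichmentRow]:
    """Rows sorted ascending by p (ties by pathway id), truncated to top_n."""
    if top_n < 0:
        raise ValidationError("top_n must be >= 0")
    ordered = sorted(result.rows, key=lambda r: (r.p_value, r.pathway_id))
    return ordered[:top_n]
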