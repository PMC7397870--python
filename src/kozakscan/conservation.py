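"""Translation Initiation Efficiency Selection Score (TIESS).

For each gene an ortholog panel holds the start-codon context observed in
each aligned species.  The score is

    TIESS = sum_i log10(TIE_i / TIE_bar)

over all orthologs i whose context yields a TIE, where TIE_bar is the
arithmetic mean TIE over every scoreable (gene, species) start context in
the panel collection.  TIESS is far from zero only for genes whose context
strength deviates from the average consistently across species: a conserved
weak context accumulates negative terms, a conserved strong one positive
terms, and inconsistent or near-average contexts cancel toward zero.  The
raw sum grows with ortholog count; the per-ortholog mean deviation is
reported alongside as a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import math

from .cohort import select_extremes
from .context import TIETable
from .stats import ComparisonResult, rank_sum_test


@dataclass
class OrthologPanel:
    """Per-gene start-codon contexts across species; a None entry marks a
    species whose aligned position lacks an intact AUG or ungapped context."""

    gene_id: str
    entries: Dict[str, Optional[str]] = field(default_factory=dict)
    anchor: str = "saug"  # saug | fdaug


@dataclass
class TIESSRecord:
    gene_id: str
    tiess: float
    n_orthologs: int

    @property
    def mean_log_dev(self) -> float:
        return self.tiess / self.n_orthologs


def _panel_ties(panel: OrthologPanel, table: TIETable) -> List[float]:
    ties = []
    for ctx in panel.entries.values():
        tie = table.lookup(ctx)
        if tie is not None:
            ties.append(tie)
    return ties


def global_mean_tie(panels: Sequence[OrthologPanel], table: TIETable) -> float:
    """Arithmetic mean TIE over every scoreable (gene, species) entry."""
    total = 0.0
    count = 0
    for panel in panels:
        for tie in _panel_ties(panel, table):
            total += tie
            count += 1
    if count == 0:
        raise ValueError("no scoreable ortholog entries in any panel")
    return total / count


def tiess(
    panel: OrthologPanel, table: TIETable, tie_bar: float, min_orthologs: int = 1
) -> Optional[TIESSRecord]:
    """Score one panel; None (absent, not 0) when fewer than `min_orthologs`
    entries are scoreable."""
    if tie_bar <= 0:
        raise ValueError(f"tie_bar must be positive, got {tie_bar}")
    ties = _panel_ties(panel, table)
    if len(ties) < max(1, min_orthologs):
        return None
    score = sum(math.log10(t / tie_bar) for t in ties)
    return TIESSRecord(gene_id=panel.gene_id, tiess=score, n_orthologs=len(ties))


def score_panels(
    panels: Sequence[OrthologPanel],
    table: TIETable,
    tie_bar: Optional[float] = None,
    min_orthologs: int = 1,
) -> List[TIESSRecord]:
    """Score a panel collection, computing TIE_bar from it when not given."""
    if tie_bar is None:
        tie_bar = global_mean_tie(panels, table)
    records = []
    for panel in panels:
        rec = tiess(panel, table, tie_bar, min_orthologs=min_orthologs)
        if rec is not None:
            records.append(rec)
    return records


def conserved_sets(
    records: Sequence[TIESSRecord], fraction: float = 0.10
) -> Tuple[List[TIESSRecord], List[TIESSRecord]]:
    """Conserved-strong (highest TIESS) and conserved-weak (lowest) sets."""
    return select_extremes(
        records, key=lambda r: r.tiess, id_key=lambda r: r.gene_id, fraction=fraction
    )


@dataclass
class SkippedComparison:
    reason: str


def compare_tiess_by_frame(
    records: Sequence[TIESSRecord],
    frame_of: Dict[str, int],
    in_frames: Set[int] = frozenset({0}),
    out_frames: Set[int] = frozenset({1, 2}),
):
    """Rank-sum comparing TIESS between genes with in-frame vs out-of-frame
    fdAUGs.  Returns a ComparisonResult, or a SkippedComparison when a
    stratum has fewer than two scoreable genes."""
    xs = [r.tiess for r in records if frame_of.get(r.gene_id) in in_frames]
    ys = [r.tiess for r in records if frame_of.get(r.gene_id) in out_frames]
    if len(xs) < 2 or len(ys) < 2:
        return SkippedComparison(
            reason=f"stratum too small (in-frame n={len(xs)}, out-of-frame n={len(ys)})"
        )
    return rank_sum_test(xs, ys)
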