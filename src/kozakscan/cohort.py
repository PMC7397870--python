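"""Strong/weak context cohorts and their pairwise comparisons.

The strong cohort is the top fraction (default 10%) of annotated transcripts
by sAUG context strength, the weak cohort the bottom fraction.  The
comparisons mirror the catalog-level analyses: fdAUG frame proportions and
the frame-0 contrast, sAUG-fdAUG spacer distances, fdAUG-to-stop lengths
(including the nested-ORF lengths of out-of-frame fdAUGs), and fdAUG context
strengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Set, Tuple, TypeVar

from .annotate import StartPair
from .stats import ComparisonResult, chi2_2x2, rank_sum_test, welch_t_test

T = TypeVar("T")

FRAMES = (0, 1, 2)


def fraction_size(n: int, fraction: float) -> int:
    """Cohort size: round fraction*n to nearest, half away from zero
    (18,297 transcripts at 10% -> 1830)."""
    import math

    return int(math.floor(fraction * n + 0.5))


def select_extremes(
    items: Sequence[T], key: Callable[[T], float], id_key: Callable[[T], str],
    fraction: float = 0.10,
) -> Tuple[List[T], List[T]]:
    """Top and bottom `fraction` of items by `key`, ties broken by id.

    Selection is a pure function of (key, id): input order never changes
    membership.  The two sets are disjoint by construction (taken from the
    two ends of one canonical ordering).
    """
    if not (0 < fraction <= 0.5):
        raise ValueError(f"fraction must be in (0, 0.5], got {fraction}")
    n = len(items)
    k = fraction_size(n, fraction)
    if k < 1 or 2 * k > n:
        raise ValueError(
            f"cannot select disjoint top/bottom {fraction:.0%} cohorts from {n} items"
        )
    order = sorted(items, key=lambda it: (-key(it), id_key(it)))
    top = order[:k]
    bottom = order[-k:][::-1]  # ascending by key
    return top, bottom


@dataclass
class ContextCohort:
    label: str  # strong | weak
    members: List[StartPair]

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class FrameSummary:
    """fdAUG frame counts and proportions for one cohort."""

    counts: Dict[int, int]
    proportions: Dict[int, float]
    n: int


def select_deciles(
    pairs: Sequence[StartPair], fraction: float = 0.10
) -> Tuple[ContextCohort, ContextCohort]:
    """Strong (top) and weak (bottom) cohorts by sAUG TIE."""
    missing = [p.transcript_id for p in pairs if p.saug_tie is None]
    if missing:
        raise ValueError(f"{len(missing)} pairs lack a sAUG TIE (first: {missing[0]})")
    strong, weak = select_extremes(
        pairs, key=lambda p: p.saug_tie, id_key=lambda p: p.transcript_id, fraction=fraction
    )
    return ContextCohort("strong", strong), ContextCohort("weak", weak)


def frame_proportions(members: Sequence[StartPair]) -> FrameSummary:
    if not members:
        raise ValueError("empty cohort")
    counts = {f: 0 for f in FRAMES}
    for p in members:
        if p.frame is None:
            raise ValueError(f"{p.transcript_id} has no fdAUG frame")
        counts[p.frame] += 1
    n = len(members)
    return FrameSummary(counts=counts, proportions={f: counts[f] / n for f in FRAMES}, n=n)


def compare_frame0(strong: FrameSummary, weak: FrameSummary) -> ComparisonResult:
    """2x2 chi-squared on frame 0 vs not-0, strong vs weak, no continuity
    correction."""
    if strong.n < 20 or weak.n < 20:
        raise ValueError("frame-0 contrast requires at least 20 members per cohort")
    table = [
        [strong.counts[0], strong.n - strong.counts[0]],
        [weak.counts[0], weak.n - weak.counts[0]],
    ]
    return chi2_2x2(table)


def _metric_values(
    members: Iterable[StartPair], frame_filter: Set[int], metric: str
) -> Tuple[List[float], int]:
    """Metric values restricted to frames; unterminated fd_stop_nt values are
    excluded and counted."""
    values: List[float] = []
    excluded = 0
    for p in members:
        if p.frame not in frame_filter:
            continue
        if metric == "spacer_nt":
            if p.spacer_nt is not None:
                values.append(float(p.spacer_nt))
        elif metric == "fd_stop_nt":
            if p.fd_terminated and p.fd_stop_nt is not None:
                values.append(float(p.fd_stop_nt))
            else:
                excluded += 1
        else:
            raise ValueError(f"unknown metric {metric!r}")
    return values, excluded


def compare_distances(
    strong: ContextCohort,
    weak: ContextCohort,
    frame_filter: Set[int] = frozenset(FRAMES),
    metric: str = "spacer_nt",
) -> ComparisonResult:
    """Two-sided rank-sum on spacer or fdAUG-to-stop distances, restricted to
    the chosen frames."""
    xs, _ = _metric_values(strong.members, set(frame_filter), metric)
    ys, _ = _metric_values(weak.members, set(frame_filter), metric)
    if len(xs) < 3 or len(ys) < 3:
        raise ValueError(
            f"need >=3 members per side after filtering, got {len(xs)}/{len(ys)}"
        )
    return rank_sum_test(xs, ys)


def compare_fd_context(
    strong: ContextCohort, weak: ContextCohort, frame_filter: Set[int] = frozenset(FRAMES)
) -> ComparisonResult:
    """Welch's t-test on fdAUG context strength (TIE), restricted to frames."""
    xs = [p.fd_tie for p in strong.members if p.frame in frame_filter and p.fd_tie is not None]
    ys = [p.fd_tie for p in weak.members if p.frame in frame_filter and p.fd_tie is not None]
    if len(xs) < 3 or len(ys) < 3:
        raise ValueError(f"need >=3 non-miss fd TIEs per side, got {len(xs)}/{len(ys)}")
    return welch_t_test(xs, ys)


def compare_nested_orf_lengths(strong: ContextCohort, weak: ContextCohort) -> ComparisonResult:
    """Rank-sum on the lengths of ORFs under control of out-of-frame fdAUGs."""
    return compare_distances(strong, weak, frame_filter={1, 2}, metric="fd_stop_nt")
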