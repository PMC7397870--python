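"""Anchor-aligned metagene analysis of ribosome footprint tracks.

Tracks arrive as per-nucleotide counts in transcript coordinates, with
footprints already assigned to A-site codons (elongating ribosomes) or
P-site codons (initiating ribosomes).  Each included transcript is
normalized so that its mean CDS codon density is 1, counts are binned into
codons phased from the anchor AUG (offset 0 = the anchor codon itself), and
metagene profiles are per-offset medians across transcripts.  Window
densities average the normalized codon densities over an upstream window
(default -15..-3 codons) and a downstream window (default +10..+44 codons)
around the anchor.

Inclusion filters: CDS of at least 200 nt, at least 200 aligned footprints,
and, for sAUG-anchored profiles, a 5' leader of at least 45 nt — or, for
fdAUG-anchored profiles, an sAUG-fdAUG spacer strictly greater than 40 nt so
the upstream window is not contaminated by initiation at the sAUG.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .annotate import StartPair, Transcript
from .stats import ComparisonResult, rank_sum_test

ELONGATING = "elongating_A_site"
INITIATING = "initiating_P_site"


@dataclass
class FootprintTrack:
    transcript_id: str
    counts: np.ndarray  # per-nt non-negative counts, length == transcript length
    mode: str = ELONGATING

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if (self.counts < 0).any():
            raise ValueError(f"{self.transcript_id}: negative footprint counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetageneConfig:
    upstream_window: Tuple[int, int] = (-15, -3)  # closed, codon offsets
    downstream_window: Tuple[int, int] = (10, 44)
    min_cds_nt: int = 200
    min_footprints: int = 200
    min_leader_nt: int = 45
    min_spacer_nt: int = 40  # strict: spacer must exceed this
    offset_range: Tuple[int, int] = (-20, 50)  # closed codon-offset span of vectors
    min_transcripts_per_offset: int = 1

    def __post_init__(self) -> None:
        if self.upstream_window[1] >= self.downstream_window[0]:
            raise ValueError("upstream and downstream windows must not overlap")
        lo, hi = self.offset_range
        if lo > self.upstream_window[0] or hi < self.downstream_window[1]:
            raise ValueError("offset_range must cover both windows")

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(self.offset_range[0], self.offset_range[1] + 1)


@dataclass
class MetageneMatrix:
    """Per-transcript normalized codon-density vectors over a fixed codon
    offset range around the anchor; NaN marks offsets outside a transcript."""

    anchor: str  # saug | fdaug
    offsets: np.ndarray
    matrix: np.ndarray  # shape (n_transcripts, n_offsets)
    transcript_ids: List[str]


def apply_filters(
    transcripts: Dict[str, Transcript],
    tracks: Dict[str, FootprintTrack],
    pairs: Dict[str, StartPair],
    cfg: MetageneConfig,
    anchor: str,
) -> Tuple[List[str], List[Tuple[str, str]]]:
    """Inclusion filters; a transcript's inclusion depends only on its own
    record, so the result is order-independent.  A track whose length does
    not match its transcript is a hard error."""
    if anchor not in ("saug", "fdaug"):
        raise ValueError(f"anchor must be 'saug' or 'fdaug', got {anchor!r}")
    included: List[str] = []
    excluded: List[Tuple[str, str]] = []
    for tid in transcripts:
        t = transcripts[tid]
        track = tracks.get(tid)
        if track is None:
            excluded.append((tid, "no_track"))
            continue
        if len(track.counts) != len(t.seq):
            raise ValueError(
                f"{tid}: track length {len(track.counts)} != transcript length {len(t.seq)}"
            )
        if t.cds_len < cfg.min_cds_nt:
            excluded.append((tid, "short_cds"))
        elif track.total < cfg.min_footprints:
            excluded.append((tid, "few_footprints"))
        elif anchor == "saug" and t.leader_len < cfg.min_leader_nt:
            excluded.append((tid, "short_leader"))
        elif anchor == "fdaug":
            pair = pairs.get(tid)
            if pair is None or pair.spacer_nt is None:
                excluded.append((tid, "no_fdaug"))
            elif pair.spacer_nt <= cfg.min_spacer_nt:
                excluded.append((tid, "short_spacer"))
            else:
                included.append(tid)
        else:
            included.append(tid)
    return included, excluded


def cds_normalization_factor(track: FootprintTrack, transcript: Transcript) -> float:
    """Mean CDS counts per codon (the density unit: 1 = average CDS density)."""
    n_codons = transcript.cds_len // 3
    cds_counts = float(track.counts[transcript.cds_start : transcript.cds_start + 3 * n_codons].sum())
    return cds_counts / n_codons


def normalize_and_codonize(
    track: FootprintTrack,
    transcript: Transcript,
    anchor_pos: int,
    cfg: MetageneConfig,
) -> Optional[np.ndarray]:
    """Normalized codon-density vector over cfg.offset_range, phased from the
    anchor position (offset 0 = the anchor codon).  NaN where the codon falls
    outside the transcript.  None when the CDS has zero counts (the
    normalization is undefined and the transcript is excluded)."""
    factor = cds_normalization_factor(track, transcript)
    if factor == 0.0:
        return None
    offsets = cfg.offsets
    vec = np.full(len(offsets), np.nan)
    n = len(track.counts)
    for i, off in enumerate(offsets):
        start = anchor_pos + 3 * int(off)
        if start < 0 or start + 3 > n:
            continue
        vec[i] = float(track.counts[start : start + 3].sum()) / factor
    return vec


def build_matrix(
    included: Sequence[str],
    transcripts: Dict[str, Transcript],
    tracks: Dict[str, FootprintTrack],
    pairs: Dict[str, StartPair],
    cfg: MetageneConfig,
    anchor: str,
) -> Tuple[MetageneMatrix, List[Tuple[str, str]]]:
    """Assemble the per-transcript vector matrix for an anchor; transcripts
    with zero CDS counts are dropped with a logged reason."""
    rows: List[np.ndarray] = []
    ids: List[str] = []
    dropped: List[Tuple[str, str]] = []
    for tid in included:
        t = transcripts[tid]
        if anchor == "saug":
            anchor_pos = t.cds_start
        else:
            pair = pairs[tid]
            assert pair.fdaug_pos is not None
            anchor_pos = pair.fdaug_pos
        vec = normalize_and_codonize(tracks[tid], t, anchor_pos, cfg)
        if vec is None:
            dropped.append((tid, "zero_cds_counts"))
            continue
        rows.append(vec)
        ids.append(tid)
    matrix = np.vstack(rows) if rows else np.empty((0, len(cfg.offsets)))
    return MetageneMatrix(anchor=anchor, offsets=cfg.offsets, matrix=matrix, transcript_ids=ids), dropped


def metagene_profile(matrix: MetageneMatrix, min_transcripts: int = 1) -> np.ndarray:
    """Per-offset median density across transcripts; offsets with fewer than
    `min_transcripts` contributing transcripts are masked (NaN)."""
    if matrix.matrix.shape[0] < 1:
        raise ValueError("metagene profile requires at least one transcript")
    with np.errstate(all="ignore"):
        med = np.nanmedian(matrix.matrix, axis=0)
    contrib = np.sum(~np.isnan(matrix.matrix), axis=0)
    med[contrib < min_transcripts] = np.nan
    return med


def _window_mean(vec: np.ndarray, offsets: np.ndarray, window: Tuple[int, int]) -> Optional[float]:
    mask = (offsets >= window[0]) & (offsets <= window[1])
    values = vec[mask]
    if np.isnan(values).any():
        return None
    return float(values.mean())


def window_densities(
    matrix: MetageneMatrix, cfg: MetageneConfig
) -> Tuple[Dict[str, Tuple[float, float]], List[Tuple[str, str]]]:
    """Per-transcript (upstream mean, downstream mean) over the closed config
    windows; transcripts whose windows extend outside the vector are skipped
    with a reason."""
    result: Dict[str, Tuple[float, float]] = {}
    skipped: List[Tuple[str, str]] = []
    for tid, vec in zip(matrix.transcript_ids, matrix.matrix):
        up = _window_mean(vec, matrix.offsets, cfg.upstream_window)
        down = _window_mean(vec, matrix.offsets, cfg.downstream_window)
        if up is None or down is None:
            skipped.append((tid, "window_out_of_range"))
        else:
            result[tid] = (up, down)
    return result, skipped


def compare_window_densities(
    matrix_a: MetageneMatrix, matrix_b: MetageneMatrix, cfg: MetageneConfig
) -> Dict[str, ComparisonResult]:
    """Rank-sum tests on per-transcript window means merged across genes,
    cohort A vs cohort B, separately for the upstream and downstream
    windows."""
    dens_a, _ = window_densities(matrix_a, cfg)
    dens_b, _ = window_densities(matrix_b, cfg)
    if len(dens_a) < 3 or len(dens_b) < 3:
        raise ValueError(f"need >=3 transcripts per side, got {len(dens_a)}/{len(dens_b)}")
    out = {}
    for name, idx in (("upstream", 0), ("downstream", 1)):
        xs = [v[idx] for v in dens_a.values()]
        ys = [v[idx] for v in dens_b.values()]
        out[name] = rank_sum_test(xs, ys)
    return out


def step_change(
    track: FootprintTrack, transcript: Transcript, fdaug_pos: int, cfg: MetageneConfig
) -> Optional[float]:
    """Per-transcript downstream/upstream window-density ratio, both windows
    anchored at the fdAUG.  None (undefined) when the upstream mean is zero
    or a window is out of range."""
    vec = normalize_and_codonize(track, transcript, fdaug_pos, cfg)
    if vec is None:
        return None
    up = _window_mean(vec, cfg.offsets, cfg.upstream_window)
    down = _window_mean(vec, cfg.offsets, cfg.downstream_window)
    if up is None or down is None or up == 0.0:
        return None
    return down / up


def pooled_step_change(matrix: MetageneMatrix, cfg: MetageneConfig) -> float:
    """Cohort-level step change: ratio of the across-transcript mean window
    densities (downstream over upstream).

    Pooling before dividing avoids the upward bias of averaging
    per-transcript ratios when upstream window counts are small.
    """
    dens, _ = window_densities(matrix, cfg)
    if not dens:
        raise ValueError("no transcripts with both windows in range")
    ups = np.array([v[0] for v in dens.values()])
    downs = np.array([v[1] for v in dens.values()])
    if ups.mean() == 0.0:
        raise ValueError("zero pooled upstream density")
    return float(downs.mean() / ups.mean())


def peak_density(matrix: MetageneMatrix) -> float:
    """Median density at offset 0 — the anchor-codon peak reported for
    initiating-ribosome (P-site) tracks."""
    i = int(np.where(matrix.offsets == 0)[0][0])
    with np.errstate(all="ignore"):
        return float(np.nanmedian(matrix.matrix[:, i]))
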