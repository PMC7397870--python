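"""Transcript catalog filtering and start-pair annotation.

A catalog is a set of mRNA transcripts with annotated CDS intervals.  For
each transcript we locate the annotated start codon (sAUG, at the CDS start)
and the first downstream AUG (fdAUG) within the CDS, classify the fdAUG
reading frame relative to the sAUG, and measure spacer and ORF-length
metrics.  Filtering reproduces the catalog construction rules: an AUG at the
CDS start, at least 6 nt of upstream flank (needed for the context), an
fdAUG present within the CDS, and per-gene deduplication of isoforms whose
sequence stretch from 6 nt upstream of the sAUG through 15 nt past the fdAUG
codon is identical (the longest isoform is kept).

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .context import TIETable, extract_context, normalize_nt

STOP_CODONS = frozenset({"UAA", "UAG", "UGA"})

# rejection reasons, in the order the rules are applied
MALFORMED_CDS = "malformed_cds"
NO_AUG_START = "no_aug_start"
SHORT_UPSTREAM_FLANK = "short_upstream_flank"
NO_FDAUG_IN_CDS = "no_fdaug_in_cds"
DUPLICATE_STRETCH = "duplicate_stretch"


@dataclass
class Transcript:
    """An mRNA with a CDS given as a 0-based half-open interval."""

    id: str
    gene_id: str
    seq: str
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        self.seq = normalize_nt(self.seq)
        if not (0 <= self.cds_start < self.cds_end <= len(self.seq)):
            raise ValueError(
                f"{self.id}: CDS [{self.cds_start},{self.cds_end}) outside sequence of "
                f"length {len(self.seq)}"
            )

    @property
    def cds_len(self) -> int:
        return self.cds_end - self.cds_start

    @property
    def leader_len(self) -> int:
        return self.cds_start


@dataclass
class StartPair:
    """sAUG/fdAUG annotation for one transcript — the unit of the cohort
    statistics (frames, distances, stop distances, context strengths)."""

    transcript_id: str
    gene_id: str
    saug_pos: int
    fdaug_pos: Optional[int] = None
    frame: Optional[int] = None
    spacer_nt: Optional[int] = None
    saug_context: Optional[str] = None
    fd_context: Optional[str] = None
    saug_tie: Optional[float] = None
    fd_tie: Optional[float] = None
    fd_stop_nt: Optional[int] = None  # None + fd_terminated=False => unterminated
    fd_terminated: bool = False


@dataclass
class RejectionLog:
    """Per-transcript rejection reasons; kept + rejected partition the input."""

    entries: List[Tuple[str, str]] = field(default_factory=list)

    def add(self, transcript_id: str, reason: str) -> None:
        self.entries.append((transcript_id, reason))

    def reasons(self) -> Dict[str, str]:
        return dict(self.entries)

    def count(self, reason: str) -> int:
        return sum(1 for _, r in self.entries if r == reason)

    def __len__(self) -> int:
        return len(self.entries)


def find_fdaug(t: Transcript) -> Optional[int]:
    """Smallest p >= cds_start+1 with an AUG whose codon fits in the CDS
    (p+3 <= cds_end); overlapping AUGs are legal hits.  Independent of the
    3' UTR: the first AUG after the sAUG either fits in the CDS or none does.
    """
    p = t.seq.find("AUG", t.cds_start + 1)
    if p != -1 and p + 3 <= t.cds_end:
        return p
    return None


def classify_frame(saug_pos: int, fdaug_pos: int) -> int:
    """(fdaug - saug) mod 3; 0 means in-frame."""
    if fdaug_pos <= saug_pos:
        raise ValueError(f"fdAUG position {fdaug_pos} not downstream of sAUG {saug_pos}")
    return (fdaug_pos - saug_pos) % 3


def stop_distance(t: Transcript, start_pos: int) -> Optional[int]:
    """Coding nt from the AUG at start_pos to its first in-frame stop codon.

    The stop itself is excluded from the count.  The search runs to the end
    of the transcript (not the CDS end), so out-of-frame ORFs may terminate
    inside the 3' UTR.  Returns None when no in-frame stop exists before the
    transcript end (unterminated).
    """
    if t.seq[start_pos : start_pos + 3] != "AUG":
        raise ValueError(f"{t.id}: no AUG at {start_pos}")
    k = 3
    n = len(t.seq)
    while start_pos + k + 3 <= n:
        if t.seq[start_pos + k : start_pos + k + 3] in STOP_CODONS:
            return k
        k += 3
    return None


def scan_downstream_of_cds(t: Transcript) -> Optional[int]:
    """First AUG starting at or after the CDS end (3' UTR fdAUG scan)."""
    p = t.seq.find("AUG", t.cds_end)
    return p if p != -1 else None


def _dedup_stretch(t: Transcript, fdaug_pos: int) -> str:
    # 6 nt upstream of the sAUG through 15 nt past the fdAUG codon
    return t.seq[t.cds_start - 6 : fdaug_pos + 18]


def filter_catalog(
    transcripts: Sequence[Transcript],
) -> Tuple[List[Transcript], RejectionLog]:
    """Apply catalog construction rules in order; every input transcript ends
    up either kept or logged with exactly one rejection reason."""
    log = RejectionLog()
    candidates: List[Tuple[Transcript, int]] = []
    for t in transcripts:
        if t.cds_len % 3 != 0:
            log.add(t.id, MALFORMED_CDS)
        elif t.seq[t.cds_start : t.cds_start + 3] != "AUG":
            log.add(t.id, NO_AUG_START)
        elif t.cds_start < 6:
            log.add(t.id, SHORT_UPSTREAM_FLANK)
        else:
            fd = find_fdaug(t)
            if fd is None:
                log.add(t.id, NO_FDAUG_IN_CDS)
            else:
                candidates.append((t, fd))

    # per-gene deduplication over the identical stretch; keep the longest,
    # ties broken by lexicographically smallest id
    groups: Dict[Tuple[str, str], List[Transcript]] = {}
    for t, fd in candidates:
        groups.setdefault((t.gene_id, _dedup_stretch(t, fd)), []).append(t)
    kept_ids = set()
    for members in groups.values():
        winner = min(members, key=lambda t: (-len(t.seq), t.id))
        kept_ids.add(winner.id)
    kept: List[Transcript] = []
    for t, _ in candidates:
        if t.id in kept_ids:
            kept.append(t)
        else:
            log.add(t.id, DUPLICATE_STRETCH)
    return kept, log


def annotate_pair(t: Transcript, table: TIETable) -> StartPair:
    """Fully populate the StartPair of a kept transcript; context and table
    misses propagate as None rather than raising."""
    saug = t.cds_start
    pair = StartPair(transcript_id=t.id, gene_id=t.gene_id, saug_pos=saug)
    pair.saug_context = extract_context(t.seq, saug)
    pair.saug_tie = table.lookup(pair.saug_context)
    fd = find_fdaug(t)
    if fd is not None:
        pair.fdaug_pos = fd
        pair.spacer_nt = fd - saug
        pair.frame = classify_frame(saug, fd)
        pair.fd_context = extract_context(t.seq, fd)
        pair.fd_tie = table.lookup(pair.fd_context)
        dist = stop_distance(t, fd)
        pair.fd_stop_nt = dist
        pair.fd_terminated = dist is not None
    return pair


def annotate_catalog(
    transcripts: Sequence[Transcript], table: TIETable
) -> Tuple[List[StartPair], RejectionLog]:
    """filter_catalog followed by annotate_pair on every kept transcript."""
    kept, log = filter_catalog(transcripts)
    return [annotate_pair(t, table) for t in kept], log


# ---------------------------------------------------------------------------
# Tabular round-trip

_PAIR_COLUMNS = [
    "transcript_id",
    "gene_id",
    "saug_pos",
    "fdaug_pos",
    "frame",
    "spacer_nt",
    "saug_context",
    "fd_context",
    "saug_tie",
    "fd_tie",
    "fd_stop_nt",
    "fd_terminated",
]


def pairs_to_frame(pairs: Sequence[StartPair]) -> pd.DataFrame:
    rows = [{col: getattr(p, col) for col in _PAIR_COLUMNS} for p in pairs]
    return pd.DataFrame(rows, columns=_PAIR_COLUMNS)


def frame_to_pairs(df: pd.DataFrame) -> List[StartPair]:
    pairs = []
    for row in df.to_dict("records"):
        kwargs = {}
        for col in _PAIR_COLUMNS:
            val = row[col]
            if pd.isna(val):
                val = None
            elif col in ("saug_pos", "fdaug_pos", "frame", "spacer_nt", "fd_stop_nt"):
                val = int(val)
            elif col in ("saug_tie", "fd_tie"):
                val = float(val)
            elif col == "fd_terminated":
                val = bool(val)
            kwargs[col] = val
        pairs.append(StartPair(**kwargs))
    return pairs
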