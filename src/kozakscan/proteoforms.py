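"""In-silico tryptic digestion and peptide support for alternative proteoforms.

When a transcript produces both a long (sAUG-initiated) proteoform and an
N-terminally truncated one (fdAUG-initiated, in frame), mass-spectrometry
peptide observation frequencies can arbitrate between them: peptides drawn
from the shared C-terminal region should be observed at least as often as
peptides unique to the long form's N terminus, and much more often if the
truncated form dominates.  This module digests the long proteoform with
trypsin rules (cleave after K or R, except before P), classifies each
peptide as unique to the long form or shared, applies a detectability length
window, and summarizes observation frequencies per class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Seq import Seq

from .annotate import Transcript

UNIQUE_LONG = "unique_long"
SHARED = "shared"

DEFAULT_MIN_DETECTABLE = 7
DEFAULT_MAX_DETECTABLE = 30


@dataclass
class ProteoformPair:
    """The long proteoform sequence and the residue index of the Met encoded
    by the in-frame fdAUG (the truncated form's start)."""

    long_protein: str
    fd_met_index: int

    def __post_init__(self) -> None:
        if not (0 < self.fd_met_index < len(self.long_protein)):
            raise ValueError("fd_met_index must lie strictly inside the protein")
        if self.long_protein[self.fd_met_index] != "M":
            raise ValueError(
                f"residue at fd_met_index is {self.long_protein[self.fd_met_index]!r}, not M"
            )


@dataclass
class PeptideCall:
    peptide: str
    start: int  # 0-based residue interval [start, end) in the long proteoform
    end: int
    klass: Optional[str] = None  # unique_long | shared
    detectable: Optional[bool] = None
    observation_frequency: Optional[float] = None


def translate_from(transcript: Transcript, start_pos: int) -> Tuple[str, bool]:
    """Standard-code translation from the AUG at start_pos until the first
    stop codon or the transcript end.  Returns (protein, terminated)."""
    seq = transcript.seq
    if seq[start_pos : start_pos + 3] != "AUG":
        raise ValueError(f"{transcript.id}: no AUG at {start_pos}")
    tail = seq[start_pos:]
    tail = tail[: len(tail) - len(tail) % 3]
    full = str(Seq(tail).translate())
    stop = full.find("*")
    if stop == -1:
        return full, False
    return full[:stop], True


def tryptic_digest(protein: str) -> List[PeptideCall]:
    """Fully tryptic digest (zero missed cleavages): cleave after K or R
    unless the next residue is P.  Spans tile the protein exactly."""
    if not protein:
        raise ValueError("empty protein")
    spans: List[PeptideCall] = []
    start = 0
    for i, aa in enumerate(protein):
        at_end = i == len(protein) - 1
        if at_end or (aa in "KR" and protein[i + 1] != "P"):
            spans.append(PeptideCall(peptide=protein[start : i + 1], start=start, end=i + 1))
            start = i + 1
    return spans


def merge_missed_cleavages(spans: Sequence[PeptideCall], missed: int) -> List[PeptideCall]:
    """Peptides with up to `missed` missed cleavages (concatenations of
    adjacent fully tryptic spans)."""
    if missed < 0:
        raise ValueError("missed cleavages must be non-negative")
    out: List[PeptideCall] = []
    for i in range(len(spans)):
        for m in range(missed + 1):
            j = i + m
            if j >= len(spans):
                break
            out.append(
                PeptideCall(
                    peptide="".join(s.peptide for s in spans[i : j + 1]),
                    start=spans[i].start,
                    end=spans[j].end,
                )
            )
    return out


def classify_peptides(
    spans: Sequence[PeptideCall],
    pair: ProteoformPair,
    min_detectable: int = DEFAULT_MIN_DETECTABLE,
    max_detectable: int = DEFAULT_MAX_DETECTABLE,
) -> List[PeptideCall]:
    """A peptide is unique to the long proteoform iff its span includes any
    residue upstream of the fdAUG-encoded Met; otherwise it is shared.
    Detectable peptides fall in the [min, max] residue length window."""
    calls = []
    for s in spans:
        klass = UNIQUE_LONG if s.start < pair.fd_met_index else SHARED
        calls.append(
            PeptideCall(
                peptide=s.peptide,
                start=s.start,
                end=s.end,
                klass=klass,
                detectable=min_detectable <= len(s.peptide) <= max_detectable,
                observation_frequency=s.observation_frequency,
            )
        )
    return calls


def attach_frequencies(
    calls: Sequence[PeptideCall], frequencies: Dict[str, float]
) -> List[PeptideCall]:
    out = []
    for c in calls:
        freq = frequencies.get(c.peptide)
        out.append(
            PeptideCall(
                peptide=c.peptide, start=c.start, end=c.end, klass=c.klass,
                detectable=c.detectable, observation_frequency=freq,
            )
        )
    return out


@dataclass
class SupportSummary:
    median_by_class: Dict[str, Optional[float]]
    max_by_class: Dict[str, Optional[float]]
    ratio_shared_over_unique: Optional[float]  # None with infinite=True when unique median is 0
    infinite_ratio: bool
    n_by_class: Dict[str, int]


def support_summary(calls: Sequence[PeptideCall]) -> SupportSummary:
    """Median/max observation frequency per class among detectable peptides,
    and the shared/unique_long median ratio (flagged infinite when the
    unique median is zero); classes lacking detectable peptides with
    frequencies are reported as absent."""
    by_class: Dict[str, List[float]] = {UNIQUE_LONG: [], SHARED: []}
    for c in calls:
        if c.detectable and c.observation_frequency is not None and c.klass in by_class:
            by_class[c.klass].append(c.observation_frequency)
    med = {
        k: (float(np.median(v)) if v else None) for k, v in by_class.items()
    }
    mx = {k: (float(max(v)) if v else None) for k, v in by_class.items()}
    ratio: Optional[float] = None
    infinite = False
    if med[UNIQUE_LONG] is not None and med[SHARED] is not None:
        if med[UNIQUE_LONG] == 0.0:
            infinite = med[SHARED] > 0.0
            ratio = None if infinite else None
        else:
            ratio = med[SHARED] / med[UNIQUE_LONG]
    return SupportSummary(
        median_by_class=med,
        max_by_class=mx,
        ratio_shared_over_unique=ratio,
        infinite_ratio=infinite,
        n_by_class={k: len(v) for k, v in by_class.items()},
    )
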