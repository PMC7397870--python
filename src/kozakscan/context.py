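"""Kozak context strings and translation initiation efficiency (TIE) models.

The initiation context of an AUG codon is represented as an 11-mer covering
positions -6..-1, +1..+3 (the AUG itself, +1 = A), and +4..+5.  Context
strength is a positive scalar TIE on an arbitrary linear scale, either looked
up from a measured table (e.g. FACS-seq-style measurements supplied as a TSV)
or computed from a multiplicative position-weight model.  The default weight
model is calibrated so that exactly the degenerate pattern RYMRMVAUGGC
(R=A/G, Y=C/U, M=A/C, V=A/C/G) attains the maximal score, matching the
experimentally determined optimum, with the -3 and +4 positions carrying the
largest dynamic range.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, Optional, TextIO, Tuple, Union

import numpy as np

RNA_ALPHABET = "ACGU"
CONTEXT_LENGTH = 11

#: flank positions scored by the weight model (the AUG core is fixed)
FLANK_POSITIONS: Tuple[int, ...] = (-6, -5, -4, -3, -2, -1, 4, 5)

#: string index of each flank position inside the 11-mer (0-based)
_FLANK_INDEX: Dict[int, int] = {-6: 0, -5: 1, -4: 2, -3: 3, -2: 4, -1: 5, 4: 9, 5: 10}


def normalize_nt(seq: str) -> str:
    """Uppercase and map DNA T to RNA U (RefSeq mRNA files use T)."""
    return seq.upper().replace("T", "U")


def normalize_context(seq: str) -> str:
    """Validate and normalize an 11-nt context string.

    Raises ValueError on wrong length, non-ACGU characters (after T->U), or a
    core that is not AUG.
    """
    ctx = normalize_nt(seq)
    if len(ctx) != CONTEXT_LENGTH:
        raise ValueError(f"context must be {CONTEXT_LENGTH} nt, got {len(ctx)}: {seq!r}")
    if any(c not in RNA_ALPHABET for c in ctx):
        raise ValueError(f"context contains non-ACGU characters: {seq!r}")
    if ctx[6:9] != "AUG":
        raise ValueError(f"context core (positions +1..+3) must be AUG: {seq!r}")
    return ctx


# ---------------------------------------------------------------------------
# Position weight model


@dataclass(frozen=True)
class PositionWeightScheme:
    """Multiplicative per-position weight model for context strength.

    TIE(context) = base * prod over the eight flank positions of
    weights[pos][nt].  Every multiplier lies in (0, 1] and each position has
    at least one nucleotide with multiplier 1, so `base` is the attainable
    maximum.
    """

    base: float = 150.0
    weights: Tuple[Tuple[int, Tuple[Tuple[str, float], ...]], ...] = ()

    def weight(self, pos: int, nt: str) -> float:
        return self._table[pos][nt]

    @property
    def _table(self) -> Dict[int, Dict[str, float]]:
        tbl = getattr(self, "_table_cache", None)
        if tbl is None:
            tbl = {pos: dict(entries) for pos, entries in self.weights}
            object.__setattr__(self, "_table_cache", tbl)
        return tbl

    def validate(self) -> None:
        if self.base <= 0:
            raise ValueError("base must be positive")
        tbl = self._table
        if set(tbl) != set(FLANK_POSITIONS):
            raise ValueError(f"weights must cover positions {FLANK_POSITIONS}")
        for pos, by_nt in tbl.items():
            if set(by_nt) != set(RNA_ALPHABET):
                raise ValueError(f"position {pos} must weight all of ACGU")
            for nt, w in by_nt.items():
                if not (0 < w <= 1):
                    raise ValueError(f"weight[{pos}][{nt}]={w} outside (0,1]")
            if max(by_nt.values()) != 1.0:
                raise ValueError(f"position {pos} needs at least one multiplier of 1")


def _freeze(weights: Dict[int, Dict[str, float]]):
    return tuple(sorted((pos, tuple(sorted(by_nt.items()))) for pos, by_nt in weights.items()))


#: Default weights.  The arg-max set is exactly RYMRMVAUGGC; -3 and +4 have
#: the widest dynamic range.
_DEFAULT_WEIGHTS: Dict[int, Dict[str, float]] = {
    -6: {"A": 1.0, "G": 1.0, "C": 0.8, "U": 0.8},
    -5: {"C": 1.0, "U": 1.0, "A": 0.8, "G": 0.8},
    -4: {"A": 1.0, "C": 1.0, "G": 0.8, "U": 0.8},
    -3: {"A": 1.0, "G": 1.0, "C": 0.5, "U": 0.45},
    -2: {"A": 1.0, "C": 1.0, "G": 0.85, "U": 0.8},
    -1: {"G": 1.0, "C": 1.0, "A": 1.0, "U": 0.75},
    4: {"G": 1.0, "A": 0.7, "C": 0.65, "U": 0.6},
    5: {"C": 1.0, "A": 0.9, "G": 0.9, "U": 0.85},
}

DEFAULT_SCHEME = PositionWeightScheme(base=150.0, weights=_freeze(_DEFAULT_WEIGHTS))
DEFAULT_SCHEME.validate()


def synthetic_tie(context: str, scheme: PositionWeightScheme = DEFAULT_SCHEME) -> float:
    """Deterministic parametric TIE for a context under a weight scheme."""
    ctx = normalize_context(context)
    tie = scheme.base
    for pos, idx in _FLANK_INDEX.items():
        tie *= scheme.weight(pos, ctx[idx])
    return tie


_FLANK_CACHE: Dict[Tuple, Tuple[Tuple[str, ...], np.ndarray]] = {}


def enumerate_flank_ties(
    scheme: PositionWeightScheme = DEFAULT_SCHEME,
) -> Tuple[Tuple[str, ...], np.ndarray]:
    """All 4^8 flank combinations (8-char strings, context order) and their TIEs.

    The flank string concatenates the -6..-1 hexamer with the +4+5 dimer; the
    corresponding 11-mer is flank[:6] + "AUG" + flank[6:].
    """
    key = (scheme.base, scheme.weights)
    if key not in _FLANK_CACHE:
        per_pos = []
        for pos in FLANK_POSITIONS:
            per_pos.append(np.array([scheme.weight(pos, nt) for nt in RNA_ALPHABET]))
        ties = np.full(1, scheme.base)
        for w in per_pos:
            ties = np.multiply.outer(ties, w).ravel()
        flanks = tuple(
            "".join(combo) for combo in itertools.product(RNA_ALPHABET, repeat=len(FLANK_POSITIONS))
        )
        _FLANK_CACHE[key] = (flanks, ties)
    return _FLANK_CACHE[key]


def flank_to_context(flank: str) -> str:
    """Insert the AUG core into an 8-char flank string."""
    return flank[:6] + "AUG" + flank[6:]


# ---------------------------------------------------------------------------
# TIE tables


@dataclass
class TIETable:
    """Mapping from 11-nt context to TIE.

    Lookups of contexts absent from the table are explicit misses (None),
    never silently zero, so filtering stages can count them.
    """

    entries: Dict[str, float] = field(default_factory=dict)
    provenance: str = "measured"

    def __post_init__(self) -> None:
        for ctx, val in self.entries.items():
            if val <= 0:
                raise ValueError(f"TIE for {ctx} must be positive, got {val}")

    def lookup(self, context: Optional[str]) -> Optional[float]:
        if context is None:
            return None
        return self.entries.get(normalize_context(context))

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, context: str) -> bool:
        return normalize_context(context) in self.entries


def synthetic_table(scheme: PositionWeightScheme = DEFAULT_SCHEME) -> TIETable:
    """Complete TIE table over every possible context under a weight scheme."""
    flanks, ties = enumerate_flank_ties(scheme)
    entries = {flank_to_context(f): float(t) for f, t in zip(flanks, ties)}
    return TIETable(entries=entries, provenance="synthetic")


def load_tie_table(source: Union[str, Path, TextIO, Iterable[str]]) -> TIETable:
    """Load a measured TIE table from TSV (`context<TAB>tie`, '#' comments).

    DNA-alphabet contexts are normalized to RNA.  Duplicate keys, malformed
    11-mers, and non-positive values are hard errors naming the offender.
    """
    close = False
    if isinstance(source, (str, Path)):
        stream: Iterator[str] = open(source)
        close = True
    else:
        stream = iter(source)
    entries: Dict[str, float] = {}
    try:
        for lineno, raw in enumerate(stream, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"line {lineno}: expected 2 tab-separated fields, got {len(parts)}")
            try:
                ctx = normalize_context(parts[0])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from None
            try:
                value = float(parts[1])
            except ValueError:
                raise ValueError(f"line {lineno}: non-numeric TIE {parts[1]!r}") from None
            if value <= 0:
                raise ValueError(f"line {lineno}: non-positive TIE {value} for {ctx}")
            if ctx in entries:
                raise ValueError(f"duplicate context key {ctx}")
            entries[ctx] = value
    finally:
        if close:
            stream.close()  # type: ignore[union-attr]
    return TIETable(entries=entries, provenance="measured")


def write_tie_table(table: TIETable, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("#context\ttie\n")
        for ctx, val in table.entries.items():
            fh.write(f"{ctx}\t{val:.10g}\n")


# ---------------------------------------------------------------------------
# Context extraction and diagnostics


def extract_context(seq: str, aug_pos: int) -> Optional[str]:
    """The 11-mer context of the AUG at `aug_pos` (0-based), or a miss.

    Returns None when fewer than 6 nt precede or fewer than 2 nt follow the
    AUG; raises if there is no AUG at `aug_pos` (a caller bug).
    """
    s = normalize_nt(seq)
    if s[aug_pos : aug_pos + 3] != "AUG":
        raise ValueError(f"no AUG at position {aug_pos}")
    if aug_pos < 6 or aug_pos + 5 > len(s):
        return None
    return s[aug_pos - 6 : aug_pos + 5]


def rank_percentile(table: TIETable, context: str) -> Optional[float]:
    """Percentile rank of a context's TIE within a table, ties sharing the
    lower rank: 100 * (fraction of entries strictly below)."""
    value = table.lookup(context)
    if value is None:
        return None
    below = sum(1 for v in table.entries.values() if v < value)
    return 100.0 * below / len(table)
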