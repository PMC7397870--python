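"""Synthetic transcript catalogs, ortholog panels, and footprint tracks.

The generator produces data with the statistical structure the analysis
assumes, plus a ground-truth table for parameter-recovery testing:

* Transcripts: each gene gets an AUG-free 5' leader (>=45 nt), a CDS whose
  start context is drawn from the strong (top) or weak (bottom) stratum of
  the synthetic context-strength distribution, exactly one engineered fdAUG
  at a drawn spacer and frame with no earlier accidental AUG, a terminal
  in-frame stop, and a 3' UTR.  Frame-0 probabilities are class-conditional;
  the defaults are the catalog-level proportions observed for weak (0.524)
  and strong (0.380) start contexts, with frame 2 depleted (stop-codon
  avoidance: an A after a frame-2 fdAUG spells UGA in frame 0).
* Ortholog panels: each of S species keeps a context from the gene's class
  stratum with probability c (the conservation probability) and otherwise
  draws from the background context distribution.
* Footprint tracks: a leaky-scanning initiation model.  The probability of
  initiating at an AUG is P_init = min(1, TIE / TIE_ref); the scanning flux
  reaching the fdAUG is (1 - P_init(sAUG)), so the fdAUG initiation flux is
  (1 - P_init(sAUG)) * P_init(fdAUG).  Elongating-mode expected density is
  proportional to the sAUG flux between the starts and to the summed flux
  downstream of the fdAUG (until the fdAUG-frame stop); initiating-mode
  tracks are point masses at the two start codons.  Counts are independent
  Poisson draws per nucleotide.

All draws derive from the config seed; runs are byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotate import STOP_CODONS, Transcript, classify_frame, stop_distance
from .context import (
    DEFAULT_SCHEME,
    PositionWeightScheme,
    TIETable,
    enumerate_flank_ties,
    extract_context,
    flank_to_context,
    synthetic_table,
    synthetic_tie,
)
from .conservation import OrthologPanel
from .metagene import ELONGATING, INITIATING, FootprintTrack

_NT = np.array(list("ACGU"))
_SENSE_CODONS = [
    a + b + c
    for a in "ACGU"
    for b in "ACGU"
    for c in "ACGU"
    if a + b + c not in STOP_CODONS
]
_STOPS = sorted(STOP_CODONS)


@dataclass
class SimConfig:
    """Generator settings; the defaults are the study conditions the
    analysis modules are exercised under."""

    n_genes: int = 200
    p_weak: float = 0.5
    p_frame0_given_weak: float = 0.524
    p_frame0_given_strong: float = 0.380
    p_frame2_given_weak: float = 0.096
    p_frame2_given_strong: float = 0.113
    spacer_mean_weak: float = 60.0
    spacer_mean_strong: float = 90.0
    min_spacer_nt: int = 4
    leader_len_range: Tuple[int, int] = (45, 75)
    utr_len_range: Tuple[int, int] = (20, 60)
    tail_codons_range: Tuple[int, int] = (50, 90)
    strong_quantile: float = 0.10  # top fraction of context TIEs = strong stratum
    weak_quantile: float = 0.10  # bottom fraction = weak stratum
    n_species: int = 50
    conservation: float = 0.9
    na_rate: float = 0.02
    tie_ref: float = 150.0  # leak model reference; optimal context => P_init = 1
    depth: float = 0.5  # expected reads per nt per unit of flux
    background_rate: float = 0.01  # background expected reads per nt (x depth)
    init_peak_scale: float = 20.0  # initiating-mode peak amplification
    p_init_saug_override: Optional[float] = None
    p_init_fd_override: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "p_weak", "p_frame0_given_weak", "p_frame0_given_strong",
            "p_frame2_given_weak", "p_frame2_given_strong", "conservation", "na_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.min_spacer_nt < 4:
            raise ValueError("min_spacer_nt must be >= 4")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.leader_len_range[0] < 45:
            raise ValueError("leader length minimum must be >= 45 nt")
        for cls in ("weak", "strong"):
            p0 = getattr(self, f"p_frame0_given_{cls}")
            p2 = getattr(self, f"p_frame2_given_{cls}")
            if p0 + p2 > 1.0:
                raise ValueError(f"frame probabilities for {cls} exceed 1")


@dataclass
class _Strata:
    """Context flanks partitioned by TIE quantile under the weight scheme."""

    strong_flanks: List[str]
    weak_flanks: List[str]
    all_flanks: Tuple[str, ...]
    ties: np.ndarray


def build_strata(cfg: SimConfig, scheme: PositionWeightScheme = DEFAULT_SCHEME) -> _Strata:
    flanks, ties = enumerate_flank_ties(scheme)
    order = np.argsort(ties, kind="stable")
    n = len(flanks)
    k_weak = max(1, int(round(cfg.weak_quantile * n)))
    k_strong = max(1, int(round(cfg.strong_quantile * n)))
    weak = [flanks[i] for i in order[:k_weak]]
    strong = [flanks[i] for i in order[-k_strong:]]
    return _Strata(strong_flanks=strong, weak_flanks=weak, all_flanks=flanks, ties=ties)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_NT[rng.integers(0, 4, size=n)])


def _random_aug_free(rng: np.random.Generator, n: int) -> str:
    """Random sequence with no AUG substring (local resampling)."""
    chars = list(_NT[rng.integers(0, 4, size=n)])
    for i in range(2, n):
        while chars[i - 2] == "A" and chars[i - 1] == "U" and chars[i] == "G":
            chars[i] = str(_NT[rng.integers(0, 4)])
    return "".join(chars)


def _draw_spacer(rng: np.random.Generator, mean: float, frame: int, min_spacer: int) -> int:
    raw = int(rng.geometric(1.0 / mean))
    spacer = max(min_spacer, raw)
    spacer += (frame - spacer) % 3
    while spacer < min_spacer:
        spacer += 3
    return spacer


def _draw_frame(rng: np.random.Generator, p0: float, p2: float) -> int:
    u = rng.random()
    if u < p0:
        return 0
    if u < p0 + p2:
        return 2
    return 1


def _assemble_gene(
    rng: np.random.Generator,
    cfg: SimConfig,
    strata: _Strata,
    is_weak: bool,
) -> Tuple[str, int, int, int]:
    """One transcript sequence; returns (seq, cds_start, cds_end, fdaug_pos).
    Rejection-samples until structural constraints hold."""
    cls_flanks = strata.weak_flanks if is_weak else strata.strong_flanks
    p0 = cfg.p_frame0_given_weak if is_weak else cfg.p_frame0_given_strong
    p2 = cfg.p_frame2_given_weak if is_weak else cfg.p_frame2_given_strong
    spacer_mean = cfg.spacer_mean_weak if is_weak else cfg.spacer_mean_strong
    # Frame and spacer are drawn once per gene; structural rejections below
    # resample only sequence content, so the class-conditional frame and
    # spacer distributions match the configured values exactly.  (Frame-2
    # genes reject more often — e.g. an A after a frame-2 fdAUG spells a
    # frame-0 UGA — which would otherwise deplete frame 2 beyond its
    # configured probability.)
    frame = _draw_frame(rng, p0, p2)
    spacer = _draw_spacer(rng, spacer_mean, frame, cfg.min_spacer_nt)
    for _ in range(200):
        leader_len = int(rng.integers(cfg.leader_len_range[0], cfg.leader_len_range[1] + 1))
        utr_len = int(rng.integers(cfg.utr_len_range[0], cfg.utr_len_range[1] + 1))
        tail_codons = int(rng.integers(cfg.tail_codons_range[0], cfg.tail_codons_range[1] + 1))
        saug_flank = cls_flanks[rng.integers(0, len(cls_flanks))]
        fd_flank = strata.all_flanks[rng.integers(0, len(strata.all_flanks))]

        leader = _random_aug_free(rng, leader_len)
        # CDS: AUG + sense codons + terminal stop, long enough to hold the
        # fdAUG codon plus the downstream tail
        n_codons = (spacer + 3 + 2) // 3 + tail_codons + 1
        cds_len = 3 * n_codons

        def write_fd_region(cds: list) -> None:
            for k, ch in enumerate(fd_flank[:6]):
                idx = spacer - 6 + k
                if idx >= 3:  # never clobber the sAUG codon
                    cds[idx] = ch
            cds[spacer : spacer + 3] = "AUG"
            cds[spacer + 3] = fd_flank[6]
            cds[spacer + 4] = fd_flank[7]

        body = [_SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), size=n_codons - 2)]
        cds = list("AUG" + "".join(body) + _STOPS[rng.integers(0, 3)])
        cds[3] = saug_flank[6]
        cds[4] = saug_flank[7]
        write_fd_region(cds)
        engineered = set(range(5)) | {spacer + 3, spacer + 4} | set(range(cds_len - 3, cds_len))
        engineered |= {spacer - 6 + k for k in range(6) if spacer - 6 + k >= 3}
        engineered |= set(range(spacer, spacer + 3))

        # Local repair: resample only the characters involved in a violation
        # (an accidental AUG before the engineered fdAUG, or an internal
        # frame-0 stop).  Violation rates are per-site, so convergence does
        # not degrade with spacer length.
        def violations(cds: list):
            out = []
            s = "".join(cds)
            p = s.find("AUG", 1)
            while p != -1 and p < spacer:
                out.append((p, p + 3))
                p = s.find("AUG", p + 1)
            for i in range(0, cds_len - 3, 3):
                if s[i : i + 3] in STOP_CODONS:
                    out.append((i, i + 3))
            return out

        repaired = True
        for _round in range(50 + cds_len // 2):
            viol = violations(cds)
            if not viol:
                break
            lo, hi = viol[0]
            free = [i for i in range(lo, hi) if i not in engineered]
            if free:
                for i in free:
                    cds[i] = str(_NT[rng.integers(0, 4)])
            else:
                # violation lies fully inside the engineered fdAUG context:
                # draw a fresh fd flank (frame-dependent exclusions, e.g. no
                # A at +4 after a frame-2 fdAUG, arise here naturally)
                fd_flank = strata.all_flanks[rng.integers(0, len(strata.all_flanks))]
                write_fd_region(cds)
        else:
            repaired = False
        if not repaired:
            continue

        cds_str = "".join(cds)
        # final verification: terminal stop intact, first AUG at the CDS
        # start, second AUG exactly at the engineered spacer
        if cds_str[cds_len - 3 :] not in STOP_CODONS:
            continue
        seq = leader + saug_flank[:6] + cds_str + _random_seq(rng, utr_len)
        cds_start = leader_len + 6
        if seq.find("AUG") != cds_start:
            continue
        if seq.find("AUG", cds_start + 1) != cds_start + spacer:
            continue
        return seq, cds_start, cds_start + cds_len, cds_start + spacer
    raise RuntimeError("gene assembly failed after 200 attempts (infeasible constraints)")


def simulate_transcripts(
    cfg: SimConfig, scheme: PositionWeightScheme = DEFAULT_SCHEME
) -> Tuple[List[Transcript], pd.DataFrame]:
    """Generate the transcript catalog and its ground-truth table.

    Truth values (contexts, TIEs, frames, spacers, initiation fluxes) are
    extracted from the assembled sequences, so round-tripping through the
    annotation stage reproduces them exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    strata = build_strata(cfg, scheme)
    transcripts: List[Transcript] = []
    rows = []
    for g in range(cfg.n_genes):
        is_weak = rng.random() < cfg.p_weak
        seq, cds_start, cds_end, fd_pos = _assemble_gene(rng, cfg, strata, is_weak)
        tid = f"T{g:05d}"
        t = Transcript(id=tid, gene_id=f"G{g:05d}", seq=seq, cds_start=cds_start, cds_end=cds_end)
        transcripts.append(t)
        saug_ctx = extract_context(seq, cds_start)
        fd_ctx = extract_context(seq, fd_pos)
        saug_tie = synthetic_tie(saug_ctx, scheme)
        fd_tie = synthetic_tie(fd_ctx, scheme)
        p_init_s = (
            cfg.p_init_saug_override
            if cfg.p_init_saug_override is not None
            else min(1.0, saug_tie / cfg.tie_ref)
        )
        p_init_fd = (
            cfg.p_init_fd_override
            if cfg.p_init_fd_override is not None
            else min(1.0, fd_tie / cfg.tie_ref)
        )
        rows.append(
            {
                "gene_id": t.gene_id,
                "transcript_id": tid,
                "sim_class": "weak" if is_weak else "strong",
                "saug_context": saug_ctx,
                "saug_tie": saug_tie,
                "fdaug_pos": fd_pos,
                "frame": classify_frame(cds_start, fd_pos),
                "spacer_nt": fd_pos - cds_start,
                "fd_context": fd_ctx,
                "fd_tie": fd_tie,
                "fd_stop_nt": stop_distance(t, fd_pos),
                "flux_saug": p_init_s,
                "flux_fdaug": (1.0 - p_init_s) * p_init_fd,
                "cds_start": cds_start,
                "cds_end": cds_end,
            }
        )
    return transcripts, pd.DataFrame(rows)


def simulate_ortholog_panels(
    cfg: SimConfig,
    truth: pd.DataFrame,
    scheme: PositionWeightScheme = DEFAULT_SCHEME,
    anchor: str = "saug",
    class_by_gene: Optional[Dict[str, str]] = None,
    seed_offset: int = 1,
) -> List[OrthologPanel]:
    """Species context panels: with probability `conservation` a species
    keeps a context from the gene's class stratum, otherwise it draws from
    the background distribution; entries become NA at `na_rate`."""
    rng = np.random.default_rng(cfg.seed + seed_offset)
    strata = build_strata(cfg, scheme)
    panels = []
    species = [f"species_{i:03d}" for i in range(cfg.n_species)]
    for row in truth.itertuples():
        gene = row.gene_id
        cls = (class_by_gene or {}).get(gene, row.sim_class)
        cls_flanks = strata.weak_flanks if cls == "weak" else strata.strong_flanks
        entries: Dict[str, Optional[str]] = {}
        for sp in species:
            if rng.random() < cfg.na_rate:
                entries[sp] = None
                continue
            if rng.random() < cfg.conservation:
                flank = cls_flanks[rng.integers(0, len(cls_flanks))]
            else:
                flank = strata.all_flanks[rng.integers(0, len(strata.all_flanks))]
            entries[sp] = flank_to_context(flank)
        panels.append(OrthologPanel(gene_id=gene, entries=entries, anchor=anchor))
    return panels


def simulate_footprints(
    cfg: SimConfig,
    transcripts: Sequence[Transcript],
    truth: pd.DataFrame,
    seed_offset: int = 2,
) -> Dict[str, Dict[str, FootprintTrack]]:
    """Poisson footprint tracks under the leaky-scanning model, in both
    elongating (A-site) and initiating (P-site) modes."""
    rng = np.random.default_rng(cfg.seed + seed_offset)
    info = truth.set_index("transcript_id")
    out: Dict[str, Dict[str, FootprintTrack]] = {ELONGATING: {}, INITIATING: {}}
    for t in transcripts:
        row = info.loc[t.id]
        flux_s = float(row["flux_saug"])
        flux_fd = float(row["flux_fdaug"])
        fd_pos = int(row["fdaug_pos"])
        fd_stop = row["fd_stop_nt"]
        n = len(t.seq)
        bg = cfg.depth * cfg.background_rate

        mean_elong = np.full(n, bg)
        mean_elong[t.cds_start : t.cds_end] += cfg.depth * flux_s
        fd_end = int(fd_pos + fd_stop + 3) if not pd.isna(fd_stop) else n
        mean_elong[fd_pos : min(fd_end, n)] += cfg.depth * flux_fd
        out[ELONGATING][t.id] = FootprintTrack(
            t.id, rng.poisson(mean_elong), mode=ELONGATING
        )

        mean_init = np.full(n, bg)
        mean_init[t.cds_start : t.cds_start + 3] += cfg.depth * cfg.init_peak_scale * flux_s
        mean_init[fd_pos : fd_pos + 3] += cfg.depth * cfg.init_peak_scale * flux_fd
        out[INITIATING][t.id] = FootprintTrack(
            t.id, rng.poisson(mean_init), mode=INITIATING
        )
    return out


def simulation_tie_table(scheme: PositionWeightScheme = DEFAULT_SCHEME) -> TIETable:
    """The complete synthetic TIE table the analysis stages use for lookups
    against generated catalogs (every possible context is present)."""
    return synthetic_table(scheme)


def config_to_dict(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    for key, val in d.items():
        if isinstance(val, tuple):
            d[key] = list(val)
    return d
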