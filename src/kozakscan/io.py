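"""Readers and writers for the plain-text formats the pipeline exchanges.

Transcripts travel as FASTA plus a CDS coordinate TSV (0-based half-open);
start-pair annotations, ortholog panels, TIESS scores, and truth tables are
TSVs; footprint tracks are bedGraph-like TSVs in transcript coordinates
(`transcript_id  start  end  count` runs, 0-based half-open).
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate import StartPair, Transcript, frame_to_pairs, pairs_to_frame
from .conservation import OrthologPanel, TIESSRecord
from .metagene import FootprintTrack

PathLike = Union[str, Path]

CDS_COLUMNS = ["transcript_id", "gene_id", "cds_start", "cds_end"]


def write_transcripts(transcripts: Sequence[Transcript], fasta: PathLike, cds_tsv: PathLike) -> None:
    records = [SeqRecord(Seq(t.seq), id=t.id, description="") for t in transcripts]
    SeqIO.write(records, str(fasta), "fasta")
    rows = [
        {"transcript_id": t.id, "gene_id": t.gene_id, "cds_start": t.cds_start, "cds_end": t.cds_end}
        for t in transcripts
    ]
    pd.DataFrame(rows, columns=CDS_COLUMNS).to_csv(cds_tsv, sep="\t", index=False)


def read_transcripts(fasta: PathLike, cds_tsv: PathLike) -> List[Transcript]:
    cds = pd.read_csv(cds_tsv, sep="\t")
    missing_cols = set(CDS_COLUMNS) - set(cds.columns)
    if missing_cols:
        raise ValueError(f"{cds_tsv}: missing columns {sorted(missing_cols)}")
    by_id = {row.transcript_id: row for row in cds.itertuples()}
    transcripts = []
    seen = set()
    for rec in SeqIO.parse(str(fasta), "fasta"):
        row = by_id.get(rec.id)
        if row is None:
            raise ValueError(f"transcript {rec.id} in {fasta} has no CDS entry in {cds_tsv}")
        transcripts.append(
            Transcript(
                id=rec.id, gene_id=row.gene_id, seq=str(rec.seq),
                cds_start=int(row.cds_start), cds_end=int(row.cds_end),
            )
        )
        seen.add(rec.id)
    absent = set(by_id) - seen
    if absent:
        raise ValueError(f"CDS entries without FASTA sequence: {sorted(absent)[:5]}")
    return transcripts


def write_pairs(pairs: Sequence[StartPair], path: PathLike) -> None:
    pairs_to_frame(pairs).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_pairs(path: PathLike) -> List[StartPair]:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    return frame_to_pairs(df)


def write_panels(panels: Sequence[OrthologPanel], path: PathLike) -> None:
    rows = []
    for p in panels:
        for species, ctx in p.entries.items():
            rows.append(
                {"gene_id": p.gene_id, "species": species, "anchor": p.anchor,
                 "context": ctx if ctx is not None else "NA"}
            )
    pd.DataFrame(rows, columns=["gene_id", "species", "anchor", "context"]).to_csv(
        path, sep="\t", index=False
    )


def read_panels(path: PathLike) -> List[OrthologPanel]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    if "anchor" not in df.columns:
        df["anchor"] = "saug"
    panels: Dict[tuple, OrthologPanel] = {}
    for row in df.itertuples():
        key = (row.gene_id, row.anchor)
        panel = panels.setdefault(key, OrthologPanel(gene_id=row.gene_id, anchor=row.anchor))
        ctx = None if row.context in ("NA", "") else row.context
        panel.entries[row.species] = ctx
    return list(panels.values())


def write_tiess(records: Sequence[TIESSRecord], path: PathLike) -> None:
    rows = [
        {"gene_id": r.gene_id, "tiess": r.tiess, "n_orthologs": r.n_orthologs,
         "mean_log_dev": r.mean_log_dev}
        for r in records
    ]
    pd.DataFrame(rows, columns=["gene_id", "tiess", "n_orthologs", "mean_log_dev"]).to_csv(
        path, sep="\t", index=False
    )


def read_tiess(path: PathLike) -> List[TIESSRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        TIESSRecord(gene_id=r.gene_id, tiess=float(r.tiess), n_orthologs=int(r.n_orthologs))
        for r in df.itertuples()
    ]


def write_tracks(tracks: Dict[str, FootprintTrack], path: PathLike) -> None:
    """Run-length encoded bedGraph-like TSV (zero runs omitted)."""
    with open(path, "w") as fh:
        fh.write("transcript_id\tstart\tend\tcount\n")
        for tid in sorted(tracks):
            counts = tracks[tid].counts
            n = len(counts)
            i = 0
            while i < n:
                j = i
                while j < n and counts[j] == counts[i]:
                    j += 1
                if counts[i] != 0:
                    fh.write(f"{tid}\t{i}\t{j}\t{int(counts[i])}\n")
                i = j


def read_tracks(path: PathLike, lengths: Dict[str, int], mode: str) -> Dict[str, FootprintTrack]:
    df = pd.read_csv(path, sep="\t")
    arrays = {tid: np.zeros(n, dtype=int) for tid, n in lengths.items()}
    for row in df.itertuples():
        arr = arrays.get(row.transcript_id)
        if arr is None:
            raise ValueError(f"{path}: track for unknown transcript {row.transcript_id}")
        if not (0 <= row.start < row.end <= len(arr)):
            raise ValueError(
                f"{path}: run [{row.start},{row.end}) outside transcript "
                f"{row.transcript_id} of length {len(arr)}"
            )
        arr[int(row.start) : int(row.end)] = int(row.count)
    return {tid: FootprintTrack(tid, arr, mode=mode) for tid, arr in arrays.items()}


def read_peptide_frequencies(path: PathLike) -> Dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    if not {"peptide", "frequency"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns 'peptide' and 'frequency'")
    return {row.peptide: float(row.frequency) for row in df.itertuples()}


def write_profile(offsets, profile, path: PathLike) -> None:
    pd.DataFrame({"codon_offset": offsets, "median_density": profile}).to_csv(
        path, sep="\t", index=False, na_rep="NA"
    )
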