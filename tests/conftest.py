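"""Shared fixtures: a complete synthetic TIE table and engineered catalogs."""

from __future__ import annotations

import numpy as np
import pytest

from kozakscan.annotate import StartPair, Transcript
from kozakscan.context import synthetic_table


@pytest.fixture(scope="session")
def tie_table():
    """Complete TIE table under the default weight scheme (every context)."""
    return synthetic_table()


def make_transcript(tid, gene, leader, cds, utr=""):
    return Transcript(
        id=tid, gene_id=gene, seq=leader + cds + utr,
        cds_start=len(leader), cds_end=len(leader) + len(cds),
    )


@pytest.fixture()
def engineered_catalog():
    """Six transcripts tripping each catalog filter rule exactly once.

    Expected outcome: t_keep and t_dup_long kept; t_gug (no AUG start),
    t_flank (short upstream flank), t_nofd (no fdAUG in CDS), and
    t_dup_short (identical dedup stretch, shorter isoform) rejected.
    """
    shared_utr9 = "AAACCCAAA"  # first 9 UTR nt lie inside the dedup stretch
    return [
        make_transcript("t_keep", "G1", "CCACCC", "AUGAAAAUGUAA", "CCCAAACC"),
        make_transcript("t_gug", "G4", "ACCACC", "GUGGCCAUGUAA", "CCC"),
        make_transcript("t_flank", "G5", "ACC", "AUGAAAAUGUAA", "CCC"),
        make_transcript("t_nofd", "G3", "ACCACC", "AUGGCCGCCUAA", "CCCCCC"),
        make_transcript(
            "t_dup_long", "G2", "GGGCCACCC", "AUGGCCAUGGCGUGA", shared_utr9 + "C" * 21
        ),
        make_transcript(
            "t_dup_short", "G2", "GGGCCACCC", "AUGGCCAUGGCGUGA", shared_utr9 + "C" * 3
        ),
    ]


def make_pair(tid, gene="G", saug_tie=100.0, frame=0, spacer=60, fd_tie=50.0,
              fd_stop=120, terminated=True, saug_pos=50):
    return StartPair(
        transcript_id=tid, gene_id=gene, saug_pos=saug_pos,
        fdaug_pos=saug_pos + spacer, frame=frame, spacer_nt=spacer,
        saug_context=None, fd_context=None, saug_tie=saug_tie, fd_tie=fd_tie,
        fd_stop_nt=fd_stop if terminated else None, fd_terminated=terminated,
    )
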