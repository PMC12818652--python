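"""YCAY-cluster scoring and GU-rich stretch detection.

NOVA-family splicing factors bind clusters of YCAY (Y = C or U) elements;
clustering density, not single-site presence, predicts regulation.  The
scorer slides a 45-nt window along the sense strand in 1-nt steps and scores
the YCAY arrangement inside each window:

======================================  =====
pattern (N_g = g intervening bases)     score
======================================  =====
YCAY - N>=7 - YCAY                          0
YCAY - N3-6 - YCAY (next >= 7 nt away)      1
YCAY - N<=2 - YCAY (next >= 7 nt away)      2
YCAY - N<=2 - YCAY - N3-6 - YCAY (or
the two gaps in the other order)            4
YCAY - N<=2 - YCAY - N<=2 - YCAY            8
======================================  =====

The per-window total is reported raw and common-log transformed; log scores
of at least 0.6 (raw >= 4) indicate a conserved multi-motif cluster, while
lower values correspond to at most two clustered motifs.

GU-rich stretches — maximal runs of four or more consecutive G or U
nucleotides, the element recognized by the LASR subunit HNRNPM — are
detected separately.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "MotifWindowTrack",
    "GURun",
    "find_ycay_sites",
    "score_window",
    "scan_sequence",
    "find_gu_runs",
    "read_fasta",
    "write_track_bedgraph",
    "write_track_tsv",
    "write_gu_runs_bed",
    "LOG_SCORE_THRESHOLD",
]

#: log10 score at or above which a window holds a conserved YCAY cluster
#: (three or more clustered motifs); raw scores 1-3 fall below it.
LOG_SCORE_THRESHOLD: float = 0.6

_VALID = set("ACGTUN")
_YCAY = re.compile(r"[CU]CA[CU]")
MOTIF_LEN = 4


def _normalize(seq: str) -> str:
    """Uppercase and map T to U; reject characters outside {A,C,G,T,U,N}."""
    up = seq.upper()
    for i, ch in enumerate(up):
        if ch not in _VALID:
            raise ValueError(f"invalid nucleotide {ch!r} at position {i}")
    return up.replace("T", "U")


def find_ycay_sites(seq: str) -> list[int]:
    """0-based start positions of greedy left-to-right YCAY matches.

    Matches are non-overlapping: after a match, the search resumes at the
    match end, so ``UCAUCAU`` yields a single site at 0.
    """
    rna = _normalize(seq)
    sites = []
    i = 0
    while i <= len(rna) - MOTIF_LEN:
        if _YCAY.match(rna, i):
            sites.append(i)
            i += MOTIF_LEN
        else:
            i += 1
    return sites


def _score_gap_pattern(gaps: Sequence[int]) -> int:
    """Score one window's motif arrangement from its inter-motif gaps.

    Gaps of >= 7 nt separate clusters.  Within a cluster, motifs are grouped
    greedily left to right into disjoint groups: a triple is formed when at
    least two gaps remain and scored 8 (both gaps <= 2) or 4 (one <= 2, one
    3-6); a (3-6, 3-6) triple is not in the published pattern table and is
    scored as its leading pair (1), continuing from the third motif.
    Remaining pairs score 2 (gap <= 2) or 1 (gap 3-6); isolated motifs
    score 0.
    """
    segments: list[list[int]] = [[]]
    for g in gaps:
        if g >= 7:
            segments.append([])
        else:
            segments[-1].append(g)
    score = 0
    for seg in segments:
        m = len(seg) + 1  # motifs in this cluster
        i = 0  # index of the first motif of the next group
        while i < m - 1:
            if i + 2 <= m - 1:  # at least three motifs remain
                g1, g2 = seg[i], seg[i + 1]
                if g1 <= 2 and g2 <= 2:
                    score += 8
                    i += 3
                    continue
                if (g1 <= 2) != (g2 <= 2):
                    score += 4
                    i += 3
                    continue
                logger.debug("triple with gaps (3-6, 3-6): scoring leading pair as 1")
                score += 1
                i += 2
                continue
            score += 2 if seg[i] <= 2 else 1
            i += 2
    return score


def score_window(seq45: str) -> int:
    """Raw YCAY-cluster score of a 45-nt window (sum over disjoint groups)."""
    rna = _normalize(seq45)
    if len(rna) != 45:
        raise ValueError(f"window must be exactly 45 nt, got {len(rna)}")
    sites = find_ycay_sites(rna)
    if len(sites) < 2:
        return 0
    gaps = [sites[k + 1] - (sites[k] + MOTIF_LEN) for k in range(len(sites) - 1)]
    return _score_gap_pattern(gaps)


@dataclass
class MotifWindowTrack:
    """Per-window raw and log10 YCAY cluster scores along one sequence."""

    sequence_id: str
    window_starts: np.ndarray  # 0-based offsets
    raw_scores: np.ndarray  # non-negative ints
    log_scores: np.ndarray  # log10(raw) for raw >= 1, else 0
    window: int = 45

    def max_log_score(self) -> float:
        return float(self.log_scores.max()) if self.log_scores.size else 0.0


def scan_sequence(seq: str, sequence_id: str = "", window: int = 45, step: int = 1) -> MotifWindowTrack:
    """Score every window of ``window`` nt advancing by ``step`` nt.

    Raises for sequences shorter than the window.  Raw score 0 maps to log
    score 0 (not -inf) so tracks stay plottable; use the raw field to
    distinguish score-1 windows from empty ones.
    """
    rna = _normalize(seq)
    if len(rna) < window:
        raise ValueError(f"sequence length {len(rna)} < window {window}")
    starts = np.arange(0, len(rna) - window + 1, step)
    raw = np.array([score_window(rna[s : s + window]) for s in starts], dtype=int)
    log = np.where(raw >= 1, np.log10(np.maximum(raw, 1)), 0.0)
    return MotifWindowTrack(
        sequence_id=sequence_id,
        window_starts=starts,
        raw_scores=raw,
        log_scores=log,
        window=window,
    )


@dataclass(frozen=True)
class GURun:
    """Maximal run of >= 4 consecutive G or U nucleotides, 0-based half-open."""

    sequence_id: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def find_gu_runs(seq: str, min_len: int = 4, sequence_id: str = "") -> list[GURun]:
    """All maximal G/U runs of at least ``min_len`` nt, sorted by start."""
    rna = _normalize(seq)
    runs = []
    for m in re.finditer(r"[GU]+", rna):
        if m.end() - m.start() >= min_len:
            runs.append(GURun(sequence_id=sequence_id, start=m.start(), end=m.end()))
    return runs


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (multi-record, wrapped) FASTA file into (id, sequence) pairs."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_track_bedgraph(track: MotifWindowTrack, path: str | Path, append: bool = False) -> None:
    """Write log scores as bedGraph: sequence_id, start, start+1, log_score."""
    with Path(path).open("a" if append else "w") as fh:
        for s, log in zip(track.window_starts, track.log_scores):
            fh.write(f"{track.sequence_id}\t{s}\t{s + 1}\t{log:.6g}\n")


def write_track_tsv(track: MotifWindowTrack, path: str | Path, header_comment: str = "") -> None:
    with Path(path).open("w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("window_start\traw_score\tlog_score\n")
        for s, raw, log in zip(track.window_starts, track.raw_scores, track.log_scores):
            fh.write(f"{s}\t{raw}\t{log:.6g}\n")


def write_gu_runs_bed(runs: Sequence[GURun], path: str | Path) -> None:
    """Write GU runs as BED3 (0-based half-open)."""
    with Path(path).open("w") as fh:
        for r in runs:
            fh.write(f"{r.sequence_id}\t{r.start}\t{r.end}\n")
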