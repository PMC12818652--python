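"""Splice-junction classification and inclusion/exclusion quantification.

An alternative 5' donor event is described by three coordinates: two donor
sites (SDS1 upstream, SDS2 downstream on the transcribed strand) feeding one
shared acceptor (SAS).  Junction-spanning reads using the downstream donor
(SDS2 -> SAS) keep the extra exonic nucleotides between the donors in the
mature mRNA ("inclusion"); reads using the upstream donor (SDS1 -> SAS) splice
them out ("exclusion").  For *KIT* the 12 nt between the two GU donors encode
the Gly-Asn-(Asn|Ser)-Lys (GN[N/S]K) tetrapeptide, so inclusion counts measure
GN[N/S]K+ and exclusion counts GN[N/S]K- isoform expression.

The per-sample summary statistic is the in-ex ratio::

    in-ex ratio = (inclusion - exclusion) / (inclusion + exclusion)

which ranges from -1 (all reads support exclusion) to +1 (all support
inclusion) and is undefined (NaN) when a sample has no junction reads.

All genomic coordinates follow the STAR ``SJ.out.tab`` dialect: 1-based,
``intron_start`` is the first intronic base and ``intron_end`` the last.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "SpliceSiteSpec",
    "JunctionEvidence",
    "SampleJunctionCounts",
    "JunctionLabel",
    "gnnk_event",
    "classify_junction",
    "count_sample_junctions",
    "compute_inex_ratio",
    "read_sj_tab",
    "read_junction_table",
    "write_sample_counts",
    "read_sample_counts",
]


class JunctionLabel(Enum):
    """Outcome of classifying one junction against an event specification."""

    INCLUSION = "INCLUSION"
    EXCLUSION = "EXCLUSION"
    OTHER = "OTHER"


@dataclass(frozen=True)
class SpliceSiteSpec:
    """Coordinates of an alternative 5' donor event.

    Parameters
    ----------
    chrom : str
        Reference sequence name.
    strand : str
        ``"+"`` or ``"-"`` (strand of the host gene).
    sds1 : int
        1-based coordinate of the first intronic base when the upstream
        (exclusion) donor is used.
    sds2 : int
        Same for the downstream (inclusion) donor.
    sas : int
        1-based coordinate of the last intronic base at the shared acceptor.
    gene_id : str
        Identifier of the host gene.
    """

    chrom: str
    strand: str
    sds1: int
    sds2: int
    sas: int
    gene_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        # On the transcribed strand SDS2 lies strictly downstream of SDS1 and
        # the acceptor strictly downstream of SDS2.
        if self.strand == "+":
            ok = self.sds1 < self.sds2 < self.sas
        else:
            ok = self.sds1 > self.sds2 > self.sas
        if not ok:
            raise ValueError(
                "splice sites out of transcribed order: "
                f"sds1={self.sds1}, sds2={self.sds2}, sas={self.sas}, strand={self.strand}"
            )

    @property
    def donor_offset(self) -> int:
        """Absolute genomic distance between the alternative donors (nt)."""
        return abs(self.sds2 - self.sds1)


def gnnk_event() -> SpliceSiteSpec:
    """Packaged GN[N/S]K alternative-donor event fixture (human *KIT*-like).

    The event geometry is that of the human *KIT* GNNK event: plus strand,
    two GT donors 12 nt apart (4 codons) feeding one acceptor.  The
    coordinates are synthetic placeholders placed inside the human *KIT*
    locus window on GRCh38 (chr4), preserving the geometry but not tied to a
    genome-validated annotation; supply your own :class:`SpliceSiteSpec` for
    analyses of real alignments.
    """
    return SpliceSiteSpec(
        chrom="chr4",
        strand="+",
        sds1=54695514,
        sds2=54695526,
        sas=54699313,
        gene_id="KIT",
    )


@dataclass(frozen=True)
class JunctionEvidence:
    """One splice-junction record (one line of an ``SJ.out.tab``-style table)."""

    chrom: str
    intron_start: int  # 1-based first intronic base
    intron_end: int  # 1-based last intronic base
    strand: str = "."  # "+", "-" or "." (undefined)
    unique_reads: int = 0
    multimap_reads: int = 0

    def __post_init__(self) -> None:
        if self.unique_reads < 0 or self.multimap_reads < 0:
            raise ValueError("read counts must be non-negative")


@dataclass(frozen=True)
class SampleJunctionCounts:
    """Per-sample inclusion/exclusion read counts and in-ex ratio."""

    sample_id: str
    inclusion_reads: int
    exclusion_reads: int

    @property
    def inex_ratio(self) -> float:
        """``(inc - exc) / (inc + exc)``; NaN when both counts are zero."""
        return compute_inex_ratio(self.inclusion_reads, self.exclusion_reads)


def compute_inex_ratio(inclusion_reads: int, exclusion_reads: int) -> float:
    """Inclusion-exclusion ratio of junction read counts.

    Returns ``(inclusion - exclusion) / (inclusion + exclusion)``, which is
    +1 when every read supports inclusion (all GN[N/S]K+), -1 when every read
    supports exclusion, and NaN (undefined, never 0) when both counts are 0.
    """
    if inclusion_reads < 0 or exclusion_reads < 0:
        raise ValueError("read counts must be non-negative")
    total = inclusion_reads + exclusion_reads
    if total == 0:
        return math.nan
    return (inclusion_reads - exclusion_reads) / total


def classify_junction(evidence: JunctionEvidence, spec: SpliceSiteSpec) -> JunctionLabel:
    """Classify one junction record against an alternative-donor event.

    A record is INCLUSION when its donor-side intronic boundary equals
    ``spec.sds2`` and its acceptor-side boundary equals ``spec.sas``;
    EXCLUSION when the donor side equals ``spec.sds1`` with the same acceptor;
    OTHER in every remaining case (including a chromosome mismatch).  On
    minus-strand genes the donor-side boundary is ``intron_end`` and the
    acceptor side is ``intron_start``.  Records with undefined strand are
    classified by coordinates alone — the event spec carries the strand.

    Malformed records (``intron_start > intron_end``) are rejected with a
    ValueError; readers downgrade this to a logged warning.
    """
    if evidence.intron_start > evidence.intron_end:
        raise ValueError(
            f"malformed junction: intron_start {evidence.intron_start} > "
            f"intron_end {evidence.intron_end}"
        )
    if evidence.chrom != spec.chrom:
        return JunctionLabel.OTHER
    if spec.strand == "+":
        donor_side, acceptor_side = evidence.intron_start, evidence.intron_end
    else:
        donor_side, acceptor_side = evidence.intron_end, evidence.intron_start
    if acceptor_side != spec.sas:
        return JunctionLabel.OTHER
    if donor_side == spec.sds2:
        return JunctionLabel.INCLUSION
    if donor_side == spec.sds1:
        return JunctionLabel.EXCLUSION
    return JunctionLabel.OTHER


def count_sample_junctions(
    evidence_list: Iterable[JunctionEvidence],
    spec: SpliceSiteSpec,
    count_mode: str = "unique_only",
    sample_id: str = "",
) -> SampleJunctionCounts:
    """Sum inclusion/exclusion read support over one sample's junction table.

    ``count_mode`` selects which read counts enter the sums:
    ``"unique_only"`` (STAR column 7, the default) or
    ``"unique_plus_multi"`` (columns 7 + 8).  Multiple records matching the
    same junction are summed.  Malformed records are skipped with a warning.
    """
    if count_mode not in ("unique_only", "unique_plus_multi"):
        raise ValueError(f"unknown count_mode: {count_mode!r}")
    inc = exc = 0
    for ev in evidence_list:
        try:
            label = classify_junction(ev, spec)
        except ValueError as err:
            logger.warning("skipping junction record: %s", err)
            continue
        if label is JunctionLabel.OTHER:
            continue
        reads = ev.unique_reads
        if count_mode == "unique_plus_multi":
            reads += ev.multimap_reads
        if label is JunctionLabel.INCLUSION:
            inc += reads
        else:
            exc += reads
    return SampleJunctionCounts(sample_id=sample_id, inclusion_reads=inc, exclusion_reads=exc)


# ---------------------------------------------------------------------------
# I/O

_SJ_STRAND = {"0": ".", "1": "+", "2": "-"}


def read_sj_tab(path: str | Path) -> list[JunctionEvidence]:
    """Read a STAR ``SJ.out.tab`` file (9 tab-separated columns).

    Columns: chrom, intron start (1-based), intron end (1-based, inclusive),
    strand (0 undefined / 1 ``+`` / 2 ``-``), intron motif, annotation flag,
    unique reads, multimapping reads, maximum overhang.  Malformed lines are
    skipped with a warning naming the file and line number.
    """
    records: list[JunctionEvidence] = []
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                logger.warning("%s:%d: expected >=8 columns, got %d — skipped",
                               path, lineno, len(fields))
                continue
            try:
                start, end = int(fields[1]), int(fields[2])
                rec = JunctionEvidence(
                    chrom=fields[0],
                    intron_start=start,
                    intron_end=end,
                    strand=_SJ_STRAND.get(fields[3], "."),
                    unique_reads=int(fields[6]),
                    multimap_reads=int(fields[7]),
                )
            except ValueError as err:
                logger.warning("%s:%d: %s — skipped", path, lineno, err)
                continue
            if rec.intron_start > rec.intron_end:
                logger.warning("%s:%d: intron_start > intron_end — skipped", path, lineno)
                continue
            records.append(rec)
    return records


def read_junction_table(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    one_based: bool = True,
    sep: str = "\t",
) -> list[JunctionEvidence]:
    """Read a generic BED-like junction table with a header row.

    ``column_map`` maps the :class:`JunctionEvidence` field names
    (``chrom``, ``intron_start``, ``intron_end``, ``strand``,
    ``unique_reads``, ``multimap_reads``) to the file's column names; by
    default the file is assumed to use the field names directly.  With
    ``one_based=False`` the start column is interpreted as 0-based half-open
    (BED convention) and converted: first intronic base = start + 1, last
    intronic base = end.
    """
    import pandas as pd

    column_map = column_map or {}
    df = pd.read_csv(path, sep=sep, comment="#")

    def col(field: str) -> str:
        return column_map.get(field, field)

    records: list[JunctionEvidence] = []
    for _, row in df.iterrows():
        start = int(row[col("intron_start")])
        end = int(row[col("intron_end")])
        if not one_based:
            start = start + 1  # 0-based half-open -> 1-based first intronic base
        strand = str(row[col("strand")]) if col("strand") in df.columns else "."
        records.append(
            JunctionEvidence(
                chrom=str(row[col("chrom")]),
                intron_start=start,
                intron_end=end,
                strand=strand if strand in ("+", "-") else ".",
                unique_reads=int(row[col("unique_reads")]) if col("unique_reads") in df.columns else 0,
                multimap_reads=int(row[col("multimap_reads")]) if col("multimap_reads") in df.columns else 0,
            )
        )
    return records


def write_sample_counts(counts: Sequence[SampleJunctionCounts], path: str | Path) -> None:
    """Write per-sample counts as TSV: sample_id, inclusion, exclusion, ratio.

    Ratios are written with full ``repr`` precision so a round-trip through
    the file reproduces them bit-for-bit.
    """
    with Path(path).open("w") as fh:
        fh.write("sample_id\tinclusion_reads\texclusion_reads\tinex_ratio\n")
        for c in counts:
            fh.write(f"{c.sample_id}\t{c.inclusion_reads}\t{c.exclusion_reads}\t{c.inex_ratio!r}\n")


def read_sample_counts(path: str | Path) -> list[SampleJunctionCounts]:
    """Read a TSV written by :func:`write_sample_counts`."""
    out: list[SampleJunctionCounts] = []
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(
                SampleJunctionCounts(
                    sample_id=f[idx["sample_id"]],
                    inclusion_reads=int(f[idx["inclusion_reads"]]),
                    exclusion_reads=int(f[idx["exclusion_reads"]]),
                )
            )
    return out
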