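"""Strand-aware single-nucleotide Pol II occupancy from aligned NET-seq reads.

NET-seq sequences the 3' end of the nascent RNA still held by elongating
Pol II.  With an fr-firststrand library the sequencing read aligns antisense
to the transcript, so the read's 5'-aligned end marks the nascent-RNA 3' end
on the opposite (transcription) strand.  This module removes reverse-
transcription mispriming artifacts (reads whose 6-nt molecular barcode
exactly matches the genomic sequence adjacent to the alignment), tallies the
remaining reads into per-base occupancy tracks, normalizes by library depth,
and applies the expression / length / overlap gene-selection rules used for
profile analyses.

All coordinates are 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

__all__ = [
    "AlignedReadRecord",
    "OccupancyTrack",
    "filter_mispriming",
    "occupancy_from_reads",
    "normalize_cpm",
    "select_genes",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignedReadRecord:
    """One aligned read with its 6-nt random-hexamer molecular barcode.

    ``start``/``end`` are the 0-based half-open genomic span of the first
    aligned block (spliced alignments contribute their 5' block only, so the
    recorded 5' end is not shifted by intron gaps).  ``aln_strand`` is the
    strand the read aligned to; the transcript it came from lies on the
    opposite strand.
    """

    chrom: str
    start: int
    end: int
    aln_strand: str
    barcode: str
    unique: bool = True

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid span [{self.start}, {self.end})")
        if self.aln_strand not in "+-":
            raise ValueError(f"invalid strand {self.aln_strand!r}")
        if len(self.barcode) != 6:
            raise ValueError("barcode must be 6 nt")

    @property
    def five_prime_end(self) -> int:
        """Genomic coordinate of the read's 5'-aligned end (= RNA 3' end)."""
        return self.start if self.aln_strand == "+" else self.end - 1

    @property
    def transcription_strand(self) -> str:
        return "-" if self.aln_strand == "+" else "+"


@dataclass
class OccupancyTrack:
    """Per-(chromosome, transcription strand) vectors of nascent-RNA 3' ends.

    ``data`` maps ``(chrom, strand)`` to a per-base vector whose length is the
    chromosome length.  Until CPM normalization the vectors are counts and sum
    to ``total_reads``.
    """

    data: dict[tuple[str, str], np.ndarray]
    total_reads: int = 0
    normalized: bool = False

    def get(self, chrom: str, strand: str) -> np.ndarray:
        return self.data[(chrom, strand)]

    def total_signal(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    @staticmethod
    def zeros(chrom_lengths: dict[str, int], dtype=np.int64) -> "OccupancyTrack":
        data = {
            (c, s): np.zeros(n, dtype=dtype)
            for c, n in chrom_lengths.items()
            for s in "+-"
        }
        return OccupancyTrack(data=data, total_reads=0, normalized=False)


# ---------------------------------------------------------------------------
# mispriming filter
# ---------------------------------------------------------------------------


def _adjacent_window(read: AlignedReadRecord, genome: dict[str, str], side: str) -> str | None:
    """Genomic 6-mer the barcode is compared against, in read orientation.

    ``side='downstream'`` (default biology) takes the 6 bases that would
    extend the nascent RNA past its recorded 3' end, i.e. immediately before
    the read's 5'-aligned end in read orientation: for a + alignment the
    forward bases at [start-6, start); for a - alignment the reverse
    complement of [end, end+6).  ``side='upstream'`` mirrors this to the
    other end of the read.  Returns None when the window runs off the
    chromosome (such reads are retained).
    """
    seq = genome[read.chrom]
    if side == "downstream":
        if read.aln_strand == "+":
            lo, hi = read.start - 6, read.start
            return seq[lo:hi].upper() if lo >= 0 else None
        lo, hi = read.end, read.end + 6
        return revcomp(seq[lo:hi]).upper() if hi <= len(seq) else None
    if side == "upstream":
        if read.aln_strand == "+":
            lo, hi = read.end, read.end + 6
            return seq[lo:hi].upper() if hi <= len(seq) else None
        lo, hi = read.start - 6, read.start
        return revcomp(seq[lo:hi]).upper() if lo >= 0 else None
    raise ValueError(f"unknown side {side!r}")


def is_misprimed(read: AlignedReadRecord, genome: dict[str, str], side: str = "downstream") -> bool:
    """True iff the barcode exactly matches the adjacent genomic window.

    Barcodes containing N never match.
    """
    if read.chrom not in genome:
        raise ValueError(f"read on unknown chromosome {read.chrom!r}")
    bc = read.barcode.upper()
    if "N" in bc:
        return False
    sides = ("downstream", "upstream") if side == "either" else (side,)
    for s in sides:
        window = _adjacent_window(read, genome, s)
        if window is not None and "N" not in window and bc == window:
            return True
    return False


def filter_mispriming(
    reads: Iterable[AlignedReadRecord],
    genome: dict[str, str],
    side: str = "downstream",
) -> tuple[list[AlignedReadRecord], dict]:
    """Remove RT-mispriming reads; return (retained reads, removal report)."""
    retained, removed = [], 0
    total = 0
    for read in reads:
        total += 1
        if is_misprimed(read, genome, side=side):
            removed += 1
        else:
            retained.append(read)
    report = {
        "reads_in": total,
        "misprimed_removed": removed,
        "retained": len(retained),
        "removal_fraction": removed / total if total else 0.0,
        "side": side,
    }
    return retained, report


# ---------------------------------------------------------------------------
# occupancy extraction and normalization
# ---------------------------------------------------------------------------


def occupancy_from_reads(
    reads: Iterable[AlignedReadRecord],
    chrom_lengths: dict[str, int],
) -> OccupancyTrack:
    """Tally each uniquely mapped read at its nascent-RNA 3'-end position.

    A read contributes +1 at its 5'-aligned end (``start`` for +, ``end-1``
    for -) on the transcription strand opposite the alignment strand.
    Multi-mapped reads are skipped.
    """
    track = OccupancyTrack.zeros(chrom_lengths)
    n = 0
    for read in reads:
        if not read.unique:
            continue
        if read.chrom not in chrom_lengths:
            raise ValueError(f"read on unknown chromosome {read.chrom!r}")
        pos = read.five_prime_end
        if not 0 <= pos < chrom_lengths[read.chrom]:
            raise ValueError(f"read position {pos} outside {read.chrom}")
        track.data[(read.chrom, read.transcription_strand)][pos] += 1
        n += 1
    track.total_reads = n
    return track


def normalize_cpm(track: OccupancyTrack) -> OccupancyTrack:
    """Scale a count track to counts per million uniquely mapped reads."""
    if track.total_reads <= 0:
        raise ValueError("cannot CPM-normalize an empty track")
    factor = 1e6 / track.total_reads
    data = {k: v.astype(float) * factor for k, v in track.data.items()}
    return OccupancyTrack(data=data, total_reads=track.total_reads, normalized=True)


# ---------------------------------------------------------------------------
# gene selection
# ---------------------------------------------------------------------------


def gene_body_span(gene) -> tuple[int, int]:
    """0-based half-open genomic span of a gene body (TSS..polyA inclusive)."""
    lo = min(gene.tss, gene.polya)
    hi = max(gene.tss, gene.polya)
    return lo, hi + 1


def reads_in_gene(track: OccupancyTrack, gene) -> float:
    lo, hi = gene_body_span(gene)
    return float(track.get(gene.chrom, gene.strand)[lo:hi].sum())


def select_genes(
    track: OccupancyTrack,
    genes: list,
    min_rpkm: float = 10.0,
    min_len: int = 500,
    overlap_exclusion_distance: int = 0,
) -> list:
    """Expression / length / overlap gene filter for profile analyses.

    Keeps genes whose body is at least ``min_len`` bp, whose RPKM (computed
    from raw counts against the library's uniquely mapped total) is strictly
    above ``min_rpkm``, and whose body — extended by
    ``overlap_exclusion_distance`` on both sides — overlaps no other gene's
    body.
    """
    if track.normalized:
        raise ValueError("RPKM needs raw counts; pass the unnormalized track")
    if track.total_reads <= 0:
        raise ValueError("empty track")
    for g in genes:
        if (g.chrom, g.strand) not in track.data:
            raise ValueError(f"gene {g.gene_id!r} on unknown chromosome {g.chrom!r}")

    spans = [gene_body_span(g) for g in genes]
    selected = []
    for i, g in enumerate(genes):
        lo, hi = spans[i]
        length = hi - lo
        if length < min_len:
            continue
        count = reads_in_gene(track, g)
        rpkm = count * 1e9 / (track.total_reads * length)
        if not rpkm > min_rpkm:
            continue
        xlo, xhi = lo - overlap_exclusion_distance, hi + overlap_exclusion_distance
        clash = any(
            j != i and genes[j].chrom == g.chrom and spans[j][0] < xhi and spans[j][1] > xlo
            for j in range(len(genes))
        )
        if not clash:
            selected.append(g)
    return selected
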