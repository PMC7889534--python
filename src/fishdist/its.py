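"""Interstitial telomeric sequence (ITS) scanning.

Telomeres are tandem TTAGGG repeats; the same motif occurring away from
chromosome ends (an interstitial telomeric sequence) is a candidate anchor
for telomere looping onto a gene.  This module scans a DNA region — the
gene body plus flanking sequence — for maximal runs of TTAGGG and of its
reverse complement CCCTAA, and reports their positions relative to the
gene span.

Coordinates are 1-based inclusive (genome-browser convention); BED output
converts to 0-based half-open.  ``N`` bases never match.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

FORWARD_MOTIF = "TTAGGG"
COMPLEMENT_MOTIF = "CCCTAA"

_VALID = re.compile(r"^[ACGTN]*$")


@dataclass
class ScanRegion:
    """A DNA search region with optional genomic anchoring.

    ``offset`` is the 1-based genomic coordinate of the region's first
    base (1 keeps coordinates region-local).
    """

    seq_id: str
    sequence: str
    offset: int = 1
    flank_bp: int = 0

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not _VALID.match(self.sequence):
            bad = sorted(set(self.sequence) - set("ACGTN"))
            raise ValueError(f"invalid characters in sequence: {bad}")
        if self.flank_bp < 0:
            raise ValueError("flank length must be non-negative")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class MotifHit:
    """One maximal run of a telomeric motif.

    ``start`` is 1-based inclusive (genomic when the region carries an
    offset); ``n_repeats`` counts consecutive motif units, so the run
    spans ``start .. start + 6 * n_repeats - 1``.
    """

    motif: str
    start: int
    n_repeats: int
    strand: str  # '+' for TTAGGG (forward repeat), '-' for CCCTAA

    @property
    def end(self) -> int:
        return self.start + len(self.motif) * self.n_repeats - 1

    @property
    def length(self) -> int:
        return len(self.motif) * self.n_repeats


def scan_motifs(region: ScanRegion,
                motifs: Tuple[str, str] = (FORWARD_MOTIF, COMPLEMENT_MOTIF)
                ) -> List[MotifHit]:
    """All maximal runs of each motif in the region, sorted by position.

    Each motif is scanned independently: a run is maximal when it cannot
    be extended by another full motif unit on either side.
    """
    hits: List[MotifHit] = []
    for motif in motifs:
        strand = "+" if motif == FORWARD_MOTIF else "-"
        pattern = re.compile(f"(?:{re.escape(motif)})+")
        for m in pattern.finditer(region.sequence):
            n = (m.end() - m.start()) // len(motif)
            hits.append(MotifHit(
                motif=motif,
                start=m.start() + region.offset,
                n_repeats=n,
                strand=strand,
            ))
    hits.sort(key=lambda h: (h.start, h.motif))
    return hits


@dataclass
class RegionReport:
    region_id: str
    gene_span: Tuple[int, int]  # 1-based inclusive, same frame as hits
    hits: List[MotifHit]
    distances_to_start: List[int]
    distances_to_end: List[int]
    n_inside: int
    n_upstream: int
    n_downstream: int

    def to_bed(self) -> str:
        """Hits as BED lines (0-based half-open)."""
        lines = []
        for h in self.hits:
            lines.append("\t".join([
                self.region_id, str(h.start - 1), str(h.end),
                f"{h.motif}x{h.n_repeats}", str(h.n_repeats), h.strand,
            ]))
        return "\n".join(lines) + ("\n" if lines else "")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "region": self.region_id,
            "motif": [h.motif for h in self.hits],
            "start": [h.start for h in self.hits],
            "end": [h.end for h in self.hits],
            "n_repeats": [h.n_repeats for h in self.hits],
            "strand": [h.strand for h in self.hits],
            "dist_to_gene_start": self.distances_to_start,
            "dist_to_gene_end": self.distances_to_end,
        })


def summarize_region(region: ScanRegion,
                     gene_span: Tuple[int, int]) -> RegionReport:
    """Scan a region and relate every hit to the gene span.

    ``gene_span`` is (start, end), 1-based inclusive, in the same
    coordinate frame as the region (genomic when the region has an
    offset).  Distances are signed: a hit 2 kb upstream of the gene start
    reports ``dist_to_gene_start = -2000``.
    """
    g0, g1 = gene_span
    if g1 < g0:
        raise ValueError("gene span end precedes start")
    if g0 < region.offset or g1 > region.offset + len(region) - 1:
        raise ValueError("gene span outside the scan region")
    hits = scan_motifs(region)
    d_start = [h.start - g0 for h in hits]
    d_end = [h.start - g1 for h in hits]
    n_in = sum(1 for h in hits if h.start <= g1 and h.end >= g0)
    n_up = sum(1 for h in hits if h.end < g0)
    n_down = sum(1 for h in hits if h.start > g1)
    return RegionReport(
        region_id=region.seq_id,
        gene_span=(g0, g1),
        hits=hits,
        distances_to_start=d_start,
        distances_to_end=d_end,
        n_inside=n_in,
        n_upstream=n_up,
        n_downstream=n_down,
    )


def region_from_fasta(path, seq_id: Optional[str] = None,
                      offset: int = 1, flank_bp: int = 0) -> ScanRegion:
    """Load one record from a FASTA file as a :class:`ScanRegion`."""
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fasta"):
        if seq_id is None or rec.id == seq_id:
            return ScanRegion(rec.id, str(rec.seq), offset=offset,
                              flank_bp=flank_bp)
    raise KeyError(f"record {seq_id!r} not found in {path}")
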