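"""Genomic loci homologous to catalytic DNAzyme cores at ssDNA sites.

Short synthetic DNAzyme core sequences are matched against the genome;
hits pass when they (1) cover at least 85% of the query length, (2) carry
zero mismatches, and (3) overlap at least one priming site. The 85%
threshold is inclusive (17/20 passes; 16/20 fails). A k-mer-seeded exact
matcher is shipped for scanning toy genomes; externally produced tabular
hits (standard 12-column local-alignment format) can be imported instead.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass

from .synthdata import Genome, revcomp


@dataclass
class DnazymeHit:
    query_id: str
    query_length: int
    aligned_length: int
    mismatches: int
    chrom: str
    start: int
    end: int
    strand: str
    overlapping_sites: int = 0

    def __post_init__(self):
        if self.query_length <= 0:
            raise ValueError(f"hit {self.query_id}: query length must be positive")
        if self.aligned_length > self.query_length or self.mismatches < 0:
            raise ValueError(f"hit {self.query_id}: invalid aligned length or mismatches")


def scan_genome(queries: dict[str, str], genome: Genome | dict[str, str]) -> list[DnazymeHit]:
    """Exact full-length occurrences of each query on either strand."""
    sequences = genome.sequences if isinstance(genome, Genome) else genome
    hits = []
    for qid, qseq in queries.items():
        for strand, needle in (("+", qseq), ("-", revcomp(qseq))):
            for chrom, seq in sequences.items():
                i = seq.find(needle)
                while i >= 0:
                    hits.append(
                        DnazymeHit(
                            query_id=qid,
                            query_length=len(qseq),
                            aligned_length=len(qseq),
                            mismatches=0,
                            chrom=chrom,
                            start=i,
                            end=i + len(needle),
                            strand=strand,
                        )
                    )
                    i = seq.find(needle, i + 1)
    hits.sort(key=lambda h: (h.chrom, h.start, h.query_id, h.strand))
    return hits


def filter_dnazyme_hits(
    hits: list[DnazymeHit], sites, min_aligned_fraction: float = 0.85
) -> list[DnazymeHit]:
    """Apply the homology criteria and the priming-site overlap requirement.

    Overlap means >= 1 bp intersection between the hit interval and a
    site's 1-bp position; the hit strand is retained but not required to
    match the site strand.
    """
    pos_by_chrom: dict[str, list[int]] = {}
    for s in sites:
        pos_by_chrom.setdefault(s.chrom, []).append(s.pos)
    pos_by_chrom = {c: sorted(v) for c, v in pos_by_chrom.items()}

    passing = []
    for h in hits:
        if h.aligned_length / h.query_length < min_aligned_fraction:
            continue
        if h.mismatches != 0:
            continue
        positions = pos_by_chrom.get(h.chrom, [])
        lo = bisect_left(positions, h.start)
        n = 0
        for p in positions[lo:]:
            if p >= h.end:
                break
            n += 1
        if n == 0:
            continue
        h.overlapping_sites = n
        passing.append(h)
    return passing


def hits_to_bed(hits: list[DnazymeHit]) -> list[tuple]:
    """BED rows with query provenance in the name field."""
    return [
        (h.chrom, h.start, h.end, f"{h.query_id};sites={h.overlapping_sites}", h.overlapping_sites, h.strand)
        for h in hits
    ]


def hits_from_tabular(rows, query_lengths: dict[str, int]) -> list[DnazymeHit]:
    """Import hits from 12-column tabular local-alignment output.

    Columns: query, subject, pident, length, mismatch, gapopen, qstart,
    qend, sstart, send, evalue, bitscore (subject coordinates 1-based
    inclusive; send < sstart marks a minus-strand hit).
    """
    hits = []
    for row in rows:
        if isinstance(row, str):
            row = row.rstrip("\n").split("\t")
        qid, subject = row[0], row[1]
        length, mism = int(row[3]), int(row[4])
        sstart, send = int(row[8]), int(row[9])
        if sstart <= send:
            start, end, strand = sstart - 1, send, "+"
        else:
            start, end, strand = send - 1, sstart, "-"
        hits.append(
            DnazymeHit(
                query_id=qid,
                query_length=query_lengths[qid],
                aligned_length=length,
                mismatches=mism,
                chrom=subject,
                start=start,
                end=end,
                strand=strand,
            )
        )
    return hits
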