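"""SAM interop: the alignment-record contract over pysam."""

from __future__ import annotations

import pysam

from .alnfilter import AlignmentRecord
from .synthdata import Genome, TrueAlignment


def write_true_sam(alns: list[TrueAlignment], genome: Genome, path) -> None:
    """Write the simulator's true alignments as a coordinate-naive SAM."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": len(s)} for c, s in genome.sequences.items()],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for a in alns:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = a.read_id
            seg.reference_name = a.chrom
            seg.reference_start = a.start
            seg.flag = 16 if a.strand == "-" else 0
            L = a.end - a.start
            seg.cigarstring = f"{L}M"
            seg.mapping_quality = 60
            seg.set_tag("AS", L)
            seg.set_tag("NM", 0)
            seg.set_tag("XC", a.quality_class)
            out.write(seg)


def records_from_sam(path) -> list[AlignmentRecord]:
    """Read SAM/BAM alignments into the record contract.

    Score comes from the AS tag (falling back to matched bases), mismatch
    count from NM; for single-end records the pair-level non-overlapping
    mapped length equals the mapped length.
    """
    records = []
    with pysam.AlignmentFile(str(path), "r") as fh:
        for seg in fh:
            if seg.is_unmapped:
                continue
            mapped = sum(n for op, n in (seg.cigartuples or []) if op in (0, 7, 8))
            nm = int(seg.get_tag("NM")) if seg.has_tag("NM") else 0
            score = float(seg.get_tag("AS")) if seg.has_tag("AS") else float(mapped - nm)
            records.append(
                AlignmentRecord(
                    read_id=seg.query_name,
                    chrom=seg.reference_name,
                    start=seg.reference_start,
                    end=seg.reference_end,
                    strand="-" if seg.is_reverse else "+",
                    aligner_score=score,
                    read_length=seg.query_length or mapped,
                    mapped_length=mapped,
                    matched_bases=mapped - nm,
                    mismatches=nm,
                    non_overlapping_mapped_length=mapped,
                    is_primary=not (seg.is_secondary or seg.is_supplementary),
                )
            )
    return records
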