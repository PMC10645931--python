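"""Strand-labelled ssDNA priming-site calls with per-bin capping.

The 5' genomic end of each barcode-carrying read is taken as the ssDNA
site. Barcode locations are tracked in 20 bp bins across the genome; for
a sample of k cells at most 2xk reads are retained per bin (two homologs
per cell), prioritized by barcode/primer quality (A1 > A2 > B1 > B2 > C1 >
C2), then aligner score, then mapped length, then read id.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

from .alnfilter import AlignmentRecord, MappabilityMask, in_blacklist
from .readproc import CLASS_ORDER

_CLASS_PRIORITY = {q: i for i, q in enumerate(CLASS_ORDER)}


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata from the sample sheet."""

    sample_id: str
    k: int = 1  # number of cells
    condition: str = "noncontrol"  # or probe+laser-, probe-laser-, mungbean
    timepoint: str | None = None
    species: str = "synthetic"
    barcode: str | None = None

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("cell count k must be >= 1")


@dataclass
class PrimingSite:
    chrom: str
    pos: int  # 0-based; the barcode read's 5' genomic end
    strand: str
    quality: str  # A1..C2
    sample_id: str
    read_id: str = ""
    score: float = 0.0
    mapped_length: int = 0


def call_priming_site(
    rec: AlignmentRecord,
    quality: str,
    sample_id: str,
    include_c: bool = True,
) -> PrimingSite:
    """Convert a filtered, classified alignment to a priming site.

    Only barcode-carrying reads define sites: class D is rejected, and
    class C only when ``include_c`` (the maximal-sensitivity default; pass
    False for the strict A/B-only mode).
    """
    cls = quality[0]
    if cls == "D":
        raise ValueError(f"class D read {rec.read_id} cannot define a priming site")
    if cls == "C" and not include_c:
        raise ValueError(f"class C read {rec.read_id} excluded in strict A/B mode")
    return PrimingSite(
        chrom=rec.chrom,
        pos=rec.five_prime,
        strand=rec.strand,
        quality=quality,
        sample_id=sample_id,
        read_id=rec.read_id,
        score=rec.aligner_score,
        mapped_length=rec.mapped_length,
    )


def drop_masked_and_blacklisted(
    sites: list[PrimingSite],
    mask: MappabilityMask | None = None,
    blacklist: dict[str, list[tuple[int, int]]] | None = None,
) -> list[PrimingSite]:
    """Remove sites in unmappable bins or blacklist intervals (pre-cap)."""
    out = []
    for s in sites:
        if mask is not None and mask.is_masked(s.chrom, s.pos):
            continue
        if blacklist is not None and in_blacklist(s.chrom, s.pos, blacklist):
            continue
        out.append(s)
    return out


def cap_bin_dedup(
    sites: list[PrimingSite], k: int, bin_size: int = 20, cap_multiplier: int = 2
) -> list[PrimingSite]:
    """Cap each 20 bp bin at 2xk sites by quality-priority deduplication.

    The bin grid is anchored at coordinate 0 per chromosome. Within a bin
    sites are ranked by (class priority, -score, -mapped length, read id)
    and the top 2xk retained (the multiplier 2 models diploidy). The cap
    applies to the count only; retained sites may share a position.
    """
    if k is None or k < 1:
        raise ValueError("sample cell count k must be a positive integer")
    cap = cap_multiplier * k
    bins: dict[tuple[str, int], list[PrimingSite]] = defaultdict(list)
    for s in sites:
        bins[(s.chrom, s.pos // bin_size)].append(s)
    retained: list[PrimingSite] = []
    for members in bins.values():
        members.sort(
            key=lambda s: (_CLASS_PRIORITY[s.quality], -s.score, -s.mapped_length, s.read_id)
        )
        retained.extend(members[:cap])
    retained.sort(key=lambda s: (s.chrom, s.pos, s.read_id))
    return retained


def count_by_region(
    sites_by_sample: dict[str, list[PrimingSite]], model
) -> pd.DataFrame:
    """Gene-by-sample priming counts per genic sub-region.

    Returns a tidy frame (gene_id, region, sample, count) covering the
    sub-regions GeneExt, Promoter, Exon, Intron and Downstream; a site may
    count toward several overlapping genes. Unseen (gene, region, sample)
    combinations are zero-filled on pivot (see :func:`count_matrix`).
    """
    known = set(model.chrom_lengths)
    rows = []
    for sample_id, sites in sites_by_sample.items():
        bad = {s.chrom for s in sites} - known
        if bad:
            raise ValueError(f"unknown chromosomes in sites: {sorted(bad)}")
        counts: dict[tuple[str, str], int] = defaultdict(int)
        for s in sites:
            for gene_id, region in model.regions_at(s.chrom, s.pos):
                counts[(gene_id, region)] += 1
        for (gene_id, region), n in counts.items():
            rows.append((gene_id, region, sample_id, n))
    return pd.DataFrame(rows, columns=["gene_id", "region", "sample", "count"])


def count_matrix(
    sites_by_sample: dict[str, list[PrimingSite]], model, region: str = "GeneExt"
) -> pd.DataFrame:
    """Genes x samples count matrix for one sub-region (zero-filled)."""
    tidy = count_by_region(sites_by_sample, model)
    sub = tidy[tidy["region"] == region]
    genes = sorted(model.genes)
    mat = (
        sub.pivot_table(index="gene_id", columns="sample", values="count", fill_value=0)
        .reindex(genes, fill_value=0)
    )
    mat = mat.reindex(columns=sorted(sites_by_sample), fill_value=0)
    mat.columns.name = None
    return mat.astype(int)


def sites_to_bed(sites: list[PrimingSite]) -> list[tuple]:
    """BED rows (chrom, pos, pos+1, class, score, strand) per sample."""
    return [
        (s.chrom, s.pos, s.pos + 1, s.quality, int(s.score), s.strand) for s in sites
    ]


def sites_from_bed(rows, sample_id: str) -> list[PrimingSite]:
    sites = []
    for row in rows:
        chrom, start, _end = row[0], int(row[1]), int(row[2])
        quality = row[3] if len(row) > 3 else "A1"
        score = float(row[4]) if len(row) > 4 else 0.0
        strand = row[5] if len(row) > 5 else "+"
        sites.append(
            PrimingSite(
                chrom=chrom,
                pos=start,
                strand=strand,
                quality=quality,
                sample_id=sample_id,
                score=score,
            )
        )
    return sites
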