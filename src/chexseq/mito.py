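"""Mitochondrial ssDNA analyses on a circular contig.

Binned (50 bp) z-scored priming density with hotspot calls (z >= 2 SD),
per-base priming rate inside vs outside the D-loop, and the
heavy-to-light strand count ratio. The mapping from reference strand to
heavy/light is a per-species configuration entry, never inferred; the
synthetic convention is heavy = '+'.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genemodel import zscore


@dataclass
class MitoProfile:
    contig_length: int
    bin_size: int
    counts: np.ndarray
    z: np.ndarray
    hotspot_bins: list[int]
    hotspot_genes: list[str] = field(default_factory=list)
    dloop: tuple[int, int] | None = None


def mito_zscore_hotspots(
    positions,
    contig_length: int,
    bin_size: int = 50,
    genes: list[tuple[str, int, int, str]] | None = None,
    z_threshold: float = 2.0,
    dloop: tuple[int, int] | None = None,
) -> MitoProfile:
    """Bin priming positions, z-score per-bin counts, call hotspot bins.

    Bins tile the circle exactly (the last bin may be short). z uses the
    sample standard deviation over bins; a zero SD leaves all z undefined
    and no hotspots. Genes overlapping any hotspot bin are listed.
    """
    positions = [int(getattr(p, "pos", p)) for p in positions]
    if any(p < 0 or p >= contig_length for p in positions):
        raise ValueError("position outside the mitochondrial contig")
    nbins = -(-contig_length // bin_size)
    counts = np.bincount([p // bin_size for p in positions], minlength=nbins).astype(float)
    z = zscore(counts)
    if np.all(np.isnan(z)):
        hot = []
    else:
        hot = [int(i) for i in np.flatnonzero(z >= z_threshold)]
    hot_genes: list[str] = []
    if genes:
        for name, gstart, gend, _strand in genes:
            for b in hot:
                bs, be = b * bin_size, min((b + 1) * bin_size, contig_length)
                if gstart < be and gend > bs:
                    hot_genes.append(name)
                    break
    return MitoProfile(
        contig_length=contig_length,
        bin_size=bin_size,
        counts=counts,
        z=z,
        hotspot_bins=hot,
        hotspot_genes=hot_genes,
        dloop=dloop,
    )


def dloop_rate(
    positions, dloop: tuple[int, int], contig_length: int
) -> tuple[float, float]:
    """Per-base priming rate inside and outside the D-loop interval."""
    start, end = dloop
    if not (0 <= start < end <= contig_length):
        raise ValueError("D-loop interval outside the contig")
    positions = [int(getattr(p, "pos", p)) for p in positions]
    inside = sum(start <= p < end for p in positions)
    outside = len(positions) - inside
    len_in = end - start
    len_out = contig_length - len_in
    return inside / len_in, (outside / len_out if len_out else float("nan"))


def heavy_light_ratio(strand_counts: dict[str, int], heavy_strand: str = "+") -> float:
    """Heavy-to-light strand count ratio; < 1 indicates light-strand bias.

    ``strand_counts`` maps reference strand ('+'/'-') to site counts;
    ``heavy_strand`` states which reference strand is heavy for the
    species/assembly at hand. A zero light count reports infinity.
    """
    if heavy_strand not in ("+", "-"):
        raise ValueError("heavy_strand must be '+' or '-'")
    heavy = strand_counts.get(heavy_strand, 0)
    light = strand_counts.get("-" if heavy_strand == "+" else "+", 0)
    if light == 0:
        return float("inf")
    return heavy / light


def strand_counts_from_sites(sites, contig: str = "chrM") -> dict[str, int]:
    counts = {"+": 0, "-": 0}
    for s in sites:
        if s.chrom == contig:
            counts[s.strand] += 1
    return counts
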