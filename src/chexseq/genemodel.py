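"""Genic/sub-genic interval models and anchored coverage profiles.

Genic units (all strand-mirrored for minus-strand genes, coordinates
0-based half-open, clipped to chromosome bounds):

- GeneExt: gene body plus 2.5 kb upstream and downstream;
- Promoter: oriented offsets [-2000, +200) around the TSS;
- Exon / Intron: from the representative (longest) transcript;
- Downstream: TES to 2.5 kb downstream.

Site annotation assigns one category per site by precedence
(promoter <1 kb > promoter <5 kb > 5' UTR > exon > intron > 3'-proximal >
distal intergenic), with promoter bins defined by absolute distance to the
nearest TSS.
"""

from __future__ import annotations

import re
from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

ANNOTATION_CATEGORIES = (
    "promoter_1kb",
    "promoter_5kb",
    "five_prime_utr",
    "exon",
    "intron",
    "three_prime",
    "distal_intergenic",
)

SUBREGIONS = ("GeneExt", "Promoter", "Exon", "Intron", "Downstream")


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    introns: list[tuple[int, int]] = field(default_factory=list)
    promoter: tuple[int, int] = (0, 0)
    geneext: tuple[int, int] = (0, 0)
    downstream: tuple[int, int] = (0, 0)
    utr5: list[tuple[int, int]] = field(default_factory=list)

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass
class GenicModel:
    genes: dict[str, GeneModel]
    chrom_lengths: dict[str, int]
    _region_trees: dict[str, IntervalTree] = field(default_factory=dict)
    _category_trees: dict[tuple[str, str], IntervalTree] = field(default_factory=dict)
    _tss_by_chrom: dict[str, np.ndarray] = field(default_factory=dict)
    _tss_strands: dict[str, np.ndarray] = field(default_factory=dict)

    def regions_at(self, chrom: str, pos: int):
        """Yield (gene_id, sub-region) pairs containing a position."""
        tree = self._region_trees.get(chrom)
        if tree is None:
            return
        for iv in tree[pos]:
            yield iv.data

    def category_hit(self, category: str, chrom: str, pos: int) -> bool:
        tree = self._category_trees.get((category, chrom))
        return bool(tree is not None and tree[pos])

    def tss_anchors(self) -> list[tuple[str, int, str]]:
        return [(g.chrom, g.tss, g.strand) for g in self.genes.values()]

    def cds_start_anchors(self) -> list[tuple[str, int, str]]:
        out = []
        for g in self.genes.values():
            if not g.cds:
                continue
            pos = min(s for s, _ in g.cds) if g.strand == "+" else max(e for _, e in g.cds) - 1
            out.append((g.chrom, pos, g.strand))
        return out


_ATTR_RE = re.compile(r'(\w+) "([^"]+)"')


def parse_gtf(path) -> pd.DataFrame:
    """Read a GTF into a frame of gene/exon/CDS features (0-based half-open)."""
    from .ioutils import _open_text

    rows = []
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] not in ("gene", "exon", "CDS"):
                continue
            attrs = dict(_ATTR_RE.findall(f[8]))
            rows.append(
                (
                    f[0],
                    f[2],
                    int(f[3]) - 1,
                    int(f[4]),
                    f[6],
                    attrs.get("gene_id", ""),
                    attrs.get("transcript_id", attrs.get("gene_id", "")),
                )
            )
    return pd.DataFrame(
        rows, columns=["chrom", "feature", "start", "end", "strand", "gene_id", "transcript_id"]
    )


def build_genic_regions(
    annotation,
    chrom_lengths: dict[str, int] | None = None,
    flank: int = 2500,
    promoter_up: int = 2000,
    promoter_down: int = 200,
) -> GenicModel:
    """Build the genic model from a GTF path or a pre-parsed feature frame.

    One representative transcript per gene (the longest by exonic span);
    genes without exon records are skipped with a warning. Intervals are
    clipped to chromosome bounds when lengths are supplied.
    """
    import logging

    log = logging.getLogger(__name__)
    gtf = annotation if isinstance(annotation, pd.DataFrame) else parse_gtf(annotation)
    chrom_lengths = dict(chrom_lengths or {})
    genes: dict[str, GeneModel] = {}

    for gene_id, sub in gtf.groupby("gene_id", sort=True):
        exon_rows = sub[sub.feature == "exon"]
        if exon_rows.empty:
            log.warning("gene %s has no exons; skipped", gene_id)
            continue
        # representative transcript: longest total exonic length
        tx = (
            exon_rows.assign(length=exon_rows.end - exon_rows.start)
            .groupby("transcript_id")["length"]
            .sum()
            .idxmax()
        )
        exon_rows = exon_rows[exon_rows.transcript_id == tx]
        cds_rows = sub[(sub.feature == "CDS") & (sub.transcript_id == tx)]
        chrom = sub.chrom.iloc[0]
        strand = sub.strand.iloc[0]
        exons = sorted(zip(exon_rows.start, exon_rows.end))
        cds = sorted(zip(cds_rows.start, cds_rows.end))
        gene_rows = sub[sub.feature == "gene"]
        start = int(gene_rows.start.min()) if not gene_rows.empty else exons[0][0]
        end = int(gene_rows.end.max()) if not gene_rows.empty else exons[-1][1]
        g = GeneModel(gene_id, chrom, start, end, strand, exons, cds)
        _derive_subregions(g, chrom_lengths.get(chrom), flank, promoter_up, promoter_down)
        genes[gene_id] = g

    model = GenicModel(genes=genes, chrom_lengths=chrom_lengths)
    _index(model)
    return model


def _clip(start: int, end: int, chrom_len: int | None) -> tuple[int, int]:
    start = max(0, start)
    if chrom_len is not None:
        end = min(end, chrom_len)
    return start, max(start, end)


def _derive_subregions(g: GeneModel, chrom_len, flank, up, down) -> None:
    g.geneext = _clip(g.start - flank, g.end + flank, chrom_len)
    if g.strand == "+":
        g.promoter = _clip(g.tss - up, g.tss + down, chrom_len)
        g.downstream = _clip(g.end, g.end + flank, chrom_len)
    else:
        # oriented offsets [-up, +down) mirror to [tss-down+1, tss+up+1)
        g.promoter = _clip(g.tss - down + 1, g.tss + up + 1, chrom_len)
        g.downstream = _clip(g.start - flank, g.start, chrom_len)
    g.introns = [
        (e0_end, e1_start)
        for (_, e0_end), (e1_start, _) in zip(g.exons, g.exons[1:])
        if e1_start > e0_end
    ]
    g.utr5 = _five_prime_utr(g)


def _five_prime_utr(g: GeneModel) -> list[tuple[int, int]]:
    if not g.cds:
        return []
    if g.strand == "+":
        cds_lo = min(s for s, _ in g.cds)
        return [(s, min(e, cds_lo)) for s, e in g.exons if s < cds_lo]
    cds_hi = max(e for _, e in g.cds)
    return [(max(s, cds_hi), e) for s, e in g.exons if e > cds_hi]


def _index(model: GenicModel) -> None:
    for g in model.genes.values():
        tree = model._region_trees.setdefault(g.chrom, IntervalTree())
        for region, ivs in (
            ("GeneExt", [g.geneext]),
            ("Promoter", [g.promoter]),
            ("Exon", g.exons),
            ("Intron", g.introns),
            ("Downstream", [g.downstream]),
        ):
            for s, e in ivs:
                if e > s:
                    tree[s:e] = (g.gene_id, region)
        for cat, ivs in (
            ("five_prime_utr", g.utr5),
            ("exon", g.exons),
            ("intron", g.introns),
            ("three_prime", [g.downstream]),
        ):
            ctree = model._category_trees.setdefault((cat, g.chrom), IntervalTree())
            for s, e in ivs:
                if e > s:
                    ctree[s:e] = g.gene_id
        model._tss_by_chrom.setdefault(g.chrom, []).append(g.tss)
        model._tss_strands.setdefault(g.chrom, []).append(g.strand)
    for chrom in list(model._tss_by_chrom):
        order = np.argsort(model._tss_by_chrom[chrom], kind="stable")
        model._tss_by_chrom[chrom] = np.asarray(model._tss_by_chrom[chrom])[order]
        model._tss_strands[chrom] = np.asarray(model._tss_strands[chrom])[order]


# ---------------------------------------------------------------------------
# site annotation
# ---------------------------------------------------------------------------


def nearest_tss_distance(model: GenicModel, chrom: str, pos: int) -> float:
    """Signed distance to the nearest TSS, oriented by that gene's strand
    (positive = downstream of the TSS in transcription direction)."""
    tss = model._tss_by_chrom.get(chrom)
    if tss is None or not tss.size:
        return float("nan")
    i = bisect_left(tss.tolist(), pos)
    best = None
    for j in (i - 1, i):
        if 0 <= j < tss.size:
            d = abs(pos - int(tss[j]))
            if best is None or d < best[0]:
                strand = model._tss_strands[chrom][j]
                signed = (pos - int(tss[j])) if strand == "+" else (int(tss[j]) - pos)
                best = (d, signed)
    return float(best[1])


def annotate_site(site, model: GenicModel) -> str:
    """One annotation category per site, by precedence."""
    # promoter bins cover the 5' upstream flank of the TSS plus the same
    # +200 bp downstream fringe as the Promoter sub-region
    d = nearest_tss_distance(model, site.chrom, site.pos)
    if not np.isnan(d) and d <= 200:
        if d > -1000:
            return "promoter_1kb"
        if d > -5000:
            return "promoter_5kb"
    for cat in ("five_prime_utr", "exon", "intron", "three_prime"):
        if model.category_hit(cat, site.chrom, site.pos):
            return cat
    return "distal_intergenic"


def annotate_sample(sites, model: GenicModel) -> pd.Series:
    """Per-category percentages over a sample (sums to 100; empty in, empty out)."""
    if not sites:
        return pd.Series(dtype=float)
    cats = pd.Series([annotate_site(s, model) for s in sites])
    pct = cats.value_counts().reindex(ANNOTATION_CATEGORIES, fill_value=0) / len(cats) * 100
    return pct


# ---------------------------------------------------------------------------
# anchored profiles and TSS enrichment
# ---------------------------------------------------------------------------


@dataclass
class AnchoredProfile:
    """Per-offset site counts around a set of oriented anchors."""

    offsets: np.ndarray  # left edge of each offset bin
    counts: np.ndarray  # total counts per bin over all anchors
    mean: np.ndarray  # mean per-anchor count per bin
    sem: np.ndarray
    n_anchors: int
    bin_size: int

    def zscores(self) -> np.ndarray:
        return zscore(self.counts.astype(float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offset": self.offsets,
                "count": self.counts,
                "mean": self.mean,
                "sem": self.sem,
                "z": self.zscores(),
            }
        )


def zscore(x: np.ndarray, ddof: int = 1) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=ddof) if x.size > ddof else 0.0
    if sd == 0:
        return np.full_like(x, np.nan)
    return (x - x.mean()) / sd


def anchored_profile(
    sites, anchors: list[tuple[str, int, str]], window: int, bin_size: int = 100
) -> AnchoredProfile:
    """Aggregate site counts per strand-oriented offset bin over anchors.

    Offsets run from -window to +window in transcription orientation of
    each anchor. Mean and SEM are across anchors.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    pos_by_chrom: dict[str, np.ndarray] = {}
    for s in sites:
        pos_by_chrom.setdefault(s.chrom, []).append(s.pos)
    pos_by_chrom = {c: np.sort(np.asarray(v)) for c, v in pos_by_chrom.items()}

    edges = np.arange(-window, window + bin_size, bin_size)
    nbins = len(edges) - 1
    total = np.zeros(nbins)
    total_sq = np.zeros(nbins)
    for chrom, apos, astrand in anchors:
        positions = pos_by_chrom.get(chrom)
        if positions is None:
            hist = np.zeros(nbins)
        else:
            lo = np.searchsorted(positions, apos - window, side="left")
            hi = np.searchsorted(positions, apos + window, side="right")
            offs = positions[lo:hi] - apos
            if astrand == "-":
                offs = -offs
            hist, _ = np.histogram(offs, bins=edges)
        total += hist
        total_sq += hist.astype(float) ** 2
    n = len(anchors)
    mean = total / n if n else np.full(nbins, np.nan)
    if n > 1:
        var = (total_sq - n * mean**2) / (n - 1)
        sem = np.sqrt(np.clip(var, 0, None) / n)
    else:
        sem = np.full(nbins, np.nan)
    return AnchoredProfile(
        offsets=edges[:-1], counts=total, mean=mean, sem=sem, n_anchors=n, bin_size=bin_size
    )


def tss_enrichment_score(
    sites, model: GenicModel, proximal: int = 1000, window: int = 5000
) -> float:
    """Width-normalized TSS fold enrichment.

    FE = (fraction of window-contained sites within the proximal band) /
    (proximal width / window width); 1 under uniform placement, NaN when
    no site falls in the window.
    """
    dists = [nearest_tss_distance(model, s.chrom, s.pos) for s in sites]
    dists = np.asarray([d for d in dists if not np.isnan(d)])
    in_window = np.abs(dists) <= window
    n_win = int(in_window.sum())
    if n_win == 0:
        return float("nan")
    n_prox = int((np.abs(dists[in_window]) <= proximal).sum())
    return (n_prox / n_win) / (proximal / window)


def cgi_anchors(bed_rows, which: str = "start") -> list[tuple[str, int, str]]:
    """CpG-island anchors from BED rows, at interval starts or ends."""
    if which not in ("start", "end"):
        raise ValueError("which must be 'start' or 'end'")
    out = []
    for row in bed_rows:
        pos = int(row[1]) if which == "start" else int(row[2]) - 1
        out.append((row[0], pos, "+"))
    return out
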