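"""Statistical analyses over priming sites.

Background estimation from negative controls, antisense/sense strand-bias
tests, priming-expression association (Fisher), TSS-distance
stratification of expression, perturbation time-course dynamics,
binarized Jaccard clustering of interval tracks, epigenome fold
enrichment with rank-quantile normalization, and a read sequence
complexity score.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log2

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .genemodel import GenicModel, nearest_tss_distance, tss_enrichment_score

STRAND_REGIONS = ("tss_up", "tss_down", "exon", "intron")


# ---------------------------------------------------------------------------
# background
# ---------------------------------------------------------------------------


def background_rate(control_median: float, noncontrol_median: float) -> float:
    """Background percentage: 100 x control / non-control medians, 1 decimal.

    The median total priming count of the no-probe/no-laser controls over
    that of the matched non-control samples estimates the overall false
    positive rate.
    """
    if noncontrol_median <= 0:
        raise ValueError("non-control median must be positive")
    return round(100.0 * control_median / noncontrol_median, 1)


# ---------------------------------------------------------------------------
# strand bias
# ---------------------------------------------------------------------------


@dataclass
class StrandRatio:
    region: str
    antisense: int
    sense: int
    sample_id: str

    @property
    def ratio(self) -> float | None:
        """Antisense/sense ratio; None below the 5-count floor."""
        if self.antisense + self.sense < 5:
            return None
        if self.sense == 0:
            return float("inf")
        return self.antisense / self.sense


def antisense_sense_counts(
    sites, model: GenicModel, window: int = 5000
) -> dict[str, tuple[int, int]]:
    """Count antisense/sense sites per sub-genic region for one sample.

    A site is antisense when its strand is opposite the host gene's
    strand. TSS regions are the oriented 5 kb windows up/downstream of
    the TSS; exon/intron use the gene model intervals, counted once per
    gene even where genes overlap.
    """
    counts = {r: [0, 0] for r in STRAND_REGIONS}
    for s in sites:
        regions = set()
        for gene_id, region in model.regions_at(s.chrom, s.pos):
            g = model.genes[gene_id]
            anti = s.strand != g.strand
            if region == "Exon":
                regions.add(("exon", gene_id, anti))
            elif region == "Intron":
                regions.add(("intron", gene_id, anti))
        d = nearest_tss_distance(model, s.chrom, s.pos)
        if not np.isnan(d) and abs(d) <= window:
            # the sign of d is oriented by the nearest-TSS gene's strand
            tss_region = "tss_down" if d >= 0 else "tss_up"
            regions.add((tss_region, "nearest_tss", _is_antisense_nearest(s, model)))
        for region, _gene, anti in regions:
            counts[region][0 if anti else 1] += 1
    return {r: (a, s_) for r, (a, s_) in counts.items()}


def _is_antisense_nearest(site, model: GenicModel) -> bool:
    tss = model._tss_by_chrom.get(site.chrom)
    if tss is None or not tss.size:
        return False
    i = int(np.argmin(np.abs(tss - site.pos)))
    return site.strand != model._tss_strands[site.chrom][i]


def strand_ratios(
    sites_by_sample: dict[str, list], model: GenicModel
) -> list[StrandRatio]:
    out = []
    for sample_id, sites in sites_by_sample.items():
        for region, (anti, sense) in antisense_sense_counts(sites, model).items():
            out.append(StrandRatio(region, anti, sense, sample_id))
    return out


def strand_ratio_test(
    ratios_a: list[float], ratios_b: list[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum between two groups of per-sample ratios.

    Exact null distribution for small groups (n <= 20 per side), normal
    approximation above. Returns (statistic, p). Raises if either group
    has fewer than two valid samples.
    """
    a = [r for r in ratios_a if r is not None and np.isfinite(r)]
    b = [r for r in ratios_b if r is not None and np.isfinite(r)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 valid samples per group")
    method = "exact" if max(len(a), len(b)) <= 20 else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# priming-expression association
# ---------------------------------------------------------------------------


def highly_expressed(expression: pd.Series, universe=None) -> set:
    """Genes with expression strictly above the median over the universe.

    The universe defaults to all genes in the table, zeros included.
    """
    if universe is not None:
        expression = expression.reindex(list(universe)).fillna(0.0)
    med = float(expression.median())
    return set(expression.index[expression > med])


@dataclass
class FisherResult:
    odds_ratio: float
    p_value: float
    table: tuple[tuple[int, int], tuple[int, int]]
    pct_primed_expressed: float  # % of primed genes that are highly expressed
    pct_expressed_primed: float  # % of highly expressed genes that are primed


def fisher_association(primed: set, high_expressed: set, universe: set) -> FisherResult:
    """Fisher's exact test for priming vs high expression over a universe."""
    if not universe:
        raise ValueError("empty gene universe")
    primed = primed & universe
    high = high_expressed & universe
    a = len(primed & high)
    b = len(primed - high)
    c = len(high - primed)
    d = len(universe - primed - high)
    oddsratio, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if not primed:
        oddsratio = 0.0  # no primed genes: no association by definition
    pct_pe = 100.0 * a / len(primed) if primed else 0.0
    pct_ep = 100.0 * a / len(high) if high else 0.0
    return FisherResult(float(oddsratio), float(p), ((a, b), (c, d)), pct_pe, pct_ep)


# ---------------------------------------------------------------------------
# TSS-distance stratification of expression
# ---------------------------------------------------------------------------


def gene_tss_priming_distance(
    sites, model: GenicModel, max_dist: int = 2500
) -> pd.Series:
    """Per-gene signed distance of the nearest priming site to the TSS.

    Distance is oriented by transcription direction; genes whose nearest
    site lies beyond ``max_dist`` in either direction are excluded.
    """
    best: dict[str, float] = {}
    for s in sites:
        for gene_id, g in model.genes.items():
            if g.chrom != s.chrom:
                continue
            d = (s.pos - g.tss) if g.strand == "+" else (g.tss - s.pos)
            if abs(d) <= max_dist and (gene_id not in best or abs(d) < abs(best[gene_id])):
                best[gene_id] = float(d)
    return pd.Series(best, dtype=float)


def stratify_expression_by_tss_distance(
    sites,
    model: GenicModel,
    expression: pd.Series,
    max_dist: int = 2500,
    edges: tuple[int, ...] = (0, 250, 500, 1000, 1500, 2500),
    cap_quantile: float = 0.90,
) -> pd.DataFrame:
    """Expression distributions stratified by |priming distance to TSS|.

    Expression values are capped at ``cap_quantile``; the frame carries
    gene, signed distance, stratum label and capped expression, with the
    Spearman correlation of |distance| vs expression in ``.attrs``.
    """
    dist = gene_tss_priming_distance(sites, model, max_dist=max_dist)
    genes = [g for g in dist.index if g in expression.index]
    if not genes:
        return pd.DataFrame(columns=["gene_id", "distance", "stratum", "expression"])
    expr = expression.loc[genes].astype(float)
    cap = expr.quantile(cap_quantile)
    expr = expr.clip(upper=cap)
    absd = dist.loc[genes].abs()
    labels = [f"{lo}-{hi}" for lo, hi in zip(edges, edges[1:])]
    strata = pd.cut(absd, bins=edges, labels=labels, include_lowest=True)
    out = pd.DataFrame(
        {
            "gene_id": genes,
            "distance": dist.loc[genes].values,
            "stratum": strata.values,
            "expression": expr.values,
        }
    )
    if len(genes) > 2 and expr.nunique() > 1 and absd.nunique() > 1:
        rho, _ = sps.spearmanr(absd.values, expr.values)
    else:
        rho = float("nan")
    out.attrs["spearman_r"] = float(rho) if rho is not None else float("nan")
    return out


# ---------------------------------------------------------------------------
# perturbation dynamics
# ---------------------------------------------------------------------------


@dataclass
class TimepointSeries:
    timepoints: list[str]
    fe: dict[str, float]  # TSS fold enrichment per timepoint
    distances: dict[str, np.ndarray]  # |sorted| signed TSS distances

    def ecdf(self, timepoint: str, x: float) -> float:
        d = self.distances.get(timepoint)
        if d is None or d.size == 0:
            return float("nan")
        return float(np.searchsorted(np.sort(d), x, side="right") / d.size)


def tss_dynamics(
    sites_by_timepoint: dict[str, list],
    model: GenicModel,
    window: int = 5000,
    proximal: int = 1000,
) -> TimepointSeries:
    """Distance-to-TSS empirical distribution and fold enrichment per timepoint.

    Single-cell replicates should already be aggregated per timepoint.
    Missing timepoints yield NaN FE and empty distance vectors.
    """
    fe, dists = {}, {}
    for tp, sites in sites_by_timepoint.items():
        ds = np.asarray(
            [
                d
                for s in sites
                if not np.isnan(d := nearest_tss_distance(model, s.chrom, s.pos))
                and abs(d) <= window
            ]
        )
        dists[tp] = ds
        fe[tp] = tss_enrichment_score(sites, model, proximal=proximal, window=window)
    return TimepointSeries(list(sites_by_timepoint), fe, dists)


def normalize_library(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample column to the median total priming count."""
    totals = counts.sum(axis=0)
    totals = totals.replace(0, np.nan)
    return counts / totals * float(totals.median())


def select_trend_genes(
    counts: pd.DataFrame,
    trend: np.ndarray,
    r_min: float = 0.9,
    normalize: bool = True,
) -> tuple[list[str], list[str], pd.Series]:
    """Genes whose priming counts track the TSS-enrichment trend.

    Pearson r of each gene's (library-normalized) counts against the
    trend: r >= r_min selects correlated genes, r <= -r_min
    anticorrelated. Constant gene vectors have undefined r and are
    skipped. Returns (correlated, anticorrelated, r per testable gene).
    """
    trend = np.asarray(trend, dtype=float)
    if counts.shape[1] != trend.size:
        raise ValueError("trend length must equal number of timepoints")
    mat = normalize_library(counts) if normalize else counts.astype(float)
    rs = {}
    for gene, row in mat.iterrows():
        x = row.values.astype(float)
        if np.isnan(x).any() or np.std(x) == 0 or np.std(trend) == 0:
            continue
        rs[gene] = float(np.corrcoef(x, trend)[0, 1])
    r = pd.Series(rs, dtype=float)
    return list(r.index[r >= r_min]), list(r.index[r <= -r_min]), r


def select_differential_genes(
    baseline: pd.Series,
    treated: pd.Series,
    min_fold: float = 2.0,
    min_count: int = 5,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Genes whose priming changes by >= min_fold between two conditions.

    A descriptive fold-change + minimum-count rule over (pseudocounted)
    per-gene priming counts; no significance model is claimed. Returns a
    frame with baseline/treated counts, log2 fold change, and direction
    ('gain'/'loss'), restricted to genes meeting min_count in at least
    one condition.
    """
    genes = baseline.index.union(treated.index)
    b = baseline.reindex(genes).fillna(0.0).astype(float)
    t = treated.reindex(genes).fillna(0.0).astype(float)
    keep = (b >= min_count) | (t >= min_count)
    lfc = np.log2((t + pseudocount) / (b + pseudocount))
    hit = keep & (np.abs(lfc) >= np.log2(min_fold))
    out = pd.DataFrame(
        {
            "baseline": b[hit],
            "treated": t[hit],
            "log2_fold_change": lfc[hit],
            "direction": np.where(lfc[hit] > 0, "gain", "loss"),
        }
    )
    return out.sort_values("log2_fold_change")


# ---------------------------------------------------------------------------
# track clustering and enrichment
# ---------------------------------------------------------------------------


def binarize_track(
    intervals, chrom_lengths: dict[str, int], bin_size: int
) -> np.ndarray:
    """Genome-wide boolean bin vector: 1 iff >= 1 interval overlaps the bin."""
    chunks = []
    for chrom in sorted(chrom_lengths):
        n = -(-chrom_lengths[chrom] // bin_size)
        v = np.zeros(n, dtype=bool)
        for row in intervals:
            if row[0] != chrom:
                continue
            lo = int(row[1]) // bin_size
            hi = (int(row[2]) - 1) // bin_size
            v[lo : hi + 1] = True
        chunks.append(v)
    return np.concatenate(chunks) if chunks else np.zeros(0, dtype=bool)


def jaccard_distance(a: np.ndarray, b: np.ndarray) -> float:
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return 1.0 - np.logical_and(a, b).sum() / union


def binarized_jaccard_cluster(
    tracks: dict[str, list],
    chrom_lengths: dict[str, int],
    bin_size: int = 5000,
) -> tuple[pd.DataFrame, np.ndarray, list[str], str]:
    """Average-linkage hierarchical clustering on binarized Jaccard distance.

    Returns (distance matrix, linkage, leaf order, newick text). All-zero
    tracks sit at distance 1 from everything (with a warning).
    """
    import logging

    names = list(tracks)
    vecs = {n: binarize_track(tracks[n], chrom_lengths, bin_size) for n in names}
    for n, v in vecs.items():
        if not v.any():
            logging.getLogger(__name__).warning("track %s has no covered bins", n)
    m = len(names)
    dist = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            dist[i, j] = dist[j, i] = jaccard_distance(vecs[names[i]], vecs[names[j]])
    dm = pd.DataFrame(dist, index=names, columns=names)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = [names[i] for i in hierarchy.leaves_list(link)]
    newick = _to_newick(hierarchy.to_tree(link), names)
    return dm, link, order, newick


def _to_newick(node, names) -> str:
    def rec(n):
        if n.is_leaf():
            return names[n.id]
        return f"({rec(n.left)},{rec(n.right)}):{n.dist:.4g}"

    return rec(node) + ";"


def region_enrichment(
    sites, track_intervals, chrom_lengths: dict[str, int]
) -> float:
    """Fold enrichment of sites in a track vs its genome coverage fraction.

    FE = (sites inside the track) / (total sites x coverage fraction f),
    the binomial-expectation model. Undefined (error) when f = 0.
    """
    genome = sum(chrom_lengths.values())
    covered: dict[str, list[tuple[int, int]]] = {}
    for row in track_intervals:
        covered.setdefault(row[0], []).append((int(row[1]), int(row[2])))
    cov_len = 0
    for chrom, ivs in covered.items():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s > cur_e:
                cov_len += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        cov_len += cur_e - cur_s
    f = cov_len / genome
    if f == 0:
        raise ValueError("track covers no genome; enrichment undefined")
    total = len(sites)
    if total == 0:
        return float("nan")
    inside = 0
    for s in sites:
        for lo, hi in covered.get(s.chrom, ()):
            if lo <= s.pos < hi:
                inside += 1
                break
    return inside / (total * f)


def quantile_normalize(scores: pd.Series) -> pd.Series:
    """Map scores to rank quantiles in [0, 1] (ties get the average rank)."""
    n = len(scores)
    if n < 2:
        return pd.Series(np.zeros(n), index=scores.index)
    ranks = sps.rankdata(scores.values, method="average")
    return pd.Series((ranks - 1) / (n - 1), index=scores.index)


# ---------------------------------------------------------------------------
# sequence complexity
# ---------------------------------------------------------------------------


def sequence_complexity(seq: str) -> float:
    """Normalized Shannon entropy of overlapping dinucleotide usage.

    0 for a homopolymer, 1 when all 16 dinucleotides are used equally.
    """
    if len(seq) < 2:
        raise ValueError("sequence must be at least 2 bp")
    counts: dict[str, int] = {}
    for i in range(len(seq) - 1):
        di = seq[i : i + 2]
        counts[di] = counts.get(di, 0) + 1
    total = sum(counts.values())
    h = -sum((c / total) * log2(c / total) for c in counts.values())
    return h / 4.0  # log2(16)
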