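"""Synthetic genomes, planted ssDNA truth, and structured read simulation.

The generator emulates the study design end-to-end: a toy diploid genome
with non-overlapping genes on both strands, a circular mitochondrial contig
with heavy/light-strand genes and a D-loop, planted strand-labelled ssDNA
intervals (TSS-enriched plus intergenic), and 75 bp paired-end reads whose
structure carries the probe's 5' barcode segment (2p) and 3' poly-C-derived
segment (pC) in the four quality configurations A-D. Negative-control
samples (no-probe/no-laser, probe-but-no-laser, nuclease-digested) are
parameter presets of the same simulator, not separate code paths.

Strand semantics: a planted region's strand is the annealing *template*
strand. The synthesized first-strand DNA is its complement, so the emitted
read aligns to the strand opposite the template. Planting the template on
the gene strand therefore yields a read mapping antisense to the gene,
which is how ``antisense_bias`` > 1 produces an antisense excess in genic
regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .ioutils import _open_text, write_fasta

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# Probe segments. 2p = constant tail + per-sample barcode; pC is the
# poly-C-derived primer appearing at the insert 3' end (mate2 5' end).
PRIMER_2P_CONST = "ACACGACGCTCTTCCGATCT"
PRIMER_PC = "CCCCCCCCC"
DEFAULT_BARCODES = {
    "BC01": "ACGTACGT",
    "BC02": "TGCATGCA",
    "BC03": "GATCGATC",
    "BC04": "CTAGCTAG",
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the simulator.

    Lengths are in bp; fractions in [0, 1]. ``antisense_bias`` is the
    expected ratio of antisense- to sense-strand priming in genic regions;
    ``background_rate`` the fraction of reads arising uniformly at random;
    ``n_cells_k`` the per-sample cell count k that drives the 2xk bin cap.
    """

    seed: int = 0
    genome_length: int = 200_000
    n_chromosomes: int = 2
    n_genes: int = 24
    gene_length: tuple[int, int] = (2_000, 6_000)
    n_ssdna_regions: int = 200
    region_length: tuple[int, int] = (200, 1_000)
    ssdna_tss_fraction: float = 0.6
    antisense_bias: float = 2.0
    background_rate: float = 0.05
    reads_per_region: int = 5
    n_cells_k: int = 1
    read_length: int = 75
    insert_length: tuple[int, int] = (20, 60)
    class_mixture: tuple[tuple[str, float], ...] = (
        ("A", 0.70),
        ("B", 0.20),
        ("C", 0.08),
        ("D", 0.02),
    )
    substitution_rate: float = 0.0
    poly_n_fraction: float = 0.05
    digestion_efficiency: float = 0.8
    mito_length: int = 16_000
    n_mito_genes: int = 10
    dloop_interval: tuple[int, int] = (15_300, 16_000)

    def __post_init__(self):
        if self.genome_length <= 0 or self.mito_length <= 0:
            raise ValueError("lengths must be positive")
        for frac in (
            self.ssdna_tss_fraction,
            self.background_rate,
            self.substitution_rate,
            self.poly_n_fraction,
            self.digestion_efficiency,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction out of [0,1]: {frac}")
        if self.antisense_bias <= 0:
            raise ValueError("antisense_bias must be > 0")
        if not (0 <= self.dloop_interval[0] < self.dloop_interval[1] <= self.mito_length):
            raise ValueError("dloop_interval must lie within the mito contig")
        if self.n_cells_k < 1:
            raise ValueError("n_cells_k must be >= 1")


@dataclass
class GeneRecord:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class Genome:
    sequences: dict[str, str]
    genes: list[GeneRecord]
    mito_contig: str
    dloop: tuple[int, int]
    heavy_strand: str = "+"

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    @property
    def nuclear_chroms(self) -> list[str]:
        return [c for c in self.sequences if c != self.mito_contig]


@dataclass
class PlantedRegion:
    region_id: str
    chrom: str
    start: int
    end: int
    strand: str  # annealing template strand
    anchor_gene: str | None = None  # gene whose TSS anchored the placement


@dataclass
class TruthTable:
    """Planted regions plus the region of origin for every emitted read."""

    regions: list[PlantedRegion] = field(default_factory=list)
    read_origin: dict[str, str] = field(default_factory=dict)

    def region_by_id(self, region_id: str) -> PlantedRegion:
        return next(r for r in self.regions if r.region_id == region_id)


@dataclass
class RawReadPair:
    read_id: str
    mate1: str
    mate2: str
    qual1: str
    qual2: str
    sample_id: str


@dataclass
class TrueAlignment:
    """The simulator's own record of where a read's insert came from."""

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str
    quality_class: str  # intended class at generation time


# ---------------------------------------------------------------------------
# genome + annotation
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _place_nonoverlapping(
    rng: np.random.Generator, chrom_len: int, lengths: list[int], gap: int = 200
) -> list[tuple[int, int]]:
    """Greedy random placement of non-overlapping intervals; sizing error if
    the intervals cannot fit."""
    total = sum(lengths) + gap * len(lengths)
    if total > chrom_len:
        raise ValueError(
            f"cannot place {len(lengths)} intervals totalling {total} bp "
            f"(with gaps) on a {chrom_len} bp chromosome"
        )
    # distribute leftover space as random gaps
    slack = chrom_len - total
    cuts = np.sort(rng.integers(0, slack + 1, len(lengths)))
    placed = []
    cursor = 0
    prev_cut = 0
    for L, cut in zip(lengths, cuts):
        cursor += int(cut - prev_cut) + gap // 2
        placed.append((cursor, cursor + L))
        cursor += L + gap // 2
        prev_cut = cut
    return placed


def generate_genome(config: SyntheticConfig) -> tuple[Genome, TruthTable]:
    """Build the toy genome and annotation; deterministic for a fixed seed.

    Returns the genome (sequences + gene records + mito layout) and an empty
    truth table to be filled by :func:`plant_ssdna` / :func:`simulate_reads`.
    """
    rng = np.random.default_rng(config.seed)
    chrom_len = config.genome_length // config.n_chromosomes
    sequences = {
        f"chr{i + 1}": _random_seq(rng, chrom_len) for i in range(config.n_chromosomes)
    }

    genes: list[GeneRecord] = []
    # spread genes evenly over chromosomes
    per_chrom = np.full(config.n_chromosomes, config.n_genes // config.n_chromosomes)
    per_chrom[: config.n_genes % config.n_chromosomes] += 1
    gidx = 0
    for ci, chrom in enumerate(sequences):
        n = int(per_chrom[ci])
        if n == 0:
            continue
        lengths = [int(rng.integers(*config.gene_length)) for _ in range(n)]
        try:
            spans = _place_nonoverlapping(rng, chrom_len, lengths)
        except ValueError as err:
            raise ValueError(f"genome too small to place {config.n_genes} genes") from err
        for start, end in spans:
            gidx += 1
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneRecord(
                    gene_id=f"G{gidx:04d}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    exons=_make_exons(rng, start, end),
                    cds=[],
                )
            )
    for g in genes:
        g.cds = _make_cds(g)

    # circular mito contig: genes outside the D-loop, mostly on the heavy
    # strand (here the '+' reference strand by convention)
    mito_seq = _random_seq(rng, config.mito_length)
    sequences["chrM"] = mito_seq
    dstart, dend = config.dloop_interval
    coding_len = dstart  # keep genes upstream of the D-loop
    mlen = [int(rng.integers(300, 900)) for _ in range(config.n_mito_genes)]
    spans = _place_nonoverlapping(rng, coding_len, mlen, gap=60)
    for i, (start, end) in enumerate(spans):
        strand = "+" if rng.random() < 0.8 else "-"
        genes.append(
            GeneRecord(
                gene_id=f"MT{i + 1:02d}",
                chrom="chrM",
                start=start,
                end=end,
                strand=strand,
                exons=[(start, end)],
                cds=[(start, end)],
            )
        )

    genome = Genome(
        sequences=sequences,
        genes=genes,
        mito_contig="chrM",
        dloop=config.dloop_interval,
    )
    return genome, TruthTable()


def _make_exons(rng, start, end) -> list[tuple[int, int]]:
    n_exons = int(rng.integers(2, 5))
    length = end - start
    # pick internal breakpoints; alternate exon/intron blocks
    n_blocks = 2 * n_exons - 1
    cuts = np.sort(rng.choice(np.arange(1, length), size=n_blocks - 1, replace=False))
    bounds = [0, *cuts.tolist(), length]
    exons = []
    for i in range(0, n_blocks, 2):
        exons.append((start + bounds[i], start + bounds[i + 1]))
    return exons


def _make_cds(gene: GeneRecord) -> list[tuple[int, int]]:
    # CDS = exonic span minus a UTR chunk at each transcript end
    exons = sorted(gene.exons)
    utr5 = min(200, (exons[0][1] - exons[0][0]) // 2)
    utr3 = min(200, (exons[-1][1] - exons[-1][0]) // 2)
    if gene.strand == "-":
        utr5, utr3 = utr3, utr5
    lo = exons[0][0] + utr5
    hi = exons[-1][1] - utr3
    return [(max(s, lo), min(e, hi)) for s, e in exons if min(e, hi) > max(s, lo)]


def write_gtf(genome: Genome, path) -> None:
    """Emit gene/exon/CDS records (1-based closed coordinates per GTF)."""
    with _open_text(path, "wt") as fh:
        for g in sorted(genome.genes, key=lambda g: (g.chrom, g.start)):
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.1";'
            rows = [("gene", g.start, g.end)]
            rows += [("exon", s, e) for s, e in sorted(g.exons)]
            rows += [("CDS", s, e) for s, e in sorted(g.cds)]
            for feat, s, e in rows:
                fh.write(
                    f"{g.chrom}\tchexseq_synth\t{feat}\t{s + 1}\t{e}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )


def write_genome(genome: Genome, fasta_path, gtf_path) -> None:
    write_fasta(genome.sequences, fasta_path)
    write_gtf(genome, gtf_path)


# ---------------------------------------------------------------------------
# planted ssDNA truth
# ---------------------------------------------------------------------------


def plant_ssdna(
    config: SyntheticConfig, genome: Genome, rng: np.random.Generator | None = None
) -> TruthTable:
    """Plant strand-labelled ssDNA intervals on the nuclear chromosomes.

    A fraction ``ssdna_tss_fraction`` of intervals is placed with midpoint
    within +/-5 kb of a randomly chosen TSS (reproducing the TSS enrichment
    the profile code must find); the rest avoid all TSS neighbourhoods.
    Each interval's strand is the template strand available for probe
    annealing: for TSS-anchored intervals the template falls on the anchor
    gene's strand with probability bias/(1+bias), so emitted reads map
    antisense to the gene with that probability.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    nuclear_genes = [g for g in genome.genes if g.chrom != genome.mito_contig]
    tss_by_chrom: dict[str, np.ndarray] = {}
    for g in nuclear_genes:
        tss_by_chrom.setdefault(g.chrom, [])
    for g in nuclear_genes:
        tss_by_chrom[g.chrom].append(g.tss)
    tss_by_chrom = {c: np.sort(np.array(v)) for c, v in tss_by_chrom.items()}
    chroms = genome.nuclear_chroms
    lengths = genome.chrom_lengths
    p_anti = config.antisense_bias / (1.0 + config.antisense_bias)

    regions: list[PlantedRegion] = []
    for i in range(config.n_ssdna_regions):
        L = int(rng.integers(*config.region_length))
        near_tss = rng.random() < config.ssdna_tss_fraction
        for _ in range(1000):
            if near_tss and nuclear_genes:
                g = nuclear_genes[int(rng.integers(len(nuclear_genes)))]
                # offsets concentrate near the TSS (truncated normal) so the
                # aggregate coverage shows the assay's TSS-centered peak
                offset = int(np.clip(rng.normal(0, 2000), -5000, 5000))
                mid = g.tss + offset
                chrom, anchor = g.chrom, g
            else:
                chrom = chroms[int(rng.integers(len(chroms)))]
                mid = int(rng.integers(0, lengths[chrom]))
                anchor = None
            mid = int(np.clip(mid, 0, lengths[chrom] - 1))
            start = max(0, mid - L // 2)
            end = min(lengths[chrom], start + L)
            mid = (start + end) // 2
            tss = tss_by_chrom.get(chrom, np.array([]))
            within = tss.size and np.min(np.abs(tss - mid)) <= 5000
            if near_tss == bool(within):
                break
        else:  # pragma: no cover - pathological configs only
            continue
        # strand bias applies to genic planting: any region whose midpoint
        # falls in a gene body takes the gene strand as template with
        # probability bias/(1+bias), making the read antisense that often
        host = next(
            (g for g in nuclear_genes if g.chrom == chrom and g.start <= mid < g.end),
            None,
        )
        if host is not None:
            template = host.strand if rng.random() < p_anti else _flip(host.strand)
            anchor = anchor or host
            # transcription-associated tracts stay within the transcribed
            # unit: clip genic regions to the host gene body
            start, end = max(start, host.start), min(end, host.end)
        elif anchor is not None:
            template = anchor.strand if rng.random() < p_anti else _flip(anchor.strand)
        else:
            template = "+" if rng.random() < 0.5 else "-"
        regions.append(
            PlantedRegion(
                region_id=f"R{i:04d}",
                chrom=chrom,
                start=start,
                end=end,
                strand=template,
                anchor_gene=anchor.gene_id if anchor else None,
            )
        )
    return TruthTable(regions=regions)


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def tss_proximal_fraction(truth: TruthTable, genome: Genome, window: int = 5000) -> float:
    """Fraction of planted intervals whose midpoint is within ``window`` of a TSS."""
    tss = {}
    for g in genome.genes:
        if g.chrom != genome.mito_contig:
            tss.setdefault(g.chrom, []).append(g.tss)
    tss = {c: np.sort(v) for c, v in tss.items()}
    hits = 0
    for r in truth.regions:
        mid = (r.start + r.end) // 2
        arr = tss.get(r.chrom)
        if arr is not None and arr.size and np.min(np.abs(arr - mid)) <= window:
            hits += 1
    return hits / len(truth.regions) if truth.regions else float("nan")


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


def simulate_reads(
    config: SyntheticConfig,
    genome: Genome,
    truth: TruthTable,
    sample_meta,
    rng: np.random.Generator | None = None,
) -> tuple[list[RawReadPair], list[TrueAlignment]]:
    """Emit structured read pairs for one sample and record their origins.

    ``sample_meta`` needs ``sample_id`` and ``condition`` attributes
    (see :class:`chexseq.priming.SampleMeta`). Conditions are presets:

    - ``noncontrol``: planted + background reads per config;
    - ``mungbean``: each planted read survives digestion with probability
      ``1 - digestion_efficiency``;
    - ``probe+laser-``: planted reads suppressed to 10%, class mixture
      shifted to mostly C (the probe is present but never activated);
    - ``probe-laser-``: no planted reads at all, background only.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    condition = getattr(sample_meta, "condition", "noncontrol")
    sample_id = sample_meta.sample_id
    barcode_id = getattr(sample_meta, "barcode", None) or "BC01"
    two_p = PRIMER_2P_CONST + DEFAULT_BARCODES[barcode_id]

    classes, weights = zip(*config.class_mixture)
    weights = np.array(weights, dtype=float)
    weights /= weights.sum()
    if condition == "probe+laser-":
        classes, weights = ("A", "B", "C", "D"), np.array([0.02, 0.02, 0.9, 0.06])

    # planted read budget
    origins: list[str] = []
    if condition != "probe-laser-":
        keep_p = 1.0
        if condition == "mungbean":
            keep_p = 1.0 - config.digestion_efficiency
        elif condition == "probe+laser-":
            keep_p = 0.1
        for r in truth.regions:
            n = int(rng.binomial(config.reads_per_region, keep_p))
            origins.extend([r.region_id] * n)
    n_planted = len(origins)
    if config.background_rate >= 1.0:
        n_bg = config.reads_per_region * max(1, len(truth.regions))
        origins = []
        n_planted = 0
    elif n_planted:
        n_bg = int(round(n_planted * config.background_rate / (1 - config.background_rate)))
    else:
        n_bg = int(round(config.reads_per_region * len(truth.regions) * config.background_rate))
    origins.extend(["background"] * n_bg)

    chroms = list(genome.sequences)
    clens = np.array([len(genome.sequences[c]) for c in chroms], dtype=float)
    cweights = clens / clens.sum()
    region_map = {r.region_id: r for r in truth.regions}

    pairs: list[RawReadPair] = []
    alns: list[TrueAlignment] = []
    for i, origin in enumerate(origins):
        read_id = f"{sample_id}:r{i:06d}"
        if origin == "background":
            chrom = chroms[int(rng.choice(len(chroms), p=cweights))]
            seq = genome.sequences[chrom]
            pos = int(rng.integers(0, len(seq)))
            read_strand = "+" if rng.random() < 0.5 else "-"
        else:
            r = region_map[origin]
            chrom = r.chrom
            seq = genome.sequences[chrom]
            pos = int(rng.integers(r.start, r.end))
            read_strand = _flip(r.strand)  # read maps opposite the template
        L = int(rng.integers(*config.insert_length))
        if read_strand == "+":
            insert = seq[pos : pos + L]
        else:
            lo = max(0, pos - L + 1)
            insert = revcomp(seq[lo : pos + 1])
        if len(insert) < config.insert_length[0]:
            insert = insert.ljust(config.insert_length[0], "A")
        insert = _mutate(insert, config.substitution_rate, rng)

        cls = classes[int(rng.choice(len(classes), p=weights))]
        mate1, mate2 = _build_pair(cls, two_p, insert, config.read_length, rng)
        if rng.random() < config.poly_n_fraction:
            mate1 += "N" * int(rng.integers(2, 6))
        pairs.append(
            RawReadPair(
                read_id=read_id,
                mate1=mate1,
                mate2=mate2,
                qual1="I" * len(mate1),
                qual2="I" * len(mate2),
                sample_id=sample_id,
            )
        )
        truth.read_origin[read_id] = origin
        start = pos if read_strand == "+" else max(0, pos - len(insert) + 1)
        alns.append(
            TrueAlignment(
                read_id=read_id,
                chrom=chrom,
                start=start,
                end=start + len(insert),
                strand=read_strand,
                quality_class=cls,
            )
        )
    return pairs, alns


def _mutate(seq: str, rate: float, rng) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = "ACGT"[int(rng.integers(0, 4))]
    return "".join(chars)


def _build_pair(cls, two_p, insert, read_length, rng):
    """Assemble mates for a quality class.

    Read-through (subclass 1 downstream) happens naturally when the
    fragment is shorter than the read: the mate runs into the reverse
    complement of the opposite primer.
    """
    frag1 = {"A": two_p + insert + revcomp(PRIMER_PC), "B": two_p + insert,
             "C": insert + revcomp(PRIMER_PC), "D": insert}[cls]
    frag2 = {"A": PRIMER_PC + revcomp(insert) + revcomp(two_p),
             "B": revcomp(insert) + revcomp(two_p),
             "C": PRIMER_PC + revcomp(insert),
             "D": revcomp(insert)}[cls]
    mate1 = frag1[:read_length]
    mate2 = frag2[:read_length]
    # pad very short fragments with random bases, like sequencing into the
    # adapter junk beyond the library insert
    while len(mate1) < min(read_length, 30):
        mate1 += "ACGT"[int(rng.integers(0, 4))]
    return mate1, mate2


def write_fastq_pair(pairs: list[RawReadPair], path1, path2) -> None:
    with _open_text(path1, "wt") as f1, _open_text(path2, "wt") as f2:
        for p in pairs:
            f1.write(f"@{p.read_id}/1\n{p.mate1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.read_id}/2\n{p.mate2}\n+\n{p.qual2}\n")


def write_truth_bed(truth: TruthTable, path) -> None:
    from .ioutils import write_bed

    write_bed(
        [(r.chrom, r.start, r.end, r.region_id, 0, r.strand) for r in truth.regions],
        path,
    )


def control_config(config: SyntheticConfig, **overrides) -> SyntheticConfig:
    """Convenience: derive a control-condition config preset."""
    return replace(config, **overrides)
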