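"""End-to-end orchestration: reads -> classes -> alignments -> sites -> stats.

Stages run in a fixed order (dedup -> trim/classify -> align -> duplicate
marking -> alignment filters -> site calling -> mask/blacklist -> per-bin
cap), with a per-stage read-count manifest that is monotonically
non-increasing through the filters. The synthetic entry point wires the
simulator to the same code path the file-based CLI uses.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import alnfilter, chexstats, genemodel, priming, readproc, synthdata

STAGES = (
    "raw",
    "deduplicated",
    "trimmed",
    "aligned",
    "filtered",
    "sites_called",
    "after_mask_blacklist",
    "after_cap",
)


@dataclass
class PipelineConfig:
    """Thresholds and policies; every value defaults to the study setting."""

    thresholds: alnfilter.FilterThresholds = field(default_factory=alnfilter.FilterThresholds)
    include_c: bool = True  # A/B/C merged (maximal sensitivity); False = strict A/B
    min_len: int = 10
    bin_size: int = 20
    cap_multiplier: int = 2
    mask_stride: int = 20
    build_mask: bool = True
    heavy_strand: str = "+"

    @classmethod
    def strict_ab(cls, **kw) -> "PipelineConfig":
        """The tightened re-analysis mode: A/B classes, mapped length >= 30."""
        thr = alnfilter.FilterThresholds(min_non_overlapping=30)
        return cls(thresholds=thr, include_c=False, **kw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thr = alnfilter.FilterThresholds(**raw.pop("thresholds", {}))
        return cls(thresholds=thr, **raw)


@dataclass
class SampleResult:
    meta: priming.SampleMeta
    sites: list[priming.PrimingSite]
    manifest: dict[str, int]
    classified: list[readproc.ClassifiedRead] = field(default_factory=list)


@dataclass
class PipelineResult:
    genome: synthdata.Genome
    truth: synthdata.TruthTable
    model: genemodel.GenicModel
    samples: dict[str, SampleResult]

    def sites_by_sample(self) -> dict[str, list[priming.PrimingSite]]:
        return {sid: r.sites for sid, r in self.samples.items()}

    def manifest_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {sid: r.manifest for sid, r in self.samples.items()}
        ).T.reindex(columns=list(STAGES))


def genome_feature_frame(genome: synthdata.Genome) -> pd.DataFrame:
    """Gene/exon/CDS features of a synthetic genome as a parsed-GTF frame."""
    rows = []
    for g in genome.genes:
        tx = f"{g.gene_id}.1"
        rows.append((g.chrom, "gene", g.start, g.end, g.strand, g.gene_id, tx))
        rows += [(g.chrom, "exon", s, e, g.strand, g.gene_id, tx) for s, e in g.exons]
        rows += [(g.chrom, "CDS", s, e, g.strand, g.gene_id, tx) for s, e in g.cds]
    return pd.DataFrame(
        rows, columns=["chrom", "feature", "start", "end", "strand", "gene_id", "transcript_id"]
    )


def build_model(genome: synthdata.Genome) -> genemodel.GenicModel:
    return genemodel.build_genic_regions(
        genome_feature_frame(genome), chrom_lengths=genome.chrom_lengths
    )


def process_sample(
    pairs: list[synthdata.RawReadPair],
    meta: priming.SampleMeta,
    aligner: alnfilter.ToyAligner,
    config: PipelineConfig,
    mask: alnfilter.MappabilityMask | None = None,
    blacklist: dict[str, list[tuple[int, int]]] | None = None,
    n_raw: int | None = None,
) -> SampleResult:
    """Run one deduplicated sample through trim -> align -> filter -> sites."""
    primers = readproc.PrimerSet(
        two_p=synthdata.PRIMER_2P_CONST + synthdata.DEFAULT_BARCODES[meta.barcode or "BC01"]
    )
    manifest = {"raw": n_raw if n_raw is not None else len(pairs), "deduplicated": len(pairs)}

    classified = []
    for p in pairs:
        cr = readproc.trim_primers(p, primers, min_len=config.min_len)
        if cr is not None:
            classified.append(cr)
    manifest["trimmed"] = len(classified)

    records: list[alnfilter.AlignmentRecord] = []
    quality_of: dict[str, str] = {}
    for cr in classified:
        if cr.quality_class == "D":
            continue
        if cr.quality_class == "C" and not config.include_c:
            continue
        rec = aligner.align_record(cr.read_id, cr.insert)
        if rec is None:
            continue
        records.append(rec)
        quality_of[cr.read_id] = cr.quality
    manifest["aligned"] = len(records)

    alnfilter.mark_duplicates(records)
    passed = [r for r in records if alnfilter.filter_alignment(r, config.thresholds)[0]]
    manifest["filtered"] = len(passed)

    sites = [
        priming.call_priming_site(r, quality_of[r.read_id], meta.sample_id, config.include_c)
        for r in passed
    ]
    manifest["sites_called"] = len(sites)

    sites = priming.drop_masked_and_blacklisted(sites, mask, blacklist)
    manifest["after_mask_blacklist"] = len(sites)

    sites = priming.cap_bin_dedup(sites, k=meta.k, bin_size=config.bin_size)
    manifest["after_cap"] = len(sites)
    return SampleResult(meta=meta, sites=sites, manifest=manifest, classified=classified)


def run_synthetic_pipeline(
    synth: synthdata.SyntheticConfig,
    samples: list[priming.SampleMeta] | None = None,
    config: PipelineConfig | None = None,
    blacklist: dict[str, list[tuple[int, int]]] | None = None,
) -> PipelineResult:
    """Simulate a study and run every sample through the full pipeline."""
    config = config or PipelineConfig()
    samples = samples or [priming.SampleMeta(sample_id="S1", k=synth.n_cells_k)]
    genome, _ = synthdata.generate_genome(synth)
    truth = synthdata.plant_ssdna(synth, genome)
    rng = np.random.default_rng(synth.seed + 2)

    raw: dict[str, list[synthdata.RawReadPair]] = {}
    for meta in samples:
        pairs, _alns = synthdata.simulate_reads(synth, genome, truth, meta, rng=rng)
        raw[meta.sample_id] = pairs
    n_raw = {sid: len(pairs) for sid, pairs in raw.items()}
    deduped, _ = readproc.dedup_raw_pairs(raw)

    aligner = alnfilter.ToyAligner(genome)
    mask = None
    if config.build_mask:
        mask = alnfilter.build_mappability_mask(
            genome, aligner, stride=config.mask_stride, bin_size=config.bin_size
        )

    results = {}
    for meta in samples:
        results[meta.sample_id] = process_sample(
            deduped[meta.sample_id],
            meta,
            aligner,
            config,
            mask=mask,
            blacklist=blacklist,
            n_raw=n_raw[meta.sample_id],
        )
    model = build_model(genome)
    return PipelineResult(genome=genome, truth=truth, model=model, samples=results)


# ---------------------------------------------------------------------------
# evaluation against planted truth
# ---------------------------------------------------------------------------


def evaluate_recovery(
    truth: synthdata.TruthTable, sites: list[priming.PrimingSite]
) -> tuple[float, float]:
    """(region sensitivity, fraction of sites outside any planted region).

    A planted region is recovered when at least one retained site falls
    inside it.
    """
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for r in truth.regions:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end, r.region_id))
    recovered: set[str] = set()
    outside = 0
    for s in sites:
        hits = [
            rid
            for start, end, rid in by_chrom.get(s.chrom, ())
            if start <= s.pos < end
        ]
        if not hits:
            outside += 1
        else:
            recovered.update(hits)
    sens = len(recovered) / len(truth.regions) if truth.regions else float("nan")
    false_frac = outside / len(sites) if sites else float("nan")
    return sens, false_frac


def estimate_background(result: PipelineResult) -> float | None:
    """Background %, from control vs non-control median total site counts."""
    controls = [
        len(r.sites) for r in result.samples.values() if r.meta.condition == "probe-laser-"
    ]
    noncontrols = [
        len(r.sites) for r in result.samples.values() if r.meta.condition == "noncontrol"
    ]
    if not controls or not noncontrols:
        return None
    return chexstats.background_rate(
        statistics.median(controls), statistics.median(noncontrols)
    )


def estimate_antisense_ratio(
    sites: list[priming.PrimingSite], model: genemodel.GenicModel
) -> float:
    """Pooled antisense/sense ratio over genic sub-regions (exons+introns)."""
    counts = chexstats.antisense_sense_counts(sites, model)
    anti = counts["exon"][0] + counts["intron"][0]
    sense = counts["exon"][1] + counts["intron"][1]
    if sense == 0:
        return float("inf")
    return anti / sense
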