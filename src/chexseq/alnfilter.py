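"""Alignment-quality, duplicate, mappability and contamination filters.

This module consumes alignment records from any external aligner through a
small record contract (:class:`AlignmentRecord`); a deterministic
exact-match k-mer-seeded aligner (:class:`ToyAligner`) is shipped so the
whole pipeline runs on synthetic genomes without an external tool.

The joint alignment-quality criteria (all must hold):

- mapped length >= 10;
- aligner score normalized to read length >= 0.4;
- matched bases normalized to read length >= 0.4;
- mismatched bases normalized to mapped length (per-base mismatch rate) <= 0.1;
- pair-level non-overlapping mapped length >= 20;
- primary location only, non-PCR duplicates removed.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

from .synthdata import Genome, revcomp

logger = logging.getLogger(__name__)


@dataclass
class AlignmentRecord:
    """One genomic alignment, on the scale the aligner reports.

    Coordinates 0-based half-open. ``non_overlapping_mapped_length`` is the
    pair-level union of mate intervals minus their overlap; for effectively
    single-mate alignments it equals the mapped length.
    """

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str
    aligner_score: float
    read_length: int
    mapped_length: int
    matched_bases: int
    mismatches: int
    non_overlapping_mapped_length: int
    is_primary: bool = True
    is_duplicate: bool = False
    mate_five_prime: int | None = None

    @property
    def five_prime(self) -> int:
        """5' genomic end of the read on its own strand."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class FilterThresholds:
    min_mapped_length: int = 10
    min_score_norm: float = 0.4
    min_matched_norm: float = 0.4
    max_mismatch_rate: float = 0.1
    min_non_overlapping: int = 20


def filter_alignment(
    rec: AlignmentRecord, thresholds: FilterThresholds = FilterThresholds()
) -> tuple[bool, str | None]:
    """Evaluate all filter criteria; the reason names the first failure."""
    required = (
        "chrom", "start", "end", "strand", "aligner_score", "read_length",
        "mapped_length", "matched_bases", "mismatches",
        "non_overlapping_mapped_length",
    )
    for name in required:
        if getattr(rec, name, None) is None:
            logger.warning("record %s missing field %s; skipped", rec.read_id, name)
            return False, "missing_field"
    t = thresholds
    if rec.mapped_length < t.min_mapped_length:
        return False, "min_mapped_length"
    if rec.aligner_score / rec.read_length < t.min_score_norm:
        return False, "score_norm"
    if rec.matched_bases / rec.read_length < t.min_matched_norm:
        return False, "matched_norm"
    if rec.mismatches / rec.mapped_length > t.max_mismatch_rate:
        return False, "mismatch_rate"
    if rec.non_overlapping_mapped_length < t.min_non_overlapping:
        return False, "non_overlapping_length"
    if not rec.is_primary:
        return False, "secondary"
    if rec.is_duplicate:
        return False, "duplicate"
    return True, None


def mark_duplicates(records: list[AlignmentRecord]) -> list[AlignmentRecord]:
    """Flag PCR duplicates within one sample (coordinate-dedup contract).

    Records sharing (chrom, 5'-end, strand, mate 5'-end) are duplicates of
    one another; the best is kept, judged by aligner score, then mapped
    length, then lexicographically smallest read id. Flags are set in
    place; the input list is returned for chaining.
    """
    groups: dict[tuple, list[AlignmentRecord]] = defaultdict(list)
    for rec in records:
        groups[(rec.chrom, rec.five_prime, rec.strand, rec.mate_five_prime)].append(rec)
    for members in groups.values():
        members.sort(key=lambda r: (-r.aligner_score, -r.mapped_length, r.read_id))
        for rec in members[1:]:
            rec.is_duplicate = True
        members[0].is_duplicate = False
    return records


def is_contaminant(target_score: float, best_alt_score: float | None) -> bool:
    """A read aligning strictly better to an alternative genome is removed."""
    if best_alt_score is None:
        return False
    return best_alt_score > target_score


# ---------------------------------------------------------------------------
# toy aligner
# ---------------------------------------------------------------------------


@dataclass
class Hit:
    chrom: str
    start: int
    strand: str
    length: int


class ToyAligner:
    """Deterministic exact-match aligner over an in-memory genome.

    Seeds on ``seed_k``-mers of the query (forward and reverse complement)
    and verifies full exact matches. All exact occurrences score equally;
    the primary hit is the lexicographically smallest (chrom, start,
    strand). Intended for synthetic genomes where reads match exactly.
    """

    def __init__(self, sequences: dict[str, str] | Genome, seed_k: int = 12):
        if isinstance(sequences, Genome):
            sequences = sequences.sequences
        self.sequences = sequences
        self.seed_k = seed_k
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for chrom, seq in sequences.items():
            for i in range(len(seq) - seed_k + 1):
                self._index[seq[i : i + seed_k]].append((chrom, i))

    def _occurrences(self, query: str) -> list[tuple[str, int]]:
        k = self.seed_k
        if len(query) < k:
            out = []
            for chrom, seq in self.sequences.items():
                i = seq.find(query)
                while i >= 0:
                    out.append((chrom, i))
                    i = seq.find(query, i + 1)
            return out
        seed = query[:k]
        out = []
        for chrom, pos in self._index.get(seed, ()):
            if self.sequences[chrom][pos : pos + len(query)] == query:
                out.append((chrom, pos))
        return out

    def align(self, query: str) -> list[Hit]:
        """All exact hits of the query on either strand, sorted."""
        hits = [Hit(c, p, "+", len(query)) for c, p in self._occurrences(query)]
        rc = revcomp(query)
        hits += [Hit(c, p, "-", len(query)) for c, p in self._occurrences(rc)]
        hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
        return hits

    def align_record(self, read_id: str, query: str) -> AlignmentRecord | None:
        """Primary alignment as an :class:`AlignmentRecord`; None if unmapped."""
        hits = self.align(query)
        if not hits:
            return None
        h = hits[0]
        L = len(query)
        return AlignmentRecord(
            read_id=read_id,
            chrom=h.chrom,
            start=h.start,
            end=h.start + L,
            strand=h.strand,
            aligner_score=float(L),
            read_length=L,
            mapped_length=L,
            matched_bases=L,
            mismatches=0,
            non_overlapping_mapped_length=L,
            is_primary=True,
        )


# ---------------------------------------------------------------------------
# mappability mask and blacklist
# ---------------------------------------------------------------------------


@dataclass
class MappabilityMask:
    """20-bp genome bins where short reads cannot be faithfully mapped."""

    bin_size: int = 20
    masked: set[tuple[str, int]] = field(default_factory=set)

    def is_masked(self, chrom: str, pos: int) -> bool:
        return (chrom, pos // self.bin_size) in self.masked


def build_mappability_mask(
    sequences: dict[str, str] | Genome,
    aligner: ToyAligner | None = None,
    read_length: int = 20,
    stride: int = 1,
    max_offset: int = 10,
    bin_size: int = 20,
) -> MappabilityMask:
    """Synthesize short reads along the genome and mask unfaithful origins.

    For each start position (every ``stride`` bp) a ``read_length``-bp read
    is taken from the forward strand and aligned; if any best-scoring hit
    lands on a different chromosome or more than ``max_offset`` bp from the
    origin, the origin's bin is masked. Aligner failures mask the bin too
    (masked-unknown).
    """
    if isinstance(sequences, Genome):
        sequences = sequences.sequences
    if aligner is None:
        aligner = ToyAligner(sequences)
    mask = MappabilityMask(bin_size=bin_size)
    for chrom, seq in sequences.items():
        for pos in range(0, len(seq) - read_length + 1, stride):
            read = seq[pos : pos + read_length]
            if "N" in read:
                mask.masked.add((chrom, pos // bin_size))
                continue
            try:
                hits = aligner.align(read)
            except Exception:  # aligner contract: failure => masked-unknown
                logger.warning("aligner failed at %s:%d; masking", chrom, pos)
                mask.masked.add((chrom, pos // bin_size))
                continue
            for h in hits:
                if h.chrom != chrom or abs(h.start - pos) > max_offset:
                    mask.masked.add((chrom, pos // bin_size))
                    break
    return mask


def load_blacklist(bed_rows) -> dict[str, list[tuple[int, int]]]:
    """Index blacklist intervals per chromosome (sorted, for bisection)."""
    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for row in bed_rows:
        by_chrom[row[0]].append((int(row[1]), int(row[2])))
    return {c: sorted(v) for c, v in by_chrom.items()}


def in_blacklist(chrom: str, pos: int, blacklist: dict[str, list[tuple[int, int]]]) -> bool:
    for start, end in blacklist.get(chrom, ()):
        if start <= pos < end:
            return True
        if start > pos:
            break
    return False
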