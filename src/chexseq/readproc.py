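"""Raw read-pair cleanup, sequential primer trimming, and quality classes.

Reads carry (or fail to carry) two diagnostic probe segments: the 5'
barcoded primer (2p) at the start of mate 1 and the 3' poly-C-derived
primer (pC) at the start of mate 2. Their presence pattern defines the
quality class:

    A: both 2p and pC    B: 2p only    C: pC only    D: neither

Classes A-C are split into subclass 1 (read-through: the mate runs past
the insert into the reverse complement of the opposite primer, i.e. the
insert is shorter than the read) or 2 (no read-through).

Trimming order is fixed: first 2p, then pC, then poly-N from the ends,
with a minimum-length gate (default 10 bp, applied per mate) after the
primer step and again after the poly-N step.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .synthdata import (
    DEFAULT_BARCODES,
    PRIMER_2P_CONST,
    PRIMER_PC,
    RawReadPair,
    revcomp,
)

CLASS_ORDER = ("A1", "A2", "B1", "B2", "C1", "C2")


@dataclass(frozen=True)
class PrimerSet:
    """Primer configuration for trimming and demultiplexing.

    ``two_p`` is the full 5' primer (constant part + expected barcode);
    ``barcodes`` maps barcode ids to sequences for demultiplexing (the
    barcode occupies the tail of 2p). ``max_mismatch`` substitutions are
    tolerated when matching primer segments of >= ``mismatch_min_len`` bp
    (sequencing-error tolerance without false barcode calls).
    """

    two_p: str = PRIMER_2P_CONST + DEFAULT_BARCODES["BC01"]
    p_c: str = PRIMER_PC
    barcodes: tuple[tuple[str, str], ...] = tuple(DEFAULT_BARCODES.items())
    max_mismatch: int = 1
    mismatch_min_len: int = 15


@dataclass
class ClassifiedRead:
    read_id: str
    insert: str
    quality_class: str  # A/B/C/D
    subclass: int | None  # 1/2 for A-C, None for D
    found_2p: bool
    found_pC: bool
    barcode_id: str | None
    sample_id: str

    @property
    def quality(self) -> str:
        """Combined label like 'A1'; 'D' for class D."""
        return self.quality_class + ("" if self.subclass is None else str(self.subclass))


def _matches(segment: str, primer: str, primers: PrimerSet) -> bool:
    if len(segment) < len(primer):
        return False
    seg = segment[: len(primer)]
    if seg == primer:
        return True
    if len(primer) >= primers.mismatch_min_len:
        mm = sum(a != b for a, b in zip(seg, primer))
        return mm <= primers.max_mismatch
    return False


def _find_tolerant(hay: str, needle: str, primers: PrimerSet) -> int:
    """Leftmost occurrence of ``needle`` in ``hay`` with mismatch tolerance."""
    idx = hay.find(needle)
    if idx >= 0 or len(needle) < primers.mismatch_min_len:
        return idx
    for i in range(len(hay) - len(needle) + 1):
        mm = 0
        for a, b in zip(hay[i : i + len(needle)], needle):
            if a != b:
                mm += 1
                if mm > primers.max_mismatch:
                    break
        else:
            return i
    return -1


def dedup_raw_pairs(
    samples: dict[str, list[RawReadPair]],
) -> tuple[dict[str, list[RawReadPair]], dict[str, int]]:
    """Collapse identical pairs within samples and drop cross-sample shares.

    Mates are concatenated per pair; within a sample, identical
    concatenations collapse to a single pair, and any concatenation seen
    in two or more samples is treated as index-hopping/artefact and
    removed from all of them. Returns the surviving pairs per sample plus
    a small count report.
    """
    seen_in: dict[str, set[str]] = {}
    for sid, pairs in samples.items():
        for p in pairs:
            if p.mate1 is None or p.mate2 is None:
                raise ValueError(f"read pair {p.read_id} is missing a mate")
            seen_in.setdefault(p.mate1 + p.mate2, set()).add(sid)
    shared = {key for key, sids in seen_in.items() if len(sids) > 1}
    out: dict[str, list[RawReadPair]] = {}
    report = {"input": 0, "unique": 0, "shared_removed": 0}
    for sid, pairs in samples.items():
        kept: list[RawReadPair] = []
        local: set[str] = set()
        for p in pairs:
            report["input"] += 1
            key = p.mate1 + p.mate2
            if key in shared:
                report["shared_removed"] += 1
                continue
            if key in local:
                continue
            local.add(key)
            kept.append(p)
        report["unique"] += len(kept)
        out[sid] = kept
    return out, report


def trim_primers(
    pair: RawReadPair, primers: PrimerSet, min_len: int = 10
) -> ClassifiedRead | None:
    """Trim 2p then pC then poly-N; classify; ``None`` means discarded.

    The 2p primer is "proper" only when anchored at the 5' end of mate 1,
    and pC only at the 5' end of mate 2 (its position at the insert's 3'
    side); internal occurrences do not count. Read-through is recorded
    when the reverse complement of the opposite primer appears in a mate.
    """
    m1, m2 = pair.mate1, pair.mate2
    found_2p = _matches(m1, primers.two_p, primers)
    found_pc = _matches(m2, primers.p_c, primers)

    insert = m1[len(primers.two_p):] if found_2p else m1
    # read-through: mate1 runs into the reverse complement of pC, and/or
    # mate2 runs into the reverse complement of 2p
    rc_pc = revcomp(primers.p_c)
    insert, readthrough = _trim_pc_tail(insert, rc_pc)
    m2_body = m2[len(primers.p_c):] if found_pc else m2
    if _find_tolerant(m2_body, revcomp(primers.two_p), primers) >= 0:
        readthrough = True

    if len(insert) < min_len:
        return None
    insert = insert.strip("N")
    # a poly-N tail can hide a partial primer remnant; finish the pC trim
    insert, rt2 = _trim_pc_tail(insert, rc_pc)
    readthrough = readthrough or rt2
    if len(insert) < min_len:
        return None

    quality_class, subclass = classify_read(found_2p, found_pc, readthrough)
    barcode_id = None
    if found_2p and primers.barcodes:
        barcode_id = demultiplex(m1, primers)
    return ClassifiedRead(
        read_id=pair.read_id,
        insert=insert,
        quality_class=quality_class,
        subclass=subclass,
        found_2p=found_2p,
        found_pC=found_pc,
        barcode_id=barcode_id,
        sample_id=pair.sample_id,
    )


def _trim_pc_tail(insert: str, rc_pc: str) -> tuple[str, bool]:
    """Remove the rc(pC) read-through tail, full or partial (>= 3 bp)."""
    idx = insert.find(rc_pc)
    if idx >= 0:
        return insert[:idx], True
    for t in range(min(len(rc_pc) - 1, len(insert)), 2, -1):
        if insert.endswith(rc_pc[:t]):
            return insert[:-t], True
    return insert, False


def classify_read(found_2p: bool, found_pC: bool, readthrough: bool) -> tuple[str, int | None]:
    """Map primer flags to the quality class and subclass."""
    if found_2p and found_pC:
        cls = "A"
    elif found_2p:
        cls = "B"
    elif found_pC:
        cls = "C"
    else:
        return "D", None
    return cls, (1 if readthrough else 2)


def demultiplex(mate1: str, primers: PrimerSet) -> str | None:
    """Best exact barcode match at the expected offset; ties unassigned.

    The barcode occupies the tail of the 2p primer, so the observed
    segment starts where the constant part of 2p ends.
    """
    best: list[str] = []
    best_score = -1
    for bc_id, bc_seq in primers.barcodes:
        offset = len(primers.two_p) - len(bc_seq)
        observed = mate1[offset : offset + len(bc_seq)]
        if len(observed) < len(bc_seq):
            continue
        score = sum(a == b for a, b in zip(observed, bc_seq))
        if score == len(bc_seq):
            if score > best_score:
                best, best_score = [bc_id], score
            elif score == best_score:
                best.append(bc_id)
    if len(best) == 1:
        return best[0]
    return None


def class_frequencies(reads: list[ClassifiedRead]) -> dict[str, float]:
    counts = Counter(r.quality_class for r in reads)
    total = sum(counts.values())
    return {c: counts.get(c, 0) / total for c in "ABCD"} if total else {}


def classification_report(reads: list[ClassifiedRead]) -> str:
    """TSV report: read_id, class, subclass, barcode_id."""
    lines = ["read_id\tclass\tsubclass\tbarcode_id"]
    for r in reads:
        sub = "" if r.subclass is None else str(r.subclass)
        lines.append(f"{r.read_id}\t{r.quality_class}\t{sub}\t{r.barcode_id or ''}")
    return "\n".join(lines) + "\n"
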