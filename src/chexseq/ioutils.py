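"""Small text-format helpers shared across modules.

Coordinates are 0-based half-open internally; BED is natively 0-based
half-open, GTF is converted at the boundary.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable


def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    import pyfaidx

    with pyfaidx.Fasta(str(path)) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_bed(intervals: Iterable[tuple], path) -> None:
    """Write (chrom, start, end[, name, score, strand]) tuples as BED."""
    with _open_text(path, "wt") as fh:
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_bed(path) -> list[tuple]:
    """Read BED rows as (chrom, start, end, *rest) with int coordinates."""
    rows = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            rows.append((parts[0], int(parts[1]), int(parts[2]), *parts[3:]))
    return rows


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
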