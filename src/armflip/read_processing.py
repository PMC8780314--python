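"""Adapter trimming and read QC (quality + length filters) for small-RNA FASTQ.

Filtering semantics: a read is kept iff its Phred quality passes
(mean >= min_phred by default; per-base minimum in ``min`` mode) AND its
length after trimming lies in [min_len, max_len]. The rejection tally plus
kept reads conserve the input count.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

PHRED_OFFSET = 33
MIN_ADAPTER_OVERLAP = 5


class ReadError(ValueError):
    pass


@dataclass(frozen=True)
class FastqRead:
    read_id: str
    sequence: str
    qualities: str  # Phred+33

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ReadError(
                f"read {self.read_id!r}: quality string length "
                f"{len(self.qualities)} != sequence length {len(self.sequence)}"
            )

    @property
    def phred(self) -> list[int]:
        return [ord(c) - PHRED_OFFSET for c in self.qualities]


@dataclass(frozen=True)
class ReadFilterParams:
    min_phred: int = 20
    min_len: int = 16
    max_len: int = 30
    adapter3p: str = ""
    quality_mode: str = "mean"  # "mean" or "min"

    def __post_init__(self) -> None:
        if not (0 < self.min_len <= self.max_len):
            raise ValueError("require 0 < min_len <= max_len")
        if self.quality_mode not in ("mean", "min"):
            raise ValueError("quality_mode must be 'mean' or 'min'")


def trim_adapter(read: FastqRead, adapter3p: str) -> FastqRead:
    """Truncate at the leftmost exact occurrence of an adapter prefix.

    Minimum overlap 5 nt, zero mismatches; a full internal adapter hit or an
    adapter prefix reaching the read's 3' end both trigger truncation.
    Qualities are cut in lockstep. Empty adapter is a no-op.
    """
    if not adapter3p:
        return read
    seq = read.sequence
    adapter = adapter3p.upper().replace("T", "U")
    n = len(seq)
    # full-adapter hit anywhere
    cut = seq.find(adapter)
    if cut == -1:
        # adapter prefix at the very end of the read (partial read-through)
        for ov in range(min(len(adapter), n) - 1, MIN_ADAPTER_OVERLAP - 1, -1):
            if seq.endswith(adapter[:ov]):
                cut = n - ov
                break
    if cut == -1:
        return read
    return FastqRead(read.read_id, seq[:cut], read.qualities[:cut])


def filter_reads(
    reads: Iterable[FastqRead], params: ReadFilterParams
) -> tuple[list[FastqRead], Counter]:
    """Apply quality then length filters; returns (kept, rejection tally).

    Tally keys are ``"quality"`` and ``"length"``; a read failing both is
    counted once, under quality (checked first).
    """
    kept: list[FastqRead] = []
    tally: Counter = Counter()
    for read in reads:
        n = len(read.sequence)
        if n == 0:
            tally["length"] += 1
            continue
        phred = read.phred
        qual = (sum(phred) / n) if params.quality_mode == "mean" else min(phred)
        if qual < params.min_phred:
            tally["quality"] += 1
        elif not (params.min_len <= n <= params.max_len):
            tally["length"] += 1
        else:
            kept.append(read)
    return kept, tally


def process_reads(
    reads: Iterable[FastqRead], params: ReadFilterParams
) -> tuple[list[FastqRead], Counter]:
    """trim_adapter then filter_reads, as one QC pass."""
    trimmed = (trim_adapter(r, params.adapter3p) for r in reads)
    return filter_reads(trimmed, params)


# ---------------------------------------------------------------------------
# FASTQ I/O (plain text, 4-line records)
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path) -> Iterator[FastqRead]:
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            header = header.rstrip("\n")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+"):
                raise ReadError(f"{path}: malformed FASTQ record at {header!r}")
            yield FastqRead(header[1:].split()[0], seq.upper().replace("T", "U"), qual)


def write_fastq(reads: Iterable[FastqRead], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.qualities}\n")
            n += 1
    return n
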