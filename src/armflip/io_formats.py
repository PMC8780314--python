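"""Readers and writers for every on-disk artifact the pipeline touches.

Conventions
-----------
* Internal coordinates are 0-based half-open; GFF3 on disk is 1-based
  inclusive and converted at the boundary.
* Sequences are normalized to uppercase RNA (T -> U) on input.
* All readers reject malformed records with an error naming the offending
  line rather than silently coercing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

VALID_TISSUES = ("root", "leaf")
DEFAULT_TIME_POINTS_H = (0.0, 1.0, 2.0, 4.0, 24.0, 48.0)

_RNA_ALPHABET = frozenset("ACGUN")


class FormatError(ValueError):
    """Malformed on-disk record; message names the file/line where possible."""


def normalize_rna(seq: str) -> str:
    """Uppercase and convert T to U; reject characters outside {A,C,G,U,N}."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - _RNA_ALPHABET
    if bad:
        raise FormatError(f"non-RNA characters after normalization: {sorted(bad)}")
    return s


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleRecord:
    """One small-RNA library in the experimental design."""

    sample_id: str
    accession: str
    tissue: str
    time_h: float
    replicate: int
    fastq_path: str | None = None
    counts_path: str | None = None

    def __post_init__(self) -> None:
        if self.tissue not in VALID_TISSUES:
            raise FormatError(
                f"sample {self.sample_id!r}: unknown tissue {self.tissue!r} "
                f"(expected one of {VALID_TISSUES})"
            )
        if self.replicate < 1:
            raise FormatError(f"sample {self.sample_id!r}: replicate must be >= 1")
        if self.fastq_path is None and self.counts_path is None:
            raise FormatError(f"sample {self.sample_id!r}: missing file path")

    @property
    def condition(self) -> tuple[str, str, float]:
        """(accession, tissue, time_h) — the unit replicates are nested in."""
        return (self.accession, self.tissue, self.time_h)


@dataclass(frozen=True)
class HairpinLocus:
    """A miRNA precursor with 5p/3p arm intervals (0-based half-open)."""

    hairpin_id: str
    sequence: str
    arm5p: tuple[int, int]
    arm3p: tuple[int, int]
    mature5p_id: str
    mature3p_id: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_rna(self.sequence))
        n = len(self.sequence)
        for name, (s, e) in (("arm5p", self.arm5p), ("arm3p", self.arm3p)):
            if not (0 <= s < e <= n):
                raise FormatError(
                    f"hairpin {self.hairpin_id!r}: {name} interval [{s},{e}) "
                    f"outside sequence of length {n}"
                )
            if not (16 <= e - s <= 30):
                raise FormatError(
                    f"hairpin {self.hairpin_id!r}: {name} length {e - s} "
                    f"outside [16, 30]"
                )
        if self.arm5p[1] > self.arm3p[0]:
            raise FormatError(
                f"hairpin {self.hairpin_id!r}: 5p arm must end before 3p arm starts"
            )

    @property
    def seq5p(self) -> str:
        return self.sequence[self.arm5p[0]:self.arm5p[1]]

    @property
    def seq3p(self) -> str:
        return self.sequence[self.arm3p[0]:self.arm3p[1]]


@dataclass
class CountMatrix:
    """Integer feature x sample count matrix plus per-sample library sizes.

    ``library_sizes`` is the total number of retained reads per sample (not
    the column sum of the matrix: multi-assigned and unassigned reads would
    otherwise distort CPM).
    """

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    library_sizes: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.library_sizes = np.asarray(self.library_sizes, dtype=np.int64)
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if self.library_sizes.shape != (len(self.sample_ids),):
            raise FormatError("library_sizes length must equal number of samples")
        if (self.counts < 0).any():
            raise FormatError("negative count")
        if (self.library_sizes <= 0).any():
            raise FormatError("library sizes must be positive")

    def column(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self.sample_ids.index(sample_id)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.feature_ids == other.feature_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
            and np.array_equal(self.library_sizes, other.library_sizes)
        )


# ---------------------------------------------------------------------------
# Hairpin annotation (FASTA + GFF3)
# ---------------------------------------------------------------------------

def _parse_gff_attributes(raw: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            raise FormatError(f"malformed GFF attribute {chunk!r}")
        k, v = chunk.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def read_hairpin_annotation(
    fasta: str | Path, gff: str | Path
) -> tuple[list[HairpinLocus], list[tuple[str, str]]]:
    """Read hairpin FASTA plus a GFF3 of arm intervals.

    GFF rows of type ``miRNA`` must carry ``arm=5p|3p`` and ``ID=`` attributes;
    ``Derives_from`` (defaulting to the seqid) names the hairpin. Returns
    ``(loci, skipped)`` where ``skipped`` pairs a hairpin id with the reason it
    could not be promoted to a :class:`HairpinLocus` (e.g. ``"no_arms"``).
    """
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta), "fasta"):
        sequences[rec.id] = normalize_rna(str(rec.seq))

    arms: dict[str, dict[str, tuple[int, int, str]]] = {}
    with open(gff) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{gff}:{lineno}: expected 9 GFF columns")
            seqid, _src, ftype, start_s, end_s, *_rest, attrs_s = fields
            if ftype != "miRNA":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{gff}:{lineno}: non-integer coordinate") from None
            if end1 < start1:
                raise FormatError(
                    f"{gff}:{lineno}: end {end1} < start {start1}"
                )
            attrs = _parse_gff_attributes(attrs_s)
            arm = attrs.get("arm")
            if arm not in ("5p", "3p"):
                raise FormatError(f"{gff}:{lineno}: missing or invalid arm attribute")
            hairpin_id = attrs.get("Derives_from", seqid)
            if hairpin_id not in sequences:
                raise FormatError(
                    f"{gff}:{lineno}: hairpin {hairpin_id!r} not in FASTA"
                )
            seqlen = len(sequences[hairpin_id])
            if start1 < 1 or end1 > seqlen:
                raise FormatError(
                    f"{gff}:{lineno}: arm interval {start1}..{end1} outside "
                    f"hairpin {hairpin_id!r} of length {seqlen}"
                )
            # GFF 1-based inclusive -> 0-based half-open
            arms.setdefault(hairpin_id, {})[arm] = (
                start1 - 1,
                end1,
                attrs.get("ID", f"{hairpin_id}-{arm}"),
            )

    loci: list[HairpinLocus] = []
    skipped: list[tuple[str, str]] = []
    for hid, seq in sequences.items():
        have = arms.get(hid, {})
        if "5p" not in have and "3p" not in have:
            skipped.append((hid, "no_arms"))
            continue
        if "5p" not in have or "3p" not in have:
            skipped.append((hid, f"missing_{'5p' if '5p' not in have else '3p'}_arm"))
            continue
        s5, e5, id5 = have["5p"]
        s3, e3, id3 = have["3p"]
        loci.append(
            HairpinLocus(
                hairpin_id=hid,
                sequence=seq,
                arm5p=(s5, e5),
                arm3p=(s3, e3),
                mature5p_id=id5,
                mature3p_id=id3,
            )
        )
    return loci, skipped


def write_hairpin_annotation(
    loci: Sequence[HairpinLocus], fasta: str | Path, gff: str | Path
) -> None:
    """Emit hairpin FASTA and arm GFF3 (inverse of read_hairpin_annotation)."""
    with open(fasta, "w") as fh:
        for locus in loci:
            fh.write(f">{locus.hairpin_id}\n{locus.sequence}\n")
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for locus in loci:
            for arm, (s, e), mid in (
                ("5p", locus.arm5p, locus.mature5p_id),
                ("3p", locus.arm3p, locus.mature3p_id),
            ):
                fh.write(
                    f"{locus.hairpin_id}\tarmflip\tmiRNA\t{s + 1}\t{e}\t.\t+\t.\t"
                    f"ID={mid};arm={arm};Derives_from={locus.hairpin_id}\n"
                )


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

_SHEET_REQUIRED = ("sample_id", "accession", "tissue", "time_h", "replicate")


def read_sample_sheet(tsv: str | Path) -> list[SampleRecord]:
    """Parse a TSV sample sheet into validated :class:`SampleRecord` rows."""
    try:
        df = pd.read_csv(tsv, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{tsv}: no samples") from None
    missing = [c for c in _SHEET_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{tsv}: missing required columns {missing}")
    if df.empty:
        raise FormatError(f"{tsv}: no samples")

    records: list[SampleRecord] = []
    seen_ids: set[str] = set()
    seen_design: set[tuple] = set()
    for idx, row in df.iterrows():
        lineno = int(idx) + 2  # header is line 1
        sid = str(row["sample_id"])
        if sid in seen_ids:
            raise FormatError(f"{tsv}:{lineno}: duplicated sample_id {sid!r}")
        seen_ids.add(sid)
        try:
            rec = SampleRecord(
                sample_id=sid,
                accession=str(row["accession"]),
                tissue=str(row["tissue"]),
                time_h=float(row["time_h"]),
                replicate=int(row["replicate"]),
                fastq_path=_opt(row, "fastq_path"),
                counts_path=_opt(row, "counts_path"),
            )
        except (FormatError, ValueError) as exc:
            raise FormatError(f"{tsv}:{lineno}: {exc}") from None
        key = (rec.accession, rec.tissue, rec.time_h, rec.replicate)
        if key in seen_design:
            raise FormatError(f"{tsv}:{lineno}: duplicated design tuple {key}")
        seen_design.add(key)
        records.append(rec)
    return records


def _opt(row: pd.Series, col: str) -> str | None:
    if col not in row.index:
        return None
    val = row[col]
    if val is None or (isinstance(val, float) and np.isnan(val)) or pd.isna(val):
        return None
    val = str(val)
    return val if val and val != "nan" else None


def write_sample_sheet(records: Sequence[SampleRecord], tsv: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "accession": r.accession,
                "tissue": r.tissue,
                "time_h": r.time_h,
                "replicate": r.replicate,
                "fastq_path": r.fastq_path or "",
                "counts_path": r.counts_path or "",
            }
        )
    pd.DataFrame(rows).to_csv(tsv, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------

_LIBSIZE_RE = re.compile(r"^#\s*library_sizes:\s*(.*)$")


def write_count_matrix(matrix: CountMatrix, path: str | Path) -> None:
    """TSV with library sizes stored on a leading ``# library_sizes:`` line."""
    with open(path, "w") as fh:
        pairs = ",".join(
            f"{sid}={int(ls)}"
            for sid, ls in zip(matrix.sample_ids, matrix.library_sizes)
        )
        fh.write(f"# library_sizes: {pairs}\n")
        fh.write("feature_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for i, fid in enumerate(matrix.feature_ids):
            fh.write(fid + "\t" + "\t".join(str(int(c)) for c in matrix.counts[i]) + "\n")


def read_count_matrix(path: str | Path) -> CountMatrix:
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        m = _LIBSIZE_RE.match(first)
        if not m:
            raise FormatError(f"{path}:1: missing '# library_sizes:' header line")
        libsizes: dict[str, int] = {}
        if m.group(1).strip():
            for pair in m.group(1).split(","):
                sid, _, val = pair.strip().partition("=")
                libsizes[sid] = int(val)
        header = fh.readline().rstrip("\n")
        cols = header.split("\t")
        if not cols or cols[0] != "feature_id":
            raise FormatError(f"{path}:2: expected header starting with 'feature_id'")
        sample_ids = cols[1:]
        feature_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=3):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(cols):
                raise FormatError(f"{path}:{lineno}: wrong number of columns")
            try:
                vals = [int(v) for v in parts[1:]]
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer count") from None
            if any(v < 0 for v in vals):
                raise FormatError(f"{path}:{lineno}: negative count")
            feature_ids.append(parts[0])
            rows.append(vals)
    missing = [s for s in sample_ids if s not in libsizes]
    if missing:
        raise FormatError(f"{path}: library size missing for samples {missing}")
    counts = (
        np.array(rows, dtype=np.int64)
        if rows
        else np.zeros((0, len(sample_ids)), dtype=np.int64)
    )
    return CountMatrix(
        feature_ids=feature_ids,
        sample_ids=sample_ids,
        counts=counts,
        library_sizes=np.array([libsizes[s] for s in sample_ids], dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# FASTA of plain sequences (matures, lncRNAs)
# ---------------------------------------------------------------------------

def read_fasta_sequences(path: str | Path) -> dict[str, str]:
    """FASTA -> ordered {id: normalized RNA sequence}; duplicate ids rejected."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        out[rec.id] = normalize_rna(str(rec.seq))
    return out


def write_fasta_sequences(seqs: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in seqs.items():
            fh.write(f">{sid}\n{seq}\n")
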