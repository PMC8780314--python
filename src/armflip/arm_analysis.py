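"""Arm quantification, the arm-selection statistic, dominance, and switch calls.

The arm-selection value for a hairpin in a sample is

    omega = count5p / (count5p + count3p)

(undefined when both arm counts are zero). A sample's dominance is 5p when
omega > high_cut, 3p when omega < low_cut (strict inequalities; boundary
values are unclassified), and "insufficient" unless at least one arm has
count strictly greater than min_count. An arm switch between two conditions
is called when every replicate of one condition shows one dominance and
every replicate of the other shows the opposite.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .io_formats import HairpinLocus, SampleRecord
from .read_processing import FastqRead

logger = logging.getLogger(__name__)

Condition = tuple[str, str, float]  # (accession, tissue, time_h)


class Dominance(str, Enum):
    DOMINANT_5P = "dominant5p"
    DOMINANT_3P = "dominant3p"
    UNCLASSIFIED = "unclassified"
    INSUFFICIENT = "insufficient"


_OPPOSITE = {
    Dominance.DOMINANT_5P: Dominance.DOMINANT_3P,
    Dominance.DOMINANT_3P: Dominance.DOMINANT_5P,
}


@dataclass(frozen=True)
class SwitchParams:
    min_count: int = 50
    low_cut: float = 0.3
    high_cut: float = 0.7
    require_all_replicates: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.low_cut < self.high_cut <= 1.0):
            raise ValueError("require 0 <= low_cut < high_cut <= 1")


@dataclass
class ArmCounts:
    count5p: int = 0
    count3p: int = 0
    unassigned: int = 0


class ArmCountTable:
    """Per-(hairpin, sample) 5p/3p/unassigned read counts."""

    def __init__(self, hairpin_ids: Sequence[str], sample_ids: Sequence[str]):
        self.hairpin_ids = list(hairpin_ids)
        self.sample_ids = list(sample_ids)
        self._rows: dict[tuple[str, str], ArmCounts] = {
            (h, s): ArmCounts() for h in self.hairpin_ids for s in self.sample_ids
        }

    def get(self, hairpin_id: str, sample_id: str) -> ArmCounts:
        return self._rows[(hairpin_id, sample_id)]

    def set(
        self, hairpin_id: str, sample_id: str,
        count5p: int, count3p: int, unassigned: int = 0,
    ) -> None:
        if min(count5p, count3p, unassigned) < 0:
            raise ValueError("arm counts must be non-negative")
        self._rows[(hairpin_id, sample_id)] = ArmCounts(count5p, count3p, unassigned)

    def items(self):
        return self._rows.items()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ArmCountTable):
            return NotImplemented
        return (
            self.hairpin_ids == other.hairpin_ids
            and self.sample_ids == other.sample_ids
            and all(
                self._rows[k].count5p == other._rows[k].count5p
                and self._rows[k].count3p == other._rows[k].count3p
                for k in self._rows
            )
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("hairpin_id\tsample_id\tcount5p\tcount3p\tunassigned\n")
            for h in self.hairpin_ids:
                for s in self.sample_ids:
                    c = self._rows[(h, s)]
                    fh.write(f"{h}\t{s}\t{c.count5p}\t{c.count3p}\t{c.unassigned}\n")

    @classmethod
    def from_tsv(cls, path) -> "ArmCountTable":
        hairpins: list[str] = []
        samples: list[str] = []
        rows: dict[tuple[str, str], tuple[int, int, int]] = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            expected = ["hairpin_id", "sample_id", "count5p", "count3p", "unassigned"]
            if header != expected:
                raise ValueError(f"{path}:1: expected columns {expected}")
            for lineno, line in enumerate(fh, start=2):
                line = line.rstrip("\n")
                if not line:
                    continue
                h, s, c5, c3, un = line.split("\t")
                c5i, c3i, uni = int(c5), int(c3), int(un)
                if min(c5i, c3i, uni) < 0:
                    raise ValueError(f"{path}:{lineno}: negative count")
                if h not in hairpins:
                    hairpins.append(h)
                if s not in samples:
                    samples.append(s)
                rows[(h, s)] = (c5i, c3i, uni)
        table = cls(hairpins, samples)
        for (h, s), (c5, c3, un) in rows.items():
            table.set(h, s, c5, c3, un)
        return table


# ---------------------------------------------------------------------------
# Quantification
# ---------------------------------------------------------------------------

def _count_mismatches(read: str, hairpin: str, offset: int) -> int:
    return sum(1 for i, base in enumerate(read) if hairpin[offset + i] != base)


def _best_offsets(read: str, hairpin: str, max_mismatch: int) -> tuple[int, int | None]:
    """(min mismatches, leftmost offset achieving it) or (inf-like, None)."""
    if max_mismatch == 0:
        pos = hairpin.find(read)
        return (0, pos) if pos != -1 else (len(read) + 1, None)
    best, best_off = len(read) + 1, None
    for off in range(len(hairpin) - len(read) + 1):
        mm = _count_mismatches(read, hairpin, off)
        if mm < best:
            best, best_off = mm, off
    if best > max_mismatch:
        return len(read) + 1, None
    return best, best_off


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def assign_read_to_arm(
    locus: HairpinLocus, offset: int, read_len: int
) -> str:
    """'5p', '3p' or 'unassigned' for a read aligned at ``offset``.

    A read belongs to an arm when the aligned interval covers >= 50% of the
    read length; if both arms qualify the larger overlap wins, exact ties are
    unassigned.
    """
    interval = (offset, offset + read_len)
    ov5 = _overlap(interval, locus.arm5p)
    ov3 = _overlap(interval, locus.arm3p)
    half = read_len / 2.0
    hit5 = ov5 >= half
    hit3 = ov3 >= half
    if hit5 and hit3:
        if ov5 > ov3:
            return "5p"
        if ov3 > ov5:
            return "3p"
        return "unassigned"
    if hit5:
        return "5p"
    if hit3:
        return "3p"
    return "unassigned"


def quantify_arms(
    reads_by_sample: Mapping[str, Iterable[FastqRead]],
    hairpins: Sequence[HairpinLocus],
    max_mismatch: int = 0,
) -> ArmCountTable:
    """Align each read ungapped (sense strand) against every hairpin.

    A read increments the 5p (resp. 3p) count of every hairpin achieving the
    global best mismatch count (<= max_mismatch), according to
    :func:`assign_read_to_arm`; best alignments overlapping neither arm
    increment ``unassigned``. Reads matching no hairpin are dropped.
    """
    if not hairpins:
        raise ValueError("empty hairpin list")
    table = ArmCountTable(
        [h.hairpin_id for h in hairpins], list(reads_by_sample.keys())
    )
    for sample_id, reads in reads_by_sample.items():
        for read in reads:
            seq = read.sequence
            if not seq:
                continue
            hits: list[tuple[int, HairpinLocus, int]] = []  # (mm, locus, offset)
            best = max_mismatch + 1
            for locus in hairpins:
                if len(seq) > len(locus.sequence):
                    continue
                mm, off = _best_offsets(seq, locus.sequence, max_mismatch)
                if off is None or mm > max_mismatch:
                    continue
                if mm < best:
                    best = mm
                    hits = [(mm, locus, off)]
                elif mm == best:
                    hits.append((mm, locus, off))
            for mm, locus, off in hits:
                arm = assign_read_to_arm(locus, off, len(seq))
                counts = table.get(locus.hairpin_id, sample_id)
                if arm == "5p":
                    counts.count5p += 1
                elif arm == "3p":
                    counts.count3p += 1
                else:
                    counts.unassigned += 1
    return table


# ---------------------------------------------------------------------------
# omega and dominance
# ---------------------------------------------------------------------------

def compute_omega(count5p: int, count3p: int) -> float | None:
    """5p / (5p + 3p); None when both counts are zero."""
    if count5p < 0 or count3p < 0:
        raise ValueError("arm counts must be non-negative")
    total = count5p + count3p
    if total == 0:
        return None
    return count5p / total


def classify_dominance(
    omega: float | None, count5p: int, count3p: int, params: SwitchParams
) -> Dominance:
    """Dominance label for one (hairpin, sample) observation.

    The count gate requires at least one arm strictly above ``min_count``.
    Boundary omega values equal to a cutoff are unclassified.
    """
    if max(count5p, count3p) <= params.min_count:
        return Dominance.INSUFFICIENT
    if omega is None:
        return Dominance.INSUFFICIENT
    if omega < params.low_cut:
        return Dominance.DOMINANT_3P
    if omega > params.high_cut:
        return Dominance.DOMINANT_5P
    return Dominance.UNCLASSIFIED


@dataclass(frozen=True)
class OmegaProfile:
    hairpin_id: str
    sample_id: str
    omega: float | None
    dominance: Dominance
    count5p: int
    count3p: int


def profile_omega(
    table: ArmCountTable, params: SwitchParams
) -> list[OmegaProfile]:
    profiles = []
    for (h, s), counts in table.items():
        om = compute_omega(counts.count5p, counts.count3p)
        dom = classify_dominance(om, counts.count5p, counts.count3p, params)
        profiles.append(OmegaProfile(h, s, om, dom, counts.count5p, counts.count3p))
    return profiles


# ---------------------------------------------------------------------------
# Switch calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SwitchCall:
    hairpin_id: str
    condition_a: Condition
    condition_b: Condition
    dominance_a: Dominance
    dominance_b: Dominance
    omegas_a: tuple[float, ...]
    omegas_b: tuple[float, ...]

    def __post_init__(self) -> None:
        if _OPPOSITE.get(self.dominance_a) != self.dominance_b:
            raise ValueError("switch call requires opposite dominance labels")


def default_condition_pairs(
    conditions: Iterable[Condition],
) -> list[tuple[Condition, Condition]]:
    """All within-accession pairs differing in tissue or time, plus
    same-tissue/same-time pairs across accessions."""
    conds = sorted(set(conditions))
    pairs = []
    for a, b in itertools.combinations(conds, 2):
        same_acc = a[0] == b[0]
        same_tissue_time = a[1:] == b[1:]
        if same_acc or same_tissue_time:
            pairs.append((a, b))
    return pairs


def _condition_dominance(
    doms: Sequence[Dominance], require_all: bool
) -> Dominance | None:
    """Unanimous 5p/3p dominance of one condition's replicates, else None."""
    if not doms:
        return None
    informative = [d for d in doms if d in _OPPOSITE]
    if require_all and len(informative) != len(doms):
        return None
    if not informative:
        return None
    first = informative[0]
    if all(d == first for d in informative):
        return first
    return None


def call_arm_switches(
    profiles: Sequence[OmegaProfile],
    samples: Sequence[SampleRecord],
    params: SwitchParams,
    condition_pairs: Sequence[tuple[Condition, Condition]] | None = None,
) -> list[SwitchCall]:
    """Replicate-consistent arm switch calls across condition pairs.

    A call is emitted for a hairpin and condition pair when every replicate
    of one condition carries one dominance and every replicate of the other
    carries the opposite; with ``require_all_replicates`` any insufficient or
    unclassified replicate vetoes the call.
    """
    sample_condition = {s.sample_id: s.condition for s in samples}
    by_condition: dict[Condition, list[str]] = {}
    for s in samples:
        by_condition.setdefault(s.condition, []).append(s.sample_id)

    if condition_pairs is None:
        condition_pairs = default_condition_pairs(by_condition.keys())

    prof_map: dict[tuple[str, str], OmegaProfile] = {
        (p.hairpin_id, p.sample_id): p for p in profiles
    }
    hairpin_ids = sorted({p.hairpin_id for p in profiles})

    calls: list[SwitchCall] = []
    for cond_a, cond_b in condition_pairs:
        ids_a = by_condition.get(cond_a, [])
        ids_b = by_condition.get(cond_b, [])
        if not ids_a or not ids_b:
            logger.warning("condition with zero replicates skipped: %s",
                           cond_a if not ids_a else cond_b)
            continue
        for hid in hairpin_ids:
            profs_a = [prof_map[(hid, s)] for s in ids_a if (hid, s) in prof_map]
            profs_b = [prof_map[(hid, s)] for s in ids_b if (hid, s) in prof_map]
            if len(profs_a) != len(ids_a) or len(profs_b) != len(ids_b):
                continue
            dom_a = _condition_dominance(
                [p.dominance for p in profs_a], params.require_all_replicates
            )
            dom_b = _condition_dominance(
                [p.dominance for p in profs_b], params.require_all_replicates
            )
            if dom_a is None or dom_b is None or dom_b != _OPPOSITE[dom_a]:
                continue
            calls.append(
                SwitchCall(
                    hairpin_id=hid,
                    condition_a=cond_a,
                    condition_b=cond_b,
                    dominance_a=dom_a,
                    dominance_b=dom_b,
                    omegas_a=tuple(p.omega for p in profs_a),
                    omegas_b=tuple(p.omega for p in profs_b),
                )
            )
    return calls


def write_switch_calls(calls: Sequence[SwitchCall], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "hairpin_id\tcondition_a\tcondition_b\tdominance_a\tdominance_b\t"
            "omegas_a\tomegas_b\n"
        )
        for c in calls:
            ca = "{},{},{:g}".format(*c.condition_a)
            cb = "{},{},{:g}".format(*c.condition_b)
            oa = ";".join(f"{o:.6g}" for o in c.omegas_a)
            ob = ";".join(f"{o:.6g}" for o in c.omegas_b)
            fh.write(
                f"{c.hairpin_id}\t{ca}\t{cb}\t{c.dominance_a.value}\t"
                f"{c.dominance_b.value}\t{oa}\t{ob}\n"
            )
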