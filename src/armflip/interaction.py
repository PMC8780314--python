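"""Two-criterion miRNA:lncRNA interaction screen.

Criterion 1 is a penalty-based complementarity scanner (plant-style scoring:
Watson-Crick pair 0, G:U wobble 0.5, mismatch 1, gap 2; penalties inside the
seed region weighted x2, zero seed mismatches allowed by default). Criterion
2 is antagonistic differential expression: the miRNA and the lncRNA must be
called in opposite directions in the same contrast.

The scanner aligns the miRNA antiparallel to each target window: miRNA
position i (1-based from its 5' end) pairs with the i-th target base counted
from the window's 3' end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .diff_expr import ContrastResult, Direction
from .io_formats import normalize_rna

WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE_PAIRS = {("G", "U"), ("U", "G")}

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DuplexParams:
    seed_start: int = 2          # 1-based, from miRNA 5' end
    seed_end: int = 8            # inclusive
    max_seed_mismatch: int = 0
    wobble_penalty: float = 0.5
    mismatch_penalty: float = 1.0
    gap_penalty: float = 2.0
    max_total_penalty: float = 4.0
    seed_weight: float = 2.0

    def __post_init__(self) -> None:
        if not (1 <= self.seed_start < self.seed_end):
            raise ValueError("require 1 <= seed_start < seed_end")

    def in_seed(self, pos_1based: int) -> bool:
        return self.seed_start <= pos_1based <= self.seed_end


@dataclass(frozen=True)
class DuplexSite:
    mirna_id: str
    target_id: str
    target_interval: tuple[int, int]  # 0-based half-open on the target
    penalty: float
    alignment: tuple[str, str, str]   # (miRNA 3'->5', pair marks, target 5'->3')
    region: str | None = None


@dataclass(frozen=True)
class InteractionCall:
    mirna_id: str
    lncrna_id: str
    site: DuplexSite
    contrast: tuple[str, str]
    mirna_direction: Direction
    lncrna_direction: Direction

    def __post_init__(self) -> None:
        if self.mirna_direction == self.lncrna_direction:
            raise ValueError("interaction call requires opposite directions")
        if self.mirna_direction not in (Direction.UP, Direction.DOWN):
            raise ValueError("directions must be up or down")


def _pair_penalty(mirna_base: str, target_base: str, params: DuplexParams) -> float:
    pair = (mirna_base, target_base)
    if pair in WC_PAIRS:
        return 0.0
    if pair in WOBBLE_PAIRS:
        return params.wobble_penalty
    return params.mismatch_penalty


def score_duplex(
    mirna: str, window: str, params: DuplexParams,
    gap_after: int | None = None, gap_in: str = "target",
) -> tuple[float, int, tuple[str, str, str]]:
    """Score one antiparallel miRNA/target-window duplex.

    ``gap_after`` inserts one gap after that 1-based miRNA position (in the
    target strand when ``gap_in == "target"``, i.e. the window is one base
    longer than the miRNA and one target base is left unpaired; in the miRNA
    strand otherwise, window one base shorter). Returns (total penalty, seed
    mismatch count, alignment triple). Seed mismatches count every non
    Watson-Crick seed pair; gaps are confined to the non-seed region.
    """
    n = len(mirna)
    # pair up positions; build target index per miRNA position (from 3' end)
    rev_window = window[::-1]  # index i-1 pairs with miRNA position i when ungapped
    penalty = 0.0
    seed_mm = 0
    mir_row: list[str] = []
    mark_row: list[str] = []
    tgt_row: list[str] = []

    offset = 0  # shift into rev_window caused by a target gap
    for i in range(1, n + 1):
        if gap_after is not None and gap_in == "target" and i == gap_after + 1:
            # one unpaired target base
            penalty += params.gap_penalty
            mir_row.append("-")
            mark_row.append(" ")
            tgt_row.append(rev_window[i - 1 + offset])
            offset += 1
        if gap_after is not None and gap_in == "mirna" and i == gap_after + 1:
            # one unpaired miRNA base
            penalty += params.gap_penalty
            mir_row.append(mirna[i - 1])
            mark_row.append(" ")
            tgt_row.append("-")
            offset -= 1
            continue
        mb = mirna[i - 1]
        tb = rev_window[i - 1 + offset]
        pen = _pair_penalty(mb, tb, params)
        if params.in_seed(i):
            pen *= params.seed_weight
            if (mb, tb) not in WC_PAIRS:
                seed_mm += 1
        penalty += pen
        mir_row.append(mb)
        mark_row.append("|" if (mb, tb) in WC_PAIRS
                        else ("o" if (mb, tb) in WOBBLE_PAIRS else " "))
        tgt_row.append(tb)
    # rows were built miRNA 5'->3'; present miRNA 3'->5' over target 5'->3'
    alignment = (
        "".join(reversed(mir_row)),
        "".join(reversed(mark_row)),
        "".join(reversed(tgt_row)),
    )
    return penalty, seed_mm, alignment


def _candidate_gaps(mirna_len: int, params: DuplexParams) -> list[int]:
    """1-based miRNA positions after which a non-seed gap may be placed."""
    return [
        i for i in range(1, mirna_len)
        if not (params.in_seed(i) or params.in_seed(i + 1))
    ]


def find_duplex_sites(
    mirna: str,
    target: str,
    params: DuplexParams = DuplexParams(),
    mirna_id: str = "mirna",
    target_id: str = "target",
) -> list[DuplexSite]:
    """Scan every target window for complementarity sites.

    Windows of miRNA length (ungapped) plus single-gap variants (length +/- 1,
    gap confined to the non-seed region) are scored; a site is reported when
    its seed mismatch count is <= max_seed_mismatch and its total penalty is
    <= max_total_penalty. Overlapping sites are reduced to the
    minimum-penalty one (ties broken leftmost).
    """
    mirna = normalize_rna(mirna)
    target = normalize_rna(target)
    n = len(mirna)
    if not (16 <= n <= 30):
        raise ValueError("miRNA length must lie in [16, 30]")
    if len(target) < n:
        return []
    if params.seed_end > n:
        raise ValueError("seed_end exceeds miRNA length")

    candidates: list[DuplexSite] = []
    gap_positions = _candidate_gaps(n, params)
    # Fast path: with zero seed mismatches allowed and all gaps falling after
    # the seed, the seed's reverse complement must appear verbatim in the
    # target at a window-anchored offset — a cheap slice test per window.
    seed_rc = reverse_complement(mirna[params.seed_start - 1:params.seed_end])
    fast = params.max_seed_mismatch == 0 and (
        not gap_positions or min(gap_positions) > params.seed_end
    )

    def seed_ok(start: int, wlen: int) -> bool:
        if not fast:
            return True
        lo = start + wlen - params.seed_end
        return target[lo:lo + len(seed_rc)] == seed_rc

    for start in range(len(target) - n + 1):
        variants: list[tuple[int, int | None, str]] = []
        if seed_ok(start, n):
            variants.append((n, None, "target"))
        if start + n + 1 <= len(target) and seed_ok(start, n + 1):
            variants += [(n + 1, g, "target") for g in gap_positions]
        if seed_ok(start, n - 1):
            variants += [(n - 1, g, "mirna") for g in gap_positions]
        best: tuple[float, int, tuple, int] | None = None
        for wlen, gap_after, gap_in in variants:
            window = target[start:start + wlen]
            pen, seed_mm, aln = score_duplex(mirna, window, params, gap_after, gap_in)
            if seed_mm > params.max_seed_mismatch or pen > params.max_total_penalty:
                continue
            if best is None or pen < best[0]:
                best = (pen, seed_mm, aln, wlen)
        if best is not None:
            pen, _mm, aln, wlen = best
            candidates.append(
                DuplexSite(mirna_id, target_id, (start, start + wlen), pen, aln)
            )
    return _prune_overlaps(candidates)


def _prune_overlaps(sites: list[DuplexSite]) -> list[DuplexSite]:
    """Greedy reduction: keep minimum-penalty site among overlaps, leftmost on ties."""
    remaining = sorted(sites, key=lambda s: (s.penalty, s.target_interval[0]))
    kept: list[DuplexSite] = []
    for site in remaining:
        s, e = site.target_interval
        if all(e <= k.target_interval[0] or s >= k.target_interval[1] for k in kept):
            kept.append(site)
    return sorted(kept, key=lambda s: s.target_interval[0])


def scan_pairs(
    mirnas: Mapping[str, str],
    targets: Mapping[str, str],
    params: DuplexParams = DuplexParams(),
) -> list[DuplexSite]:
    """find_duplex_sites over the full miRNA x target cross product."""
    sites: list[DuplexSite] = []
    for mid, mseq in mirnas.items():
        for tid, tseq in targets.items():
            sites.extend(find_duplex_sites(mseq, tseq, params, mid, tid))
    return sites


def predict_targets(
    mirna: str,
    transcript_regions: Sequence[tuple[str, str, str]],
    params: DuplexParams = DuplexParams(),
    mirna_id: str = "mirna",
) -> list[DuplexSite]:
    """Scan labelled transcript regions ((region_id, label, sequence)).

    Labels must be one of {5UTR, CDS, 3UTR, other}. Sites spanning a region
    boundary are not found (scanning is per-region).
    """
    valid_labels = {"5UTR", "CDS", "3UTR", "other"}
    seen: set[str] = set()
    out: list[DuplexSite] = []
    for region_id, label, seq in transcript_regions:
        if region_id in seen:
            raise ValueError(f"duplicate region_id {region_id!r}")
        seen.add(region_id)
        if label not in valid_labels:
            raise ValueError(f"region {region_id!r}: invalid label {label!r}")
        for site in find_duplex_sites(mirna, seq, params, mirna_id, region_id):
            out.append(
                DuplexSite(site.mirna_id, site.target_id, site.target_interval,
                           site.penalty, site.alignment, region=label)
            )
    return out


def screen_interactions(
    mirna_de: Sequence[ContrastResult],
    lncrna_de: Sequence[ContrastResult],
    sites: Sequence[DuplexSite],
) -> list[InteractionCall]:
    """Emit one call per (miRNA, lncRNA, contrast) with a duplex site and
    opposite up/down directions in the same contrast."""
    contrasts_m = {r.contrast for r in mirna_de}
    contrasts_l = {r.contrast for r in lncrna_de}
    if contrasts_m != contrasts_l:
        raise ValueError(
            f"contrast label mismatch between DE sets: "
            f"{sorted(contrasts_m ^ contrasts_l)}"
        )
    m_dir = {(r.feature_id, r.contrast): r.direction for r in mirna_de}
    l_dir = {(r.feature_id, r.contrast): r.direction for r in lncrna_de}

    best_site: dict[tuple[str, str], DuplexSite] = {}
    for s in sites:
        key = (s.mirna_id, s.target_id)
        if key not in best_site or s.penalty < best_site[key].penalty:
            best_site[key] = s

    calls: list[InteractionCall] = []
    for (mid, lid), site in sorted(best_site.items()):
        for contrast in sorted(contrasts_m):
            dm = m_dir.get((mid, contrast), Direction.NS)
            dl = l_dir.get((lid, contrast), Direction.NS)
            if {dm, dl} == {Direction.UP, Direction.DOWN}:
                calls.append(InteractionCall(mid, lid, site, contrast, dm, dl))
    return calls


def write_interaction_calls(calls: Sequence[InteractionCall], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "mirna_id\tlncrna_id\tcontrast\tmirna_dir\tlncrna_dir\t"
            "site_start\tsite_end\tpenalty\talignment\n"
        )
        for c in calls:
            aln = "/".join(c.site.alignment)
            fh.write(
                f"{c.mirna_id}\t{c.lncrna_id}\t{c.contrast[0]} vs {c.contrast[1]}\t"
                f"{c.mirna_direction.value}\t{c.lncrna_direction.value}\t"
                f"{c.site.target_interval[0]}\t{c.site.target_interval[1]}\t"
                f"{c.site.penalty:.3g}\t{aln}\n"
            )
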