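import numpy as np
import pytest

from armflip.diff_expr import ContrastResult, Direction
from armflip.interaction import (
    DuplexParams,
    DuplexSite,
    InteractionCall,
    find_duplex_sites,
    predict_targets,
    reverse_complement,
    scan_pairs,
    score_duplex,
    screen_interactions,
)
from armflip.synthetic_data import _random_seq

MIRNA = "UGGAGCUCCCUUCAUUCCAAU"  # 21 nt


def brute_force_ungapped_penalty(mirna: str, window: str,
                                 params: DuplexParams) -> tuple[float, int]:
    """Independent rescoring of an ungapped duplex: pair miRNA position i
    (1-based, 5'->3') with the i-th window base from the window's 3' end."""
    assert len(window) == len(mirna)
    pen, seed_mm = 0.0, 0
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    for i in range(1, len(mirna) + 1):
        mb = mirna[i - 1]
        tb = window[len(window) - i]
        if comp[mb] == tb:
            p = 0.0
        elif (mb, tb) in (("G", "U"), ("U", "G")):
            p = params.wobble_penalty
        else:
            p = params.mismatch_penalty
        if params.seed_start <= i <= params.seed_end:
            p *= params.seed_weight
            if comp[mb] != tb:
                seed_mm += 1
        pen += p
    return pen, seed_mm


class TestFindDuplexSites:
    def test_perfect_complement_recovered(self, rng):
        target = _random_seq(rng, 200)
        site_seq = reverse_complement(MIRNA)
        planted = target[:90] + site_seq + target[90:]
        sites = find_duplex_sites(MIRNA, planted)
        exact = [s for s in sites if s.penalty == 0.0]
        assert len(exact) == 1
        assert exact[0].target_interval == (90, 90 + 21)

    def test_no_hit_on_hostile_target(self):
        # poly-A target cannot pair the G/C-containing seed
        assert find_duplex_sites(MIRNA, "A" * 300) == []

    def test_planted_wobble_outside_seed_scores_wobble_penalty(self, rng):
        params = DuplexParams()
        site = list(reverse_complement(MIRNA))
        pos = 12  # miRNA position 12, outside seed 2..8
        assert MIRNA[pos - 1] == "U"
        site[len(MIRNA) - pos] = "G"  # U:G wobble
        target = _random_seq(rng, 120) + "".join(site) + _random_seq(rng, 120)
        sites = find_duplex_sites(MIRNA, target, params)
        best = min(sites, key=lambda s: s.penalty)
        assert best.penalty == pytest.approx(params.wobble_penalty)
        # cross-check with the independent brute-force scorer
        window = target[best.target_interval[0]:best.target_interval[1]]
        pen, seed_mm = brute_force_ungapped_penalty(MIRNA, window, params)
        assert pen == pytest.approx(best.penalty)
        assert seed_mm == 0

    def test_seed_mismatch_vetoes(self, rng):
        site = list(reverse_complement(MIRNA))
        pos = 4  # inside seed
        current = site[len(MIRNA) - pos]
        site[len(MIRNA) - pos] = {"A": "C", "C": "A", "G": "A", "U": "C"}[current]
        target = _random_seq(rng, 100) + "".join(site) + _random_seq(rng, 100)
        sites = find_duplex_sites(MIRNA, target)
        assert all(s.penalty > 0 for s in sites)
        # the planted window itself is rejected by the seed rule
        lo = 100
        window = target[lo:lo + 21]
        _, seed_mm = brute_force_ungapped_penalty(MIRNA, window, DuplexParams())
        assert seed_mm == 1

    def test_target_gap_site_found(self, rng):
        # one extra target base between miRNA positions 12 and 13
        site = reverse_complement(MIRNA)
        k = len(MIRNA) - 12  # insertion point on the target strand
        gapped = site[:k] + "A" + site[k:]
        target = _random_seq(rng, 80) + gapped + _random_seq(rng, 80)
        params = DuplexParams()
        sites = find_duplex_sites(MIRNA, target, params)
        best = min(sites, key=lambda s: s.penalty)
        assert best.penalty == pytest.approx(params.gap_penalty)
        assert best.target_interval[1] - best.target_interval[0] == 22

    def test_alignment_self_consistency(self, rng):
        params = DuplexParams()
        for _ in range(20):
            target = _random_seq(rng, 300)
            planted = target[:150] + reverse_complement(MIRNA) + target[150:]
            for s in find_duplex_sites(MIRNA, planted, params):
                mir_row, marks, tgt_row = s.alignment
                # rescore the reported alignment from its rows alone
                pen = 0.0
                pos = len([c for c in mir_row if c != "-"])
                for mb, tb in zip(mir_row, tgt_row):
                    if mb == "-" or tb == "-":
                        pen += params.gap_penalty
                        if mb != "-":
                            pos -= 1
                        continue
                    pair = (mb, tb)
                    if pair in (("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")):
                        p = 0.0
                    elif pair in (("G", "U"), ("U", "G")):
                        p = params.wobble_penalty
                    else:
                        p = params.mismatch_penalty
                    if params.seed_start <= pos <= params.seed_end:
                        p *= params.seed_weight
                    pen += p
                    pos -= 1
                assert pen == pytest.approx(s.penalty)

    def test_relabel_invariance_on_perfect_site(self, rng):
        # A<->U, G<->C relabeling maps WC pairs to WC pairs
        swap = str.maketrans("AUGC", "UACG")
        target = _random_seq(rng, 150) + reverse_complement(MIRNA) + _random_seq(rng, 150)
        s1 = find_duplex_sites(MIRNA, target)
        s2 = find_duplex_sites(MIRNA.translate(swap), target.translate(swap))
        p1 = {s.target_interval: s.penalty for s in s1 if s.penalty == 0.0}
        p2 = {s.target_interval: s.penalty for s in s2 if s.penalty == 0.0}
        assert p1 == p2 and p1

    def test_short_mirna_rejected(self):
        with pytest.raises(ValueError):
            find_duplex_sites("ACGUACGU", "A" * 100)

    def test_target_shorter_than_mirna(self):
        assert find_duplex_sites(MIRNA, "ACGU") == []

    def test_overlap_pruning_keeps_min_penalty(self):
        sites = [
            DuplexSite("m", "t", (10, 31), 2.0, ("", "", "")),
            DuplexSite("m", "t", (15, 36), 0.5, ("", "", "")),
            DuplexSite("m", "t", (100, 121), 1.0, ("", "", "")),
        ]
        from armflip.interaction import _prune_overlaps
        kept = _prune_overlaps(sites)
        assert [(s.target_interval, s.penalty) for s in kept] == [
            ((15, 36), 0.5), ((100, 121), 1.0)]


class TestPredictTargets:
    def test_site_in_3utr(self, rng):
        utr3 = _random_seq(rng, 100) + reverse_complement(MIRNA) + _random_seq(rng, 50)
        regions = [
            ("g1:5UTR", "5UTR", _random_seq(rng, 120)),
            ("g1:CDS", "CDS", _random_seq(rng, 300)),
            ("g1:3UTR", "3UTR", utr3),
        ]
        sites = predict_targets(MIRNA, regions)
        exact = [s for s in sites if s.penalty == 0.0]
        assert len(exact) == 1 and exact[0].region == "3UTR"

    def test_empty_regions(self):
        assert predict_targets(MIRNA, []) == []

    def test_duplicate_region_id(self, rng):
        regions = [("r1", "CDS", _random_seq(rng, 100)),
                   ("r1", "3UTR", _random_seq(rng, 100))]
        with pytest.raises(ValueError, match="duplicate"):
            predict_targets(MIRNA, regions)


def _de(feature, direction, contrast=("c0", "c1")):
    return ContrastResult(feature, contrast[0], contrast[1], 10.0, 10.0,
                          0.0 if direction == Direction.NS else
                          (2.0 if direction == Direction.UP else -2.0),
                          0.001, 0.001, direction)


def _site(mid="m1", lid="l1"):
    return DuplexSite(mid, lid, (10, 31), 0.0, ("", "", ""))


class TestScreenInteractions:
    def test_antagonistic_pair_called(self):
        calls = screen_interactions(
            [_de("m1", Direction.DOWN)], [_de("l1", Direction.UP)], [_site()])
        assert len(calls) == 1
        assert calls[0].mirna_direction == Direction.DOWN
        assert calls[0].lncrna_direction == Direction.UP

    def test_same_direction_no_call(self):
        calls = screen_interactions(
            [_de("m1", Direction.UP)], [_de("l1", Direction.UP)], [_site()])
        assert calls == []

    def test_no_site_no_call(self):
        calls = screen_interactions(
            [_de("m1", Direction.DOWN)], [_de("l1", Direction.UP)], [])
        assert calls == []

    def test_contrast_mismatch_is_error(self):
        with pytest.raises(ValueError, match="contrast"):
            screen_interactions(
                [_de("m1", Direction.DOWN, ("c0", "c1"))],
                [_de("l1", Direction.UP, ("c0", "c2"))],
                [_site()])

    def test_equal_directions_guarded_by_type(self):
        with pytest.raises(ValueError):
            InteractionCall("m", "l", _site(), ("a", "b"),
                            Direction.UP, Direction.UP)
        with pytest.raises(ValueError):
            InteractionCall("m", "l", _site(), ("a", "b"),
                            Direction.NS, Direction.UP)
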