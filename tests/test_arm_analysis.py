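import numpy as np
import pytest
from hypothesis import given, strategies as st

from armflip.arm_analysis import (
    ArmCountTable,
    Dominance,
    SwitchParams,
    assign_read_to_arm,
    call_arm_switches,
    classify_dominance,
    compute_omega,
    profile_omega,
    quantify_arms,
)
from armflip.io_formats import SampleRecord
from armflip.read_processing import FastqRead
from armflip.synthetic_data import simulate_arm_counts


def q(n):
    return chr(35 + 33) * n


class TestComputeOmega:
    def test_all_5p(self):
        assert compute_omega(100, 0) == 1.0

    def test_exact_ratio(self):
        assert compute_omega(30, 70) == pytest.approx(0.3)

    def test_undefined_at_zero(self):
        assert compute_omega(0, 0) is None

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            compute_omega(-1, 5)

    @given(st.integers(0, 10_000), st.integers(0, 10_000))
    def test_complement_symmetry(self, a, b):
        if a + b == 0:
            assert compute_omega(a, b) is None
        else:
            assert compute_omega(a, b) + compute_omega(b, a) == pytest.approx(1.0)

    @given(st.integers(0, 500), st.integers(1, 500))
    def test_strictly_increasing_in_5p(self, a, b):
        assert compute_omega(a + 1, b) > compute_omega(a, b)


class TestClassifyDominance:
    params = SwitchParams()

    def test_insufficient_counts(self):
        # neither arm strictly above 50
        assert classify_dominance(0.25, 12, 38, self.params) == Dominance.INSUFFICIENT

    def test_one_arm_above_gate_is_sufficient(self):
        assert classify_dominance(0.25, 25, 75, self.params) == Dominance.DOMINANT_3P

    def test_dominant_3p(self):
        assert classify_dominance(0.25, 100, 300, self.params) == Dominance.DOMINANT_3P

    def test_boundary_is_unclassified(self):
        assert classify_dominance(0.7, 700, 300, self.params) == Dominance.UNCLASSIFIED
        assert classify_dominance(0.3, 300, 700, self.params) == Dominance.UNCLASSIFIED

    def test_dominant_5p(self):
        assert classify_dominance(0.75, 300, 100, self.params) == Dominance.DOMINANT_5P

    def test_count_gate_is_strict(self):
        # exactly 50 on the larger arm does not pass
        assert classify_dominance(1.0, 50, 0, self.params) == Dominance.INSUFFICIENT
        assert classify_dominance(1.0, 51, 0, self.params) == Dominance.DOMINANT_5P

    @given(st.integers(0, 1000), st.integers(0, 1000))
    def test_mirror_symmetry(self, a, b):
        om = compute_omega(a, b)
        mirror = {
            Dominance.DOMINANT_5P: Dominance.DOMINANT_3P,
            Dominance.DOMINANT_3P: Dominance.DOMINANT_5P,
            Dominance.UNCLASSIFIED: Dominance.UNCLASSIFIED,
            Dominance.INSUFFICIENT: Dominance.INSUFFICIENT,
        }
        d1 = classify_dominance(om, a, b, self.params)
        d2 = classify_dominance(None if om is None else 1 - om, b, a, self.params)
        assert d2 == mirror[d1]


class TestQuantifyArms:
    def test_exact_5p_read(self, toy_locus):
        reads = {"s1": [FastqRead("r", toy_locus.seq5p, q(21))]}
        table = quantify_arms(reads, [toy_locus])
        counts = table.get("hp-toy", "s1")
        assert (counts.count5p, counts.count3p, counts.unassigned) == (1, 0, 0)

    def test_loop_read_unassigned(self, toy_locus):
        loop_read = toy_locus.sequence[21:37]  # 16 nt pure loop
        reads = {"s1": [FastqRead("r", loop_read, q(16))]}
        counts = quantify_arms(reads, [toy_locus]).get("hp-toy", "s1")
        assert (counts.count5p, counts.count3p, counts.unassigned) == (0, 0, 1)

    def test_unmatched_read_dropped(self, toy_locus):
        reads = {"s1": [FastqRead("r", "U" * 21, q(21))]}
        counts = quantify_arms(reads, [toy_locus]).get("hp-toy", "s1")
        assert (counts.count5p, counts.count3p, counts.unassigned) == (0, 0, 0)

    def test_empty_hairpins_error(self):
        with pytest.raises(ValueError):
            quantify_arms({"s1": []}, [])

    def test_700_300_split_matches_containment_oracle(self, toy_locus, rng):
        # 1000 reads drawn 700/300 from the two arms
        reads = [FastqRead(f"r{i}", toy_locus.seq5p, q(21)) for i in range(700)]
        reads += [FastqRead(f"r{700+i}", toy_locus.seq3p, q(21)) for i in range(300)]
        order = rng.permutation(len(reads))
        reads = [reads[i] for i in order]
        table = quantify_arms({"s1": reads}, [toy_locus])
        counts = table.get("hp-toy", "s1")
        # independent oracle: direct substring containment per read
        o5 = sum(1 for r in reads if r.sequence == toy_locus.seq5p)
        o3 = sum(1 for r in reads if r.sequence == toy_locus.seq3p)
        assert (o5, o3) == (700, 300)
        assert (counts.count5p, counts.count3p) == (700, 300)

    def test_mismatch_tolerance(self, toy_locus):
        one_off = "G" + toy_locus.seq5p[1:]
        reads = {"s1": [FastqRead("r", one_off, q(21))]}
        strict = quantify_arms(reads, [toy_locus], max_mismatch=0)
        loose = quantify_arms(reads, [toy_locus], max_mismatch=1)
        assert strict.get("hp-toy", "s1").count5p == 0
        assert loose.get("hp-toy", "s1").count5p == 1


class TestAssignReadToArm:
    def test_half_overlap_boundary(self, toy_locus):
        # 20-nt read starting 10 nt into the 5p arm: overlap 11 >= 10 -> 5p
        assert assign_read_to_arm(toy_locus, 10, 20) == "5p"
        # starting 12 in: overlap 9 < 10 -> unassigned (loop covers the rest)
        assert assign_read_to_arm(toy_locus, 12, 20) == "unassigned"


def _mk_samples(conditions, n_reps=3):
    out = []
    for acc, tis, t in conditions:
        for r in range(1, n_reps + 1):
            out.append(
                SampleRecord(f"{acc}_{tis}_{t:g}_r{r}", acc, tis, t, r,
                             counts_path="x.tsv")
            )
    return out


def _table_from_omegas(samples, omega_by_sample, total=1000):
    table = ArmCountTable(["hp1"], [s.sample_id for s in samples])
    for s in samples:
        om = omega_by_sample[s.sample_id]
        c5 = int(round(om * total))
        table.set("hp1", s.sample_id, c5, total - c5)
    return table


class TestCallArmSwitches:
    conditions = [("C08", "root", 48.0), ("C08", "leaf", 48.0)]

    def test_clean_switch_called(self):
        samples = _mk_samples(self.conditions)
        omegas = {}
        for s in samples:
            omegas[s.sample_id] = {"root": {1: 0.9, 2: 0.85, 3: 0.95},
                                   "leaf": {1: 0.1, 2: 0.2, 3: 0.15}}[s.tissue][s.replicate]
        params = SwitchParams()
        profiles = profile_omega(_table_from_omegas(samples, omegas), params)
        calls = call_arm_switches(profiles, samples, params)
        assert len(calls) == 1
        (call,) = calls
        assert {call.dominance_a, call.dominance_b} == {
            Dominance.DOMINANT_5P, Dominance.DOMINANT_3P}

    def test_same_dominance_no_call(self):
        samples = _mk_samples(self.conditions)
        omegas = {s.sample_id: 0.9 for s in samples}
        params = SwitchParams()
        profiles = profile_omega(_table_from_omegas(samples, omegas), params)
        assert call_arm_switches(profiles, samples, params) == []

    def test_one_unclassified_replicate_vetoes(self):
        samples = _mk_samples(self.conditions)
        omegas = {}
        for s in samples:
            if s.tissue == "root":
                omegas[s.sample_id] = 0.5 if s.replicate == 1 else 0.9
            else:
                omegas[s.sample_id] = 0.1
        params = SwitchParams()
        profiles = profile_omega(_table_from_omegas(samples, omegas), params)
        assert call_arm_switches(profiles, samples, params) == []

    def test_label_swap_symmetry(self):
        samples = _mk_samples(self.conditions)
        omegas = {s.sample_id: (0.9 if s.tissue == "root" else 0.1)
                  for s in samples}
        params = SwitchParams()
        profiles = profile_omega(_table_from_omegas(samples, omegas), params)
        fwd = call_arm_switches(profiles, samples, params,
                                condition_pairs=[(("C08", "root", 48.0),
                                                  ("C08", "leaf", 48.0))])
        rev = call_arm_switches(profiles, samples, params,
                                condition_pairs=[(("C08", "leaf", 48.0),
                                                  ("C08", "root", 48.0))])
        assert len(fwd) == len(rev) == 1
        assert fwd[0].dominance_a == rev[0].dominance_b
        assert fwd[0].dominance_b == rev[0].dominance_a


def test_planted_switch_recovery_small(small_cfg, small_loci, small_samples):
    """Generator-truth oracle: recompute dominance from true counts."""
    rng = np.random.default_rng(7)
    params = SwitchParams()
    cfg = small_cfg
    counts = simulate_arm_counts(cfg, small_loci, small_samples, rng)
    profiles = profile_omega(counts, params)
    calls = call_arm_switches(profiles, small_samples, params)
    planted = {l.hairpin_id for l in small_loci[: cfg.n_switch_loci]}
    called = {c.hairpin_id for c in calls}
    assert planted <= called
    # constant-0.5 loci never called
    assert not (called - planted)


def test_arm_count_table_tsv_roundtrip(tmp_path, small_cfg, small_loci,
                                       small_samples, rng):
    counts = simulate_arm_counts(small_cfg, small_loci, small_samples, rng)
    path = tmp_path / "counts.tsv"
    counts.to_tsv(path)
    assert ArmCountTable.from_tsv(path) == counts
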