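"""Inspection rules: homopolymer scanning, slippage/coupling proxies, triage."""

import dataclasses

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ionsom.core import make_variant_key
from ionsom.inspection import (ClassifierParams, ReadEvidence, build_context,
                               classify_all, classify_variant,
                               collapse_locus_labels, find_homopolymer_runs,
                               has_coupled_calls, is_slippage_signature)
from ionsom.simulate import (generate_reference, plant_truth,
                             simulate_evidence)

from conftest import small_config

PARAMS = ClassifierParams()

# 60 bp heterogeneous backbone with no run >= 3
CLEAN = "ACGTACGGTCACGTACGGTCACGTACGGTCACGTACGGTCACGTACGGTCACGTACGGTC"


def ev(key, *, depth=500, fwd=50, rev=50, poor=0.0, dn=500, an=0, sample="s1"):
    return ReadEvidence(key, sample, depth, fwd, rev, poor, dn, an)


def ctx_for(key, seq):
    return build_context(key, lambda chrom: seq, PARAMS)


class TestFindRuns:
    @pytest.mark.parametrize("seq,min_len,expected", [
        ("ACGTAAAAAAGT", 6, [("A", 4, 6)]),
        ("ACGTACGTACG", 6, []),
        ("AAAAA", 6, []),
        ("AAAAA", 5, [("A", 0, 5)]),
        ("AANAAA", 3, [("A", 3, 3)]),   # N breaks runs
        ("NNNNNN", 3, []),              # N never forms a run
        ("CCCGGGGG", 3, [("C", 0, 3), ("G", 3, 5)]),
    ])
    def test_maximal_runs(self, seq, min_len, expected):
        assert find_homopolymer_runs(seq, min_len) == expected


class TestSlippage:
    def test_alt_base_run_abutting_position(self):
        # pos 21 (T), G-run at 22..27
        seq = CLEAN[:20] + "TGGGGGG" + CLEAN[27:]
        key = make_variant_key("c", 21, "T", "G")
        assert is_slippage_signature(key, ev(key), ctx_for(key, seq), PARAMS)

    def test_wrong_base_run_does_not_count(self):
        seq = CLEAN[:20] + "TGGGGGG" + CLEAN[27:]
        key = make_variant_key("c", 21, "T", "A")
        assert not is_slippage_signature(key, ev(key), ctx_for(key, seq), PARAMS)

    def test_proximity_boundary_tabulated(self):
        # run of 6 G at positions 31..36 on a G-free backbone; variant
        # placed upstream at increasing gaps; the signature holds only
        # within 2 bp
        backbone = "ACTTCATCAC" * 6
        for gap in range(0, 9):
            pos = 30 - gap
            seq = backbone[:30] + "GGGGGG" + backbone[36:]
            assert seq[pos - 1] != "G"
            key = make_variant_key("c", pos, seq[pos - 1], "G")
            expected = gap <= 2
            got = is_slippage_signature(key, ev(key), ctx_for(key, seq), PARAMS)
            assert got is expected, f"gap {gap}"


class TestCoupled:
    def lookup(self, entries):
        return {(e.key, e.sample): e for e in entries}

    def test_two_unidirectional_calls_nearby(self):
        k1 = make_variant_key("c", 100, "A", "G")
        k2 = make_variant_key("c", 104, "C", "T")
        lk = self.lookup([ev(k1, fwd=30, rev=0), ev(k2, fwd=12, rev=0)])
        assert has_coupled_calls(k1, [k1, k2], lk, "s1", PARAMS)

    def test_isolated_call(self):
        k1 = make_variant_key("c", 100, "A", "G")
        lk = self.lookup([ev(k1, fwd=30, rev=0)])
        assert not has_coupled_calls(k1, [k1], lk, "s1", PARAMS)

    def test_bidirectional_neighbors_not_coupled(self):
        k1 = make_variant_key("c", 100, "A", "G")
        k2 = make_variant_key("c", 104, "C", "T")
        lk = self.lookup([ev(k1), ev(k2)])
        assert not has_coupled_calls(k1, [k1, k2], lk, "s1", PARAMS)

    def test_neighbor_outside_window_ignored(self):
        k1 = make_variant_key("c", 100, "A", "G")
        k2 = make_variant_key("c", 130, "C", "T")
        lk = self.lookup([ev(k1, fwd=30, rev=0), ev(k2, fwd=12, rev=0)])
        assert not has_coupled_calls(k1, [k1, k2], lk, "s1", PARAMS)


class TestClassifyVariant:
    def test_typical_valid_call(self):
        key = make_variant_key("c", 30, CLEAN[29], "T" if CLEAN[29] != "T" else "A")
        lab = classify_variant(key, ev(key, depth=500, fwd=50, rev=50),
                               ctx_for(key, CLEAN))
        assert lab.label == "valid" and lab.reasons == ()

    def test_unidirectional_is_bad(self):
        key = make_variant_key("c", 30, CLEAN[29], "T")
        lab = classify_variant(key, ev(key, fwd=100, rev=0), ctx_for(key, CLEAN))
        assert lab.label == "bad" and "NO_BIDIR" in lab.reasons

    def test_low_af_is_bad(self):
        key = make_variant_key("c", 30, CLEAN[29], "T")
        lab = classify_variant(key, ev(key, depth=400, fwd=6, rev=6),
                               ctx_for(key, CLEAN))
        assert lab.label == "bad" and "LOW_AF" in lab.reasons

    def test_poor_mapping_is_bad(self):
        key = make_variant_key("c", 30, CLEAN[29], "T")
        lab = classify_variant(key, ev(key, poor=0.8), ctx_for(key, CLEAN))
        assert lab.label == "bad" and "POOR_MAP" in lab.reasons

    def test_present_in_normal_is_bad(self):
        key = make_variant_key("c", 30, CLEAN[29], "T")
        lab = classify_variant(key, ev(key, dn=500, an=50), ctx_for(key, CLEAN))
        assert lab.label == "bad" and "IN_NORMAL" in lab.reasons

    def test_all_triggered_reasons_recorded(self):
        key = make_variant_key("c", 30, CLEAN[29], "T")
        lab = classify_variant(key, ev(key, depth=400, fwd=10, rev=0,
                                       poor=0.9, an=60), ctx_for(key, CLEAN))
        assert lab.label == "bad"
        assert set(lab.reasons) >= {"NO_BIDIR", "LOW_AF", "POOR_MAP", "IN_NORMAL"}

    def test_slippage_next_to_long_run_is_homopolymer(self):
        seq = CLEAN[:20] + "TAAAAAAA" + CLEAN[28:]  # A x7 at 22..28
        key = make_variant_key("c", 21, "T", "A")
        lab = classify_variant(key, ev(key, fwd=40, rev=0), ctx_for(key, seq))
        assert lab.label == "homopolymer"
        assert lab.reasons[0] == "HP_SLIPPAGE"

    def test_exception_for_run_of_six_with_heterogeneous_flanks(self):
        seq = CLEAN[:20] + "TAAAAAA" + CLEAN[27:]   # A x6, rich flanks
        key = make_variant_key("c", 21, "T", "A")
        lab = classify_variant(key, ev(key, depth=500, fwd=75, rev=75),
                               ctx_for(key, seq))
        assert lab.label == "valid"

    def test_run_of_seven_does_not_get_the_exception(self):
        seq = CLEAN[:20] + "TAAAAAAA" + CLEAN[28:]  # A x7
        key = make_variant_key("c", 21, "T", "A")
        lab = classify_variant(key, ev(key, depth=500, fwd=75, rev=75),
                               ctx_for(key, seq))
        assert lab.label == "homopolymer"

    def test_low_depth_note_is_advisory(self):
        key = make_variant_key("c", 30, CLEAN[29], "T")
        lab = classify_variant(key, ev(key, depth=150, fwd=30, rev=30),
                               ctx_for(key, CLEAN))
        assert lab.label == "valid"
        assert lab.reasons == ("LOW_DEPTH_NOTE",)

    def test_missing_context_is_error(self):
        key = make_variant_key("c", 30, CLEAN[29], "T")
        with pytest.raises(ValueError):
            classify_variant(key, ev(key), None)


class TestClassifierProperties:
    @settings(max_examples=200, deadline=None)
    @given(depth=st.integers(50, 2000), fwd_frac=st.floats(0, 1),
           af=st.floats(0, 0.6), poor=st.floats(0, 1),
           normal_af=st.floats(0, 0.3), with_run=st.booleans())
    def test_exactly_one_label_always(self, depth, fwd_frac, af, poor,
                                      normal_af, with_run):
        alt_total = int(af * depth)
        fwd = int(fwd_frac * alt_total)
        seq = (CLEAN[:20] + "TAAAAAAA" + CLEAN[28:]) if with_run else CLEAN
        key = make_variant_key("c", 21, "T", "A")
        e = ReadEvidence(key, "s1", depth, fwd, alt_total - fwd, poor,
                         500, int(normal_af * 500))
        lab = classify_variant(key, e, ctx_for(key, seq))
        assert lab.label in ("valid", "bad", "homopolymer")
        if lab.label == "valid":
            assert set(lab.reasons) <= {"LOW_DEPTH_NOTE"}
        if lab.label == "homopolymer":
            assert lab.reasons[0] in ("HP_SLIPPAGE", "HP_COUPLED")

    @settings(max_examples=100, deadline=None)
    @given(depth=st.integers(100, 1000), af=st.floats(0.01, 0.2))
    def test_af_threshold_monotone(self, depth, af):
        alt = max(2, int(af * depth))
        key = make_variant_key("c", 30, CLEAN[29], "T")
        e = ReadEvidence(key, "s1", depth, alt // 2, alt - alt // 2, 0.0, 500, 0)
        strict = classify_variant(key, e, ctx_for(key, CLEAN),
                                  params=ClassifierParams(af_min=0.05))
        loose = classify_variant(key, e, ctx_for(key, CLEAN),
                                 params=ClassifierParams(af_min=0.02))
        if strict.label == "valid":
            assert "LOW_AF" not in loose.reasons

    @settings(max_examples=100, deadline=None)
    @given(an=st.integers(0, 100))
    def test_normal_threshold_monotone(self, an):
        key = make_variant_key("c", 30, CLEAN[29], "T")
        e = ev(key, an=an)
        strict = classify_variant(key, e, ctx_for(key, CLEAN),
                                  params=ClassifierParams(normal_af_max=0.05))
        loose = classify_variant(key, e, ctx_for(key, CLEAN),
                                 params=ClassifierParams(normal_af_max=0.10))
        if "IN_NORMAL" not in strict.reasons:
            assert "IN_NORMAL" not in loose.reasons


@pytest.fixture(scope="module")
def labelled():
    cfg = small_config()
    ref = generate_reference(cfg)
    truth = plant_truth(ref, cfg)
    evidence, _ = simulate_evidence(truth, ref, cfg)
    keys = [r.key for r in truth]
    labels = classify_all(keys, evidence, lambda c: ref.sequences[c])
    per_locus = collapse_locus_labels(labels)
    return truth, labels, per_locus


class TestClassifyAllOnFixture:

    def test_mechanisms_map_to_expected_labels(self, labelled):
        truth, labels, per_locus = labelled
        by_status = {}
        for rec in truth:
            lab = per_locus[rec.key]
            by_status.setdefault(rec.mechanism if rec.status != "somatic"
                                 else "somatic", []).append(lab)
        som = by_status["somatic"]
        assert sum(l == "valid" for l in som) / len(som) > 0.9
        hp = by_status["homopolymer_slippage"]
        assert sum(l == "homopolymer" for l in hp) / len(hp) > 0.9
        for mech in ("strand_bias", "low_af_noise", "germline_leak"):
            labs = by_status[mech]
            assert sum(l != "valid" for l in labs) / len(labs) > 0.9, mech

    def test_strand_bias_reasons(self, labelled):
        truth, labels, _ = labelled
        sb = {(r.key.chrom, r.key.pos) for r in truth
              if r.mechanism == "strand_bias"}
        rows = labels[[(c, p) in sb for c, p in zip(labels.chrom, labels.pos)]]
        assert len(rows)
        assert rows.reasons.str.contains("NO_BIDIR|HP_COUPLED").all()

    def test_germline_leak_reasons(self, labelled):
        truth, labels, _ = labelled
        leak = {(r.key.chrom, r.key.pos) for r in truth
                if r.mechanism == "germline_leak"}
        rows = labels[[(c, p) in leak for c, p in zip(labels.chrom, labels.pos)]]
        assert len(rows)
        assert rows.reasons.str.contains("IN_NORMAL").all()

    def test_determinism(self, labelled):
        cfg = small_config()
        ref = generate_reference(cfg)
        truth = plant_truth(ref, cfg)
        evidence, _ = simulate_evidence(truth, ref, cfg)
        keys = [r.key for r in truth]
        l1 = classify_all(keys, evidence, lambda c: ref.sequences[c])
        l2 = classify_all(keys, evidence, lambda c: ref.sequences[c])
        pd.testing.assert_frame_equal(l1, l2)

    def test_empty_input(self):
        cols = ["chrom", "pos", "ref", "alt", "sample", "depth_tumor",
                "alt_fwd", "alt_rev", "poor_map_frac", "depth_normal",
                "alt_normal"]
        out = classify_all([], pd.DataFrame(columns=cols), lambda c: CLEAN)
        assert out.empty
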