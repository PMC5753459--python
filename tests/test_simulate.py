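"""Generator contracts: determinism, planted structure, caller profiles."""

import dataclasses
import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ionsom.core import make_variant_key
from ionsom.simulate import (CallerProfile, SimulationConfig, default_profiles,
                             generate_reference, plant_truth, realized_channels,
                             simulate_caller_calls, simulate_evidence,
                             write_fixture)

from conftest import small_config


def scan_runs(seq: str, min_len: int):
    """Independent homopolymer scan (oracle for the generator's planting)."""
    runs, i = [], 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            runs.append((seq[i], i, j - i))
        i = j
    return runs


class TestReference:
    def test_zero_density_has_no_runs(self):
        cfg = dataclasses.replace(small_config(), hp_runs_per_kb=0.0)
        ref = generate_reference(cfg)
        for seq in ref.sequences.values():
            assert scan_runs(seq, 4) == []

    def test_fixed_seed_reproducible(self):
        cfg = small_config()
        r1 = generate_reference(cfg)
        r2 = generate_reference(cfg)
        assert r1.sequences == r2.sequences
        assert r1.runs == r2.runs

    def test_run_count_within_poisson_band(self):
        # 5 runs/kb over 10 kb: expect ~50, check the central 99% band
        cfg = SimulationConfig(seed=3, n_regions=2, region_length=5000,
                               hp_runs_per_kb=5.0)
        ref = generate_reference(cfg)
        n = sum(len(scan_runs(seq, 4)) for seq in ref.sequences.values())
        lo, hi = stats.poisson.ppf([0.005, 0.995], 50)
        assert lo <= n <= hi

    def test_panel_tiles_sequences(self):
        cfg = small_config()
        ref = generate_reference(cfg)
        for chrom, start, end in ref.panel:
            assert start == 0 and end == len(ref.sequences[chrom])

    def test_zero_length_region_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, region_length=0)


class TestTruth:
    def test_slippage_loci_sit_near_long_runs(self):
        cfg = small_config()
        ref = generate_reference(cfg)
        truth = plant_truth(ref, cfg)
        hp = [r for r in truth if r.mechanism == "homopolymer_slippage"]
        assert hp
        for rec in hp:
            runs = scan_runs(ref.sequences[rec.key.chrom], 5)
            near = [r for r in runs
                    if r[0] == rec.key.alt
                    and (r[1] - 10 <= rec.key.pos - 1 <= r[1] + r[2] + 9)]
            assert near, f"{rec.key} not within 10 bp of a >=5 run of its alt base"

    def test_no_somatic_requested(self):
        cfg = dataclasses.replace(small_config(), n_somatic_per_patient=0)
        truth = plant_truth(generate_reference(cfg), cfg)
        assert all(r.status != "somatic" for r in truth)

    def test_somatic_af_matches_beta_moments(self):
        cfg = dataclasses.replace(small_config(), n_somatic_per_patient=150)
        truth = plant_truth(generate_reference(cfg), cfg)
        afs = np.array([r.true_af for r in truth if r.status == "somatic"])
        a, b = cfg.af_beta
        mean, sd = a / (a + b), np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
        assert abs(afs.mean() - mean) < 3 * sd / np.sqrt(len(afs))

    def test_overfull_panel_rejected(self):
        cfg = SimulationConfig(seed=5, n_regions=1, region_length=200,
                               n_somatic_per_patient=500)
        with pytest.raises(ValueError):
            plant_truth(generate_reference(cfg), cfg)


@pytest.fixture(scope="module")
def generated():
    cfg = small_config()
    ref = generate_reference(cfg)
    truth = plant_truth(ref, cfg)
    ev, ctx = simulate_evidence(truth, ref, cfg)
    return cfg, truth, ev, ctx


class TestEvidence:

    def test_strand_bias_is_unidirectional(self, generated):
        _, truth, ev, _ = generated
        sb = {r.key for r in truth if r.mechanism == "strand_bias"}
        rows = ev[[make_variant_key(c, p, rf, al) in sb
                   for c, p, rf, al in zip(ev.chrom, ev.pos, ev.ref, ev.alt)]]
        assert len(rows)
        assert ((rows.alt_fwd == 0) | (rows.alt_rev == 0)).all()

    def test_germline_leak_visible_in_normal(self, generated):
        _, truth, ev, _ = generated
        leak = {r.key for r in truth if r.mechanism == "germline_leak"}
        rows = ev[[make_variant_key(c, p, rf, al) in leak
                   for c, p, rf, al in zip(ev.chrom, ev.pos, ev.ref, ev.alt)]]
        assert len(rows)
        assert (rows.alt_normal / rows.depth_normal > 0.05).all()

    def test_low_af_noise_below_threshold_in_truth(self, generated):
        _, truth, _, _ = generated
        assert all(r.true_af < 0.05 for r in truth
                   if r.mechanism == "low_af_noise")

    def test_somatic_alt_counts_binomial(self, generated):
        _, truth, ev, _ = generated
        by_key = {r.key: r for r in truth}
        misses = 0
        checked = 0
        for row in ev.itertuples(index=False):
            rec = by_key[make_variant_key(row.chrom, row.pos, row.ref, row.alt)]
            if rec.status != "somatic":
                continue
            checked += 1
            lo, hi = stats.binom.ppf([0.0005, 0.9995], row.depth_tumor, rec.true_af)
            if not (lo <= row.alt_fwd + row.alt_rev <= hi):
                misses += 1
        assert checked > 50
        assert misses <= max(2, 0.005 * checked)

    def test_context_window_matches_reference(self, generated):
        cfg, _, _, ctx = generated
        ref = generate_reference(cfg)
        row = ctx.iloc[0]
        seq = ref.sequences[row.chrom]
        lo = max(0, row.pos - 1 - 10)
        assert seq[lo:lo + len(row.window)] == row.window


class TestCallerCalls:
    def test_perfect_profiles_recover_truth_exactly(self):
        cfg = small_config()
        perfect = {
            name: CallerProfile(name, 1.0, {}, tvc_linked=p.tvc_linked)
            for name, p in default_profiles().items()
        }
        cfg = dataclasses.replace(cfg, profiles=perfect,
                                  n_germline_per_patient=0)
        ref = generate_reference(cfg)
        truth = plant_truth(ref, cfg)
        ev, _ = simulate_evidence(truth, ref, cfg)
        sim = simulate_caller_calls(truth, ev, cfg)
        somatic = {r.key for r in truth if r.status == "somatic"}
        for name, cs in realized_channels(sim, cfg).items():
            assert cs.loci == somatic, name

    def test_tvc_linked_channels_share_artifacts(self):
        # equal marginal artifact rates; IR/PM linked, VS not
        rates = {"homopolymer_slippage": 150, "strand_bias": 150,
                 "low_af_noise": 150}
        overlap_linked, overlap_unlinked = [], []
        for seed in range(6):
            cfg = dataclasses.replace(
                small_config(seed),
                n_somatic_per_patient=0, n_germline_per_patient=0,
                profiles={
                    "IR": CallerProfile("IR", 0.8, rates, tvc_linked=True),
                    "PM": CallerProfile("PM", 0.9, rates, tvc_linked=True),
                    "MG": CallerProfile("MG", 0.6, rates),
                    "VS": CallerProfile("VS", 0.9, rates),
                })
            ref = generate_reference(cfg)
            truth = plant_truth(ref, cfg)
            ev, _ = simulate_evidence(truth, ref, cfg)
            sim = simulate_caller_calls(truth, ev, cfg)
            ch = realized_channels(sim, cfg)
            overlap_linked.append(len(ch["IR"].loci & ch["PM"].loci))
            overlap_unlinked.append(len(ch["IR"].loci & ch["VS"].loci))
        assert np.mean(overlap_linked) > np.mean(overlap_unlinked)

    def test_varscan_pvalues_straddle_threshold(self):
        cfg = small_config()
        ref = generate_reference(cfg)
        truth = plant_truth(ref, cfg)
        ev, _ = simulate_evidence(truth, ref, cfg)
        sim = simulate_caller_calls(truth, ev, cfg)
        ps = [c.p_value for c in sim.vs]
        assert any(p <= 1e-6 for p in ps) and any(p > 1e-6 for p in ps)

    def test_callstats_contains_rescuable_and_lost_rejects(self):
        cfg = small_config()
        ref = generate_reference(cfg)
        truth = plant_truth(ref, cfg)
        ev, _ = simulate_evidence(truth, ref, cfg)
        cs = simulate_caller_calls(truth, ev, cfg).callstats
        rej = cs[cs.judgement == "REJECT"]
        assert (rej.failure_reasons == "nearby_gap_events").any()
        assert rej.failure_reasons.str.contains("clustered_read_position").any()
        assert (cs[cs.judgement == "KEEP"].failure_reasons == "").all()


class TestFixture:
    def test_manifest_lists_required_file_kinds(self, fixture_dir):
        manifest = json.loads((fixture_dir / "manifest.json").read_text())
        kinds = set(manifest["paths"])
        assert {"reference", "panel", "vcfs", "callstats", "annotations",
                "evidence", "truth"} <= kinds

    def test_rerun_same_seed_identical_checksums(self, tmp_path, sim_config,
                                                 fixture_dir):
        m1 = json.loads((fixture_dir / "manifest.json").read_text())
        m2 = write_fixture(tmp_path / "again", sim_config)
        assert m1["checksums"] == m2["checksums"]

    def test_annotation_rows_cover_all_truth_records(self, fixture_dir):
        truth = pd.read_csv(fixture_dir / "truth.tsv", sep="\t")
        annot = pd.read_csv(fixture_dir / "annotations.tsv", sep="\t")
        assert len(annot) == len(truth)
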