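"""Ground-truth-labelled synthetic fixtures for the calling pipeline.

This module emulates the data a deep targeted amplicon sequencing
experiment hands to the pipeline: a reference panel with homopolymer
runs, planted somatic variants, the error mechanisms that dominate
flow-based chemistry (homopolymer slippage, strand-biased artifacts,
low-allele-fraction noise, germline leakage through tumor-normal
subtraction), and four caller channels with configurable sensitivity
and false-positive profiles. Two of the channels (IR and PM) share the
same underlying Torrent Variant Caller machinery, so their artifact
draws are linked through a common latent indicator per artifact locus.

Nothing here simulates reads: the generator emits caller VCFs, a
MuTect-style call-stats table, an annotation table, and per-variant
pileup summaries (the quantities the inspection rules consume), all
labelled with the truth.

Every operation is a pure function of ``(config, seed)``; randomness
flows from the single seed through named substreams per stage so stages
can be regenerated independently.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
import pysam

from .core import CallSet, VariantCall, VariantKey, make_variant_key

__all__ = [
    "CallerProfile",
    "SimulationConfig",
    "TruthRecord",
    "Reference",
    "SimulatedCalls",
    "generate_reference",
    "plant_truth",
    "simulate_evidence",
    "simulate_caller_calls",
    "realized_channels",
    "write_fixture",
    "expected_channel_performance",
    "default_profiles",
    "substream",
]

MECHANISMS = ("homopolymer_slippage", "strand_bias", "low_af_noise")
_BASES = np.array(list("ACGT"))


def substream(seed: int, name: str) -> np.random.Generator:
    """A named, reproducible child RNG of the master seed."""
    return np.random.default_rng([int(seed) % (2**31), zlib.crc32(name.encode())])


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth label for one planted variant allele."""

    key: VariantKey
    patient: str
    status: str  # somatic | artifact | germline
    mechanism: str  # none | homopolymer_slippage | strand_bias | low_af_noise | germline_leak
    true_af: float

    def __post_init__(self) -> None:
        if self.status == "somatic" and self.mechanism != "none":
            raise ValueError("somatic records carry mechanism 'none'")
        if self.status == "artifact" and self.mechanism not in MECHANISMS:
            raise ValueError(f"artifact mechanism invalid: {self.mechanism}")
        if self.status == "germline" and self.mechanism not in ("none", "germline_leak"):
            raise ValueError(f"germline mechanism invalid: {self.mechanism}")
        if not (0.0 < self.true_af <= 1.0):
            raise ValueError(f"true_af out of (0,1]: {self.true_af}")


@dataclass(frozen=True)
class CallerProfile:
    """Per-channel error profile.

    ``sensitivity`` is the probability a true somatic variant is called
    (at the patient-locus level). ``fp_rates`` maps an artifact mechanism
    (or ``germline_leak``) to the expected number of artifact calls per Mb
    of panel. ``tvc_linked`` channels share one latent artifact draw per
    locus, reproducing the excess IR/PM concordance that follows from both
    being built on the Torrent Variant Caller.
    """

    caller: str
    sensitivity: float
    fp_rates: Mapping[str, float] = field(default_factory=dict)
    tvc_linked: bool = False
    # MuTect-style judgement split for detected calls (MG channel only).
    rescued_fraction: float = 0.0  # REJECT with only nearby_gap_events
    lost_fraction: float = 0.0  # REJECT with additional reasons (unrescuable)

    def __post_init__(self) -> None:
        if not (0.0 <= self.sensitivity <= 1.0):
            raise ValueError(f"sensitivity out of [0,1]: {self.sensitivity}")
        for m, r in self.fp_rates.items():
            if r < 0:
                raise ValueError(f"negative fp rate for {m}")
        if self.rescued_fraction + self.lost_fraction > 1.0:
            raise ValueError("rescued_fraction + lost_fraction > 1")

    @property
    def effective_sensitivity(self) -> float:
        """Detection probability after unrescuable rejections."""
        return self.sensitivity * (1.0 - self.lost_fraction)


def default_profiles() -> Dict[str, CallerProfile]:
    """Study-condition channel profiles.

    Sensitivities mirror the ordering observed for the four channels on
    real amplicon data (PM and VS permissive, MG conservative); artifact
    rates are per-mechanism calibration knobs with no measured
    counterpart, set so every mechanism exercises every downstream rule.
    Rates are per Mb of panel.
    """
    return {
        "IR": CallerProfile(
            "IR", 0.80,
            {"homopolymer_slippage": 250, "strand_bias": 80, "low_af_noise": 60,
             "germline_leak": 100},
            tvc_linked=True,
        ),
        "PM": CallerProfile(
            "PM", 0.90,
            {"homopolymer_slippage": 250, "strand_bias": 120, "low_af_noise": 150,
             "germline_leak": 400},
            tvc_linked=True,
        ),
        "MG": CallerProfile(
            "MG", 0.60,
            {"homopolymer_slippage": 120, "strand_bias": 60, "low_af_noise": 60,
             "germline_leak": 60},
            rescued_fraction=0.30,
            lost_fraction=0.10,
        ),
        "VS": CallerProfile(
            "VS", 0.92,
            {"homopolymer_slippage": 350, "strand_bias": 250, "low_af_noise": 450,
             "germline_leak": 150},
        ),
    }


@dataclass
class SimulationConfig:
    """All knobs of the generator. ``seed`` is mandatory.

    Defaults are the study conditions: four patients, seven tumor samples
    (whole section plus core biopsies) and one matched normal each, mean
    read depth 1400, somatic allele fractions Beta(2,5), 75 true somatic
    variants per patient over a scaled-down 100 kb panel.
    """

    seed: int
    n_regions: int = 20
    region_length: int = 5000
    hp_runs_per_kb: float = 3.0
    hp_run_length_range: Tuple[int, int] = (4, 9)
    n_patients: int = 4
    tumor_samples_per_patient: int = 7
    n_somatic_per_patient: int = 75
    af_beta: Tuple[float, float] = (2.0, 5.0)
    tumor_depth_mean: float = 1400.0
    normal_depth_mean: float = 1400.0
    depth_shape: float = 8.0
    carry_prob: float = 0.8
    n_artifact_loci: Mapping[str, int] = field(
        default_factory=lambda: {
            "homopolymer_slippage": 60,
            "strand_bias": 45,
            "low_af_noise": 60,
        }
    )
    n_germline_per_patient: int = 15
    germline_leak_fraction: float = 0.4
    germline_popdb_fraction: float = 0.5
    somatic_intronic_fraction: float = 0.2
    artifact_intronic_fraction: float = 0.3
    poor_map_degrade_fraction: float = 0.25
    vs_fp_keep_fraction: float = 0.5
    profiles: Dict[str, CallerProfile] = field(default_factory=default_profiles)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_regions < 1 or self.region_length < 1:
            raise ValueError("zero-length panels are rejected")
        for v in (self.n_somatic_per_patient, self.n_patients,
                  self.tumor_samples_per_patient, self.n_germline_per_patient):
            if v < 0:
                raise ValueError("counts must be >= 0")

    @property
    def panel_mb(self) -> float:
        return self.n_regions * self.region_length / 1e6

    def patient_ids(self) -> List[str]:
        return [f"P{i+1}" for i in range(self.n_patients)]

    def tumor_samples(self, patient: str) -> List[str]:
        return [f"{patient}_T{j+1}" for j in range(self.tumor_samples_per_patient)]

    def normal_sample(self, patient: str) -> str:
        return f"{patient}_N"


@dataclass
class Reference:
    """Synthetic reference panel: sequences, intervals, planted runs."""

    sequences: Dict[str, str]
    panel: List[Tuple[str, int, int]]  # BED convention: 0-based half-open
    runs: Dict[str, List[Tuple[str, int, int]]]  # (base, start0, length), maximal

    def base_at(self, chrom: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        return self.sequences[chrom][pos - 1]


# ---------------------------------------------------------------------------
# reference


def _sequence_without_runs(rng: np.random.Generator, length: int) -> np.ndarray:
    """Random sequence with no homopolymer run of length >= 4."""
    seq = rng.choice(_BASES, size=length)
    # break any run of 4 at its 4th base by substituting a different base
    for i in range(3, length):
        if seq[i] == seq[i - 1] == seq[i - 2] == seq[i - 3]:
            choices = [b for b in "ACGT" if b != seq[i]]
            seq[i] = choices[rng.integers(len(choices))]
    return seq


def generate_reference(config: SimulationConfig) -> Reference:
    """Generate panel sequences with homopolymer runs at the configured density.

    The background sequence is run-free (no run of length >= 4); runs of the
    configured length distribution are planted on top, flanked by mismatching
    bases so every planted run is maximal. With density 0 the output contains
    no run of length >= 4 at all.
    """
    rng = substream(config.seed, "reference")
    sequences: Dict[str, str] = {}
    panel: List[Tuple[str, int, int]] = []
    runs: Dict[str, List[Tuple[str, int, int]]] = {}
    lo, hi = config.hp_run_length_range
    for i in range(config.n_regions):
        chrom = f"sim{i+1:02d}"
        L = config.region_length
        seq = _sequence_without_runs(rng, L)
        planted: List[Tuple[str, int, int]] = []
        n_runs = rng.poisson(config.hp_runs_per_kb * L / 1000.0)
        occupied = np.zeros(L, dtype=bool)
        attempts = 0
        while len(planted) < n_runs and attempts < 50 * max(n_runs, 1):
            attempts += 1
            run_len = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(2, L - run_len - 2))
            # keep 2 bp clearance so planted runs never merge
            if occupied[max(0, start - 2): start + run_len + 2].any():
                continue
            base = str(rng.choice(_BASES))
            seq[start: start + run_len] = base
            for flank in (start - 1, start + run_len):
                if seq[flank] == base:
                    choices = [b for b in "ACGT" if b != base]
                    seq[flank] = choices[rng.integers(len(choices))]
            occupied[max(0, start - 2): start + run_len + 2] = True
            planted.append((base, start, run_len))
        sequences[chrom] = "".join(seq)
        panel.append((chrom, 0, L))
        runs[chrom] = sorted(planted, key=lambda r: r[1])
    return Reference(sequences=sequences, panel=panel, runs=runs)


# ---------------------------------------------------------------------------
# truth


def _other_base(rng: np.random.Generator, ref: str) -> str:
    choices = [b for b in "ACGT" if b != ref]
    return choices[rng.integers(3)]


def plant_truth(reference: Reference, config: SimulationConfig) -> List[TruthRecord]:
    """Place somatic variants, artifact loci and germline variants.

    Somatic, strand-bias, low-AF and germline loci sit on run-free
    background sequence (at least 12 bp from any planted run) so the
    homopolymer rules never fire on them; slippage artifacts are placed
    0-2 bp outside a planted run of length >= 6 with the alternate allele
    equal to the run base, the footprint of flow-chemistry alignment
    slippage.
    """
    rng = substream(config.seed, "truth")
    # candidate clean positions: away from planted runs
    clean: List[Tuple[str, int]] = []
    for chrom, seq in reference.sequences.items():
        blocked = np.zeros(len(seq), dtype=bool)
        for base, start, length in reference.runs[chrom]:
            s = max(0, start - 12)
            blocked[s: start + length + 12] = True
        blocked[:2] = True
        blocked[-2:] = True
        for pos0 in np.flatnonzero(~blocked):
            clean.append((chrom, int(pos0)))
    order = rng.permutation(len(clean))
    clean_iter = iter(order)

    def next_clean() -> Tuple[str, int]:
        try:
            idx = next(clean_iter)
        except StopIteration:
            raise ValueError("more variants requested than available panel positions")
        return clean[idx]

    records: List[TruthRecord] = []
    patients = config.patient_ids()
    a, b = config.af_beta

    for patient in patients:
        for _ in range(config.n_somatic_per_patient):
            chrom, pos0 = next_clean()
            ref = reference.sequences[chrom][pos0]
            alt = _other_base(rng, ref)
            af = float(np.clip(rng.beta(a, b), 1e-3, 1.0))
            records.append(TruthRecord(
                make_variant_key(chrom, pos0 + 1, ref, alt),
                patient, "somatic", "none", af))

    # slippage artifacts adjacent to long runs
    long_runs = [
        (chrom, base, start, length)
        for chrom, rlist in reference.runs.items()
        for base, start, length in rlist
        if length >= 6
    ]
    rng.shuffle(long_runs)
    n_hp = config.n_artifact_loci.get("homopolymer_slippage", 0)
    if n_hp > len(long_runs):
        raise ValueError("not enough homopolymer runs >= 6 for requested slippage loci")
    used_keys = {r.key for r in records}
    placed = 0
    for chrom, base, start, length in long_runs:
        if placed >= n_hp:
            break
        seq = reference.sequences[chrom]
        candidates = []
        for gap in (0, 1, 2):
            for pos0 in (start - 1 - gap, start + length + gap):
                if 0 <= pos0 < len(seq) and seq[pos0] != base:
                    candidates.append(pos0)
        rng.shuffle(candidates)
        for pos0 in candidates:
            key = make_variant_key(chrom, pos0 + 1, seq[pos0], base)
            if key in used_keys:
                continue
            used_keys.add(key)
            af = float(rng.uniform(0.10, 0.40))
            records.append(TruthRecord(
                key, patients[rng.integers(len(patients))],
                "artifact", "homopolymer_slippage", af))
            placed += 1
            break

    for mechanism, af_range in (("strand_bias", (0.10, 0.40)),
                                ("low_af_noise", (0.005, 0.035))):
        for _ in range(config.n_artifact_loci.get(mechanism, 0)):
            chrom, pos0 = next_clean()
            ref = reference.sequences[chrom][pos0]
            records.append(TruthRecord(
                make_variant_key(chrom, pos0 + 1, ref, _other_base(rng, ref)),
                patients[rng.integers(len(patients))],
                "artifact", mechanism, float(rng.uniform(*af_range))))

    for patient in patients:
        for _ in range(config.n_germline_per_patient):
            chrom, pos0 = next_clean()
            ref = reference.sequences[chrom][pos0]
            leak = rng.uniform() < config.germline_leak_fraction
            records.append(TruthRecord(
                make_variant_key(chrom, pos0 + 1, ref, _other_base(rng, ref)),
                patient, "germline",
                "germline_leak" if leak else "none",
                float(np.clip(rng.normal(0.5, 0.03), 0.3, 0.7))))

    return records


# ---------------------------------------------------------------------------
# evidence


def _nb_depth(rng: np.random.Generator, mean: float, shape: float, size=None):
    p = shape / (shape + mean)
    return np.maximum(rng.negative_binomial(shape, p, size=size), 1)


def simulate_evidence(
    truth: List[TruthRecord],
    reference: Reference,
    config: SimulationConfig,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-variant pileup summaries plus reference context windows.

    Tumor alternate counts are binomial in depth and true allele
    fraction, split across strands; strand-biased artifacts put every
    supporting read on one strand; germline leaks show the allele at
    germline fraction in the matched normal; low-AF noise stays below
    the 5% validity threshold in truth. A configurable subset of
    artifacts has its mapping-quality fraction degraded.
    """
    rng = substream(config.seed, "evidence")
    ev_rows = []
    ctx_rows = []
    carriage: Dict[Tuple[VariantKey, str], List[str]] = {}

    for rec in truth:
        tumors = config.tumor_samples(rec.patient)
        if rec.status == "somatic":
            carried = [s for s in tumors if rng.uniform() < config.carry_prob]
            if not carried:
                carried = [tumors[rng.integers(len(tumors))]]
        elif rec.status == "germline":
            carried = list(tumors)
        else:  # artifact: sample-specific event
            carried = [tumors[rng.integers(len(tumors))]]
        carriage[(rec.key, rec.patient)] = carried

        for sample in carried:
            depth_t = int(_nb_depth(rng, config.tumor_depth_mean, config.depth_shape))
            depth_n = int(_nb_depth(rng, config.normal_depth_mean, config.depth_shape))
            alt = int(rng.binomial(depth_t, rec.true_af))
            if rec.mechanism in ("strand_bias", "homopolymer_slippage"):
                alt = max(alt, 1)
                if rng.uniform() < 0.5:
                    alt_fwd, alt_rev = alt, 0
                else:
                    alt_fwd, alt_rev = 0, alt
            else:
                alt_fwd = int(rng.binomial(alt, 0.5))
                alt_rev = alt - alt_fwd
            if rec.status == "germline":
                alt_normal = int(rng.binomial(depth_n, rec.true_af))
            else:
                alt_normal = int(rng.binomial(depth_n, 0.002))
            if rec.status == "artifact" and rng.uniform() < config.poor_map_degrade_fraction:
                poor_map = float(rng.uniform(0.6, 0.95))
            else:
                poor_map = float(rng.uniform(0.0, 0.10))
            ev_rows.append({
                "chrom": rec.key.chrom, "pos": rec.key.pos,
                "ref": rec.key.ref, "alt": rec.key.alt,
                "patient": rec.patient, "sample": sample,
                "depth_tumor": depth_t, "alt_fwd": alt_fwd, "alt_rev": alt_rev,
                "poor_map_frac": round(poor_map, 4),
                "depth_normal": depth_n, "alt_normal": alt_normal,
            })
        seq = reference.sequences[rec.key.chrom]
        lo = max(0, rec.key.pos - 1 - 10)
        hi = min(len(seq), rec.key.pos + 10)
        ctx_rows.append({
            "chrom": rec.key.chrom, "pos": rec.key.pos,
            "ref": rec.key.ref, "alt": rec.key.alt,
            "window": seq[lo:hi],
        })

    evidence = pd.DataFrame(ev_rows)
    context = pd.DataFrame(ctx_rows)
    evidence.attrs["carriage"] = carriage
    return evidence, context


# ---------------------------------------------------------------------------
# caller calls


@dataclass
class SimulatedCalls:
    """Raw channel material: per-sample calls, TVC pairs, call-stats rows."""

    ir: CallSet
    vs: CallSet  # includes p-values straddling the VarScan threshold
    tvc_tumor: CallSet
    tvc_normal: Dict[str, CallSet]  # per patient
    mg_vcf: CallSet  # MuTect KEEP calls (what the VCF contains)
    callstats: pd.DataFrame  # contig position ref_allele alt_allele judgement failure_reasons


def _artifact_call_prob(profile: CallerProfile, mechanism: str,
                        n_loci: int, panel_mb: float) -> float:
    rate = profile.fp_rates.get(mechanism, 0.0)
    if n_loci == 0:
        return 0.0
    return min(1.0, rate * panel_mb / n_loci)


def simulate_caller_calls(
    truth: List[TruthRecord],
    evidence: pd.DataFrame,
    config: SimulationConfig,
) -> SimulatedCalls:
    """Draw each channel's calls from the truth and the caller profiles.

    True somatic variants are detected by channel ``c`` with probability
    ``sensitivity(c)``; TVC-linked channels share a single latent uniform
    per artifact locus, so equal marginal rates give identical artifact
    sets; MuTect detections are split into KEEP, rescuable REJECT
    (``nearby_gap_events`` only) and unrescuable REJECT; VarScan attaches
    somatic p-values that straddle 1e-6 for artifacts.
    """
    rng = substream(config.seed, "calls")
    carriage = evidence.attrs["carriage"]
    mech_counts = {m: sum(1 for r in truth if r.mechanism == m)
                   for m in (*MECHANISMS, "germline_leak")}
    profiles = config.profiles
    panel_mb = config.panel_mb

    ir = CallSet("IR")
    vs = CallSet("VS")
    tvc_tumor = CallSet("TVC")
    tvc_normal = {p: CallSet("TVC") for p in config.patient_ids()}
    mg_vcf = CallSet("MU")
    cs_rows: List[dict] = []

    def emit(cset: CallSet, rec: TruthRecord, caller: str,
             p_value: Optional[float] = None) -> None:
        for sample in carriage[(rec.key, rec.patient)]:
            cset.add(VariantCall(rec.key, caller, rec.patient, sample,
                                 tumor_af=round(rec.true_af, 4), p_value=p_value))

    def vs_p(is_true: bool) -> float:
        if is_true:
            expo = rng.uniform(6.5, 12.0)
        elif rng.uniform() < config.vs_fp_keep_fraction:
            expo = rng.uniform(6.0, 8.0)
        else:
            expo = rng.uniform(3.0, 6.0) - 1e-9
        return float(10.0 ** -expo)

    def mg_judgement(rec: TruthRecord) -> Tuple[str, str]:
        u = rng.uniform()
        prof = profiles["MG"]
        if u < prof.rescued_fraction:
            return "REJECT", "nearby_gap_events"
        if u < prof.rescued_fraction + prof.lost_fraction:
            return "REJECT", "nearby_gap_events,clustered_read_position"
        return "KEEP", ""

    def mg_emit(rec: TruthRecord) -> None:
        judgement, reasons = mg_judgement(rec)
        cs_rows.append({
            "contig": rec.key.chrom, "position": rec.key.pos,
            "ref_allele": rec.key.ref, "alt_allele": rec.key.alt,
            "judgement": judgement, "failure_reasons": reasons,
        })
        if judgement == "KEEP":
            emit(mg_vcf, rec, "MU")

    for rec in truth:
        if rec.status == "somatic":
            if rng.uniform() < profiles["IR"].sensitivity:
                emit(ir, rec, "IR")
            if rng.uniform() < profiles["PM"].sensitivity:
                emit(tvc_tumor, rec, "TVC")
            if rng.uniform() < profiles["VS"].sensitivity:
                emit(vs, rec, "VS", p_value=vs_p(True))
            if rng.uniform() < profiles["MG"].sensitivity:
                mg_emit(rec)
        elif rec.status == "germline":
            # TVC sees the allele in every sample; a leak means the normal
            # call was missed, so subtraction fails to remove it.
            emit(tvc_tumor, rec, "TVC")
            if rec.mechanism == "none":
                tvc_normal[rec.patient].add(VariantCall(
                    rec.key, "TVC", rec.patient,
                    config.normal_sample(rec.patient),
                    tumor_af=round(rec.true_af, 4)))
            else:  # germline_leak: other channels may also leak it
                n = mech_counts["germline_leak"]
                for name, cset in (("IR", ir), ("VS", vs), ("MG", None)):
                    p = _artifact_call_prob(profiles[name], "germline_leak", n, panel_mb)
                    if rng.uniform() < p:
                        if name == "IR":
                            emit(ir, rec, "IR")
                        elif name == "VS":
                            emit(vs, rec, "VS", p_value=vs_p(True))
                        else:
                            mg_emit(rec)
        else:  # artifact
            n = mech_counts[rec.mechanism]
            u_shared = rng.uniform()  # one latent draw for TVC-linked channels
            for name in ("IR", "PM", "VS", "MG"):
                prof = profiles[name]
                p = _artifact_call_prob(prof, rec.mechanism, n, panel_mb)
                u = u_shared if prof.tvc_linked else rng.uniform()
                if u >= p:
                    continue
                if name == "IR":
                    emit(ir, rec, "IR")
                elif name == "PM":
                    emit(tvc_tumor, rec, "TVC")
                elif name == "VS":
                    emit(vs, rec, "VS", p_value=vs_p(False))
                else:
                    mg_emit(rec)

    callstats = pd.DataFrame(
        cs_rows, columns=["contig", "position", "ref_allele",
                          "alt_allele", "judgement", "failure_reasons"])
    return SimulatedCalls(ir=ir, vs=vs, tvc_tumor=tvc_tumor,
                          tvc_normal=tvc_normal, mg_vcf=mg_vcf,
                          callstats=callstats)


def realized_channels(sim: SimulatedCalls, config: SimulationConfig) -> Dict[str, CallSet]:
    """Apply the channel constructions in memory (IR, MG, PM, VS).

    Convenience for tests and expectation checks; the pipeline proper
    performs the same constructions from the emitted files.
    """
    from .callers import (mutect_rescue, parse_callstats, pm_subtract,
                          varscan_somatic_filter)

    pm = CallSet("PM")
    for patient, normal in sim.tvc_normal.items():
        tumor = CallSet("TVC", [c for c in sim.tvc_tumor if c.patient == patient])
        for call in pm_subtract(tumor, normal):
            pm.add(call)
    mg = mutect_rescue(parse_callstats(sim.callstats), patient="*", sample="*")
    vs = varscan_somatic_filter(sim.vs)
    return {"IR": sim.ir, "MG": mg, "PM": pm, "VS": vs}


# ---------------------------------------------------------------------------
# annotations


_KEEP_CLASSES = ("exonic", "UTR3", "UTR5", "stopgain", "splicing", "ncRNA")
_KEEP_WEIGHTS = (0.62, 0.12, 0.08, 0.04, 0.06, 0.08)


def simulate_annotations(truth: List[TruthRecord], config: SimulationConfig) -> pd.DataFrame:
    """Functional classes and population-database flags for every truth locus."""
    rng = substream(config.seed, "annotations")
    rows = []
    for rec in truth:
        if rec.status == "somatic":
            intronic_p = config.somatic_intronic_fraction
        elif rec.status == "artifact":
            intronic_p = config.artifact_intronic_fraction
        else:
            intronic_p = config.somatic_intronic_fraction
        if rng.uniform() < intronic_p:
            func = "intronic" if rng.uniform() < 0.8 else "intergenic"
        else:
            func = str(rng.choice(_KEEP_CLASSES, p=_KEEP_WEIGHTS))
        in_1kg = in_evs = False
        if rec.status == "germline" and rng.uniform() < config.germline_popdb_fraction:
            which = rng.uniform()
            in_1kg = which < 0.8
            in_evs = which > 0.4  # overlapping membership, as in real databases
        rows.append({
            "chrom": rec.key.chrom, "pos": rec.key.pos,
            "ref": rec.key.ref, "alt": rec.key.alt,
            "func_class": func,
            "in_1kg": in_1kg, "in_evs": in_evs,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fixture emission


def _vcf_header(reference: Reference, sample: str, with_spv: bool) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom, seq in reference.sequences.items():
        header.contigs.add(chrom, length=len(seq))
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AF", "A", "Float", "Alternate allele fraction")
    if with_spv:
        header.info.add("SPV", 1, "Float", "Somatic p-value")
    header.add_sample(sample)
    return header


def _write_vcf(path: Path, reference: Reference, sample: str,
               calls: List[VariantCall], with_spv: bool = False) -> None:
    header = _vcf_header(reference, sample, with_spv)
    path.parent.mkdir(parents=True, exist_ok=True)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for call in sorted(calls, key=lambda c: c.key.sort_key()):
            rec = vf.new_record(
                contig=call.key.chrom, start=call.key.pos - 1,
                alleles=(call.key.ref, call.key.alt))
            rec.filter.add("PASS")
            rec.samples[sample]["GT"] = (0, 1)
            if call.tumor_af is not None:
                rec.samples[sample]["AF"] = call.tumor_af
            if with_spv and call.p_value is not None:
                rec.info["SPV"] = call.p_value
            vf.write(rec)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture(outdir, config: SimulationConfig) -> dict:
    """Generate everything and write the on-disk fixture.

    Emits reference FASTA (+ .fai), panel BED, per-sample VCFs for the
    IR / VS / TVC (tumor and normal) / MuTect channels, the MuTect
    call-stats TSV, the annotation TSV, the evidence TSV and the truth
    TSV, plus a manifest with SHA-256 checksums. Byte-identical across
    runs with the same config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    reference = generate_reference(config)
    truth = plant_truth(reference, config)
    evidence, context = simulate_evidence(truth, reference, config)
    sim = simulate_caller_calls(truth, evidence, config)
    annotations = simulate_annotations(truth, config)

    paths: Dict[str, str] = {}

    fasta = outdir / "reference.fa"
    with fasta.open("w") as fh:
        for chrom, seq in reference.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
    pysam.faidx(str(fasta))
    paths["reference"] = "reference.fa"

    bed = outdir / "panel.bed"
    with bed.open("w") as fh:
        for chrom, start, end in reference.panel:
            fh.write(f"{chrom}\t{start}\t{end}\n")
    paths["panel"] = "panel.bed"

    def by_sample(calls) -> Dict[str, List[VariantCall]]:
        out: Dict[str, List[VariantCall]] = {}
        for c in calls:
            out.setdefault(c.sample, []).append(c)
        return out

    vcf_files: Dict[str, Dict[str, str]] = {}
    for channel, calls, spv in (("IR", sim.ir, False), ("VS", sim.vs, True),
                                ("TVC", sim.tvc_tumor, False),
                                ("MG", sim.mg_vcf, False)):
        vcf_files[channel] = {}
        for sample, sample_calls in sorted(by_sample(calls).items()):
            rel = f"vcf/{channel}/{sample}.vcf"
            _write_vcf(outdir / rel, reference, sample, sample_calls, with_spv=spv)
            vcf_files[channel][sample] = rel
    vcf_files["TVC_normal"] = {}
    for patient, cset in sorted(sim.tvc_normal.items()):
        sample = config.normal_sample(patient)
        rel = f"vcf/TVC/{sample}.vcf"
        _write_vcf(outdir / rel, reference, sample, list(cset))
        vcf_files["TVC_normal"][patient] = rel
    paths["vcfs"] = vcf_files

    sim.callstats.to_csv(outdir / "mutect_callstats.tsv", sep="\t", index=False)
    paths["callstats"] = "mutect_callstats.tsv"
    annotations.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
    paths["annotations"] = "annotations.tsv"
    evidence.to_csv(outdir / "evidence.tsv", sep="\t", index=False)
    paths["evidence"] = "evidence.tsv"
    context.to_csv(outdir / "context.tsv", sep="\t", index=False)
    paths["context"] = "context.tsv"

    truth_df = pd.DataFrame([{
        "chrom": r.key.chrom, "pos": r.key.pos, "ref": r.key.ref,
        "alt": r.key.alt, "patient": r.patient, "status": r.status,
        "mechanism": r.mechanism, "true_af": round(r.true_af, 4),
    } for r in truth])
    truth_df.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    paths["truth"] = "truth.tsv"

    checksums = {}
    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            checksums[str(p.relative_to(outdir))] = _sha256(p)
    manifest = {
        "seed": config.seed,
        "patients": {p: {"tumor_samples": config.tumor_samples(p),
                         "normal_sample": config.normal_sample(p)}
                     for p in config.patient_ids()},
        "paths": paths,
        "checksums": checksums,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# analytic expectations (for parameter-recovery checks)


def expected_channel_performance(config: SimulationConfig) -> pd.DataFrame:
    """Expected per-channel PPV and sensitivity under the config.

    PPV is the expected fraction of a channel's post-annotation-filter
    loci that the inspection rules label valid; sensitivity is relative
    to the union proxy (valid loci found by at least one channel), the
    same denominator the pipeline estimates. The validity probability of
    a true somatic variant integrates the Beta allele-fraction prior
    against the binomial read-sampling around the 5% threshold across
    carried samples.
    """
    from scipy import stats

    D = config.tumor_depth_mean
    a, b = config.af_beta
    cut = int(np.ceil(0.05 * D))
    n_carry = 1.0 + (config.tumor_samples_per_patient - 1) * config.carry_prob
    grid = np.linspace(1e-4, 1 - 1e-4, 4000)
    pdf = stats.beta.pdf(grid, a, b)
    p_below = stats.binom.cdf(cut - 1, int(D), grid)
    p_valid_given_af = 1.0 - p_below ** n_carry
    p_valid = float(np.trapezoid(pdf * p_valid_given_af, grid))

    n_som = config.n_patients * config.n_somatic_per_patient
    keep_som = 1.0 - config.somatic_intronic_fraction
    keep_art = 1.0 - config.artifact_intronic_fraction
    n_leak_total = (config.n_patients * config.n_germline_per_patient
                    * config.germline_leak_fraction)
    keep_leak = keep_som * (1.0 - config.germline_popdb_fraction)

    sens_eff = {c: p.effective_sensitivity for c, p in config.profiles.items()}
    union = 1.0
    for s in sens_eff.values():
        union *= (1.0 - s)
    union = 1.0 - union

    rows = []
    for name, prof in config.profiles.items():
        s = sens_eff[name]
        true_calls = s * n_som * keep_som
        valid_calls = true_calls * p_valid
        fp = 0.0
        for mech in MECHANISMS:
            n_m = config.n_artifact_loci.get(mech, 0)
            p_call = _artifact_call_prob(prof, mech, n_m, config.panel_mb)
            if name == "MG":
                p_call *= (1.0 - prof.lost_fraction)
            calls = p_call * n_m * keep_art
            if name == "VS":
                calls *= config.vs_fp_keep_fraction
            fp += calls
        if name == "PM":
            leak_p = 1.0
        else:
            leak_p = _artifact_call_prob(prof, "germline_leak",
                                         int(round(n_leak_total)), config.panel_mb)
            if name == "MG":
                leak_p *= (1.0 - prof.lost_fraction)
        fp += leak_p * n_leak_total * keep_leak
        C = true_calls + fp
        rows.append({
            "caller": name,
            "expected_C": C,
            "expected_valid": valid_calls,
            "expected_ppv": valid_calls / C,
            "expected_sensitivity": s / union,
        })
    return pd.DataFrame(rows).set_index("caller")
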