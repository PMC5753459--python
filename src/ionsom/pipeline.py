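"""End-to-end orchestration: channels → filters → concordance →
inspection → classification → strategy evaluation.

The pipeline consumes a fixture directory (as written by
:func:`ionsom.simulate.write_fixture`, or assembled by hand in the same
layout) and a configuration, and writes every stage's output as TSV
plus a run log and an output manifest. Runs are deterministic: the same
configuration and seed produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set

import pandas as pd
import pyfaidx
import yaml

from .annotations import (AnnotationTable, apply_functional_filter,
                          apply_population_filter, DEFAULT_KEEP_CLASSES)
from .callers import (load_vcf_calls, mutect_rescue, parse_callstats,
                      pm_subtract, varscan_somatic_filter, VARSCAN_P_MAX)
from .concordance import (build_matrix, select_inspection_set, shared_fraction,
                          venn_counts)
from .core import CallSet, VariantKey, make_variant_key
from .evaluation import (DEFAULT_STRATEGIES, StrategyPerformanceModel,
                         StrategyPerformanceResults)
from .inspection import ClassifierParams, classify_all, collapse_locus_labels

__all__ = ["PipelineConfig", "PipelineRun", "run_pipeline", "summarize_run",
           "calls_to_frame"]


@dataclass
class PipelineConfig:
    """One serializable source of truth for a pipeline run.

    ``fixture_dir`` must contain a ``manifest.json`` in the fixture
    layout (per-channel VCFs, call-stats, annotation, evidence,
    reference). Every knob of the run — strategies, classifier
    thresholds, sampling cap, seed — lives here; CLI flags override
    config keys.
    """

    fixture_dir: str
    output_dir: str
    seed: int = 0
    strategies: Sequence[str] = DEFAULT_STRATEGIES
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    keep_classes: Set[str] = field(default_factory=lambda: set(DEFAULT_KEEP_CLASSES))
    max_singletons: int = 50
    varscan_p_max: float = VARSCAN_P_MAX
    rescue_flags: Set[str] = field(default_factory=lambda: {"nearby_gap_events"})
    collapse_rule: str = "any_valid"
    lenient_annotations: bool = False
    external_labels: Optional[str] = None  # TSV replacing the classifier

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cls_params = raw.pop("classifier", None)
        cfg = cls(**raw)
        if cls_params:
            cfg.classifier = ClassifierParams(**cls_params)
        return cfg

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        raw["strategies"] = list(self.strategies)
        raw["keep_classes"] = sorted(self.keep_classes)
        raw["rescue_flags"] = sorted(self.rescue_flags)
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=True))


@dataclass
class PipelineRun:
    """In-memory results of one pipeline execution."""

    config: PipelineConfig
    channels: Dict[str, CallSet]
    filtered: Dict[str, CallSet]
    stage_counts: pd.DataFrame
    matrix: "object"
    venn: Dict[frozenset, int]
    inspected: Set[VariantKey]
    sampling_log: Dict[str, Dict[str, int]]
    labels: pd.DataFrame
    results: StrategyPerformanceResults
    output_dir: Path


def calls_to_frame(calls: CallSet) -> pd.DataFrame:
    """Normalized calls table (chrom, pos, ref, alt, caller, patient, sample, tumor_af)."""
    rows = [{
        "chrom": c.key.chrom, "pos": c.key.pos, "ref": c.key.ref,
        "alt": c.key.alt, "caller": c.caller, "patient": c.patient,
        "sample": c.sample,
        "tumor_af": "" if c.tumor_af is None else c.tumor_af,
    } for c in sorted(calls, key=lambda c: (c.key.sort_key(), c.sample))]
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "caller",
                                       "patient", "sample", "tumor_af"])


def _load_channels(fixture: Path, manifest: dict, config: PipelineConfig):
    """Construct the four channels from the fixture files."""
    patients = manifest["patients"]
    sample_patient = {}
    for pid, info in patients.items():
        for s in info["tumor_samples"]:
            sample_patient[s] = pid
        sample_patient[info["normal_sample"]] = pid
    vcfs = manifest["paths"]["vcfs"]

    log: List[dict] = []

    def load_channel(channel: str, caller: str) -> CallSet:
        cs = CallSet(caller)
        skipped = 0
        for sample, rel in sorted(vcfs.get(channel, {}).items()):
            res = load_vcf_calls(fixture / rel, caller, sample,
                                 sample_patient[sample])
            skipped += res.skipped_non_snv
            for c in res.calls:
                cs.add(c)
        log.append({"stage": f"load_{channel}", "n": len(cs),
                    "note": f"skipped_non_snv={skipped}"})
        return cs

    ir = load_channel("IR", "IR")

    vs_raw = load_channel("VS", "VS")
    vs = varscan_somatic_filter(vs_raw, config.varscan_p_max)
    log.append({"stage": "varscan_p_filter", "n": len(vs),
                "note": f"p_max={config.varscan_p_max}"})

    tvc_tumor = load_channel("TVC", "TVC")
    pm = CallSet("PM")
    for pid, rel in sorted(vcfs.get("TVC_normal", {}).items()):
        normal_sample = patients[pid]["normal_sample"]
        res = load_vcf_calls(fixture / rel, "TVC", normal_sample, pid)
        tumor_p = CallSet("TVC", [c for c in tvc_tumor if c.patient == pid])
        for c in pm_subtract(tumor_p, res.calls):
            pm.add(c)
    log.append({"stage": "pm_subtract", "n": len(pm), "note": ""})

    callstats = parse_callstats(fixture / manifest["paths"]["callstats"])
    mg = mutect_rescue(callstats, config.rescue_flags)
    log.append({"stage": "mutect_rescue", "n": len(mg),
                "note": f"rescue_flags={sorted(config.rescue_flags)}"})

    return {"IR": ir, "MG": mg, "PM": pm, "VS": vs}, log


def run_pipeline(config: PipelineConfig) -> PipelineRun:
    """Execute every stage and write all outputs under ``output_dir``."""
    fixture = Path(config.fixture_dir)
    manifest_path = fixture / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"fixture manifest not found: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    channels, log = _load_channels(fixture, manifest, config)

    annotations = AnnotationTable.from_tsv(fixture / manifest["paths"]["annotations"])
    filtered: Dict[str, CallSet] = {}
    for name, cs in channels.items():
        pop = apply_population_filter(cs, annotations,
                                      lenient=config.lenient_annotations)
        fun = apply_functional_filter(pop.kept, annotations, config.keep_classes,
                                      lenient=config.lenient_annotations)
        filtered[name] = fun.kept
        log.append({"stage": f"filter_{name}", "n": len(fun.kept),
                    "note": (f"popdb_excluded={pop.n_excluded};"
                             f"func_excluded={fun.n_excluded}")})

    matrix = build_matrix(filtered)
    log.append({"stage": "concordance", "n": len(matrix),
                "note": f"channels={','.join(matrix.callers)}"})
    venn = venn_counts(matrix)

    inspected, sampling_log = select_inspection_set(
        matrix, config.max_singletons, seed=config.seed)
    log.append({"stage": "inspection_set", "n": len(inspected),
                "note": json.dumps(sampling_log, sort_keys=True)})

    if config.external_labels:
        labels = pd.read_csv(config.external_labels, sep="\t")
    else:
        evidence = pd.read_csv(fixture / manifest["paths"]["evidence"], sep="\t")
        ref = pyfaidx.Fasta(str(fixture / manifest["paths"]["reference"]))
        get_sequence = lambda chrom: str(ref[chrom])
        labels = classify_all(inspected, evidence, get_sequence, config.classifier)
    log.append({"stage": "classify", "n": len(labels), "note": ""})

    # only inspected loci carry verdicts
    label_keys = {make_variant_key(r.chrom, r.pos, r.ref, r.alt)
                  for r in labels.itertuples(index=False)}
    missing = inspected - label_keys
    if missing:
        raise RuntimeError(
            f"stage classify: {len(missing)} inspected loci lack labels "
            f"(first: {sorted(missing)[0]})")

    model = StrategyPerformanceModel.from_labels(
        matrix, labels, inspected, config.strategies,
        collapse=config.collapse_rule)
    results = model.fit()
    log.append({"stage": "evaluate", "n": len(results.results),
                "note": f"V_hat={results.V_hat}"})

    stage_counts = pd.DataFrame(log, columns=["stage", "n", "note"])

    # ---- outputs
    for name, cs in filtered.items():
        calls_to_frame(cs).to_csv(outdir / f"calls_{name}.tsv", sep="\t", index=False)
    venn_df = pd.DataFrame(
        [{"signature": "+".join(sorted(sig)), "n_loci": n}
         for sig, n in sorted(venn.items(),
                              key=lambda kv: (len(kv[0]), sorted(kv[0])))])
    venn_df.to_csv(outdir / "venn_counts.tsv", sep="\t", index=False)
    insp_df = pd.DataFrame(
        [{"chrom": k.chrom, "pos": k.pos, "ref": k.ref, "alt": k.alt,
          "signature": "+".join(sorted(matrix.signature(k)))}
         for k in sorted(inspected)])
    insp_df.to_csv(outdir / "inspection_set.tsv", sep="\t", index=False)
    labels.to_csv(outdir / "labels.tsv", sep="\t", index=False)
    results.to_frame().to_csv(outdir / "strategy_results.tsv", sep="\t", index=False)
    results.extrapolation.strata.drop(columns=["callers"]).to_csv(
        outdir / "extrapolation.tsv", sep="\t", index=False)
    stage_counts.to_csv(outdir / "run_log.tsv", sep="\t", index=False)
    config.to_yaml(outdir / "config_used.yaml")

    checksums = {}
    for p in sorted(outdir.iterdir()):
        if p.is_file() and p.name != "outputs_manifest.json":
            checksums[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    (outdir / "outputs_manifest.json").write_text(
        json.dumps({"seed": config.seed, "checksums": checksums},
                   indent=2, sort_keys=True))

    return PipelineRun(config=config, channels=channels, filtered=filtered,
                       stage_counts=stage_counts, matrix=matrix, venn=venn,
                       inspected=inspected, sampling_log=sampling_log,
                       labels=labels, results=results, output_dir=outdir)


def summarize_run(run: PipelineRun) -> str:
    """Human-readable report: stage counts, Venn, reasons, strategy table."""
    lines = ["Pipeline summary", "================", "", "Stage counts:"]
    for r in run.stage_counts.itertuples(index=False):
        lines.append(f"  {r.stage:<18} {r.n:>7}  {r.note}")
    lines += ["", "Caller signatures (Venn cells):"]
    for sig, n in sorted(run.venn.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))):
        if n:
            lines.append(f"  {'+'.join(sorted(sig)):<16} {n:>6}")
    pair = []
    for a in run.matrix.callers:
        for b in run.matrix.callers:
            if a < b and run.matrix.channel_loci(a) and run.matrix.channel_loci(b):
                pair.append((a, b, 100 * shared_fraction(run.matrix, a, b),
                             100 * shared_fraction(run.matrix, b, a)))
    if pair:
        lines += ["", "Pairwise sharing (% of first channel's loci):"]
        for a, b, fa, fb in pair:
            lines.append(f"  {a} vs {b}: {fa:.0f}% of {a}, {fb:.0f}% of {b}")
    reason_counts: Dict[str, int] = {}
    for reasons in run.labels["reasons"]:
        for tok in str(reasons).split(","):
            tok = tok.strip()
            if tok and tok != "nan":
                reason_counts[tok] = reason_counts.get(tok, 0) + 1
    lines += ["", "Classifier reason histogram:"]
    for tok in sorted(reason_counts):
        lines.append(f"  {tok:<16} {reason_counts[tok]:>6}")
    lines += ["", run.results.summary(), ""]
    return "\n".join(lines)
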