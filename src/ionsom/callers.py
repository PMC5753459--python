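"""Channel ingestion and the three bespoke channel constructions.

Four call-set constructions feed the downstream analysis:

* **IR** — Ion Reporter tumor-normal calls, ingested as-is.
* **PM** — the "Poor Man's" somatic detector: tumor-normal subtraction of
  the VCFs emitted by the unpaired Torrent Variant Caller.
* **MG** — MuTect with a rescue pass over its call-stats annotation file:
  candidates rejected *only* for ``nearby_gap_events`` are recovered,
  because gaps are implicit in amplicon sequencing and that filter is
  tuned for shotgun Illumina data.
* **VS** — VarScan2 somatic calls filtered to somatic p-value <= 1e-6,
  which brings its permissive Illumina-tuned defaults in line with the
  other channels on Ion Torrent data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Optional, Set, Union

import pandas as pd
import pysam

from .core import CallSet, VariantCall, VariantKey, make_variant_key, NotAnSNVError

__all__ = [
    "CallStatsRecord",
    "VcfLoadResult",
    "VcfParseError",
    "load_vcf_calls",
    "pm_subtract",
    "parse_callstats",
    "mutect_rescue",
    "varscan_somatic_filter",
    "DEFAULT_RESCUE_FLAGS",
    "VARSCAN_P_MAX",
]

DEFAULT_RESCUE_FLAGS = frozenset({"nearby_gap_events"})
VARSCAN_P_MAX = 1e-6


class VcfParseError(ValueError):
    """A VCF could not be parsed; carries the offending path."""


@dataclass(frozen=True)
class CallStatsRecord:
    """One row of a MuTect call-stats annotation file."""

    key: VariantKey
    judgement: str  # KEEP | REJECT
    failure_reasons: frozenset

    def __post_init__(self) -> None:
        if self.judgement not in ("KEEP", "REJECT"):
            raise ValueError(f"unknown judgement token {self.judgement!r} at {self.key}")
        if self.judgement == "KEEP" and self.failure_reasons:
            raise ValueError(f"KEEP record with failure reasons at {self.key}")


@dataclass
class VcfLoadResult:
    """A loaded call set plus ingestion counters."""

    calls: CallSet
    skipped_non_snv: int = 0
    skipped_filtered: int = 0


def load_vcf_calls(path, caller: str, sample: str, patient: str) -> VcfLoadResult:
    """Load the SNV calls of one sample's VCF into a call set.

    One candidate per alternate allele (multi-allelic records are split);
    only records whose FILTER is PASS or ``.`` are kept; anything that is
    not a simple SNV (indels, MNVs, symbolic alleles, ``*``) is counted
    and skipped. Allele fraction is taken from the sample's ``AF`` FORMAT
    field (or the ``AF`` INFO field), the VarScan somatic p-value from
    the ``SPV`` INFO field, when present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    result = VcfLoadResult(CallSet(caller))
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc
    with vf:
        for line_no, rec in enumerate(vf, start=1):
            try:
                filters = set(rec.filter.keys())
            except Exception as exc:  # malformed record body
                raise VcfParseError(
                    f"malformed VCF record #{line_no} in {path}: {exc}") from exc
            if filters and filters != {"PASS"}:
                result.skipped_filtered += 1
                continue
            alts = rec.alts or ()
            for alt in alts:
                try:
                    key = make_variant_key(rec.chrom, rec.pos, rec.ref, alt)
                except NotAnSNVError:
                    result.skipped_non_snv += 1
                    continue
                af = None
                if sample in (rec.samples or {}) and "AF" in rec.samples[sample]:
                    val = rec.samples[sample]["AF"]
                    if val is not None:
                        af = float(val[0] if isinstance(val, tuple) else val)
                elif "AF" in rec.info:
                    val = rec.info["AF"]
                    af = float(val[0] if isinstance(val, tuple) else val)
                p_value = None
                if "SPV" in rec.info:
                    p_value = float(rec.info["SPV"])
                result.calls.add(VariantCall(
                    key, caller, patient, sample,
                    tumor_af=af, p_value=p_value,
                    filter_flags=frozenset(filters)))
    return result


def pm_subtract(tumor: CallSet, normal: CallSet, *, match_alleles: bool = True) -> CallSet:
    """Poor Man's somatic detector: tumor calls absent from the normal.

    Subtraction matches the exact allele (chrom, pos, ref, alt) by
    default — a different alternate allele at the same site in the normal
    is not evidence that the tumor allele is germline. A locus-level mode
    (``match_alleles=False``) subtracts any tumor call whose site appears
    in the normal, for sensitivity analysis.

    Both inputs must come from the same patient's TVC channel. The
    subtraction deliberately consults only *called* normal variants, not
    normal pileups: a real allele the normal caller missed will leak
    through, which is exactly the failure mode the downstream
    matched-normal rule exists to catch.
    """
    patients = {c.patient for c in tumor} | {c.patient for c in normal}
    if len(patients) > 1:
        raise ValueError(f"pm_subtract across patients: {sorted(patients)}")
    if match_alleles:
        normal_index = {c.key for c in normal}
        kept = [c for c in tumor if c.key not in normal_index]
    else:
        normal_sites = {(c.key.canonical_chrom, c.key.pos) for c in normal}
        kept = [c for c in tumor
                if (c.key.canonical_chrom, c.key.pos) not in normal_sites]
    out = CallSet("PM")
    for c in kept:
        out.add(VariantCall(c.key, "PM", c.patient, c.sample,
                            tumor_af=c.tumor_af, filter_flags=c.filter_flags))
    return out


def parse_callstats(source: Union[pd.DataFrame, str, Path]) -> List[CallStatsRecord]:
    """Parse a MuTect call-stats table (TSV or DataFrame) into records.

    Required columns: contig, position, ref_allele, alt_allele,
    judgement, failure_reasons (comma-separated tokens, empty for KEEP).
    Non-SNV rows are dropped.
    """
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(source, sep="\t", comment="#",
                         dtype={"failure_reasons": str}, keep_default_na=False)
    records: List[CallStatsRecord] = []
    for row in df.itertuples(index=False):
        try:
            key = make_variant_key(row.contig, row.position,
                                   row.ref_allele, row.alt_allele)
        except NotAnSNVError:
            continue
        reasons = frozenset(
            t.strip() for t in str(row.failure_reasons or "").split(",") if t.strip())
        records.append(CallStatsRecord(key, str(row.judgement), reasons))
    return records


def mutect_rescue(
    callstats: Iterable[CallStatsRecord],
    rescue_flags: Set[str] = DEFAULT_RESCUE_FLAGS,
    *,
    patient: str = "NA",
    sample: str = "NA",
) -> CallSet:
    """Build the MG channel: MuTect KEEPs plus rescuable REJECTs.

    A REJECT is rescued iff its failure reasons form a non-empty subset of
    ``rescue_flags`` — by default, rejected *only* for
    ``nearby_gap_events``. A rejection that additionally carries any other
    reason stands. ``clustered_read_position`` may be added to the rescue
    flags but is off by default: on inspected amplicon data it showed
    poor overlap with the other channels and poor validity.

    With empty ``rescue_flags`` this is exactly the KEEP-only call set.
    """
    rescue_flags = frozenset(rescue_flags)
    out = CallSet("MG")
    seen: Set[VariantKey] = set()
    for rec in callstats:
        if rec.judgement == "KEEP":
            include = True
        else:
            include = bool(rec.failure_reasons) and rec.failure_reasons <= rescue_flags
        if include and rec.key not in seen:
            seen.add(rec.key)
            out.add(VariantCall(rec.key, "MG", patient, sample))
    return out


def varscan_somatic_filter(calls: CallSet, p_max: float = VARSCAN_P_MAX) -> CallSet:
    """Retain VarScan somatic calls with p-value <= ``p_max``.

    The rejection condition is *p greater than* the threshold, so a call
    at exactly the threshold is retained. A call without a p-value is an
    error naming the record.
    """
    out = CallSet(calls.caller)
    for c in calls:
        if c.p_value is None:
            raise ValueError(f"VarScan call without somatic p-value: {c.key}")
        if c.p_value <= p_max:
            out.add(c)
    return out
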