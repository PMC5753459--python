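"""Rule-based triage of candidate somatic SNVs from pileup evidence.

This is an automated analogue of expert review of read alignments in a
genome browser. Each candidate is classified as ``valid``, ``bad`` or
``homopolymer`` from per-variant pileup summaries and the local
reference context, with reason codes:

* ``HP_SLIPPAGE`` — homopolymer run nearby and the called base is present
  on the reference in close proximity (alignment slippage footprint).
* ``HP_COUPLED`` — homopolymer run nearby and conspicuously coupled calls
  at two or more nearby loci, not supported on both strands.
* ``NO_BIDIR`` — no supporting reads on one strand.
* ``LOW_AF`` — tumor allele fraction below 5%.
* ``POOR_MAP`` — variant-supporting reads predominantly poorly mapped.
* ``IN_NORMAL`` — allele above 5% in the matched normal.
* ``LOW_DEPTH_NOTE`` — advisory only: depth below the level that supports
  a precise allele-fraction estimate (default 200 reads).

Homopolymer triage takes precedence. A run of 6 bases escapes it when
the surrounding sequence is heterogeneous enough for good mappings and
the call itself is plausible (bidirectional, AF above threshold). The
visual cues of the human procedure are replaced by quantitative proxies;
every proxy threshold is a named parameter of :class:`ClassifierParams`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import pandas as pd

from .core import VariantKey, make_variant_key

__all__ = [
    "HomopolymerRun",
    "ReadEvidence",
    "ReferenceContext",
    "InspectionLabel",
    "ClassifierParams",
    "find_homopolymer_runs",
    "is_slippage_signature",
    "has_coupled_calls",
    "classify_variant",
    "classify_all",
    "collapse_locus_labels",
]

HP_REASONS = ("HP_SLIPPAGE", "HP_COUPLED")
BAD_REASONS = ("NO_BIDIR", "LOW_AF", "POOR_MAP", "IN_NORMAL")


@dataclass(frozen=True)
class HomopolymerRun:
    """A maximal run of identical bases; ``start`` is 1-based genomic."""

    base: str
    start: int
    length: int

    @property
    def end(self) -> int:
        """1-based inclusive end position."""
        return self.start + self.length - 1

    def distance_to(self, pos: int) -> int:
        """Gap in bases between ``pos`` and the run (0 if inside/abutting)."""
        if pos < self.start:
            return self.start - pos - 1
        if pos > self.end:
            return pos - self.end - 1
        return 0


@dataclass(frozen=True)
class ReadEvidence:
    """Pileup summary for one variant in one sample."""

    key: VariantKey
    sample: str
    depth_tumor: int
    alt_fwd: int
    alt_rev: int
    poor_map_frac: float
    depth_normal: int
    alt_normal: int

    def __post_init__(self) -> None:
        if self.alt_fwd + self.alt_rev > self.depth_tumor:
            raise ValueError(f"alt reads exceed tumor depth at {self.key}")
        if self.alt_normal > self.depth_normal:
            raise ValueError(f"normal alt reads exceed normal depth at {self.key}")
        if not (0.0 <= self.poor_map_frac <= 1.0):
            raise ValueError(f"poor_map_frac out of [0,1] at {self.key}")

    @property
    def tumor_af(self) -> float:
        return (self.alt_fwd + self.alt_rev) / self.depth_tumor if self.depth_tumor else 0.0

    @property
    def normal_af(self) -> float:
        return self.alt_normal / self.depth_normal if self.depth_normal else 0.0

    @property
    def bidirectional(self) -> bool:
        return self.alt_fwd >= 1 and self.alt_rev >= 1


@dataclass(frozen=True)
class ReferenceContext:
    """Reference window around a variant with its homopolymer runs.

    ``window`` covers ±``window_bp`` bases centred on the variant
    (truncated at contig edges); ``window_start`` is the 1-based genomic
    position of its first base. ``runs`` are the maximal runs (of at
    least the exception length) overlapping the window.
    """

    key: VariantKey
    window: str
    window_start: int
    runs: Tuple[HomopolymerRun, ...]


@dataclass(frozen=True)
class InspectionLabel:
    key: VariantKey
    sample: str
    label: str  # valid | bad | homopolymer
    reasons: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.label not in ("valid", "bad", "homopolymer"):
            raise ValueError(f"unknown label {self.label!r}")
        if self.label == "valid" and set(self.reasons) - {"LOW_DEPTH_NOTE"}:
            raise ValueError("valid labels carry no disqualifying reasons")
        if self.label == "homopolymer" and (
                not self.reasons or self.reasons[0] not in HP_REASONS):
            raise ValueError("homopolymer labels lead with an HP reason")


@dataclass(frozen=True)
class ClassifierParams:
    """Thresholds of the triage rules (all tunable, defaults stated).

    ``window_bp``: half-width of the reference context window (bp).
    ``min_run``: homopolymer length that triggers triage (bases).
    ``exception_run_min``: shortest run length relevant to slippage and
    to the good-mapping exception. ``af_min``: minimum tumor allele
    fraction for a plausible call. ``af_precision_depth``: tumor depth
    below which the AF estimate is annotated as imprecise.
    ``poor_map_max``: maximum tolerated fraction of poorly-mapped
    supporting reads. ``normal_af_max``: maximum allele fraction in the
    matched normal. ``coupled_window_bp``: window for coupled-call search.
    """

    window_bp: int = 10
    min_run: int = 6
    exception_run_min: int = 5
    heterogeneity_min_distinct: int = 3
    min_alt_per_strand: int = 1
    af_min: float = 0.05
    af_precision_depth: int = 200
    poor_map_max: float = 0.5
    normal_af_max: float = 0.05
    coupled_window_bp: int = 15
    slippage_proximity_bp: int = 2

    def __post_init__(self) -> None:
        if self.window_bp < 1 or self.min_run < 2:
            raise ValueError("window_bp >= 1 and min_run >= 2 required")
        if not (0 < self.exception_run_min <= self.min_run):
            raise ValueError("exception_run_min must be in (0, min_run]")
        for f in (self.af_min, self.poor_map_max, self.normal_af_max):
            if not (0.0 <= f <= 1.0):
                raise ValueError("fraction thresholds must lie in [0,1]")


def find_homopolymer_runs(window: str, min_length: int) -> List[Tuple[str, int, int]]:
    """Maximal runs of identical non-N bases of at least ``min_length``.

    Returns ``(base, start_offset, length)`` with ``start_offset``
    0-based within ``window``. N breaks runs and never forms one.
    """
    runs: List[Tuple[str, int, int]] = []
    i, n = 0, len(window)
    while i < n:
        base = window[i]
        j = i + 1
        while j < n and window[j] == base:
            j += 1
        if base != "N" and base in "ACGT" and j - i >= min_length:
            runs.append((base, i, j - i))
        i = j
    return runs


def build_context(key: VariantKey, get_sequence, params: ClassifierParams = ClassifierParams()) -> ReferenceContext:
    """Extract the reference window and its runs for one variant.

    ``get_sequence(chrom) -> str`` supplies the contig sequence (a
    pyfaidx record, a plain string, or anything sliceable to one).
    """
    seq = str(get_sequence(key.chrom))
    lo = max(0, key.pos - 1 - params.window_bp)
    hi = min(len(seq), key.pos + params.window_bp)
    window = seq[lo:hi].upper()
    runs = tuple(
        HomopolymerRun(base, lo + off + 1, length)
        for base, off, length in find_homopolymer_runs(window, params.exception_run_min))
    return ReferenceContext(key, window, lo + 1, runs)


def is_slippage_signature(
    key: VariantKey,
    evidence: ReadEvidence,
    context: ReferenceContext,
    params: ClassifierParams = ClassifierParams(),
) -> bool:
    """Alignment-slippage footprint: the called base forms a run nearby.

    True iff a reference run of the alternate base, of at least
    ``exception_run_min`` bases, lies within ``slippage_proximity_bp``
    of the variant position.
    """
    for run in context.runs:
        if run.base == key.alt and run.length >= params.exception_run_min \
                and run.distance_to(key.pos) <= params.slippage_proximity_bp:
            return True
    return False


def has_coupled_calls(
    key: VariantKey,
    neighbor_keys: Iterable[VariantKey],
    evidence_lookup: Mapping[Tuple[VariantKey, str], ReadEvidence],
    sample: str,
    params: ClassifierParams = ClassifierParams(),
) -> bool:
    """Coupled unidirectional calls at nearby loci in the same sample.

    True iff at least one *other* called locus lies within
    ``coupled_window_bp`` and both this call and at least one such
    neighbor lack bidirectional support.
    """
    this = evidence_lookup.get((key, sample))
    if this is None or this.bidirectional:
        return False
    for nk in neighbor_keys:
        if nk == key or nk.canonical_chrom != key.canonical_chrom:
            continue
        if abs(nk.pos - key.pos) > params.coupled_window_bp:
            continue
        nb = evidence_lookup.get((nk, sample))
        if nb is not None and not nb.bidirectional:
            return True
    return False


def _heterogeneous_flanks(context: ReferenceContext, params: ClassifierParams) -> bool:
    """Distinct bases outside the triggering run(s) within the window."""
    masked = list(context.window)
    for run in context.runs:
        if run.length >= params.exception_run_min:
            for pos in range(run.start, run.end + 1):
                off = pos - context.window_start
                if 0 <= off < len(masked):
                    masked[off] = None
    distinct = {b for b in masked if b is not None and b in "ACGT"}
    return len(distinct) >= params.heterogeneity_min_distinct


def classify_variant(
    key: VariantKey,
    evidence: ReadEvidence,
    context: Optional[ReferenceContext],
    neighbor_keys: Iterable[VariantKey] = (),
    params: ClassifierParams = ClassifierParams(),
    evidence_lookup: Optional[Mapping[Tuple[VariantKey, str], ReadEvidence]] = None,
) -> InspectionLabel:
    """Classify one (variant, sample) as valid / bad / homopolymer.

    Precedence: homopolymer triage first (run of at least ``min_run``
    in the window and either the slippage footprint or coupled
    unidirectional calls), unless the good-mapping exception applies;
    then any of the four disqualifying rules makes the call bad, with
    every triggered reason recorded; otherwise valid. A low-depth
    advisory note is appended whatever the label.
    """
    if context is None:
        raise ValueError(f"missing reference context for {key}")
    if evidence_lookup is None:
        evidence_lookup = {(key, evidence.sample): evidence}

    reasons: List[str] = []
    label = None

    trigger_runs = [r for r in context.runs if r.length >= params.min_run]
    if trigger_runs:
        slippage = is_slippage_signature(key, evidence, context, params)
        coupled = has_coupled_calls(key, neighbor_keys, evidence_lookup,
                                    evidence.sample, params)
        if slippage or coupled:
            exception = (
                all(r.length <= params.min_run for r in trigger_runs)
                and _heterogeneous_flanks(context, params)
                and evidence.bidirectional
                and evidence.tumor_af >= params.af_min
            )
            if not exception:
                label = "homopolymer"
                reasons.append("HP_SLIPPAGE" if slippage else "HP_COUPLED")

    bad_hits: List[str] = []
    if evidence.alt_fwd < params.min_alt_per_strand \
            or evidence.alt_rev < params.min_alt_per_strand:
        bad_hits.append("NO_BIDIR")
    if evidence.tumor_af < params.af_min:
        bad_hits.append("LOW_AF")
    if evidence.poor_map_frac > params.poor_map_max:
        bad_hits.append("POOR_MAP")
    if evidence.normal_af > params.normal_af_max:
        bad_hits.append("IN_NORMAL")

    if label == "homopolymer":
        reasons.extend(bad_hits)
    elif bad_hits:
        label = "bad"
        reasons.extend(bad_hits)
    else:
        label = "valid"

    if evidence.depth_tumor < params.af_precision_depth:
        reasons.append("LOW_DEPTH_NOTE")
    return InspectionLabel(key, evidence.sample, label, tuple(reasons))


def _evidence_from_frame(df: pd.DataFrame) -> Dict[Tuple[VariantKey, str], ReadEvidence]:
    out: Dict[Tuple[VariantKey, str], ReadEvidence] = {}
    for r in df.itertuples(index=False):
        key = make_variant_key(r.chrom, r.pos, r.ref, r.alt)
        out[(key, r.sample)] = ReadEvidence(
            key, r.sample, int(r.depth_tumor), int(r.alt_fwd), int(r.alt_rev),
            float(r.poor_map_frac), int(r.depth_normal), int(r.alt_normal))
    return out


def classify_all(
    keys: Iterable[VariantKey],
    evidence: pd.DataFrame,
    get_sequence,
    params: ClassifierParams = ClassifierParams(),
) -> pd.DataFrame:
    """Classify every (locus, sample) with evidence among ``keys``.

    ``evidence`` is the per-variant pileup table (columns chrom, pos,
    ref, alt, sample, depth_tumor, alt_fwd, alt_rev, poor_map_frac,
    depth_normal, alt_normal); ``get_sequence(chrom)`` supplies contig
    sequence for context extraction. Neighbor sets for the coupled-call
    rule are the *classified* loci observed in the same sample.
    """
    wanted = set(keys)
    lookup = _evidence_from_frame(evidence)
    by_sample: Dict[str, List[VariantKey]] = {}
    for (key, sample) in lookup:
        if key in wanted:
            by_sample.setdefault(sample, []).append(key)

    rows = []
    contexts: Dict[VariantKey, ReferenceContext] = {}
    for sample in sorted(by_sample):
        sample_keys = sorted(by_sample[sample])
        for key in sample_keys:
            if key not in contexts:
                contexts[key] = build_context(key, get_sequence, params)
            lab = classify_variant(
                key, lookup[(key, sample)], contexts[key],
                neighbor_keys=sample_keys, params=params,
                evidence_lookup=lookup)
            rows.append({
                "chrom": key.chrom, "pos": key.pos, "ref": key.ref,
                "alt": key.alt, "sample": sample, "label": lab.label,
                "reasons": ",".join(lab.reasons),
            })
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "sample", "label", "reasons"])


def collapse_locus_labels(labels: pd.DataFrame, rule: str = "any_valid") -> Dict[VariantKey, str]:
    """Collapse per-sample labels to one verdict per locus.

    ``any_valid`` (default): valid if valid in at least one sample,
    matching the practice of reviewing all carrying samples in one
    browser view and issuing one verdict; otherwise homopolymer if any
    sample was, else bad. ``majority``: most frequent label, ties broken
    valid < homopolymer < bad conservatively toward bad.
    """
    out: Dict[VariantKey, str] = {}
    for (chrom, pos, ref, alt), grp in labels.groupby(
            ["chrom", "pos", "ref", "alt"], sort=False):
        key = make_variant_key(chrom, pos, ref, alt)
        vals = list(grp["label"])
        if rule == "any_valid":
            if "valid" in vals:
                out[key] = "valid"
            elif "homopolymer" in vals:
                out[key] = "homopolymer"
            else:
                out[key] = "bad"
        elif rule == "majority":
            counts = pd.Series(vals).value_counts()
            top = counts.max()
            for cand in ("bad", "homopolymer", "valid"):
                if counts.get(cand, 0) == top:
                    out[key] = cand
        else:
            raise ValueError(f"unknown collapse rule {rule!r}")
    return out
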