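"""Population-database and functional-class exclusions.

Candidate somatic calls already present in the 1000 Genomes Project or
the Exome Variant Server are overwhelmingly germline and are excluded
outright (presence/absence, no frequency threshold). For the final
tabulation only variants in informative functional classes are kept:
exonic, UTR3, UTR5, stopgain, splicing and non-coding RNA; intronic and
intergenic calls (and anything else, e.g. upstream/downstream) are
excluded. Annotations are consumed as input — computing them is someone
else's job (ANNOVAR / Variant Tools).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Set, Union

import pandas as pd

from .core import CallSet, VariantKey, make_variant_key

__all__ = [
    "FUNC_CLASSES",
    "DEFAULT_KEEP_CLASSES",
    "AnnotationRecord",
    "AnnotationTable",
    "FilterReport",
    "apply_population_filter",
    "apply_functional_filter",
]

FUNC_CLASSES = ("exonic", "UTR3", "UTR5", "stopgain", "splicing", "ncRNA",
                "intronic", "intergenic", "other")
DEFAULT_KEEP_CLASSES = frozenset(
    {"exonic", "UTR3", "UTR5", "stopgain", "splicing", "ncRNA"})


@dataclass(frozen=True)
class AnnotationRecord:
    key: VariantKey
    func_class: str
    in_1kg: bool
    in_evs: bool

    def __post_init__(self) -> None:
        if self.func_class not in FUNC_CLASSES:
            raise ValueError(f"unknown func_class {self.func_class!r} at {self.key}")


class AnnotationTable:
    """Allele-exact lookup of annotation records.

    Lookup is by exact :class:`VariantKey`; no locus-level fallback is
    offered, since population-database membership is allele-specific.
    """

    def __init__(self, records: Iterable[AnnotationRecord] = ()):
        self._by_key: Dict[VariantKey, AnnotationRecord] = {}
        for rec in records:
            if rec.key in self._by_key:
                raise ValueError(f"duplicate annotation for {rec.key}")
            self._by_key[rec.key] = rec

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "AnnotationTable":
        df = pd.read_csv(path, sep="\t")
        return cls(
            AnnotationRecord(
                make_variant_key(r.chrom, r.pos, r.ref, r.alt),
                str(r.func_class), bool(r.in_1kg), bool(r.in_evs))
            for r in df.itertuples(index=False))

    def get(self, key: VariantKey):
        return self._by_key.get(key)

    def __len__(self) -> int:
        return len(self._by_key)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self._by_key


@dataclass
class FilterReport:
    """Accounting for one filter pass: kept + excluded = input."""

    kept: CallSet
    n_input: int
    excluded_by_reason: Dict[str, int] = field(default_factory=dict)
    n_unannotated_retained: int = 0

    @property
    def n_excluded(self) -> int:
        return sum(self.excluded_by_reason.values())


def _lookup(annotations: AnnotationTable, key: VariantKey, lenient: bool):
    rec = annotations.get(key)
    if rec is None and not lenient:
        raise KeyError(f"no annotation for {key} (strict mode)")
    return rec


def apply_population_filter(
    calls: CallSet, annotations: AnnotationTable, *, lenient: bool = False
) -> FilterReport:
    """Exclude calls present in either 1KG or EVS.

    Strict mode (default) errors on an unannotated call; lenient mode
    retains it with a counted warning.
    """
    kept = CallSet(calls.caller)
    reasons: Dict[str, int] = {}
    n_unannotated = 0
    for c in calls:
        rec = _lookup(annotations, c.key, lenient)
        if rec is None:
            n_unannotated += 1
            kept.add(c)
            continue
        if rec.in_1kg or rec.in_evs:
            tag = "in_1kg" if rec.in_1kg else "in_evs"
            reasons[tag] = reasons.get(tag, 0) + 1
        else:
            kept.add(c)
    return FilterReport(kept, len(calls), reasons,
                        n_unannotated_retained=n_unannotated)


def apply_functional_filter(
    calls: CallSet,
    annotations: AnnotationTable,
    keep_classes: Set[str] = DEFAULT_KEEP_CLASSES,
    *,
    lenient: bool = False,
) -> FilterReport:
    """Retain only calls whose functional class is in ``keep_classes``."""
    kept = CallSet(calls.caller)
    reasons: Dict[str, int] = {}
    for c in calls:
        rec = _lookup(annotations, c.key, lenient)
        if rec is None or rec.func_class in keep_classes:
            kept.add(c)
        else:
            reasons[rec.func_class] = reasons.get(rec.func_class, 0) + 1
    return FilterReport(kept, len(calls), reasons)
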