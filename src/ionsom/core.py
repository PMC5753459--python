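"""Shared domain types for somatic SNV call sets.

The unit of analysis throughout the package is a single-nucleotide variant
allele: one reference base replaced by one alternate base at a 1-based
genomic position. Indels, MNVs and symbolic alleles are rejected at
construction time — flow-based (Ion Torrent) chemistry makes indel calls
unreliable and the pipeline analyses SNVs only.

Chromosome names are kept as given but *compared* on a canonical form with
any leading ``chr`` prefix stripped and case folded, so ``"1"`` and
``"chr1"`` refer to the same chromosome. Mixed-dialect inputs (panel BED in
one dialect, caller VCFs in another) are common enough that this is the
safe default.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Iterable, Optional

__all__ = [
    "CHANNELS",
    "NotAnSNVError",
    "VariantKey",
    "VariantCall",
    "CallSet",
    "PatientContext",
    "make_variant_key",
    "locus_projection",
]

#: Declared caller channels: Ion Reporter, MuTect-with-gap-rescue,
#: Poor Man's TVC subtraction, VarScan2, plus the raw channels they are
#: built from (unpaired Torrent Variant Caller, unmodified MuTect).
CHANNELS = ("IR", "MG", "PM", "VS", "TVC", "MU")

_BASES = frozenset("ACGT")


class NotAnSNVError(ValueError):
    """Raised when an allele pair is not a simple single-nucleotide variant."""


def _canonical_chrom(chrom: str) -> str:
    c = chrom.lower()
    return c[3:] if c.startswith("chr") else c


@functools.total_ordering
@dataclass(frozen=True)
class VariantKey:
    """A single-nucleotide variant allele at a 1-based locus.

    Equality, hashing and ordering use the canonical chromosome form
    (``chr`` prefix stripped, case-insensitive), then position, then
    ref, then alt — a total order.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if len(allele) != 1 or allele not in _BASES:
                raise NotAnSNVError(
                    f"not an SNV: {name} allele {allele!r} at "
                    f"{self.chrom}:{self.pos} (single A/C/G/T required)"
                )
        if self.ref == self.alt:
            raise NotAnSNVError(
                f"not an SNV: ref equals alt ({self.ref}) at {self.chrom}:{self.pos}"
            )

    @property
    def canonical_chrom(self) -> str:
        return _canonical_chrom(self.chrom)

    def sort_key(self) -> tuple:
        return (self.canonical_chrom, self.pos, self.ref, self.alt)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VariantKey):
            return NotImplemented
        return self.sort_key() == other.sort_key()

    def __lt__(self, other: "VariantKey") -> bool:
        if not isinstance(other, VariantKey):
            return NotImplemented
        return self.sort_key() < other.sort_key()

    def __hash__(self) -> int:
        return hash(self.sort_key())

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}{self.ref}>{self.alt}"


def make_variant_key(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Construct a normalized :class:`VariantKey`.

    Rejects anything that is not a simple SNV (multi-base alleles,
    symbolic alleles such as ``<DEL>``, spanning-deletion ``*`` markers,
    ref==alt) with :class:`NotAnSNVError`.
    """
    return VariantKey(str(chrom), int(pos), str(ref).upper(), str(alt).upper())


@dataclass(frozen=True)
class VariantCall:
    """One caller channel's call of a variant allele in one sample."""

    key: VariantKey
    caller: str
    patient: str
    sample: str
    tumor_af: Optional[float] = None
    p_value: Optional[float] = None
    filter_flags: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.caller not in CHANNELS:
            raise ValueError(
                f"unknown caller channel {self.caller!r}; declared: {CHANNELS}"
            )
        if self.tumor_af is not None and not (0.0 <= self.tumor_af <= 1.0):
            raise ValueError(f"tumor_af out of [0,1]: {self.tumor_af}")
        if self.p_value is not None and not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value out of (0,1]: {self.p_value}")


class CallSet:
    """A channel's collection of calls plus its distinct-locus projection.

    ``loci`` collapses across samples and patients: a variant allele seen
    in several samples counts as one locus. This is the variants-vs-loci
    distinction used everywhere downstream (concordance and strategy
    evaluation operate on loci by default).
    """

    def __init__(self, caller: str, calls: Iterable[VariantCall] = ()):
        if caller not in CHANNELS:
            raise ValueError(f"unknown caller channel {caller!r}")
        self.caller = caller
        self.calls: list[VariantCall] = []
        for c in calls:
            self.add(c)

    def add(self, call: VariantCall) -> None:
        if call.caller != self.caller:
            raise ValueError(
                f"call labelled {call.caller} added to {self.caller} call set"
            )
        self.calls.append(call)

    @property
    def loci(self) -> set[VariantKey]:
        return locus_projection(self.calls)

    def relabel(self, caller: str) -> "CallSet":
        """Return a copy of this set attributed to another channel."""
        out = CallSet(caller)
        for c in self.calls:
            out.add(
                VariantCall(
                    key=c.key,
                    caller=caller,
                    patient=c.patient,
                    sample=c.sample,
                    tumor_af=c.tumor_af,
                    p_value=c.p_value,
                    filter_flags=c.filter_flags,
                )
            )
        return out

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self):
        return iter(self.calls)

    def __repr__(self) -> str:
        return f"CallSet({self.caller}, {len(self.calls)} calls, {len(self.loci)} loci)"


@dataclass(frozen=True)
class PatientContext:
    """A patient's samples: exactly one matched normal, one or more tumors."""

    patient: str
    tumor_samples: tuple
    normal_sample: str

    def __post_init__(self) -> None:
        if not self.tumor_samples:
            raise ValueError(f"patient {self.patient}: at least one tumor sample required")
        if not self.normal_sample:
            raise ValueError(f"patient {self.patient}: normal sample required")


def locus_projection(calls: Iterable[VariantCall]) -> set[VariantKey]:
    """Distinct variant keys of a call collection (idempotent, monotone)."""
    return {c.key for c in calls}
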