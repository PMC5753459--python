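"""Caller × locus incidence, combination strategies, inspection sampling.

A locus is attributed to a channel if any of that channel's filtered
tumor-sample calls covers it, pooled across samples and patients.
Combination strategies are written in a tiny expression language over
channel names — ``&`` (intersection), ``|`` (union), parentheses, and
``any(k)`` (called by at least *k* of all channels) — so that rows like
``IR & PM`` or ``(IR | PM) & (MG | VS)`` can be stated verbatim in a
config file.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple, Union

from .core import CallSet, VariantKey

__all__ = [
    "ConcordanceMatrix",
    "StrategyParseError",
    "build_matrix",
    "evaluate_strategy",
    "venn_counts",
    "select_inspection_set",
    "shared_fraction",
]


class StrategyParseError(ValueError):
    """Strategy expression could not be parsed; message carries position."""


@dataclass
class ConcordanceMatrix:
    """Incidence of loci across caller channels.

    ``signature(locus)`` is the (nonempty) subset of channels that called
    it — the unit of Venn and combination analysis.
    """

    callers: Tuple[str, ...]
    signatures: Dict[VariantKey, frozenset]

    @property
    def loci(self) -> List[VariantKey]:
        return sorted(self.signatures)

    def signature(self, locus: VariantKey) -> frozenset:
        return self.signatures[locus]

    def channel_loci(self, caller: str) -> Set[VariantKey]:
        if caller not in self.callers:
            raise KeyError(f"unknown channel {caller!r}")
        return {k for k, sig in self.signatures.items() if caller in sig}

    def __len__(self) -> int:
        return len(self.signatures)


def build_matrix(
    channels: Union[Mapping[str, Union[CallSet, Set[VariantKey]]], Iterable[CallSet]],
) -> ConcordanceMatrix:
    """Build the caller × locus incidence from channel call sets.

    Accepts a mapping of channel name to call set (or plain locus set),
    or an iterable of call sets labelled by their caller. Duplicate
    channel names are an error.
    """
    if isinstance(channels, Mapping):
        items = list(channels.items())
    else:
        items = [(cs.caller, cs) for cs in channels]
    names = [n for n, _ in items]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate channel names: {names}")
    if not names:
        raise ValueError("at least one channel required")
    signatures: Dict[VariantKey, set] = {}
    for name, cs in items:
        loci = cs.loci if isinstance(cs, CallSet) else set(cs)
        for key in loci:
            signatures.setdefault(key, set()).add(name)
    return ConcordanceMatrix(
        callers=tuple(names),
        signatures={k: frozenset(v) for k, v in signatures.items()})


# --- strategy expression mini-language -------------------------------------

_TOKEN_RE = re.compile(r"\s*(?:(?P<name>[A-Za-z_][A-Za-z0-9_]*)"
                       r"|(?P<int>\d+)"
                       r"|(?P<op>[&|()]))")


def _tokenize(expr: str) -> List[Tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(expr):
        m = _TOKEN_RE.match(expr, pos)
        if m is None:
            if expr[pos:].strip() == "":
                break
            raise StrategyParseError(
                f"cannot tokenize strategy {expr!r} at position {pos}")
        for kind in ("name", "int", "op"):
            if m.group(kind) is not None:
                tokens.append((kind, m.group(kind), m.start(kind)))
        pos = m.end()
    return tokens


class _Parser:
    """Recursive descent: expr := term ('|' term)* ; term := factor ('&' factor)*."""

    def __init__(self, expr: str, matrix: ConcordanceMatrix):
        self.expr = expr
        self.tokens = _tokenize(expr)
        self.i = 0
        self.matrix = matrix

    def _peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def _next(self):
        tok = self._peek()
        if tok is None:
            raise StrategyParseError(f"unexpected end of strategy {self.expr!r}")
        self.i += 1
        return tok

    def parse(self) -> Set[VariantKey]:
        result = self._expr()
        if self._peek() is not None:
            kind, val, pos = self._peek()
            raise StrategyParseError(
                f"trailing input {val!r} at position {pos} in {self.expr!r}")
        return result

    def _expr(self) -> Set[VariantKey]:
        left = self._term()
        while self._peek() and self._peek()[1] == "|":
            self._next()
            left = left | self._term()
        return left

    def _term(self) -> Set[VariantKey]:
        left = self._factor()
        while self._peek() and self._peek()[1] == "&":
            self._next()
            left = left & self._factor()
        return left

    def _factor(self) -> Set[VariantKey]:
        kind, val, pos = self._next()
        if kind == "op" and val == "(":
            inner = self._expr()
            kind, val, pos = self._next()
            if val != ")":
                raise StrategyParseError(
                    f"expected ')' at position {pos} in {self.expr!r}")
            return inner
        if kind == "name" and val.lower() == "any":
            kind, val, pos = self._next()
            if val != "(":
                raise StrategyParseError(
                    f"expected '(' after any at position {pos} in {self.expr!r}")
            kind, val, pos = self._next()
            if kind != "int":
                raise StrategyParseError(
                    f"any(k) needs an integer at position {pos} in {self.expr!r}")
            k = int(val)
            if not (1 <= k <= len(self.matrix.callers)):
                raise StrategyParseError(
                    f"any({k}) out of range 1..{len(self.matrix.callers)}")
            kind, val, pos = self._next()
            if val != ")":
                raise StrategyParseError(
                    f"expected ')' at position {pos} in {self.expr!r}")
            return {loc for loc, sig in self.matrix.signatures.items()
                    if len(sig) >= k}
        if kind == "name":
            if val not in self.matrix.callers:
                raise StrategyParseError(
                    f"unknown channel {val!r} at position {pos} in {self.expr!r}")
            return self.matrix.channel_loci(val)
        raise StrategyParseError(
            f"unexpected token {val!r} at position {pos} in {self.expr!r}")


def evaluate_strategy(matrix: ConcordanceMatrix, expr: str) -> Set[VariantKey]:
    """Locus set selected by a strategy expression (set semantics)."""
    return _Parser(expr, matrix).parse()


def venn_counts(matrix: ConcordanceMatrix) -> Dict[frozenset, int]:
    """Locus count per nonempty caller-subset signature.

    All 2^n − 1 subsets are present (zero where empty); per-channel
    marginal totals are recoverable by summing the cells containing the
    channel.
    """
    from itertools import combinations

    counts: Dict[frozenset, int] = {}
    for r in range(1, len(matrix.callers) + 1):
        for combo in combinations(matrix.callers, r):
            counts[frozenset(combo)] = 0
    for sig in matrix.signatures.values():
        counts[sig] += 1
    return counts


def select_inspection_set(
    matrix: ConcordanceMatrix,
    max_singletons: int = 50,
    seed: int = 0,
) -> Tuple[Set[VariantKey], Dict[str, Dict[str, int]]]:
    """All multi-caller loci plus sampled single-caller loci per channel.

    Every locus called by two or more channels is always included
    (deterministically, independent of the seed); for each channel, at
    most ``max_singletons`` of its singleton loci are sampled uniformly
    without replacement. Returns the locus set and a per-channel
    sampling log.
    """
    from .simulate import substream

    rng = substream(seed, "inspection-set")
    selected: Set[VariantKey] = {
        loc for loc, sig in matrix.signatures.items() if len(sig) >= 2}
    log: Dict[str, Dict[str, int]] = {}
    for caller in matrix.callers:
        singles = sorted(
            loc for loc, sig in matrix.signatures.items() if sig == {caller})
        n_take = min(max_singletons, len(singles))
        if n_take < len(singles):
            idx = rng.choice(len(singles), size=n_take, replace=False)
            taken = {singles[i] for i in idx}
        else:
            taken = set(singles)
        selected |= taken
        log[caller] = {"n_singletons": len(singles), "n_sampled": n_take}
    return selected, log


def shared_fraction(matrix: ConcordanceMatrix, channel: str, other: str) -> float:
    """Fraction of ``channel``'s loci also called by ``other``."""
    a = matrix.channel_loci(channel)
    if not a:
        raise ValueError(f"channel {channel!r} has no loci")
    return len(a & matrix.channel_loci(other)) / len(a)
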