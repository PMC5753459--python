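"""Strategy performance: PPV, sensitivity, extrapolation, standard errors.

For a calling strategy with called-locus set of size *C*, of which *v*
are valid, PPV = v/C. Sensitivity = v/V, where V is a proxy for the
true number of valid variants: the valid calls discovered by *any*
channel, extrapolated to the uninspected remainder under the assumption
that the validity rates observed among inspected loci also hold in the
uninspected ones (stratified by caller signature, the finest partition
consistent with that assumption). The binomial standard error
``sqrt(p(1-p)/n)`` is reported only when ``n * min(p, 1-p) >= 5``,
with *n* the number of loci *examined* (not called, since extrapolated
counts contribute no precision); otherwise the table shows ``NA``.

The module is organised as a model/results pair: build a
:class:`StrategyPerformanceModel` from a concordance matrix, per-locus
validity verdicts and the inspected set, then :meth:`fit` to obtain a
:class:`StrategyPerformanceResults` carrying one row per strategy and a
``summary()`` table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .concordance import ConcordanceMatrix, evaluate_strategy
from .core import VariantKey

__all__ = [
    "ppv",
    "sensitivity",
    "binomial_se",
    "round_half_up",
    "ExtrapolationReport",
    "extrapolate_valid",
    "StrategyResult",
    "StrategyPerformanceModel",
    "StrategyPerformanceResults",
    "strategy_row_from_counts",
    "DEFAULT_STRATEGIES",
]

#: The canonical strategy panel for four channels: each single channel,
#: every pairwise and three-way intersection, the at-least-k rows, the
#: four-way intersection, and the two union-based combinations.
DEFAULT_STRATEGIES = (
    "IR", "MG", "PM", "VS",
    "any(1)",
    "IR & MG", "IR & PM", "IR & VS", "MG & PM", "MG & VS", "PM & VS",
    "any(2)",
    "IR & MG & PM", "IR & MG & VS", "IR & PM & VS", "MG & PM & VS",
    "any(3)",
    "IR & MG & PM & VS",
    "IR | PM",
    "(IR | PM) & (MG | VS)",
)


def ppv(v: int, C: int) -> float:
    """Positive predictive value v/C."""
    if C <= 0:
        raise ZeroDivisionError("PPV undefined for zero called variants")
    if not (0 <= v <= C):
        raise ValueError(f"need 0 <= v <= C, got v={v}, C={C}")
    return v / C


def sensitivity(v: int, V: int) -> float:
    """Sensitivity v/V against the valid-variant proxy V."""
    if V <= 0:
        raise ZeroDivisionError("sensitivity undefined for zero valid variants")
    if not (0 <= v <= V):
        raise ValueError(f"need 0 <= v <= V, got v={v}, V={V}")
    return v / V


def binomial_se(p: float, n: int) -> Optional[float]:
    """sqrt(p(1-p)/n) when n*min(p, 1-p) >= 5, else None (reported NA)."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p out of [0,1]: {p}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if n * min(p, 1.0 - p) < 5:
        return None
    return math.sqrt(p * (1.0 - p) / n)


def round_half_up(x: float, digits: int = 0) -> float:
    """Decimal half-up rounding (0.5 always rounds away from zero)."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ExtrapolationReport:
    """Per-signature extrapolation of validity to uninspected loci.

    ``strata`` has one row per caller signature with inspected counts,
    inspected valid counts, uninspected counts and the (integer)
    extrapolated addition. ``V_hat`` = total inspected valid + total
    additions.
    """

    strata: pd.DataFrame
    total_inspected: int
    total_inspected_valid: int

    @property
    def total_additions(self) -> int:
        return int(self.strata["addition"].sum())

    @property
    def V_hat(self) -> int:
        return self.total_inspected_valid + self.total_additions


def extrapolate_valid(
    matrix: ConcordanceMatrix,
    valid_by_locus: Mapping[VariantKey, bool],
    inspected: Set[VariantKey],
) -> ExtrapolationReport:
    """Extrapolate validity rates from inspected to uninspected loci.

    Stratifies by full caller signature; within each stratum the
    addition is ``round(rate * n_uninspected)`` (half-up) with ``rate``
    the inspected valid fraction. Under the intended inspection design
    uninspected loci exist only in singleton strata; if a stratum has
    uninspected loci but none inspected, the pooled inspected singleton
    rate of that channel (or, failing that, the overall inspected rate)
    is used with a warning.
    """
    for loc in inspected:
        if loc not in matrix.signatures:
            raise ValueError(f"inspected locus {loc} not in matrix")
        if loc not in valid_by_locus:
            raise ValueError(f"inspected locus {loc} lacks a validity verdict")

    strata: Dict[frozenset, Dict[str, int]] = {}
    for loc, sig in matrix.signatures.items():
        s = strata.setdefault(sig, {"n": 0, "n_inspected": 0, "n_valid": 0})
        s["n"] += 1
        if loc in inspected:
            s["n_inspected"] += 1
            s["n_valid"] += int(bool(valid_by_locus[loc]))

    total_inspected = sum(s["n_inspected"] for s in strata.values())
    total_valid = sum(s["n_valid"] for s in strata.values())
    overall_rate = total_valid / total_inspected if total_inspected else 0.0

    def channel_singleton_rate(caller: str) -> Optional[float]:
        s = strata.get(frozenset({caller}))
        if s and s["n_inspected"]:
            return s["n_valid"] / s["n_inspected"]
        return None

    rows = []
    for sig in sorted(strata, key=lambda s: (len(s), sorted(s))):
        s = strata[sig]
        uninspected = s["n"] - s["n_inspected"]
        if s["n_inspected"]:
            rate = s["n_valid"] / s["n_inspected"]
        elif uninspected:
            fallback = None
            if len(sig) == 1:
                fallback = channel_singleton_rate(next(iter(sig)))
            rate = fallback if fallback is not None else overall_rate
            warnings.warn(
                f"stratum {sorted(sig)} has {uninspected} uninspected loci but "
                f"none inspected; using fallback rate {rate:.3f}")
        else:
            rate = 0.0
        addition = int(math.floor(rate * uninspected + 0.5))
        rows.append({
            "signature": "+".join(sorted(sig)),
            "callers": sig,
            "n_loci": s["n"],
            "n_inspected": s["n_inspected"],
            "n_valid": s["n_valid"],
            "rate": rate,
            "n_uninspected": uninspected,
            "addition": addition,
        })
    return ExtrapolationReport(pd.DataFrame(rows), total_inspected, total_valid)


@dataclass(frozen=True)
class StrategyResult:
    """One performance-table row for one strategy."""

    name: str
    C: int
    n_inspected: int
    v_inspected: int
    v_hat: int
    extrapolated: bool
    V_hat: int
    ppv: float
    ppv_se: Optional[float]
    sens: float
    sens_se: Optional[float]
    n_sens: int

    def as_row(self, ppv_digits: int = 2, se_digits: int = 3) -> dict:
        # display rounding is IEEE round-half-even (the builtin), the
        # convention of the float tabulation stack this table targets
        fmt = lambda x, d: round(x, d)
        se = lambda x: "NA" if x is None else fmt(x, se_digits)
        return {
            "name": self.name,
            "C": self.C,
            "v": self.v_hat,
            "extrapolated": "*" if self.extrapolated else "",
            "PPV": fmt(self.ppv, ppv_digits),
            "PPV_SE": se(self.ppv_se),
            "n_inspected": self.n_inspected,
            "Sensitivity": fmt(self.sens, ppv_digits),
            "Sens_SE": se(self.sens_se),
        }


def strategy_row_from_counts(
    name: str,
    C: int,
    v: int,
    n_inspected: int,
    V: int,
    n_sens: int,
    extrapolated: bool = False,
) -> StrategyResult:
    """Performance arithmetic from given counts.

    Useful when the called/valid tallies come from an external
    inspection campaign rather than from this package's classifier: the
    PPV, sensitivity, standard errors and reportability verdicts follow
    from (C, v, n_inspected, V, n_sens) alone.
    """
    p = ppv(v, C)
    s = sensitivity(v, V)
    return StrategyResult(
        name=name, C=C, n_inspected=n_inspected, v_inspected=min(v, n_inspected),
        v_hat=v, extrapolated=extrapolated, V_hat=V,
        ppv=p, ppv_se=binomial_se(p, n_inspected),
        sens=s, sens_se=binomial_se(s, n_sens), n_sens=n_sens)


class StrategyPerformanceModel:
    """Performance surface of caller-combination strategies.

    Built from the caller × locus incidence, per-locus validity verdicts
    for the inspected loci, the inspected set itself, and the strategy
    expressions to evaluate. ``fit`` extrapolates validity to the
    uninspected loci and computes one :class:`StrategyResult` per
    strategy.
    """

    def __init__(
        self,
        matrix: ConcordanceMatrix,
        valid_by_locus: Mapping[VariantKey, bool],
        inspected: Set[VariantKey],
        strategies: Sequence[str] = DEFAULT_STRATEGIES,
    ):
        self.matrix = matrix
        self.valid_by_locus = dict(valid_by_locus)
        self.inspected = set(inspected)
        self.strategies = list(strategies)

    @classmethod
    def from_labels(
        cls,
        matrix: ConcordanceMatrix,
        labels: pd.DataFrame,
        inspected: Set[VariantKey],
        strategies: Sequence[str] = DEFAULT_STRATEGIES,
        collapse: str = "any_valid",
    ) -> "StrategyPerformanceModel":
        """Build from a per-sample label table (classifier output)."""
        from .inspection import collapse_locus_labels

        per_locus = collapse_locus_labels(labels, rule=collapse)
        valid = {k: (lab == "valid") for k, lab in per_locus.items()}
        return cls(matrix, valid, inspected, strategies)

    def fit(self) -> "StrategyPerformanceResults":
        report = extrapolate_valid(self.matrix, self.valid_by_locus, self.inspected)
        V_hat = max(report.V_hat, 1)
        n_sens = report.total_inspected
        results: List[StrategyResult] = []
        for expr in self.strategies:
            S = evaluate_strategy(self.matrix, expr)
            C = len(S)
            insp = S & self.inspected
            v_insp = sum(bool(self.valid_by_locus[k]) for k in insp)
            additions = 0
            for row in report.strata.itertuples(index=False):
                if row.n_uninspected == 0 or row.addition == 0:
                    continue
                # signature determines strategy membership; test one member
                member = next(loc for loc, sig in self.matrix.signatures.items()
                              if sig == row.callers)
                if member in S:
                    additions += row.addition
            v_hat = v_insp + additions
            p = ppv(v_hat, C) if C else float("nan")
            s = sensitivity(min(v_hat, V_hat), V_hat)
            results.append(StrategyResult(
                name=expr, C=C, n_inspected=len(insp), v_inspected=v_insp,
                v_hat=v_hat, extrapolated=additions > 0, V_hat=V_hat,
                ppv=p, ppv_se=binomial_se(p, len(insp)) if C and insp else None,
                sens=s, sens_se=binomial_se(s, n_sens) if n_sens else None,
                n_sens=n_sens))
        return StrategyPerformanceResults(self, results, report)


class StrategyPerformanceResults:
    """Fitted performance table with per-strategy estimates and SEs."""

    def __init__(self, model: StrategyPerformanceModel,
                 results: List[StrategyResult], extrapolation: ExtrapolationReport):
        self.model = model
        self.results = results
        self.extrapolation = extrapolation

    def __iter__(self):
        return iter(self.results)

    def __getitem__(self, name: str) -> StrategyResult:
        for r in self.results:
            if r.name == name:
                return r
        raise KeyError(name)

    @property
    def V_hat(self) -> int:
        return self.extrapolation.V_hat

    def to_frame(self, ppv_digits: int = 2, se_digits: int = 3) -> pd.DataFrame:
        return pd.DataFrame([r.as_row(ppv_digits, se_digits) for r in self.results])

    def summary(self) -> str:
        """Human-readable performance table (one row per strategy)."""
        df = self.to_frame()
        lines = [
            "Strategy performance",
            "====================",
            f"inspected loci: {self.extrapolation.total_inspected}   "
            f"inspected valid: {self.extrapolation.total_inspected_valid}   "
            f"extrapolated additions: {self.extrapolation.total_additions}   "
            f"V = {self.V_hat}",
            "",
            df.to_string(index=False),
            "",
            "* v includes extrapolated valid counts; SE shown when "
            "n_examined * min(p, 1-p) >= 5, else NA.",
        ]
        return "\n".join(lines)
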