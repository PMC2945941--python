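"""Context-bias statistics: per-pattern impact, per-length totals, rankings.

Context bias of a pattern is ``(rho - 1) * f``: how over/under-represented the
substitution is, weighted by how often the pattern occurs.  Total context bias
sums ``|rho - 1| * w`` over all patterns of one length and measures the
aggregate context effect at that size scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

from .counting import PatternCountTable
from .patterns import SubstitutionPattern
from .relabund import Method, RhoCalculator

PatternFilter = Literal["all", "substitutions_only", "single_substitution"]
Weighting = Literal["frequency", "uniform"]


@dataclass
class BiasRecord:
    """Per-pattern statistics row."""

    pattern: SubstitutionPattern
    count: int
    pr: float | None
    f: float | None
    rho: float | None
    context_bias: float | None
    rho_ci: tuple[float, float] | None = None
    context_bias_ci: tuple[float, float] | None = None
    p_value: float | None = None
    q_value: float | None = None


@dataclass
class TotalBiasResult:
    """Total context bias at one pattern length."""

    length: int
    value: float
    n_patterns: int
    n_skipped_undefined: int
    pattern_filter: PatternFilter
    weighting: Weighting
    exclude_ancestral_cpg: bool


def _passes_filter(
    P: SubstitutionPattern,
    pattern_filter: PatternFilter,
    exclude_ancestral_cpg: bool,
) -> bool:
    if exclude_ancestral_cpg and "CG" in P.anc:
        return False
    if pattern_filter == "all":
        return True
    if pattern_filter == "substitutions_only":
        return not P.is_identity
    if pattern_filter == "single_substitution":
        return P.n_substitutions == 1
    raise ValueError(f"unknown pattern filter {pattern_filter!r}")


def context_bias(
    table: PatternCountTable,
    P: SubstitutionPattern | str,
    method: Method = "fast",
    calc: RhoCalculator | None = None,
) -> float | None:
    """(rho(P) - 1) * f(P); exactly 0 for unobserved P; None if rho undefined."""
    if isinstance(P, str):
        P = SubstitutionPattern.from_key(P)
    if table.pattern_count(P) == 0:
        return 0.0
    f = table.frequency(P)
    if f is None:
        return 0.0
    calc = calc or RhoCalculator(table)
    r = calc.rho(P, method)
    if r is None:
        return None
    return (r - 1.0) * f


def total_context_bias(
    table: PatternCountTable,
    L: int,
    pattern_filter: PatternFilter = "all",
    weighting: Weighting = "frequency",
    exclude_ancestral_cpg: bool = False,
    method: Method = "fast",
    calc: RhoCalculator | None = None,
) -> TotalBiasResult:
    """Sum of |rho - 1| * w over selected observed length-L patterns.

    Unobserved patterns contribute zero under frequency weighting and are not
    enumerated.  Patterns with undefined rho are skipped and counted.  The
    ``exclude_ancestral_cpg`` flag here is pattern-level (drops patterns whose
    ancestral word contains a contiguous CG); window-level exclusion is an
    option of the counting pass.
    """
    if table.windows_per_length.get(L, 0) == 0:
        raise ValueError(f"no windows at length {L}")
    calc = calc or RhoCalculator(table)
    n_used = 0
    n_skipped = 0
    total = 0.0
    deviations: list[float] = []
    for P, _count in table.iter_pattern_counts(L):
        if not _passes_filter(P, pattern_filter, exclude_ancestral_cpg):
            continue
        r = calc.rho(P, method)
        if r is None:
            n_skipped += 1
            continue
        n_used += 1
        if weighting == "frequency":
            total += abs(r - 1.0) * table.frequency(P)
        elif weighting == "uniform":
            deviations.append(abs(r - 1.0))
        else:
            raise ValueError(f"unknown weighting {weighting!r}")
    if weighting == "uniform":
        if not deviations:
            raise ValueError(f"no defined patterns at length {L}")
        total = sum(deviations) / len(deviations)
    return TotalBiasResult(
        length=L,
        value=total,
        n_patterns=n_used,
        n_skipped_undefined=n_skipped,
        pattern_filter=pattern_filter,
        weighting=weighting,
        exclude_ancestral_cpg=exclude_ancestral_cpg,
    )


def total_context_bias_profile(
    table: PatternCountTable,
    lengths: Iterable[int],
    **kwargs,
) -> dict[int, TotalBiasResult]:
    calc = kwargs.pop("calc", None) or RhoCalculator(table)
    return {L: total_context_bias(table, L, calc=calc, **kwargs) for L in lengths}


def bias_records(
    table: PatternCountTable,
    L: int,
    pattern_filter: PatternFilter = "all",
    exclude_ancestral_cpg: bool = False,
    method: Method = "fast",
    min_count: int = 1,
    calc: RhoCalculator | None = None,
) -> list[BiasRecord]:
    """Per-pattern rows for reporting, sorted by |context bias| descending."""
    calc = calc or RhoCalculator(table)
    rows: list[BiasRecord] = []
    for P, count in table.iter_pattern_counts(L, min_count=min_count):
        if not _passes_filter(P, pattern_filter, exclude_ancestral_cpg):
            continue
        r = calc.rho(P, method)
        f = table.frequency(P)
        cb = None if r is None else (r - 1.0) * f
        rows.append(
            BiasRecord(
                pattern=P,
                count=count,
                pr=table.proportion(P),
                f=f,
                rho=r,
                context_bias=cb,
            )
        )
    rows.sort(
        key=lambda rec: -abs(rec.context_bias) if rec.context_bias is not None else 1.0
    )
    return rows


@dataclass
class PatternDifference:
    pattern: SubstitutionPattern
    context_bias_a: float
    context_bias_b: float
    difference: float
    cumulative: float = 0.0


def rank_pattern_differences(
    table_a: PatternCountTable,
    table_b: PatternCountTable,
    L: int,
    pattern_filter: PatternFilter = "all",
    method: Method = "fast",
) -> list[PatternDifference]:
    """Context-bias differences (A - B) over shared patterns, sorted descending
    with running cumulative sums — the "few patterns drive the difference"
    diagnostic.
    """
    calc_a = RhoCalculator(table_a)
    calc_b = RhoCalculator(table_b)
    seen: set[str] = set()
    out: list[PatternDifference] = []
    for table in (table_a, table_b):
        for P, _count in table.iter_pattern_counts(L):
            if P.key in seen:
                continue
            seen.add(P.key)
            if not _passes_filter(P, pattern_filter, False):
                continue
            cb_a = context_bias(table_a, P, method, calc_a)
            cb_b = context_bias(table_b, P, method, calc_b)
            if cb_a is None or cb_b is None:
                continue
            out.append(PatternDifference(P, cb_a, cb_b, cb_a - cb_b))
    out.sort(key=lambda rec: -rec.difference)
    running = 0.0
    for rec in out:
        running += rec.difference
        rec.cumulative = running
    return out
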