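"""Relative abundance of substitution patterns.

``rho(P)`` compares the observed proportion of a pattern with the expectation
assembled from all of its smaller constituent subpatterns.  Two routes are
provided: the recursive definition (normative) and a fast algorithm that only
needs three substring proportions plus the full-length gapped subpatterns; the
two are algebraically equivalent and the test suite checks this numerically.

Undefined values (zero ancestral counts, zero denominators) propagate as
``None`` with a machine-readable reason code; they are never coerced to 0/1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

from .counting import PatternCountTable
from .patterns import (
    SubstitutionPattern,
    full_length_gapped_subpatterns,
    subpattern_multiplicities,
    trim_flanking_n,
)

Method = Literal["recursive", "fast"]

#: reason codes for undefined values
UNDEF_ZERO_ANCESTRAL = "zero_ancestral_count"
UNDEF_ZERO_DENOMINATOR = "zero_denominator"
UNDEF_PROPAGATED = "undefined_subterm"


class RhoCalculator:
    """Memoized relative-abundance computation over one count table.

    The cache is keyed by canonical pattern text and shared across rho, psi
    and gamma, for both methods.
    """

    def __init__(self, table: PatternCountTable):
        self.table = table
        self._pr: dict[tuple[str, str], float | None] = {}
        self._rho: dict[tuple[str, str, str], float | None] = {}
        self.reasons: dict[str, str] = {}

    # -------------------------------------------------------------- proportions

    def pr(self, anc: str, desc: str) -> float | None:
        """pr of the pattern after trimming flanking N; 1.0 for the empty word."""
        key = (anc, desc)
        try:
            return self._pr[key]
        except KeyError:
            pass
        t_anc, t_desc = trim_flanking_n(anc, desc)
        if not t_anc:
            value: float | None = 1.0
        else:
            denom = self.table.ancestral_count(t_anc)
            if denom == 0:
                value = None
            else:
                value = self.table.pattern_count(
                    SubstitutionPattern(t_anc, t_desc)
                ) / denom
        self._pr[key] = value
        return value

    # -------------------------------------------------------------- rho

    def rho(self, P: SubstitutionPattern | str, method: Method = "fast") -> float | None:
        if isinstance(P, str):
            P = SubstitutionPattern.from_key(P)
        key = (P.anc, P.desc, method)
        try:
            return self._rho[key]
        except KeyError:
            pass
        value = self._rho_uncached(P, method)
        self._rho[key] = value
        return value

    def _undef(self, P: SubstitutionPattern, reason: str) -> None:
        self.reasons.setdefault(P.key, reason)
        return None

    def _rho_uncached(self, P: SubstitutionPattern, method: Method) -> float | None:
        if P.L == 1:
            value = self.pr(P.anc, P.desc)
            if value is None:
                return self._undef(P, UNDEF_ZERO_ANCESTRAL)
            return value
        if method == "recursive" or P.L == 2:
            return self._rho_recursive(P, method)
        if method != "fast":
            raise ValueError(f"unknown method {method!r}")
        return self._rho_fast(P)

    def _rho_recursive(self, P: SubstitutionPattern, method: Method) -> float | None:
        numer = self.pr(P.anc, P.desc)
        if numer is None:
            return self._undef(P, UNDEF_ZERO_ANCESTRAL)
        psi = self.psi(P, method)
        if psi is None:
            return self._undef(P, UNDEF_PROPAGATED)
        if psi == 0.0:
            return self._undef(P, UNDEF_ZERO_DENOMINATOR)
        return numer / psi

    def _rho_fast(self, P: SubstitutionPattern) -> float | None:
        numer = self.pr(P.anc, P.desc)
        if numer is None:
            return self._undef(P, UNDEF_ZERO_ANCESTRAL)
        mid = self.pr(P.anc[1:-1], P.desc[1:-1])
        left = self.pr(P.anc[:-1], P.desc[:-1])
        right = self.pr(P.anc[1:], P.desc[1:])
        if mid is None or left is None or right is None:
            return self._undef(P, UNDEF_PROPAGATED)
        gamma = self.gamma(P, "fast")
        if gamma is None:
            return self._undef(P, UNDEF_PROPAGATED)
        denom = left * right * gamma
        if denom == 0.0:
            return self._undef(P, UNDEF_ZERO_DENOMINATOR)
        return numer * mid / denom

    # -------------------------------------------------------------- products

    def psi(self, P: SubstitutionPattern | str, method: Method = "fast") -> float | None:
        """Expected proportion: product of rho over all subpatterns of P.

        One factor per proper non-empty subset of P's concrete positions, so a
        subpattern arising from several subsets contributes its rho once per
        subset (required for agreement with the fast algorithm).
        """
        if isinstance(P, str):
            P = SubstitutionPattern.from_key(P)
        product = 1.0
        for s, mult in subpattern_multiplicities(P).items():
            r = self.rho(s, method)
            if r is None:
                return None
            product *= r**mult
        return product

    def gamma(self, P: SubstitutionPattern | str, method: Method = "fast") -> float | None:
        """Product of rho over all full-length gapped subpatterns of P."""
        if isinstance(P, str):
            P = SubstitutionPattern.from_key(P)
        product = 1.0
        for s in full_length_gapped_subpatterns(P):
            r = self.rho(s, method)
            if r is None:
                return None
            product *= r
        return product


@dataclass
class RelativeAbundanceTable:
    """rho for a set of patterns, with undefined entries accounted for."""

    method: Method
    values: dict[str, float] = field(default_factory=dict)
    undefined: dict[str, str] = field(default_factory=dict)

    @property
    def n_undefined(self) -> int:
        return len(self.undefined)


def rho(
    table: PatternCountTable,
    P: SubstitutionPattern | str,
    method: Method = "fast",
    calc: RhoCalculator | None = None,
) -> float | None:
    """Relative abundance of one pattern (convenience wrapper)."""
    calc = calc or RhoCalculator(table)
    return calc.rho(P, method)


def psi(
    table: PatternCountTable,
    P: SubstitutionPattern | str,
    method: Method = "fast",
    calc: RhoCalculator | None = None,
) -> float | None:
    calc = calc or RhoCalculator(table)
    return calc.psi(P, method)


def compute_relative_abundance(
    table: PatternCountTable,
    patterns: Iterable[SubstitutionPattern] | None = None,
    L: int | None = None,
    method: Method = "fast",
    min_count: int = 1,
    calc: RhoCalculator | None = None,
) -> RelativeAbundanceTable:
    """rho for all observed patterns (or a given pattern collection)."""
    calc = calc or RhoCalculator(table)
    if patterns is None:
        patterns = table.observed_patterns(L, min_count) if L is not None else [
            p for p, _ in table.iter_pattern_counts(min_count=min_count)
        ]
    out = RelativeAbundanceTable(method=method)
    for P in patterns:
        value = calc.rho(P, method)
        if value is None:
            out.undefined[P.key] = calc.reasons.get(P.key, UNDEF_PROPAGATED)
        else:
            out.values[P.key] = value
    return out
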