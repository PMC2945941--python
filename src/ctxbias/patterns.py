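"""Substitution-pattern algebra.

A substitution pattern pairs an ancestral word with a same-length descendant
word, e.g. ``ACT->ATT``.  Interior positions may be ``N`` ("any base") in both
words simultaneously; such patterns are called *gapped* and capture context at
a distance (``ANT->ANT``).  The first and last positions are always concrete
bases.
"""

from __future__ import annotations

import itertools
from typing import Iterator, NamedTuple

BASES = "ACGT"
ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class PatternError(ValueError):
    """Raised for malformed patterns or masks."""


class SubstitutionPattern(NamedTuple):
    """An ancestral word paired with a descendant word of the same length."""

    anc: str
    desc: str

    @property
    def L(self) -> int:
        return len(self.anc)

    @property
    def key(self) -> str:
        """Canonical text form, ``ANC->DESC``."""
        return f"{self.anc}->{self.desc}"

    @property
    def is_gapped(self) -> bool:
        return "N" in self.anc

    @property
    def n_substitutions(self) -> int:
        """Number of non-N positions where ancestor and descendant differ."""
        return sum(
            1 for a, d in zip(self.anc, self.desc) if a != "N" and a != d
        )

    @property
    def is_identity(self) -> bool:
        return self.anc == self.desc

    def validate(self) -> "SubstitutionPattern":
        anc, desc = self.anc, self.desc
        if len(anc) != len(desc):
            raise PatternError(
                f"ancestral and descendant words differ in length: {anc!r} vs {desc!r}"
            )
        if not anc:
            raise PatternError("empty pattern")
        for word in (anc, desc):
            bad = set(word) - ALPHABET
            if bad:
                raise PatternError(f"illegal characters {sorted(bad)} in {word!r}")
        if anc[0] == "N" or anc[-1] == "N":
            raise PatternError(f"pattern ends must be concrete bases: {self.key}")
        for i, (a, d) in enumerate(zip(anc, desc)):
            if (a == "N") != (d == "N"):
                raise PatternError(
                    f"N positions must match in both words at offset {i}: {self.key}"
                )
        return self

    @classmethod
    def from_key(cls, key: str) -> "SubstitutionPattern":
        """Parse the canonical ``ANC->DESC`` serialization."""
        try:
            anc, desc = key.split("->")
        except ValueError as exc:
            raise PatternError(f"cannot parse pattern key {key!r}") from exc
        return cls(anc, desc).validate()

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.key


class GapMask(NamedTuple):
    """Boolean keep-vector over pattern positions; ends are always kept."""

    kept: tuple[bool, ...]

    @property
    def L(self) -> int:
        return len(self.kept)

    @property
    def kept_offsets(self) -> tuple[int, ...]:
        return tuple(i for i, k in enumerate(self.kept) if k)

    @property
    def bitstring(self) -> str:
        return "".join("1" if k else "0" for k in self.kept)

    def validate(self) -> "GapMask":
        if not self.kept:
            raise PatternError("empty mask")
        if not (self.kept[0] and self.kept[-1]):
            raise PatternError(f"mask must keep both ends: {self.bitstring}")
        return self

    @classmethod
    def from_bitstring(cls, bits: str) -> "GapMask":
        return cls(tuple(c == "1" for c in bits)).validate()


def enumerate_masks(L: int) -> list[GapMask]:
    """All gap masks of length ``L``: 2**(L-2) for L >= 2, one for L == 1."""
    if L < 1:
        raise PatternError("L must be >= 1")
    if L == 1:
        return [GapMask((True,))]
    masks = []
    for interior in itertools.product((True, False), repeat=L - 2):
        masks.append(GapMask((True,) + interior + (True,)))
    return masks


def apply_mask(anc: str, desc: str, mask: GapMask) -> SubstitutionPattern:
    """Mask out positions with ``kept=False`` (set to N in both words)."""
    if len(anc) != mask.L or len(desc) != mask.L:
        raise PatternError(
            f"mask length {mask.L} does not match words {anc!r}/{desc!r}"
        )
    a = "".join(c if k else "N" for c, k in zip(anc, mask.kept))
    d = "".join(c if k else "N" for c, k in zip(desc, mask.kept))
    return SubstitutionPattern(a, d)


def trim_flanking_n(anc: str, desc: str) -> tuple[str, str]:
    """Drop leading/trailing N columns so the result is a valid pattern.

    Returns ``("", "")`` when every position is N.
    """
    lo = 0
    hi = len(anc)
    while lo < hi and anc[lo] == "N":
        lo += 1
    while hi > lo and anc[hi - 1] == "N":
        hi -= 1
    return anc[lo:hi], desc[lo:hi]


def _span_pattern(P: SubstitutionPattern, positions: tuple[int, ...]) -> SubstitutionPattern:
    """Pattern spanning min..max of ``positions`` with other positions masked."""
    lo, hi = positions[0], positions[-1]
    sel = set(positions)
    anc = "".join(
        P.anc[i] if i in sel else "N" for i in range(lo, hi + 1)
    )
    desc = "".join(
        P.desc[i] if i in sel else "N" for i in range(lo, hi + 1)
    )
    return SubstitutionPattern(anc, desc)


def subpatterns(P: SubstitutionPattern) -> frozenset[SubstitutionPattern]:
    """The set S_P of all smaller constituent subpatterns of ``P``.

    One pattern per proper non-empty subset of P's non-N positions, spanning
    from the subset's minimum to maximum position with unselected interior
    positions set to N.  Empty for L == 1.
    """
    concrete = tuple(i for i, c in enumerate(P.anc) if c != "N")
    out: set[SubstitutionPattern] = set()
    for r in range(1, len(concrete)):
        for combo in itertools.combinations(concrete, r):
            out.add(_span_pattern(P, combo))
    return frozenset(out)


def subpattern_multiplicities(P: SubstitutionPattern) -> dict[SubstitutionPattern, int]:
    """S_P with per-subset multiplicity.

    Repetitive words make distinct position subsets collapse to the same
    subpattern text (every subset of AAA yields A->A or AA->AA); the expected
    proportion must multiply one factor per subset, which is what makes the
    recursive definition and the fast algorithm agree.
    """
    concrete = tuple(i for i, c in enumerate(P.anc) if c != "N")
    out: dict[SubstitutionPattern, int] = {}
    for r in range(1, len(concrete)):
        for combo in itertools.combinations(concrete, r):
            s = _span_pattern(P, combo)
            out[s] = out.get(s, 0) + 1
    return out


def full_length_gapped_subpatterns(P: SubstitutionPattern) -> frozenset[SubstitutionPattern]:
    """The set G_P: mask every non-empty subset of interior non-N positions.

    Ends are retained and the full length is preserved.  Empty for L < 3.
    """
    interior = tuple(
        i for i, c in enumerate(P.anc) if c != "N" and 0 < i < P.L - 1
    )
    out: set[SubstitutionPattern] = set()
    for r in range(1, len(interior) + 1):
        for combo in itertools.combinations(interior, r):
            drop = set(combo)
            anc = "".join(
                "N" if i in drop else c for i, c in enumerate(P.anc)
            )
            desc = "".join(
                "N" if i in drop else c for i, c in enumerate(P.desc)
            )
            out.add(SubstitutionPattern(anc, desc))
    return frozenset(out)


def reverse_complement(P: SubstitutionPattern) -> SubstitutionPattern:
    """Reverse-complement both words (N maps to N); an involution."""
    return SubstitutionPattern(
        P.anc.translate(_COMPLEMENT)[::-1],
        P.desc.translate(_COMPLEMENT)[::-1],
    )


def iter_patterns_for_mask(mask: GapMask) -> Iterator[SubstitutionPattern]:
    """Enumerate every pattern compatible with ``mask`` (testing helper)."""
    offsets = mask.kept_offsets
    k = len(offsets)
    for anc_bases in itertools.product(BASES, repeat=k):
        for desc_bases in itertools.product(BASES, repeat=k):
            anc = ["N"] * mask.L
            desc = ["N"] * mask.L
            for off, a, d in zip(offsets, anc_bases, desc_bases):
                anc[off] = a
                desc[off] = d
            yield SubstitutionPattern("".join(anc), "".join(desc))
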