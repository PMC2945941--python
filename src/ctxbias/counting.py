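"""Count ancestral words and substitution patterns over window streams.

The count table is the substrate for proportions, frequencies and relative
abundance.  Semantics are sparse (counts keyed by canonical pattern text); the
storage is dense integer arrays per (window length, gap mask), indexed by a
base-4 code for ancestral words and a base-16 code for ancestor->descendant
patterns, which makes whole-genome counting a handful of vectorized passes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .align_io import AlignmentBlock
from .patterns import (
    BASES,
    GapMask,
    SubstitutionPattern,
    enumerate_masks,
)

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_C, _G = 1, 2


def n_masks(L: int) -> int:
    """Number of gap masks at window length L: 2**(L-2) for L >= 2, else 1."""
    return 1 if L < 2 else 2 ** (L - 2)


@dataclass(frozen=True)
class WindowOptions:
    """Options applied while streaming windows out of blocks."""

    exclude_ancestral_cpg: bool = False


def encode_sequence(seq: str) -> np.ndarray:
    """Map a sequence to uint8 codes: A,C,G,T -> 0..3; N/gap/other -> 255."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _mask_key(L: int, mask: GapMask) -> tuple[int, tuple[int, ...]]:
    return (L, mask.kept_offsets)


class PatternCountTable:
    """Counts of ancestral words and substitution patterns for lengths 1..Lmax."""

    def __init__(self, Lmax: int):
        if Lmax < 1:
            raise ValueError("Lmax must be >= 1")
        self.Lmax = Lmax
        self.windows_per_length: dict[int, int] = {L: 0 for L in range(1, Lmax + 1)}
        self.masks: dict[int, list[GapMask]] = {
            L: enumerate_masks(L) for L in range(1, Lmax + 1)
        }
        self._anc: dict[tuple[int, tuple[int, ...]], np.ndarray] = {}
        self._pat: dict[tuple[int, tuple[int, ...]], np.ndarray] = {}
        for L in range(1, Lmax + 1):
            for mask in self.masks[L]:
                k = len(mask.kept_offsets)
                key = _mask_key(L, mask)
                self._anc[key] = np.zeros(4**k, dtype=np.int64)
                self._pat[key] = np.zeros(16**k, dtype=np.int64)

    # ------------------------------------------------------------------ build

    def add_block(self, block: AlignmentBlock, options: WindowOptions | None = None) -> None:
        options = options or WindowOptions()
        a = encode_sequence(block.ancestor)
        d = encode_sequence(block.descendant)
        self.add_encoded(a, d, options)

    def add_encoded(
        self, a: np.ndarray, d: np.ndarray, options: WindowOptions | None = None
    ) -> None:
        options = options or WindowOptions()
        n = a.size
        valid = (a < 4) & (d < 4)
        if not valid.any():
            return
        a64 = a.astype(np.int64)
        ad = np.where(valid, a64 * 4 + d, 0)
        a64 = np.where(valid, a64, 0)
        vcum = np.concatenate(([0], np.cumsum(valid, dtype=np.int64)))
        if options.exclude_ancestral_cpg and n >= 2:
            cpg = valid[:-1] & valid[1:] & (a[:-1] == _C) & (a[1:] == _G)
            # cpg_ext[s] covers the CpG starting one column before window start
            cpg_ext = np.concatenate(([False], cpg, [False]))
            ccum = np.concatenate(([0], np.cumsum(cpg_ext, dtype=np.int64)))
        else:
            ccum = None
        for L in range(1, self.Lmax + 1):
            if n < L:
                continue
            ok = (vcum[L:] - vcum[:-L]) == L
            if ccum is not None:
                span = min(L + 1, ccum.size - 1)
                # windows tainted by a CpG at offsets s-1 .. s+L-1
                ncpg = ccum[span:] - ccum[:-span]
                ok &= ncpg[: ok.size] == 0
            starts = np.nonzero(ok)[0]
            if starts.size == 0:
                continue
            self.windows_per_length[L] += int(starts.size)
            for mask in self.masks[L]:
                offsets = mask.kept_offsets
                k = len(offsets)
                anc_code = np.zeros(starts.size, dtype=np.int64)
                pat_code = np.zeros(starts.size, dtype=np.int64)
                for j, off in enumerate(offsets):
                    w4 = 4 ** (k - 1 - j)
                    w16 = 16 ** (k - 1 - j)
                    anc_code += a64[starts + off] * w4
                    pat_code += ad[starts + off] * w16
                key = _mask_key(L, mask)
                self._anc[key] += np.bincount(anc_code, minlength=4**k)
                self._pat[key] += np.bincount(pat_code, minlength=16**k)

    # ------------------------------------------------------------------ algebra

    def __add__(self, other: "PatternCountTable") -> "PatternCountTable":
        if self.Lmax != other.Lmax:
            raise ValueError("cannot add tables with different Lmax")
        out = PatternCountTable(self.Lmax)
        for L in out.windows_per_length:
            out.windows_per_length[L] = (
                self.windows_per_length[L] + other.windows_per_length[L]
            )
        for key in out._anc:
            out._anc[key] = self._anc[key] + other._anc[key]
            out._pat[key] = self._pat[key] + other._pat[key]
        return out

    def __iadd__(self, other: "PatternCountTable") -> "PatternCountTable":
        if self.Lmax != other.Lmax:
            raise ValueError("cannot add tables with different Lmax")
        for L in self.windows_per_length:
            self.windows_per_length[L] += other.windows_per_length[L]
        for key in self._anc:
            self._anc[key] += other._anc[key]
            self._pat[key] += other._pat[key]
        return self

    # ------------------------------------------------------------------ lookup

    @staticmethod
    def _word_code(word: str) -> tuple[int, tuple[int, ...], int]:
        """(L, kept offsets, base-4 code) for a possibly gapped ancestral word."""
        offsets = []
        code = 0
        for i, c in enumerate(word):
            if c == "N":
                continue
            offsets.append(i)
            code = code * 4 + BASES.index(c)
        return len(word), tuple(offsets), code

    @staticmethod
    def _pattern_code(anc: str, desc: str) -> tuple[int, tuple[int, ...], int]:
        offsets = []
        code = 0
        for i, (ca, cd) in enumerate(zip(anc, desc)):
            if ca == "N":
                continue
            offsets.append(i)
            code = code * 16 + BASES.index(ca) * 4 + BASES.index(cd)
        return len(anc), tuple(offsets), code

    def ancestral_count(self, word: str) -> int:
        L, offsets, code = self._word_code(word)
        try:
            return int(self._anc[(L, offsets)][code])
        except KeyError:
            raise KeyError(f"no mask {offsets} at length {L} (Lmax={self.Lmax})")

    def pattern_count(self, P: SubstitutionPattern | str) -> int:
        if isinstance(P, str):
            P = SubstitutionPattern.from_key(P)
        L, offsets, code = self._pattern_code(P.anc, P.desc)
        try:
            return int(self._pat[(L, offsets)][code])
        except KeyError:
            raise KeyError(f"no mask {offsets} at length {L} (Lmax={self.Lmax})")

    def proportion(self, P: SubstitutionPattern | str) -> float | None:
        """pr(P): fraction of the ancestral word converting to the descendant.

        ``None`` (undefined) when the ancestral word was never observed.
        """
        if isinstance(P, str):
            P = SubstitutionPattern.from_key(P)
        denom = self.ancestral_count(P.anc)
        if denom == 0:
            return None
        return self.pattern_count(P) / denom

    def frequency(self, P: SubstitutionPattern | str) -> float | None:
        """f(P): count of P over the total count of all length-L patterns.

        The denominator is windows_per_length[L] * n_masks(L); ``None`` when no
        windows of that length exist.
        """
        if isinstance(P, str):
            P = SubstitutionPattern.from_key(P)
        L = P.L
        denom = self.windows_per_length[L] * n_masks(L)
        if denom == 0:
            return None
        return self.pattern_count(P) / denom

    # ------------------------------------------------------------------ iterate

    def _decode(self, L: int, offsets: tuple[int, ...], code: int) -> SubstitutionPattern:
        anc = ["N"] * L
        desc = ["N"] * L
        for off in reversed(offsets):
            pair = code % 16
            code //= 16
            anc[off] = BASES[pair // 4]
            desc[off] = BASES[pair % 4]
        return SubstitutionPattern("".join(anc), "".join(desc))

    def iter_pattern_counts(
        self, L: int | None = None, min_count: int = 1
    ) -> Iterator[tuple[SubstitutionPattern, int]]:
        """Yield (pattern, count) for observed patterns, optionally one length."""
        lengths = range(1, self.Lmax + 1) if L is None else [L]
        for length in lengths:
            for mask in self.masks[length]:
                key = _mask_key(length, mask)
                vec = self._pat[key]
                codes = np.nonzero(vec >= min_count)[0]
                for code in codes:
                    yield self._decode(length, mask.kept_offsets, int(code)), int(vec[code])

    def observed_patterns(self, L: int, min_count: int = 1) -> list[SubstitutionPattern]:
        return [p for p, _ in self.iter_pattern_counts(L, min_count)]

    # ------------------------------------------------------------------ checks

    def validate(self) -> None:
        """Assert the table's count-consistency invariants (testing aid)."""
        for L in range(1, self.Lmax + 1):
            for mask in self.masks[L]:
                key = _mask_key(L, mask)
                pat = self._pat[key]
                anc = self._anc[key]
                assert int(pat.sum()) == self.windows_per_length[L], (L, mask)
                assert int(anc.sum()) == self.windows_per_length[L], (L, mask)
                k = len(mask.kept_offsets)
                # pattern counts marginalize to ancestral counts
                tens = pat.reshape((4, 4) * k)
                marg = tens.sum(axis=tuple(range(1, 2 * k, 2))).reshape(-1)
                assert np.array_equal(marg, anc), (L, mask)

    # ------------------------------------------------------------------ io

    def to_tsv(self, path: str | Path) -> None:
        """Serialize sparsely: length, mask bitstring, pattern, counts."""
        with open(path, "w") as fh:
            fh.write(f"#lmax\t{self.Lmax}\n")
            for L in range(1, self.Lmax + 1):
                fh.write(f"#windows\t{L}\t{self.windows_per_length[L]}\n")
            fh.write("length\tmask\tpattern\tanc_count\tpattern_count\n")
            for L in range(1, self.Lmax + 1):
                for mask in self.masks[L]:
                    key = _mask_key(L, mask)
                    vec = self._pat[key]
                    for code in np.nonzero(vec)[0]:
                        P = self._decode(L, mask.kept_offsets, int(code))
                        fh.write(
                            f"{L}\t{mask.bitstring}\t{P.key}\t"
                            f"{self.ancestral_count(P.anc)}\t{int(vec[code])}\n"
                        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PatternCountTable":
        lmax = None
        windows: dict[int, int] = {}
        rows: list[tuple[str, int]] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#lmax"):
                    lmax = int(line.split("\t")[1])
                    continue
                if line.startswith("#windows"):
                    _, L, w = line.split("\t")
                    windows[int(L)] = int(w)
                    continue
                if line.startswith("#") or line.startswith("length\t") or not line:
                    continue
                parts = line.split("\t")
                rows.append((parts[2], int(parts[4])))
        if lmax is None:
            raise ValueError(f"{path}: missing #lmax header")
        table = cls(lmax)
        for L, w in windows.items():
            table.windows_per_length[L] = w
        for key, count in rows:
            P = SubstitutionPattern.from_key(key)
            L, offsets, pcode = cls._pattern_code(P.anc, P.desc)
            _, _, acode = cls._word_code(P.anc)
            table._pat[(L, offsets)][pcode] += count
            table._anc[(L, offsets)][acode] += count
        return table


def count_patterns(
    blocks: Iterable[AlignmentBlock],
    Lmax: int,
    options: WindowOptions | None = None,
) -> PatternCountTable:
    """Count patterns and ancestral words over all blocks in one pass."""
    table = PatternCountTable(Lmax)
    for block in blocks:
        table.add_block(block, options)
    return table


def count_patterns_per_block(
    blocks: Sequence[AlignmentBlock],
    Lmax: int,
    options: WindowOptions | None = None,
) -> list[PatternCountTable]:
    """One table per block; summing them reproduces :func:`count_patterns`."""
    out = []
    for block in blocks:
        table = PatternCountTable(Lmax)
        table.add_block(block, options)
        out.append(table)
    return out
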