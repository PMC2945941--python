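from __future__ import annotations

import pytest

from ctxbias.align_io import AlignmentBlock, iter_windows
from ctxbias.counting import PatternCountTable, count_patterns, n_masks
from ctxbias.patterns import apply_mask, enumerate_masks


@pytest.fixture
def hand_block() -> AlignmentBlock:
    """The 6 bp worked fixture: CACGCA -> CATGCA."""
    return AlignmentBlock("fix", "CACGCA", "CATGCA")


@pytest.fixture
def hand_table(hand_block) -> PatternCountTable:
    return count_patterns([hand_block], 3)


def naive_count(blocks, Lmax, exclude_ancestral_cpg=False):
    """Independent window-stream counting oracle (pure python dicts).

    Returns (pattern_counts, ancestral_counts, windows_per_length) keyed by
    canonical text.
    """
    pattern_counts: dict[str, int] = {}
    ancestral_counts: dict[str, int] = {}
    windows = {L: 0 for L in range(1, Lmax + 1)}
    for L in range(1, Lmax + 1):
        masks = enumerate_masks(L)
        for block in blocks:
            for anc, desc in iter_windows(block, L, exclude_ancestral_cpg):
                windows[L] += 1
                for mask in masks:
                    P = apply_mask(anc, desc, mask)
                    pattern_counts[P.key] = pattern_counts.get(P.key, 0) + 1
                    ancestral_counts[P.anc] = ancestral_counts.get(P.anc, 0) + 1
    return pattern_counts, ancestral_counts, windows


def naive_rho(pattern_counts, ancestral_counts, key):
    """Independent recursive relative abundance over naive count dicts.

    Expected proportion multiplies one factor per proper non-empty subset of
    concrete positions (re-spanned, interior masked).
    """
    import itertools

    anc, desc = key.split("->")

    def pr(a, d):
        denom = ancestral_counts.get(a, 0)
        if denom == 0:
            return None
        return pattern_counts.get(f"{a}->{d}", 0) / denom

    concrete = [i for i, c in enumerate(anc) if c != "N"]
    if len(concrete) == 1:
        return pr(anc, desc)
    psi = 1.0
    for r in range(1, len(concrete)):
        for combo in itertools.combinations(concrete, r):
            lo, hi = combo[0], combo[-1]
            sub_anc = "".join(
                anc[i] if i in combo else "N" for i in range(lo, hi + 1)
            )
            sub_desc = "".join(
                desc[i] if i in combo else "N" for i in range(lo, hi + 1)
            )
            sub = naive_rho(pattern_counts, ancestral_counts, f"{sub_anc}->{sub_desc}")
            if sub is None:
                return None
            psi *= sub
    top = pr(anc, desc)
    if top is None or psi == 0.0:
        return None
    return top / psi
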