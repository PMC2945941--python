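"""Generators: ancestors, no-bias controls, context-biased descendants, errors.

The no-bias generator mutates an ancestor site-by-site according to a 4x4
single-base divergence matrix, destroying all context effects while preserving
base composition and single-nucleotide divergence.  Context rules multiply
chosen off-diagonal entries when an ancestral context template matches,
providing known ground truth for validating the relative-abundance machinery.
Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .align_io import AlignmentBlock
from .counting import PatternCountTable, encode_sequence
from .patterns import BASES, SubstitutionPattern

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SingleBaseModel:
    """4x4 ancestral->descendant probability matrix (rows: A,C,G,T)."""

    matrix: tuple[tuple[float, float, float, float], ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise SimulationError("model must be a 4x4 matrix")
        if (m < 0).any():
            raise SimulationError("model entries must be non-negative")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-12):
            raise SimulationError("model rows must each sum to 1 within 1e-12")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.matrix, dtype=float)

    def row(self, base: str) -> np.ndarray:
        return self.array[BASES.index(base)]

    @classmethod
    def from_array(cls, m) -> "SingleBaseModel":
        return cls(tuple(tuple(float(x) for x in row) for row in np.asarray(m)))

    @classmethod
    def identity(cls) -> "SingleBaseModel":
        return cls.from_array(np.eye(4))


def example_divergence_model() -> SingleBaseModel:
    """A strand-symmetric divergence matrix at roughly 1% divergence.

    The C row converts to A, G, T at 0.13%, 0.13% and 0.60% (staying C the
    rest of the time, ~99.1%); the other rows mirror it with transitions
    elevated.  Diagonals are exact complements so rows sum to 1.
    """
    m = np.array(
        [
            # A       C       G       T
            [0.0, 0.0013, 0.0060, 0.0013],  # A
            [0.0013, 0.0, 0.0013, 0.0060],  # C
            [0.0060, 0.0013, 0.0, 0.0013],  # G
            [0.0013, 0.0060, 0.0013, 0.0],  # T
        ]
    )
    np.fill_diagonal(m, 1.0 - m.sum(axis=1))
    return SingleBaseModel.from_array(m)


@dataclass(frozen=True)
class ContextRule:
    """Multiply one substitution probability when an ancestral context matches.

    ``template`` is a word over {A,C,G,T,N} and ``focal`` the 0-based offset of
    the mutating site within it; the template base at ``focal`` must equal the
    rule's ancestral base.  Sites whose context extends past a sequence end are
    left to the base model.
    """

    anc_base: str
    desc_base: str
    template: str
    focal: int
    multiplier: float

    def __post_init__(self) -> None:
        if self.anc_base not in BASES or self.desc_base not in BASES:
            raise SimulationError("rule bases must be A/C/G/T")
        if self.anc_base == self.desc_base:
            raise SimulationError("rule must target a substitution, not identity")
        if self.multiplier <= 0:
            raise SimulationError("multiplier must be positive")
        if not (0 <= self.focal < len(self.template)):
            raise SimulationError("focal offset outside template")
        if self.template[self.focal] != self.anc_base:
            raise SimulationError(
                "template base at the focal offset must equal the ancestral base"
            )
        bad = set(self.template) - set("ACGTN")
        if bad:
            raise SimulationError(f"illegal template characters {sorted(bad)}")


def generate_ancestor(
    length: int,
    composition: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
) -> str:
    """i.i.d. ancestral sequence with the given A,C,G,T composition."""
    if length < 1:
        raise SimulationError("length must be >= 1")
    comp = np.asarray(composition, dtype=float)
    if comp.shape != (4,) or (comp < 0).any() or abs(comp.sum() - 1.0) > 1e-9:
        raise SimulationError("composition must be 4 probabilities summing to 1")
    rng = np.random.default_rng(seed)
    codes = rng.choice(4, size=length, p=comp)
    return bytes(_DECODE[codes]).decode("ascii")


def _rule_matches(codes: np.ndarray, rule: ContextRule) -> np.ndarray:
    """Boolean per-site match of the rule's ancestral context template."""
    n = codes.size
    match = np.ones(n, dtype=bool)
    for t, ch in enumerate(rule.template):
        if ch == "N":
            continue
        off = t - rule.focal
        want = BASES.index(ch)
        shifted = np.zeros(n, dtype=bool)
        lo = max(0, -off)
        hi = min(n, n - off)
        if lo < hi:
            shifted[lo:hi] = codes[lo + off : hi + off] == want
        match &= shifted
    return match


def mutate_with_context(
    ancestor: str,
    model: SingleBaseModel,
    rules: Sequence[ContextRule] = (),
    seed: int = 0,
) -> str:
    """Draw a descendant site-by-site; matching rules scale off-diagonal rates.

    Context is evaluated on the ancestor only (no feedback).  After applying
    all matching multipliers the row is renormalized by adjusting the identity
    entry; multipliers that drive it negative are an error.
    """
    codes = encode_sequence(ancestor)
    if (codes > 3).any():
        raise SimulationError("ancestor must be over A/C/G/T")
    n = codes.size
    rng = np.random.default_rng(seed)
    out = np.empty(n, dtype=np.uint8)
    matches = [_rule_matches(codes, rule) for rule in rules]
    signature = np.zeros(n, dtype=np.int64)
    for r, m in enumerate(matches):
        signature |= m.astype(np.int64) << r
    for b in range(4):
        sel_base = codes == b
        if not sel_base.any():
            continue
        sigs = np.unique(signature[sel_base])
        for sig in sigs:
            sel = sel_base & (signature == sig)
            row = model.array[b].copy()
            for r, rule in enumerate(rules):
                if sig >> r & 1:
                    row[BASES.index(rule.desc_base)] *= rule.multiplier
            off_diag = row.sum() - row[b]
            diag = 1.0 - off_diag
            if diag < 0:
                raise SimulationError(
                    f"multipliers drive the identity probability of "
                    f"{BASES[b]} below 0 (off-diagonal mass {off_diag:.4f})"
                )
            row[b] = diag
            out[sel] = rng.choice(4, size=int(sel.sum()), p=row)
    return bytes(_DECODE[out]).decode("ascii")


def mutate_no_bias(ancestor: str, model: SingleBaseModel, seed: int = 0) -> str:
    """Context-free descendant: each site drawn from its ancestral base's row."""
    return mutate_with_context(ancestor, model, (), seed)


def estimate_model(table: PatternCountTable) -> SingleBaseModel:
    """Single-base divergence matrix from a count table's length-1 proportions."""
    m = np.zeros((4, 4))
    for i, b in enumerate(BASES):
        denom = table.ancestral_count(b)
        if denom == 0:
            raise SimulationError(f"ancestral base {b} unobserved; cannot estimate row")
        for j, d in enumerate(BASES):
            m[i, j] = table.pattern_count(SubstitutionPattern(b, d)) / denom
    return SingleBaseModel.from_array(m)


def blocks_from_pair(
    ancestor: str,
    descendant: str,
    block_length: int = 10_000,
    id_prefix: str = "sim",
    seq_name: str = "simseq",
) -> list[AlignmentBlock]:
    """Wrap one aligned pair into fixed-length blocks (bootstrap units)."""
    if len(ancestor) != len(descendant):
        raise SimulationError("ancestor and descendant lengths differ")
    blocks = []
    for i, start in enumerate(range(0, len(ancestor), block_length)):
        end = min(start + block_length, len(ancestor))
        blocks.append(
            AlignmentBlock(
                f"{id_prefix}{i:05d}",
                ancestor[start:end],
                descendant[start:end],
                (seq_name, start, end, "+"),
            )
        )
    return blocks


def simulate_blocks(
    length: int,
    seed: int,
    composition: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    model: SingleBaseModel | None = None,
    rules: Sequence[ContextRule] = (),
    block_length: int = 10_000,
) -> list[AlignmentBlock]:
    """Ancestor + (possibly biased) descendant, wrapped into blocks."""
    model = model or example_divergence_model()
    rng = np.random.default_rng(seed)
    anc_seed, mut_seed = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
    ancestor = generate_ancestor(length, composition, anc_seed)
    descendant = mutate_with_context(ancestor, model, rules, mut_seed)
    return blocks_from_pair(ancestor, descendant, block_length)


def inject_errors(
    blocks: Sequence[AlignmentBlock],
    rate_ancestor: float,
    rate_descendant: float,
    seed: int = 0,
) -> list[AlignmentBlock]:
    """Replace each A/C/G/T base, independently with the per-sequence rate,
    by one of the three other bases uniformly (sequencing-error simulation).
    """
    for rate in (rate_ancestor, rate_descendant):
        if not 0.0 <= rate <= 1.0:
            raise SimulationError("error rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for block in blocks:
        seqs = []
        for seq, rate in (
            (block.ancestor, rate_ancestor),
            (block.descendant, rate_descendant),
        ):
            codes = encode_sequence(seq)
            eligible = codes < 4
            flip = eligible & (rng.random(codes.size) < rate)
            if flip.any():
                offsets = rng.integers(1, 4, size=int(flip.sum()))
                arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
                arr[flip] = _DECODE[(codes[flip].astype(np.int64) + offsets) % 4]
                seq = bytes(arr).decode("ascii")
            seqs.append(seq)
        out.append(
            AlignmentBlock(block.block_id, seqs[0], seqs[1], block.source_coords)
        )
    return out
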