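"""Read, validate, filter, and window ancestor-descendant alignments.

Supported inputs are MAF files (species picked by source-name prefix) and
"paired FASTA" files in which records strictly alternate ancestor, descendant.
Blocks are uppercased on read; columns gapped in both sequences are dropped
with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import AlignIO, SeqIO

logger = logging.getLogger(__name__)

BLOCK_ALPHABET = frozenset("ACGTN-")
_WINDOW_BASES = frozenset("ACGT")


class AlignmentError(ValueError):
    """Raised for malformed alignment input."""


@dataclass(frozen=True)
class AlignmentBlock:
    """One contiguous pair of aligned ancestor/descendant sequences."""

    block_id: str
    ancestor: str
    descendant: str
    #: optional (sequence name, start, end, strand) on the ancestor
    source_coords: tuple[str, int, int, str] | None = None

    def __post_init__(self) -> None:
        anc, desc = self.ancestor, self.descendant
        if len(anc) != len(desc):
            raise AlignmentError(
                f"block {self.block_id}: ancestor length {len(anc)} != "
                f"descendant length {len(desc)}"
            )
        for name, seq in (("ancestor", anc), ("descendant", desc)):
            for off, c in enumerate(seq):
                if c not in BLOCK_ALPHABET:
                    raise AlignmentError(
                        f"block {self.block_id}: illegal character {c!r} in "
                        f"{name} at offset {off}"
                    )
        for off, (a, d) in enumerate(zip(anc, desc)):
            if a == "-" and d == "-":
                raise AlignmentError(
                    f"block {self.block_id}: column {off} is gap in both sequences"
                )

    @property
    def n_columns(self) -> int:
        return len(self.ancestor)


@dataclass
class ReadStats:
    """Accounting from a read pass."""

    n_blocks: int = 0
    n_skipped_missing_label: int = 0
    n_dual_gap_columns_dropped: int = 0


@dataclass
class FilterStats:
    n_removed_short_run: int = 0
    n_removed_gappy: int = 0


def _normalize_pair(block_id: str, anc: str, desc: str) -> tuple[str, str, int]:
    """Uppercase, validate the alphabet, and drop columns gapped in both."""
    anc = anc.upper()
    desc = desc.upper()
    if len(anc) != len(desc):
        raise AlignmentError(
            f"block {block_id}: ancestor length {len(anc)} != descendant length {len(desc)}"
        )
    for name, seq in (("ancestor", anc), ("descendant", desc)):
        for off, c in enumerate(seq):
            if c not in BLOCK_ALPHABET:
                raise AlignmentError(
                    f"block {block_id}: illegal character {c!r} in {name} at offset {off}"
                )
    dropped = 0
    if "-" in anc and "-" in desc:
        keep_a = []
        keep_d = []
        for a, d in zip(anc, desc):
            if a == "-" and d == "-":
                dropped += 1
                continue
            keep_a.append(a)
            keep_d.append(d)
        anc = "".join(keep_a)
        desc = "".join(keep_d)
    return anc, desc, dropped


def read_paired_fasta_with_stats(path: str | Path) -> tuple[list[AlignmentBlock], ReadStats]:
    """Read a FASTA in which records strictly alternate ancestor, descendant."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) % 2 != 0:
        raise AlignmentError(
            f"{path}: paired FASTA must contain an even number of records, "
            f"found {len(records)}"
        )
    stats = ReadStats()
    blocks: list[AlignmentBlock] = []
    for i in range(0, len(records), 2):
        anc_rec, desc_rec = records[i], records[i + 1]
        block_id = _common_prefix(anc_rec.id, desc_rec.id)
        if not block_id:
            raise AlignmentError(
                f"{path}: paired records {anc_rec.id!r}/{desc_rec.id!r} share "
                "no common id prefix"
            )
        block_id = block_id.rstrip("|_.-") or block_id
        anc, desc, dropped = _normalize_pair(block_id, str(anc_rec.seq), str(desc_rec.seq))
        stats.n_dual_gap_columns_dropped += dropped
        blocks.append(AlignmentBlock(block_id, anc, desc))
        stats.n_blocks += 1
    if stats.n_dual_gap_columns_dropped:
        logger.info(
            "%s: dropped %d columns gapped in both sequences",
            path, stats.n_dual_gap_columns_dropped,
        )
    return blocks, stats


def _common_prefix(a: str, b: str) -> str:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return a[:n]


def _maf_component(alignment, label: str):
    for rec in alignment:
        src = rec.id
        if src == label or src.split(".", 1)[0] == label:
            return rec
    return None


def read_maf_with_stats(
    path: str | Path, ancestor_label: str, descendant_label: str
) -> tuple[list[AlignmentBlock], ReadStats]:
    """Read pairwise blocks out of a MAF file.

    A species is selected when its MAF source name equals the label or has the
    label as its dot-separated prefix (``hg18.chr1`` matches ``hg18``).  Blocks
    lacking either label are skipped and counted.
    """
    stats = ReadStats()
    blocks: list[AlignmentBlock] = []
    for i, alignment in enumerate(AlignIO.parse(str(path), "maf")):
        anc_rec = _maf_component(alignment, ancestor_label)
        desc_rec = _maf_component(alignment, descendant_label)
        if anc_rec is None or desc_rec is None:
            stats.n_skipped_missing_label += 1
            continue
        block_id = f"{Path(path).stem}.{i}"
        anc, desc, dropped = _normalize_pair(block_id, str(anc_rec.seq), str(desc_rec.seq))
        stats.n_dual_gap_columns_dropped += dropped
        ann = anc_rec.annotations
        coords = None
        if "start" in ann and "size" in ann:
            coords = (
                anc_rec.id,
                int(ann["start"]),
                int(ann["start"]) + int(ann["size"]),
                "+" if ann.get("strand", 1) == 1 else "-",
            )
        blocks.append(AlignmentBlock(block_id, anc, desc, coords))
        stats.n_blocks += 1
    if stats.n_skipped_missing_label:
        logger.info(
            "%s: skipped %d blocks missing %r or %r",
            path, stats.n_skipped_missing_label, ancestor_label, descendant_label,
        )
    return blocks, stats


def read_blocks(
    path: str | Path,
    format: str = "paired_fasta",
    ancestor_label: str | None = None,
    descendant_label: str | None = None,
) -> list[AlignmentBlock]:
    """Read alignment blocks from ``path`` (``maf`` or ``paired_fasta``)."""
    blocks, _ = read_blocks_with_stats(path, format, ancestor_label, descendant_label)
    return blocks


def read_blocks_with_stats(
    path: str | Path,
    format: str = "paired_fasta",
    ancestor_label: str | None = None,
    descendant_label: str | None = None,
) -> tuple[list[AlignmentBlock], ReadStats]:
    if format == "paired_fasta":
        return read_paired_fasta_with_stats(path)
    if format == "maf":
        if ancestor_label is None or descendant_label is None:
            raise ValueError("maf input requires ancestor_label and descendant_label")
        return read_maf_with_stats(path, ancestor_label, descendant_label)
    raise ValueError(f"unknown alignment format {format!r}")


def _longest_nongap_run(block: AlignmentBlock) -> int:
    best = run = 0
    for a, d in zip(block.ancestor, block.descendant):
        if a != "-" and d != "-":
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best


def filter_blocks(
    blocks: Iterable[AlignmentBlock],
    min_contiguous_nongap: int = 10,
    require_gaps_le_aligned: bool = True,
) -> list[AlignmentBlock]:
    survivors, _ = filter_blocks_with_stats(
        blocks, min_contiguous_nongap, require_gaps_le_aligned
    )
    return survivors


def filter_blocks_with_stats(
    blocks: Iterable[AlignmentBlock],
    min_contiguous_nongap: int = 10,
    require_gaps_le_aligned: bool = True,
) -> tuple[list[AlignmentBlock], FilterStats]:
    """Drop blocks with too-short non-gap runs or more gaps than aligned bases."""
    if min_contiguous_nongap < 1:
        raise ValueError("min_contiguous_nongap must be >= 1")
    stats = FilterStats()
    survivors: list[AlignmentBlock] = []
    for block in blocks:
        if _longest_nongap_run(block) < min_contiguous_nongap:
            stats.n_removed_short_run += 1
            continue
        if require_gaps_le_aligned:
            aligned = sum(
                1 for a, d in zip(block.ancestor, block.descendant)
                if a != "-" and d != "-"
            )
            gapped = block.n_columns - aligned
            if gapped > aligned:
                stats.n_removed_gappy += 1
                continue
        survivors.append(block)
    if stats.n_removed_short_run or stats.n_removed_gappy:
        logger.info(
            "filter_blocks removed %d short-run and %d gap-heavy blocks",
            stats.n_removed_short_run, stats.n_removed_gappy,
        )
    return survivors, stats


def iter_windows(
    block: AlignmentBlock, L: int, exclude_ancestral_cpg: bool = False
) -> Iterator[tuple[str, str]]:
    """Yield every L-column window that is gap-free and N-free in both sequences.

    Windows never span a gap or an N (either sequence breaks the run).  With
    ``exclude_ancestral_cpg``, a window is omitted when the ancestral run
    contains a CpG dinucleotide overlapping or immediately flanking the window:
    a CG inside the window, a window-initial G preceded by C in the same run,
    or a window-final C followed by G in the same run.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    anc, desc = block.ancestor, block.descendant
    n = block.n_columns
    i = 0
    while i < n:
        if anc[i] not in _WINDOW_BASES or desc[i] not in _WINDOW_BASES:
            i += 1
            continue
        j = i
        while j < n and anc[j] in _WINDOW_BASES and desc[j] in _WINDOW_BASES:
            j += 1
        run_anc = anc[i:j]
        run_desc = desc[i:j]
        r = j - i
        if exclude_ancestral_cpg:
            cpg_at = [
                run_anc[t] == "C" and run_anc[t + 1] == "G" for t in range(r - 1)
            ]
        for s in range(r - L + 1):
            if exclude_ancestral_cpg:
                lo = max(0, s - 1)
                hi = min(r - 2, s + L - 1)  # CpG start offsets to test, inclusive
                if any(cpg_at[t] for t in range(lo, hi + 1)):
                    continue
            yield run_anc[s : s + L], run_desc[s : s + L]
        i = j


def _bed_intervals(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            intervals.setdefault(chrom, []).append((start, end))
    for chrom in intervals:
        intervals[chrom].sort()
    return intervals


def apply_bed_mask(
    blocks: Iterable[AlignmentBlock], bed_path: str | Path
) -> list[AlignmentBlock]:
    """Restrict blocks to BED regions (0-based half-open) on ancestor coords.

    Blocks without ``source_coords`` are dropped.  Retained column stretches
    become sub-blocks.  Only '+' strand coordinates are supported.
    """
    intervals = _bed_intervals(bed_path)
    out: list[AlignmentBlock] = []
    for block in blocks:
        if block.source_coords is None:
            continue
        name, start, _end, strand = block.source_coords
        if strand != "+":
            raise NotImplementedError("BED masking of '-' strand blocks")
        ivs = intervals.get(name, [])
        if not ivs:
            continue
        keep = []
        pos = start
        iv_idx = 0
        for col, a in enumerate(block.ancestor):
            if a == "-":
                keep.append(bool(keep) and keep[-1])
                continue
            while iv_idx < len(ivs) and ivs[iv_idx][1] <= pos:
                iv_idx += 1
            inside = iv_idx < len(ivs) and ivs[iv_idx][0] <= pos < ivs[iv_idx][1]
            keep.append(inside)
            pos += 1
        # contiguous kept stretches -> sub-blocks
        col = 0
        part = 0
        while col < block.n_columns:
            if not keep[col]:
                col += 1
                continue
            col2 = col
            while col2 < block.n_columns and keep[col2]:
                col2 += 1
            anc = block.ancestor[col:col2]
            desc = block.descendant[col:col2]
            if not (set(anc) <= {"-"} or set(desc) <= {"-"}):
                out.append(
                    AlignmentBlock(f"{block.block_id}.bed{part}", anc, desc)
                )
                part += 1
            col = col2
    return out


def write_paired_fasta(blocks: Sequence[AlignmentBlock], path: str | Path) -> None:
    with open(path, "w") as fh:
        for block in blocks:
            fh.write(f">{block.block_id}|ancestor\n{block.ancestor}\n")
            fh.write(f">{block.block_id}|descendant\n{block.descendant}\n")


def write_maf(
    blocks: Sequence[AlignmentBlock],
    path: str | Path,
    ancestor_label: str = "ancestor",
    descendant_label: str = "descendant",
) -> None:
    """Write blocks as a minimal MAF file (synthetic coordinates if absent)."""
    with open(path, "w") as fh:
        fh.write("##maf version=1 scoring=none\n\n")
        offset = 0
        for block in blocks:
            anc_len = sum(1 for c in block.ancestor if c != "-")
            desc_len = sum(1 for c in block.descendant if c != "-")
            if block.source_coords is not None:
                name, start, _end, strand = block.source_coords
            else:
                name, start, strand = f"{ancestor_label}.seq", offset, "+"
            fh.write("a score=0\n")
            fh.write(
                f"s {name} {start} {anc_len} {strand} {start + anc_len} {block.ancestor}\n"
            )
            fh.write(
                f"s {descendant_label}.seq {offset} {desc_len} + {offset + desc_len} "
                f"{block.descendant}\n\n"
            )
            offset += anc_len
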