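"""Seed-and-extend placement of short reads on a circular reference.

A transparent replacement for the usual BWA-aln / Samtools / Picard stage,
restricted to what ~33 bp degraded fragments need: exact k-mer seeding on
both strands, ungapped scoring over the full read, a mismatch-fraction cap,
a uniqueness margin standing in for mapping quality, and duplicate flagging
by (start, length, strand).  The reference index is built over the sequence
extended by its leading bases so that reads spanning the circular origin
seed like any others; all reported coordinates are wrapped back onto the
true reference.

Damage tolerance: with ``damage_tolerant`` the penalty of C(ref)→T(read) and
G(ref)→A(read) mismatches is halved, so deaminated reads are not pushed to
spurious placements.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .io import CircularSequence, reverse_complement

DEFAULT_K = 12
DEFAULT_MISMATCH_PENALTY = 3
DEFAULT_UNIQUENESS_MARGIN = 5
DEFAULT_MAX_MISMATCH_FRAC = 0.05
DEFAULT_MIN_READ_LEN = 20


@dataclass
class AlignedRead:
    """One ungapped placement of a read on the (unrotated) reference frame."""

    read_id: str
    ref_start: int  # 1-based, wrapped
    strand: str
    matched: list[tuple[str, str]]  # (reference base, read base) in ref orientation
    score: int
    unique: bool = True
    duplicate: bool = False

    @property
    def length(self) -> int:
        return len(self.matched)

    @property
    def mismatches(self) -> int:
        return sum(1 for r, q in self.matched if r != q)

    def ref_positions(self, ref_length: int) -> list[int]:
        """1-based reference coordinates covered, wrapped on the circle."""
        s = self.ref_start - 1
        return [(s + i) % ref_length + 1 for i in range(len(self.matched))]


@dataclass
class SeedIndex:
    """Exact k-mer index over a circular reference."""

    ref: CircularSequence
    k: int = DEFAULT_K
    extension: int = 75  # origin overhang; >= max read length
    positions: dict[str, list[int]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.k > len(self.ref):
            raise ValueError(f"k={self.k} exceeds reference length {len(self.ref)}")
        L = len(self.ref)
        ext = self.ref.residues + (self.ref.residues[: self.extension] if self.ref.circular else "")
        index: dict[str, list[int]] = defaultdict(list)
        for i in range(len(ext) - self.k + 1):
            if i >= L:  # k-mers fully inside the overhang duplicate start-of-genome ones
                break
            index[ext[i : i + self.k]].append(i % L + 1)
        self.positions = dict(index)

    def hits(self, kmer: str) -> list[int]:
        """1-based reference positions (wrapped) where ``kmer`` occurs."""
        return self.positions.get(kmer, [])


def build_index(ref: CircularSequence, k: int = DEFAULT_K, extension: int = 75) -> SeedIndex:
    return SeedIndex(ref, k, extension)


def _score(ref_sub: str, read: str, penalty: float, damage_tolerant: bool) -> float:
    score = 0.0
    for r, q in zip(ref_sub, read):
        if r == q:
            score += 1
        elif damage_tolerant and ((r == "C" and q == "T") or (r == "G" and q == "A")):
            score -= penalty / 2
        else:
            score -= penalty
    return score


def map_read(
    read_id: str,
    read: str,
    index: SeedIndex,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
    damage_tolerant: bool = True,
    uniqueness_margin: float = DEFAULT_UNIQUENESS_MARGIN,
    mismatch_penalty: float = DEFAULT_MISMATCH_PENALTY,
    min_read_len: int = DEFAULT_MIN_READ_LEN,
) -> AlignedRead | None:
    """Best ungapped placement of one read, or ``None`` if unmappable.

    Candidate placements are gathered from exact k-mer seeds at the read's
    start, middle and end on both strands, scored over the full read length,
    and capped at ``ceil(max_mismatch_frac * length)`` mismatches.  The
    ``unique`` flag requires the best score to beat the runner-up by at
    least ``uniqueness_margin``.
    """
    n = len(read)
    if n < min_read_len or n < index.k:
        return None
    ref = index.ref
    L = len(ref)
    max_mm = math.ceil(max_mismatch_frac * n)
    k = index.k
    offsets = sorted({0, (n - k) // 2, n - k})
    candidates: list[tuple[float, int, str, str]] = []  # (score, start, strand, oriented read)
    seen: set[tuple[int, str]] = set()
    for strand in "+-":
        oriented = read if strand == "+" else reverse_complement(read)
        for off in offsets:
            for pos in index.hits(oriented[off : off + k]):
                start = (pos - 1 - off) % L + 1
                key = (start, strand)
                if key in seen:
                    continue
                seen.add(key)
                try:
                    ref_sub = ref.fetch(start, n)
                except IndexError:
                    continue  # linear reference, read would overrun
                s = _score(ref_sub, oriented, mismatch_penalty, damage_tolerant)
                candidates.append((s, start, strand, oriented))
    if not candidates:
        return None
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    best_score, start, strand, oriented = candidates[0]
    ref_sub = ref.fetch(start, n)
    mismatches = sum(1 for r, q in zip(ref_sub, oriented) if r != q)
    if mismatches > max_mm:
        return None
    second = candidates[1][0] if len(candidates) > 1 else float("-inf")
    unique = best_score - second >= uniqueness_margin
    return AlignedRead(
        read_id=read_id,
        ref_start=start,
        strand=strand,
        matched=list(zip(ref_sub, oriented)),
        score=int(round(best_score)),
        unique=unique,
    )


def map_reads(
    reads: Iterable[tuple[str, str]],
    index: SeedIndex,
    **kwargs,
) -> tuple[list[AlignedRead], int]:
    """Map many reads; returns (alignments, unmapped count)."""
    out: list[AlignedRead] = []
    unmapped = 0
    for rid, seq in reads:
        aln = map_read(rid, seq, index, **kwargs)
        if aln is None:
            unmapped += 1
        else:
            out.append(aln)
    return out, unmapped


def mark_duplicates(alignments: Sequence[AlignedRead]) -> list[AlignedRead]:
    """Flag all but the best-scoring read in each (start, length, strand) class.

    Ties break deterministically by read id, so the survivor never depends on
    input order; the input list is not modified.
    """
    groups: dict[tuple[int, int, str], list[AlignedRead]] = defaultdict(list)
    for a in alignments:
        groups[(a.ref_start, a.length, a.strand)].append(a)
    out: list[AlignedRead] = []
    for group in groups.values():
        group.sort(key=lambda a: (-a.score, a.read_id))
        out.append(replace(group[0], duplicate=False))
        out.extend(replace(a, duplicate=True) for a in group[1:])
    out.sort(key=lambda a: (a.ref_start, a.read_id))
    return out


def filter_alignments(
    alignments: Sequence[AlignedRead],
    require_unique: bool = True,
    drop_duplicates: bool = True,
) -> tuple[list[AlignedRead], dict[str, int]]:
    """Apply uniqueness/duplicate filters; returns (kept, counts)."""
    kept = []
    dropped_unique = dropped_dup = 0
    for a in alignments:
        if require_unique and not a.unique:
            dropped_unique += 1
        elif drop_duplicates and a.duplicate:
            dropped_dup += 1
        else:
            kept.append(a)
    counts = {
        "input": len(alignments),
        "kept": len(kept),
        "dropped_nonunique": dropped_unique,
        "dropped_duplicate": dropped_dup,
    }
    return kept, counts


def write_sam(path: str | Path, alignments: Sequence[AlignedRead], ref: CircularSequence) -> None:
    """Write minimal ungapped SAM: FLAG carries strand and duplicate status,
    MAPQ is 37 for unique placements and 0 otherwise."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": ref.id, "LN": len(ref)}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for a in alignments:
            seg = pysam.AlignedSegment(fh.header)
            seg.query_name = a.read_id
            seg.query_sequence = "".join(q for _, q in a.matched)
            seg.flag = (16 if a.strand == "-" else 0) | (1024 if a.duplicate else 0)
            seg.reference_id = 0
            seg.reference_start = a.ref_start - 1
            seg.mapping_quality = 37 if a.unique else 0
            seg.cigarstring = f"{a.length}M"
            seg.query_qualities = pysam.qualitystring_to_array("I" * a.length)
            fh.write(seg)


def read_sam(path: str | Path, ref: CircularSequence) -> list[AlignedRead]:
    """Read externally produced ungapped alignments back into AlignedRead records."""
    out: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped or seg.query_sequence is None:
                continue
            if any(op != 0 for op, _ in (seg.cigartuples or [])):
                raise ValueError(f"read {seg.query_name}: only ungapped (all-M) CIGARs accepted")
            start = seg.reference_start + 1
            seq = seg.query_sequence.upper()
            ref_sub = ref.fetch(start, len(seq))
            score = sum(1 if r == q else -DEFAULT_MISMATCH_PENALTY for r, q in zip(ref_sub, seq))
            out.append(
                AlignedRead(
                    read_id=seg.query_name,
                    ref_start=start,
                    strand="-" if seg.is_reverse else "+",
                    matched=list(zip(ref_sub, seq)),
                    score=score,
                    unique=seg.mapping_quality > 0,
                    duplicate=seg.is_duplicate,
                )
            )
    return out
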