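"""Consensus calling on a circular reference from filtered alignments.

The calling rules are those of a conservative degraded-DNA workflow: a site
is called only at read depth >= 3 and only when a strict majority base
exists (ties give N); low-complexity or repeat regions longer than the read
length cannot be bridged by short fragments and are masked to N; the
terminal positions of the linearised reference are recovered by rotating
the reference (default 200 bp) and repeating the mapping, then merging the
two passes; and homopolymer-length indels are emitted as flagged candidates
for manual confirmation, supported by the reads that fully span the run —
never auto-applied.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .io import CircularSequence
from .mapping import AlignedRead, SeedIndex, map_reads, mark_duplicates, filter_alignments

logger = logging.getLogger(__name__)

_BASE_IDX = {b: i for i, b in enumerate("ACGT")}
_IDX_BASE = "ACGT"


@dataclass
class Pileup:
    """Per-site base counts over the reference frame (1-based sites)."""

    ref_length: int
    counts: np.ndarray  # shape (4, L): A, C, G, T

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def site_counts(self, site: int) -> dict[str, int]:
        return {b: int(self.counts[i, site - 1]) for b, i in _BASE_IDX.items()}


@dataclass
class IndelCandidate:
    """A homopolymer-length change supported by spanning reads; needs manual
    confirmation before being applied."""

    site: int  # 1-based start of the reference run
    ref_allele: str
    alt_allele: str
    support: int  # spanning reads agreeing on the alt run length
    spanning: int  # all reads fully spanning the run
    flag: str = "manual-confirmation"


@dataclass
class ConsensusResult:
    sequence: str
    mask_intervals: list[tuple[int, int, str]] = field(default_factory=list)
    indel_candidates: list[IndelCandidate] = field(default_factory=list)

    @property
    def called_fraction(self) -> float:
        n = len(self.sequence)
        return (n - self.sequence.count("N")) / n if n else 0.0


def pileup(alignments: Sequence[AlignedRead], ref: CircularSequence) -> Pileup:
    """Per-site base counts; origin-wrapped alignments contribute to both arcs."""
    L = len(ref)
    counts = np.zeros((4, L), dtype=np.int64)
    for a in alignments:
        s = a.ref_start - 1
        if not ref.circular and s + a.length > L:
            raise IndexError(f"read {a.read_id} overruns linear reference")
        for i, (_, q) in enumerate(a.matched):
            j = _BASE_IDX.get(q)
            if j is not None:
                counts[j, (s + i) % L] += 1
    return Pileup(L, counts)


def call_consensus(p: Pileup, min_depth: int = 3) -> ConsensusResult:
    """Strict-majority call per site: N below ``min_depth`` or on a top-two tie."""
    depth = p.depth
    top = p.counts.max(axis=0)
    argtop = p.counts.argmax(axis=0)
    # tie: more than one base achieves the top count
    ties = (p.counts == top).sum(axis=0) > 1
    called = (depth >= min_depth) & ~ties & (top > 0)
    seq = np.full(p.ref_length, "N", dtype="<U1")
    seq[called] = np.array(list(_IDX_BASE))[argtop[called]]
    return ConsensusResult("".join(seq))


def consensus_from_reads(
    reads: Sequence[tuple[str, str]],
    ref: CircularSequence,
    min_depth: int = 3,
    k: int = 12,
    **map_kwargs,
) -> tuple[ConsensusResult, Pileup, list[AlignedRead]]:
    """Map, deduplicate, filter and consensus-call in one step (single frame)."""
    index = SeedIndex(ref, k)
    alns, _ = map_reads(reads, index, **map_kwargs)
    alns = mark_duplicates(alns)
    kept, _ = filter_alignments(alns)
    p = pileup(kept, ref)
    return call_consensus(p, min_depth), p, kept


def recover_terminal(
    reads: Sequence[tuple[str, str]],
    ref: CircularSequence,
    rotation_bp: int = 200,
    min_depth: int = 3,
    k: int = 12,
    **map_kwargs,
) -> ConsensusResult:
    """Two-pass consensus with rotation-based recovery of terminal positions.

    The second pass maps against the reference rotated by ``rotation_bp``;
    calls within ``rotation_bp`` of the origin junction are taken from the
    rotated pass (where they are interior); conflicting non-N calls between
    passes are set to N with a logged warning.
    """
    if not ref.circular:
        raise ValueError("terminal recovery requires a circular reference")
    plain, _, _ = consensus_from_reads(reads, ref, min_depth, k, **map_kwargs)
    if rotation_bp == 0:
        return plain
    rotated_ref = ref.rotate(rotation_bp)
    rot, _, _ = consensus_from_reads(reads, rotated_ref, min_depth, k, **map_kwargs)
    L = len(ref)
    # unrotate the second pass: rotated position i (0-based) is original (i + rotation_bp) % L
    rot_seq = np.array(list(rot.sequence))
    back = np.empty(L, dtype="<U1")
    idx = (np.arange(L) + rotation_bp) % L
    back[idx] = rot_seq
    merged = np.array(list(plain.sequence))
    junction = np.zeros(L, dtype=bool)
    junction[:rotation_bp] = True  # positions 1..rotation_bp
    junction[L - rotation_bp :] = True  # positions L-rotation_bp+1..L
    conflict = (merged != "N") & (back != "N") & (merged != back)
    n_conflict = int(conflict.sum())
    if n_conflict:
        logger.warning("%d sites conflict between rotation passes; set to N", n_conflict)
    merged[junction] = back[junction]
    merged[conflict] = "N"
    return ConsensusResult("".join(merged))


def _reference_repeats(ref: CircularSequence, min_span: int, max_unit: int = 10) -> list[tuple[int, int, str]]:
    """Perfect tandem repeats (unit 1..max_unit) spanning >= min_span bases."""
    s = ref.residues
    L = len(s)
    out = []
    for unit in range(1, max_unit + 1):
        i = 0
        while i + unit <= L:
            j = i + unit
            while j < L and s[j] == s[j - unit]:
                j += 1
            span = j - i
            if span >= min_span and span >= 2 * unit:
                out.append((i + 1, j, f"tandem_repeat_unit{unit}"))
                i = j
            else:
                i += 1 if span < 2 * unit else span - unit + 1
    return out


def mask_regions(
    result: ConsensusResult,
    ref: CircularSequence,
    read_len_max: int = 75,
    manual_intervals: Sequence[tuple[int, int]] = (),
) -> ConsensusResult:
    """Mask repeat regions longer than the read length, plus manual intervals.

    Manual intervals (1-based inclusive) are merged if overlapping, never
    rejected.  Masked sites become N and are recorded with a reason.
    """
    intervals: list[tuple[int, int, str]] = list(
        _reference_repeats(ref, min_span=read_len_max)
    )
    manual = sorted((int(a), int(b)) for a, b in manual_intervals)
    merged_manual: list[list[int]] = []
    for a, b in manual:
        if merged_manual and a <= merged_manual[-1][1] + 1:
            merged_manual[-1][1] = max(merged_manual[-1][1], b)
        else:
            merged_manual.append([a, b])
    intervals.extend((a, b, "manual") for a, b in merged_manual)
    seq = np.array(list(result.sequence))
    for a, b, _ in intervals:
        seq[a - 1 : b] = "N"
    return ConsensusResult(
        "".join(seq),
        mask_intervals=result.mask_intervals + sorted(intervals),
        indel_candidates=result.indel_candidates,
    )


def masked_site_count(intervals: Sequence[tuple[int, int]]) -> int:
    """Total distinct sites covered by 1-based inclusive intervals."""
    covered: set[int] = set()
    for a, b in intervals:
        covered.update(range(a, b + 1))
    return len(covered)


def _homopolymer_runs(s: str, min_len: int = 3) -> list[tuple[int, int, str]]:
    runs = []
    i = 0
    L = len(s)
    while i < L:
        j = i + 1
        while j < L and s[j] == s[i]:
            j += 1
        if j - i >= min_len and s[i] in "ACGT":
            runs.append((i + 1, j, s[i]))
        i = j
    return runs


def call_homopolymer_indels(
    alignments: Sequence[AlignedRead],
    ref: CircularSequence,
    min_support: int = 2,
    min_run: int = 5,
    max_delta: int = 3,
) -> list[IndelCandidate]:
    """Vote on homopolymer run lengths using reads that fully span each run.

    For every reference homopolymer of length >= ``min_run``, reads whose
    alignment overlaps the run and that carry the full run internally (their
    own maximal block of the run base is bounded by non-run bases on both
    sides within the read) report the run length they actually carry.  The
    internal-block rule makes the vote independent of which flank an
    ungapped aligner anchored when the molecule's run length differs from
    the reference.  Reads whose run is split into several blocks (a
    deaminated C inside the run) carry ambiguous length evidence and are
    excluded, as are blocks differing from the reference run by more than
    ``max_delta`` bases — homopolymer slippage evidence, not arbitrary
    rearrangement.  A candidate is emitted when >= ``min_support`` spanning
    reads agree on the same non-reference length and no spanning read
    supports the reference length.  Candidates are flagged for manual
    confirmation, never applied automatically.
    """
    L = len(ref)
    candidates = []
    for run_start, run_end, base in _homopolymer_runs(ref.residues, min_run):
        run_len = run_end - run_start + 1
        votes: dict[int, int] = {}
        spanning = 0
        for a in alignments:
            s = a.ref_start  # 1-based start in (possibly origin-wrapped) frame
            covered_to = s + a.length - 1
            # shift the run interval into the read's frame if the read wraps
            lo, hi = run_start, run_end
            if covered_to > L and hi < s:
                lo, hi = lo + L, hi + L
            if covered_to < lo or s > hi:
                continue
            read_seq = "".join(q for _, q in a.matched)
            # run-base blocks in the read overlapping the reference run
            blocks = []
            i = 0
            while i < len(read_seq):
                if read_seq[i] != base:
                    i += 1
                    continue
                j = i
                while j < len(read_seq) and read_seq[j] == base:
                    j += 1
                if s + j - 1 >= lo and s + i <= hi:
                    blocks.append((i, j))
                i = j
            if len(blocks) != 1:
                continue  # no evidence, or run split by an interior mismatch
            i, j = blocks[0]
            if i == 0 or j == len(read_seq):
                continue  # run not fully contained: read does not span it
            obs = j - i
            if abs(obs - run_len) > max_delta:
                continue  # partial overlap, not length evidence
            if s > lo - 1 or covered_to < hi - max_delta:
                continue  # does not reach both flanks
            spanning += 1
            votes[obs] = votes.get(obs, 0) + 1
        if not spanning:
            continue
        ref_votes = votes.get(run_len, 0)
        for obs, n in sorted(votes.items()):
            if obs != run_len and n >= min_support and ref_votes == 0:
                candidates.append(
                    IndelCandidate(
                        site=run_start,
                        ref_allele=base * run_len,
                        alt_allele=base * obs,
                        support=n,
                        spanning=spanning,
                    )
                )
    return candidates


def apply_indels(
    sequence: str, candidates: Sequence[IndelCandidate]
) -> tuple[str, dict[int, int]]:
    """Apply homopolymer candidates to a consensus, returning the edited
    sequence and a map from original to edited 1-based coordinates."""
    edits = {c.site: c for c in candidates}
    out: list[str] = []
    coord_map: dict[int, int] = {}
    site = 1
    L = len(sequence)
    while site <= L:
        c = edits.get(site)
        if c is None:
            out.append(sequence[site - 1])
            coord_map[site] = len(out)
            site += 1
        else:
            for i, b in enumerate(c.alt_allele):
                out.append(b)
            for i in range(len(c.ref_allele)):
                coord_map[site + i] = min(len(out), len(out) - len(c.alt_allele) + 1 + i)
            site += len(c.ref_allele)
    return "".join(out), coord_map


def write_mask_bed(path: str | Path, intervals: Sequence[tuple[int, int, str]], ref_id: str) -> None:
    """Write mask intervals as BED (0-based half-open on disk)."""
    with open(path, "w") as fh:
        for a, b, reason in sorted(intervals):
            fh.write(f"{ref_id}\t{a - 1}\t{b}\t{reason}\n")


def read_mask_bed(path: str | Path) -> list[tuple[int, int, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            parts = line.split("\t")
            out.append((int(parts[1]) + 1, int(parts[2]), parts[3].strip() if len(parts) > 3 else ""))
    return out


def write_indel_candidates(path: str | Path, candidates: Sequence[IndelCandidate]) -> None:
    with open(path, "w") as fh:
        fh.write("#site\tref_allele\talt_allele\tsupport\tspanning\tflag\n")
        for c in candidates:
            fh.write(f"{c.site}\t{c.ref_allele}\t{c.alt_allele}\t{c.support}\t{c.spanning}\t{c.flag}\n")
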