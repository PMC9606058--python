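"""Simulation of degraded-specimen sequencing reads with known ground truth.

Formalin-fixed and ancient specimens yield very short DNA fragments whose
cytosines are partially deaminated, so that sequencers read C as T — with the
damage concentrated at fragment ends, where single-stranded overhangs are
exposed.  This module generates reads that reproduce that structure from a
circular reference with a planted set of variants, so every downstream stage
(mapping, damage profiling, consensus, comparison) can be scored against
truth.

The fragment-length model is a truncated lognormal: short-fragment museum
libraries show an asymmetric unimodal length distribution, bounded below by
the length filter applied after adapter trimming (20 bp) and above by the
single-end read length of the instrument (75 bp).  The damage model places a
per-position deamination probability ``p(i) = p_base + (p_max - p_base) *
exp(-decay * i)`` at 0-based distance ``i`` from the nearer fragment end.
With single-stranded library preparation both read ends show C→T; with
double-stranded preparation the 5' end shows C→T and the 3' end G→A.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .io import CircularSequence, reverse_complement

_BASES = "ACGT"


@dataclass(frozen=True)
class VariantTruth:
    """One planted difference between the reference and the simulated genome."""

    site: int  # 1-based reference coordinate
    ref_base: str
    alt: str  # alt base, "-" for a deletion, or inserted string
    kind: str  # substitution | deletion | insertion

    def __post_init__(self) -> None:
        if self.kind not in ("substitution", "deletion", "insertion"):
            raise ValueError(f"unknown variant kind {self.kind!r}")


class TruthSetError(ValueError):
    """A planted variant disagrees with the reference it is planted on."""


@dataclass(frozen=True)
class FragmentModel:
    """Truncated-lognormal fragment lengths, in bp.

    Defaults give a truncated mean of ~33 bp with ~0.2% of fragments at
    70 bp or longer, the regime of short-fragment museum libraries.
    """

    mean_log: float = math.log(30.5)
    sd_log: float = 0.30
    min_len: int = 20
    max_len: int = 75

    def __post_init__(self) -> None:
        if self.min_len < 1 or self.max_len < self.min_len:
            raise ValueError("require 1 <= min_len <= max_len")

    def truncated_mean(self) -> float:
        """Closed-form mean of the lognormal truncated to [min_len, max_len]."""
        if self.min_len == self.max_len:
            return float(self.min_len)
        mu, sig = self.mean_log, self.sd_log
        a, b = math.log(self.min_len), math.log(self.max_len)
        num = norm.cdf((b - mu - sig**2) / sig) - norm.cdf((a - mu - sig**2) / sig)
        den = norm.cdf((b - mu) / sig) - norm.cdf((a - mu) / sig)
        return math.exp(mu + sig**2 / 2) * num / den

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Sample ``n`` integer lengths by inverse-CDF truncation."""
        mu, sig = self.mean_log, self.sd_log
        lo = norm.cdf((math.log(self.min_len) - mu) / sig)
        hi = norm.cdf((math.log(self.max_len) - mu) / sig)
        u = rng.uniform(lo, hi, size=n)
        lengths = np.exp(mu + sig * norm.ppf(u))
        return np.clip(np.rint(lengths).astype(int), self.min_len, self.max_len)


@dataclass(frozen=True)
class DamageModel:
    """End-biased cytosine-deamination model plus uniform sequencing error."""

    library: str = "single_stranded"  # or double_stranded
    p_max: float = 0.30
    p_base: float = 0.01
    decay: float = 0.3
    seq_error: float = 0.001

    def __post_init__(self) -> None:
        if self.library not in ("single_stranded", "double_stranded"):
            raise ValueError(f"unknown library type {self.library!r}")
        if not 0 <= self.p_base <= self.p_max <= 1:
            raise ValueError("require 0 <= p_base <= p_max <= 1")
        if self.decay < 0:
            raise ValueError("decay must be >= 0")

    def p(self, i: int) -> float:
        """Deamination probability at 0-based distance ``i`` from the end."""
        return self.p_base + (self.p_max - self.p_base) * math.exp(-self.decay * i)


@dataclass(frozen=True)
class SimConfig:
    """Scale and nuisance parameters of one simulated sequencing experiment."""

    target_depth: float = 35.0
    seed: int = 0
    contamination_fraction: float = 0.0
    read_len: int = 75  # instrument read length; longer fragments are truncated

    def __post_init__(self) -> None:
        if self.target_depth <= 0:
            raise ValueError("target_depth must be > 0")
        if not 0 <= self.contamination_fraction < 1:
            raise ValueError("contamination_fraction must be in [0, 1)")


def plant_variants(
    genome: CircularSequence, variants: Sequence[VariantTruth]
) -> tuple[CircularSequence, dict[int, int]]:
    """Apply a truth set to a genome; return the mutated genome and a coordinate map.

    The returned map sends each original 1-based coordinate to its 1-based
    coordinate in the mutated genome; deleted sites map to the coordinate of
    the previous surviving base (convention: left-anchored).
    """
    seen: set[int] = set()
    for v in variants:
        if v.site in seen:
            raise TruthSetError(f"duplicate variant site {v.site}")
        seen.add(v.site)
        if not 1 <= v.site <= len(genome):
            raise TruthSetError(f"variant site {v.site} outside genome")
        if v.kind in ("substitution", "deletion"):
            actual = genome.residues[v.site - 1]
            if actual != v.ref_base:
                raise TruthSetError(
                    f"site {v.site}: truth set says ref {v.ref_base!r} but genome has {actual!r}"
                )
    by_site = {v.site: v for v in variants}
    out: list[str] = []
    coord_map: dict[int, int] = {}
    for site in range(1, len(genome) + 1):
        v = by_site.get(site)
        if v is None:
            out.append(genome.residues[site - 1])
            coord_map[site] = len(out)
        elif v.kind == "substitution":
            out.append(v.alt)
            coord_map[site] = len(out)
        elif v.kind == "deletion":
            coord_map[site] = len(out)  # maps to previous surviving base
        else:  # insertion after this site
            out.append(genome.residues[site - 1])
            coord_map[site] = len(out)
            out.append(v.alt)
    return CircularSequence(genome.id + "_mut", "".join(out), genome.circular), coord_map


def simulate_fragments(
    genome: CircularSequence,
    fm: FragmentModel,
    n: int,
    rng: np.random.Generator | int,
) -> list[tuple[int, int, str]]:
    """Draw ``n`` fragments as (1-based start, length, strand).

    Starts are uniform on the circle; fragments may span the origin.
    """
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    if n == 0:
        return []
    starts = rng.integers(1, len(genome) + 1, size=n)
    lengths = fm.sample(n, rng)
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    return list(zip(starts.tolist(), lengths.tolist(), strands.tolist()))


def apply_damage(fragment: str, dm: DamageModel, rng: np.random.Generator) -> str:
    """Deaminate and add sequencing error to one fragment sequence.

    The fragment is given in its sequenced orientation.  Single-stranded
    libraries deaminate C→T from both ends; double-stranded libraries show
    C→T from the 5' end and G→A from the 3' end.  Uniform sequencing error is
    applied afterwards, each erroneous base drawn from the 3 alternatives.
    """
    n = len(fragment)
    bases = list(fragment)
    u = rng.random(n)
    if dm.library == "single_stranded":
        for i, b in enumerate(bases):
            if b == "C" and u[i] < dm.p(min(i, n - 1 - i)):
                bases[i] = "T"
    else:
        for i, b in enumerate(bases):
            if b == "C" and u[i] < dm.p(i):
                bases[i] = "T"
            elif b == "G" and u[i] < dm.p(n - 1 - i):
                bases[i] = "A"
    if dm.seq_error > 0:
        err = rng.random(n) < dm.seq_error
        for i in np.flatnonzero(err):
            alts = [b for b in _BASES if b != bases[i]]
            bases[i] = alts[rng.integers(3)]
    return "".join(bases)


@dataclass
class ReadTruth:
    """Provenance of one simulated read."""

    read_id: str
    origin: str  # "endogenous" or "contaminant"
    start: int  # 1-based start on the source genome (fragment 5' on + strand)
    length: int
    strand: str


@dataclass
class ReadSet:
    """In-memory result of a simulation: reads plus their truth records."""

    reads: list[tuple[str, str]]  # (read_id, sequence)
    truth: list[ReadTruth]


def random_genome(
    length: int, seed: int | np.random.Generator, gc: float = 0.45, id: str = "ref"
) -> CircularSequence:
    """An i.i.d. random circular genome at the given GC content."""
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return CircularSequence(id, "".join(_BASES[i] for i in idx), True)


def expected_read_count(genome_length: int, cfg: SimConfig, fm: FragmentModel) -> int:
    """Read count for which expected coverage equals the target depth."""
    return int(round(genome_length * cfg.target_depth / fm.truncated_mean()))


def simulate_readset(
    genome: CircularSequence,
    fm: FragmentModel,
    dm: DamageModel,
    cfg: SimConfig,
) -> ReadSet:
    """Simulate a full read set at the configured depth.

    Contaminant reads are drawn from a seeded random decoy genome (GC 50%)
    and flagged in the truth records.  Fragments longer than the instrument
    read length are truncated at the 3' end of the read.
    """
    rng = np.random.default_rng(cfg.seed)
    n_total = expected_read_count(len(genome), cfg, fm)
    n_contam = int(round(n_total * cfg.contamination_fraction))
    n_endo = n_total - n_contam
    decoy = random_genome(len(genome), np.random.default_rng(cfg.seed + 1), gc=0.5, id="decoy")

    reads: list[tuple[str, str]] = []
    truth: list[ReadTruth] = []
    specs = [("endogenous", genome, n_endo), ("contaminant", decoy, n_contam)]
    counter = 0
    for origin, src, n in specs:
        for start, length, strand in simulate_fragments(src, fm, n, rng):
            frag = src.fetch(start, length)
            if strand == "-":
                frag = reverse_complement(frag)
            read = apply_damage(frag, dm, rng)[: cfg.read_len]
            rid = f"r{counter:06d}"
            counter += 1
            reads.append((rid, read))
            truth.append(ReadTruth(rid, origin, start, length, strand))
    return ReadSet(reads, truth)


def write_fastq(path: str | Path, readset: ReadSet, quality: str = "I") -> None:
    """Write reads as Phred+33 FASTQ with constant placeholder qualities."""
    with open(path, "w") as fh:
        for rid, seq in readset.reads:
            fh.write(f"@{rid}\n{seq}\n+\n{quality * len(seq)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    reads = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            reads.append((header.strip().lstrip("@"), seq))
    return reads


def write_read_truth(path: str | Path, readset: ReadSet) -> None:
    with open(path, "w") as fh:
        fh.write("#read_id\torigin\tstart\tlength\tstrand\n")
        for t in readset.truth:
            fh.write(f"{t.read_id}\t{t.origin}\t{t.start}\t{t.length}\t{t.strand}\n")


def write_variant_truth(path: str | Path, variants: Sequence[VariantTruth]) -> None:
    with open(path, "w") as fh:
        fh.write("#site\tref_base\talt\tkind\n")
        for v in variants:
            fh.write(f"{v.site}\t{v.ref_base}\t{v.alt}\t{v.kind}\n")


def read_variant_truth(path: str | Path) -> list[VariantTruth]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            site, ref_base, alt, kind = line.rstrip("\n").split("\t")
            out.append(VariantTruth(int(site), ref_base, alt, kind))
    return out


_TS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def table2_like_variants(
    genome: CircularSequence,
    rng: np.random.Generator | int,
    n_transitions: int = 21,
    n_transversions: int = 5,
    homopolymer_site: int | None = None,
) -> list[VariantTruth]:
    """A planted truth set shaped like the published icefish difference table:
    21 transitions, 5 transversions and one single-base deletion inside a
    C-homopolymer (pass ``homopolymer_site`` = 1-based start of a C run in
    the genome; the deletion removes one C of that run).
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    L = len(genome)
    taken: set[int] = set()
    variants: list[VariantTruth] = []
    if homopolymer_site is not None:
        if genome.residues[homopolymer_site - 1] != "C":
            raise TruthSetError(f"site {homopolymer_site} is not a C")
        variants.append(VariantTruth(homopolymer_site, "C", "-", "deletion"))
        run_start = homopolymer_site
        while run_start > 1 and genome.residues[run_start - 2] == "C":
            run_start -= 1
        run_end = homopolymer_site
        while run_end < L and genome.residues[run_end] == "C":
            run_end += 1
        taken.update(range(max(1, run_start - 40), min(L, run_end + 40) + 1))
    transitions = {"A": "G", "G": "A", "C": "T", "T": "C"}
    transversions = {"A": "C", "G": "C", "C": "A", "T": "G"}
    for count, table in ((n_transitions, transitions), (n_transversions, transversions)):
        placed = 0
        while placed < count:
            site = int(rng.integers(1, L + 1))
            # keep variants well separated so short reads see at most one
            if any(abs(site - t) < 40 for t in taken):
                continue
            ref = genome.residues[site - 1]
            variants.append(VariantTruth(site, ref, table[ref], "substitution"))
            taken.update(range(site - 40, site + 41))
            placed += 1
    return sorted(variants, key=lambda v: v.site)


def embed_homopolymer(
    genome: CircularSequence, site: int, base: str = "C", length: int = 14
) -> CircularSequence:
    """Overwrite ``length`` bases starting at 1-based ``site`` with a homopolymer,
    ensuring the flanking bases differ from ``base`` so the run is exact."""
    res = list(genome.residues)
    res[site - 2] = "A" if base != "A" else "G"
    for i in range(length):
        res[site - 1 + i] = base
    res[site - 1 + length] = "A" if base != "A" else "G"
    return CircularSequence(genome.id, "".join(res), genome.circular)
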