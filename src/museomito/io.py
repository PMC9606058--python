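"""Sequence, feature, alignment and tree I/O, plus circular-coordinate arithmetic.

Mitochondrial genomes are circular: reads and features may span the junction
between the last and the first base of the linearised reference, and the
standard trick to recover the terminal positions of a reference-based
consensus is to rotate the reference and repeat the mapping.  Everything in
this package therefore works in terms of :class:`CircularSequence`, which
carries an explicit circularity flag and supports rotation, circular
substring extraction and wrapped coordinates.

All externally visible coordinates are 1-based inclusive on the reference
heavy strand; BED output converts to 0-based half-open on disk.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ParseError(ValueError):
    """Raised when an input file violates the formats accepted here."""


def reverse_complement(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CircularSequence:
    """A nucleotide sequence with optional circular topology.

    Residues are uppercase A/C/G/T/N.  ``N`` marks masked or missing bases;
    other IUPAC ambiguity codes are rejected on input.
    """

    id: str
    residues: str
    circular: bool = True

    def __post_init__(self) -> None:
        bad = set(self.residues) - VALID_BASES
        if bad:
            raise ParseError(
                f"record {self.id!r}: non-ACGTN characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    def rotate(self, offset: int) -> "CircularSequence":
        """Rotate so that 1-based position ``offset + 1`` becomes position 1.

        Only defined for circular sequences.  ``rotate(L)`` is the identity.
        """
        if not self.circular:
            raise ValueError(f"cannot rotate non-circular sequence {self.id!r}")
        L = len(self.residues)
        offset %= L
        return CircularSequence(
            self.id, self.residues[offset:] + self.residues[:offset], True
        )

    def fetch(self, start: int, length: int) -> str:
        """Circular substring: ``length`` bases starting at 1-based ``start``.

        Wraps past the origin when the sequence is circular; raises
        ``IndexError`` on overrun of a linear sequence.
        """
        L = len(self.residues)
        if not 1 <= start <= L:
            raise IndexError(f"start {start} outside [1, {L}]")
        end0 = start - 1 + length
        if end0 <= L:
            return self.residues[start - 1 : end0]
        if not self.circular:
            raise IndexError(
                f"substring [{start}, +{length}] overruns linear sequence of length {L}"
            )
        return self.residues[start - 1 :] + self.residues[: end0 - L]

    def wrap(self, pos: int) -> int:
        """Map an arbitrary integer onto 1-based circular coordinates."""
        return (pos - 1) % len(self.residues) + 1


def rotate(seq: CircularSequence, offset: int) -> CircularSequence:
    """Functional form of :meth:`CircularSequence.rotate`."""
    return seq.rotate(offset)


FEATURE_TYPES = frozenset({"protein_coding", "rRNA", "tRNA", "control_region"})


@dataclass(frozen=True)
class Feature:
    """An annotated region of the reference, 1-based inclusive coordinates.

    ``phase`` is the number of bases before the first complete codon, as in
    GFF3; it only matters for protein-coding features.  Features spanning the
    circular origin are represented as two parts sharing a ``name``.
    """

    name: str
    ftype: str
    start: int
    end: int
    strand: str = "+"
    phase: int = 0

    def __post_init__(self) -> None:
        if self.ftype not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.ftype!r}")
        if not 1 <= self.start <= self.end:
            raise ValueError(
                f"feature {self.name!r}: invalid interval {self.start}..{self.end}"
            )
        if self.strand not in "+-":
            raise ValueError(f"feature {self.name!r}: strand must be + or -")
        if self.phase not in (0, 1, 2):
            raise ValueError(f"feature {self.name!r}: phase must be 0, 1 or 2")

    def contains(self, site: int) -> bool:
        return self.start <= site <= self.end


@dataclass
class SequenceAlignment:
    """A multiple alignment: ordered (id, gapped residue string) records.

    The gap symbol is ``-``; ``N`` marks missing data and is distinct from a
    gap (an N base exists but its identity is unknown).
    """

    records: list[tuple[str, str]]

    def __post_init__(self) -> None:
        lengths = {len(s) for _, s in self.records}
        if len(lengths) > 1:
            raise ParseError(f"alignment rows differ in length: {sorted(lengths)}")

    @property
    def columns(self) -> int:
        return len(self.records[0][1]) if self.records else 0

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.records]

    def row(self, rid: str) -> str:
        for i, s in self.records:
            if i == rid:
                return s
        raise KeyError(rid)


def read_fasta(path: str | Path, circular: bool = True) -> list[CircularSequence]:
    """Read a nucleotide FASTA file; residues uppercased, U converted to T."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper().replace("U", "T")
        try:
            records.append(CircularSequence(rec.id, residues, circular))
        except ParseError as exc:
            raise ParseError(str(exc)) from None
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(path: str | Path, seqs: Iterable[CircularSequence], width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


def extract_coding(seq: CircularSequence, feature: Feature) -> str:
    """Coding-orientation nucleotide sequence of a feature.

    Returns the reference substring for ``+`` strand features and its reverse
    complement for ``-`` strand features, with ``phase`` leading bases dropped
    so that position 1 of the result is codon position 1.
    """
    if feature.end > len(seq) and not seq.circular:
        raise IndexError(
            f"feature {feature.name!r} ends at {feature.end} beyond sequence length {len(seq)}"
        )
    sub = seq.fetch(seq.wrap(feature.start), feature.end - feature.start + 1)
    if feature.strand == "-":
        sub = reverse_complement(sub)
    return sub[feature.phase :]


def read_feature_table(path: str | Path) -> list[Feature]:
    """Read features from a simple TSV or a GFF3-like file.

    TSV columns: name, ftype, start, end[, strand[, phase]].  Lines starting
    with ``#`` are skipped.  GFF3 is detected by its 9-column layout; the
    feature name is taken from the ``Name=`` or ``ID=`` attribute and the type
    column is mapped onto {protein_coding, rRNA, tRNA, control_region}.
    """
    feats: list[Feature] = []
    gff_types = {
        "CDS": "protein_coding",
        "gene": "protein_coding",
        "rRNA": "rRNA",
        "tRNA": "tRNA",
        "D_loop": "control_region",
        "control_region": "control_region",
    }
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 9 and parts[3].isdigit() and parts[4].isdigit():
                # GFF3: seqid source type start end score strand phase attrs
                _, _, gtype, start, end, _, strand, phase, attrs = parts
                if gtype not in gff_types:
                    continue
                attr_map = dict(
                    kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
                )
                name = attr_map.get("Name") or attr_map.get("ID")
                feats.append(
                    Feature(
                        name or f"feature_{ln}",
                        gff_types[gtype],
                        int(start),
                        int(end),
                        strand if strand in "+-" else "+",
                        int(phase) if phase in "012" else 0,
                    )
                )
            elif len(parts) >= 4:
                name, ftype, start, end = parts[:4]
                strand = parts[4] if len(parts) > 4 and parts[4] else "+"
                phase = int(parts[5]) if len(parts) > 5 and parts[5] else 0
                feats.append(Feature(name, ftype, int(start), int(end), strand, phase))
            else:
                raise ParseError(f"{path}:{ln}: cannot parse feature line {line!r}")
    return feats


def write_feature_table(path: str | Path, feats: Iterable[Feature]) -> None:
    with open(path, "w") as fh:
        fh.write("#name\tftype\tstart\tend\tstrand\tphase\n")
        for f in feats:
            fh.write(f"{f.name}\t{f.ftype}\t{f.start}\t{f.end}\t{f.strand}\t{f.phase}\n")


def read_alignment(path: str | Path) -> SequenceAlignment:
    """Read an aligned FASTA into a :class:`SequenceAlignment`."""
    try:
        aln = AlignIO.read(str(path), "fasta")
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None
    records = [(rec.id, str(rec.seq).upper().replace("U", "T")) for rec in aln]
    for rid, row in records:
        bad = set(row) - (VALID_BASES | {"-"})
        if bad:
            raise ParseError(f"alignment row {rid!r}: invalid characters {sorted(bad)!r}")
    return SequenceAlignment(records)


def write_alignment(path: str | Path, aln: SequenceAlignment) -> None:
    with open(path, "w") as fh:
        for rid, row in aln.records:
            fh.write(f">{rid}\n{row}\n")


def read_tree(path: str | Path, alignment: SequenceAlignment | None = None) -> dendropy.Tree:
    """Read a newick tree; optionally cross-check tip labels against an alignment.

    Raises :class:`ParseError` when tip labels and alignment ids do not match
    one-to-one.
    """
    tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon}
    if alignment is not None:
        ids = set(alignment.ids)
        if tips != ids:
            missing = sorted(ids - tips)
            extra = sorted(tips - ids)
            raise ParseError(
                f"tree/alignment id mismatch: alignment-only {missing}, tree-only {extra}"
            )
    return tree


def parse_newick(text: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
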