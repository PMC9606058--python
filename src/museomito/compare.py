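"""Annotated comparison of near-identical mitochondrial genomes.

Given a pairwise alignment of two mitogenomes and a feature table, this
module produces a difference table (one record per substitution or per
maximal gap run), classifies each substitution as transition or
transversion, annotates codon position and amino-acid change under the
vertebrate mitochondrial genetic code (TGA=Trp, ATA=Met, AGA/AGG=Stop —
the code matters: e.g. tgg→tga is synonymous only mitochondrially), and
summarises divergence genome-wide and with a region excluded.  Reported
bases are reference-strand; codons are reported in coding orientation,
because genes such as ND6 are light-strand encoded.

Missing data (N) in either sequence is ignored throughout, including in the
pairwise-deletion distance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io import CircularSequence, Feature, SequenceAlignment, reverse_complement

VERTEBRATE_MITO = "Vertebrate Mitochondrial"  # NCBI translation table 2
STANDARD = "Standard"

_CODE_TABLE = {"vertmito": 2, "standard": 1}

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def classify_ts_tv(ref_base: str, alt_base: str) -> str:
    """Transition (purine↔purine or pyrimidine↔pyrimidine) vs transversion."""
    r, a = ref_base.upper(), alt_base.upper()
    if r == a:
        raise ValueError(f"bases are identical ({r}); not a substitution")
    if r not in "ACGT" or a not in "ACGT":
        raise ValueError(f"bases must be A/C/G/T, got {ref_base!r}/{alt_base!r}")
    if (r in _PURINES) == (a in _PURINES):
        return "transition"
    return "transversion"


def translate_codon(codon: str, code: str = "vertmito") -> str:
    """Single-letter amino acid ('*' for stop) of one codon."""
    table = _CODE_TABLE[code]
    return str(Seq(codon.upper()).translate(table=table))


@dataclass
class DifferenceRecord:
    """One row of a published-style difference table."""

    site: int
    ref_base: str
    alt_base: str
    kind: str  # substitution | indel
    ts_tv: str | None = None  # transition | transversion | None for indels
    feature: str = "intergenic/control"
    codon_position: int | None = None
    ref_codon: str | None = None
    alt_codon: str | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    synonymous: bool | None = None


@dataclass
class PairwiseSummary:
    substitutions: int
    indels: int
    substitutions_excl: int
    indels_excl: int
    compared_sites: int
    rate_overall: float  # substitutions per compared bp
    rate_in_region: float | None
    rate_out_region: float | None
    percent_divergence: float  # (all differing events / covered_length) * 100


def _feature_parts(features: Sequence[Feature], name: str) -> list[Feature]:
    return [f for f in features if f.name == name]


def _find_feature(features: Sequence[Feature], site: int) -> Feature | None:
    coding = [f for f in features if f.ftype == "protein_coding" and f.contains(site)]
    if coding:
        return coding[0]
    other = [f for f in features if f.contains(site)]
    return other[0] if other else None


def annotate_codon(
    site: int,
    ref_seq: CircularSequence,
    alt_base: str,
    features: Sequence[Feature],
    code: str = "vertmito",
) -> tuple[int, str, str, str, str, bool] | None:
    """Codon-level annotation of a substitution inside a protein-coding gene.

    Returns (codon_position 1-3, ref_codon, alt_codon, ref_aa, alt_aa,
    synonymous) with codons in coding orientation, or ``None`` when the site
    is not protein-coding.  Genes split across the circular origin are
    handled by concatenating the parts in coding order.
    """
    feat = _find_feature(features, site)
    if feat is None or feat.ftype != "protein_coding":
        return None
    parts = sorted(_feature_parts(features, feat.name), key=lambda f: f.start)
    if feat.strand == "-":
        parts = parts[::-1]
    coding = "".join(
        reverse_complement(ref_seq.fetch(p.start, p.end - p.start + 1))
        if feat.strand == "-"
        else ref_seq.fetch(p.start, p.end - p.start + 1)
        for p in parts
    )
    phase = parts[0].phase
    coding = coding[phase:]
    # 0-based offset of the site within the coding sequence
    offset = 0
    for p in parts:
        if p.contains(site):
            offset += (p.end - site) if feat.strand == "-" else (site - p.start)
            break
        offset += p.end - p.start + 1
    offset -= phase
    if offset < 0:
        return None  # site inside the incomplete leading codon
    codon_index = offset // 3
    codon_pos = offset % 3 + 1
    ref_codon = coding[codon_index * 3 : codon_index * 3 + 3]
    if len(ref_codon) < 3:
        return None  # trailing incomplete codon
    alt_in_coding = reverse_complement(alt_base) if feat.strand == "-" else alt_base
    alt_codon = ref_codon[: codon_pos - 1] + alt_in_coding + ref_codon[codon_pos:]
    ref_aa = translate_codon(ref_codon, code)
    alt_aa = translate_codon(alt_codon, code)
    return codon_pos, ref_codon.lower(), alt_codon.lower(), ref_aa, alt_aa, ref_aa == alt_aa


def pairwise_differences(
    alignment: SequenceAlignment,
    features: Sequence[Feature] = (),
    code: str = "vertmito",
) -> list[DifferenceRecord]:
    """Difference records between the first (reference) and second row.

    Columns with N in either row are skipped entirely.  A substitution gives
    one record; a maximal gap run gives a single indel record anchored at
    the reference coordinate of its first column (for insertions, at the
    preceding reference base).  Coordinates are 1-based in the reference's
    ungapped frame.
    """
    if len(alignment.records) != 2:
        raise ValueError(f"need a 2-row alignment, got {len(alignment.records)} rows")
    ref_row = alignment.records[0][1]
    alt_row = alignment.records[1][1]
    ref_ungapped = ref_row.replace("-", "")
    ref_seq = CircularSequence(alignment.records[0][0], ref_ungapped, circular=False)
    records: list[DifferenceRecord] = []
    ref_pos = 0  # last seen 1-based reference coordinate
    in_gap = False
    for col, (r, a) in enumerate(zip(ref_row, alt_row)):
        if r != "-":
            ref_pos += 1
        if r == "N" or a == "N":
            in_gap = False
            continue
        if r == "-" and a == "-":
            in_gap = False
            continue
        if r == "-" or a == "-":
            if not in_gap:
                feat = _find_feature(features, max(ref_pos, 1))
                records.append(
                    DifferenceRecord(
                        site=max(ref_pos, 1),
                        ref_base=r if r != "-" else "-",
                        alt_base=a if a != "-" else "-",
                        kind="indel",
                        feature=feat.name if feat else "intergenic/control",
                    )
                )
                in_gap = True
            elif records and records[-1].kind == "indel":
                # extend the run's alleles
                rec = records[-1]
                rec.ref_base = (rec.ref_base.replace("-", "") + (r if r != "-" else "")) or "-"
                rec.alt_base = (rec.alt_base.replace("-", "") + (a if a != "-" else "")) or "-"
            continue
        in_gap = False
        if r != a:
            rec = DifferenceRecord(
                site=ref_pos,
                ref_base=r,
                alt_base=a,
                kind="substitution",
                ts_tv=classify_ts_tv(r, a),
            )
            ann = annotate_codon(ref_pos, ref_seq, a, features, code)
            feat = _find_feature(features, ref_pos)
            rec.feature = feat.name if feat else "intergenic/control"
            if ann is not None:
                (
                    rec.codon_position,
                    rec.ref_codon,
                    rec.alt_codon,
                    rec.ref_aa,
                    rec.alt_aa,
                    rec.synonymous,
                ) = ann
            records.append(rec)
    return records


def _interval_length(intervals: Sequence[tuple[int, int]]) -> int:
    covered: set[int] = set()
    for a, b in intervals:
        covered.update(range(a, b + 1))
    return len(covered)


def _in_region(site: int, intervals: Sequence[tuple[int, int]]) -> bool:
    return any(a <= site <= b for a, b in intervals)


def summarize_pair(
    differences: Sequence[DifferenceRecord],
    excluded_region: Sequence[tuple[int, int]] = (),
    covered_length: int | None = None,
    compared_sites: int | None = None,
) -> PairwiseSummary:
    """Counts and rates, overall and with a region excluded.

    ``covered_length`` is the denominator of the headline percent divergence
    (conventionally the full reference length); ``compared_sites`` the
    number of columns where both sequences have A/C/G/T, used for per-bp
    rates (defaults to ``covered_length``).
    """
    subs = [d for d in differences if d.kind == "substitution"]
    indels = [d for d in differences if d.kind == "indel"]
    subs_excl = [d for d in subs if not _in_region(d.site, excluded_region)]
    indels_excl = [d for d in indels if not _in_region(d.site, excluded_region)]
    if covered_length is None:
        raise ValueError("covered_length is required")
    if compared_sites is None:
        compared_sites = covered_length
    region_len = _interval_length(excluded_region)
    rate_overall = len(subs) / compared_sites if compared_sites else 0.0
    rate_in = (
        (len(subs) - len(subs_excl)) / region_len if region_len else None
    )
    out_len = compared_sites - region_len
    rate_out = len(subs_excl) / out_len if excluded_region and out_len > 0 else None
    percent = 100.0 * len(differences) / covered_length
    return PairwiseSummary(
        substitutions=len(subs),
        indels=len(indels),
        substitutions_excl=len(subs_excl),
        indels_excl=len(indels_excl),
        compared_sites=compared_sites,
        rate_overall=rate_overall,
        rate_in_region=rate_in,
        rate_out_region=rate_out,
        percent_divergence=percent,
    )


def distance_matrix(alignment: SequenceAlignment) -> np.ndarray:
    """Pairwise-deletion distances: substitutions per site compared, where a
    site is compared only if both rows carry an unambiguous base.  Entries
    with zero comparable columns are NaN."""
    rows = [np.frombuffer(s.encode(), dtype="S1") for _, s in alignment.records]
    n = len(rows)
    acgt = np.frombuffer(b"ACGT", dtype="S1")
    valid = [np.isin(r, acgt) for r in rows]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            if m == 0:
                D[i, j] = D[j, i] = np.nan
                continue
            diff = int((rows[i][both] != rows[j][both]).sum())
            D[i, j] = D[j, i] = diff / m
    return D


def align_pair(
    a: CircularSequence | str, b: CircularSequence | str, ids: tuple[str, str] = ("ref", "qry")
) -> SequenceAlignment:
    """Global alignment of two near-identical sequences (edit-distance path).

    Intended for genomes differing by a handful of substitutions and short
    indels; not a general aligner.
    """
    sa = a.residues if isinstance(a, CircularSequence) else a
    sb = b.residues if isinstance(b, CircularSequence) else b
    res = edlib.align(sb, sa, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, sb, sa)
    ida = a.id if isinstance(a, CircularSequence) else ids[0]
    idb = b.id if isinstance(b, CircularSequence) else ids[1]
    return SequenceAlignment([(ida, nice["target_aligned"]), (idb, nice["query_aligned"])])


# ---------------------------------------------------------------------------
# Published difference-table fixture


def load_builtin_differences() -> pd.DataFrame:
    """The published 27-row difference table between the C. rhinoceratus and
    C. rugosus mitochondrial genomes, as shipped with the package."""
    path = resources.files("museomito.data").joinpath("channichthys_mtdna_differences.tsv")
    with resources.as_file(path) as p:
        df = pd.read_csv(
            p,
            sep="\t",
            comment="#",
            header=None,
            names=[
                "site",
                "ref_base",
                "alt_base",
                "codon_position",
                "ref_codon",
                "alt_codon",
                "aa_change",
            ],
            dtype={"site": int},
        )
    return df


def reclassify_differences(df: pd.DataFrame, code: str = "vertmito") -> list[DifferenceRecord]:
    """Rebuild difference records from a printed table: transition/transversion
    status is recomputed from the bases and amino acids are re-translated
    from the printed codons — nothing is taken from the table's own
    classification columns."""
    records: list[DifferenceRecord] = []
    for row in df.itertuples(index=False):
        ref_b, alt_b = str(row.ref_base).upper(), str(row.alt_base).upper()
        if ref_b == "-" or alt_b == "-":
            records.append(
                DifferenceRecord(site=int(row.site), ref_base=ref_b, alt_base=alt_b, kind="indel")
            )
            continue
        rec = DifferenceRecord(
            site=int(row.site),
            ref_base=ref_b,
            alt_base=alt_b,
            kind="substitution",
            ts_tv=classify_ts_tv(ref_b, alt_b),
        )
        if pd.notna(row.ref_codon) and str(row.ref_codon).strip():
            rec.codon_position = int(row.codon_position)
            rec.ref_codon = str(row.ref_codon).lower()
            rec.alt_codon = str(row.alt_codon).lower()
            rec.ref_aa = translate_codon(rec.ref_codon, code)
            rec.alt_aa = translate_codon(rec.alt_codon, code)
            rec.synonymous = rec.ref_aa == rec.alt_aa
            rec.feature = "protein_coding"
        records.append(rec)
    return records


def difference_counts(records: Sequence[DifferenceRecord]) -> dict[str, int]:
    """Headline counts of a difference list."""
    subs = [r for r in records if r.kind == "substitution"]
    return {
        "substitutions": len(subs),
        "indels": sum(1 for r in records if r.kind == "indel"),
        "transitions": sum(1 for r in subs if r.ts_tv == "transition"),
        "transversions": sum(1 for r in subs if r.ts_tv == "transversion"),
        "aa_substitutions": sum(1 for r in subs if r.synonymous is False),
    }


def differences_to_frame(records: Sequence[DifferenceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "site": r.site,
                "ref_base": r.ref_base,
                "alt_base": r.alt_base,
                "kind": r.kind,
                "ts_tv": r.ts_tv or "",
                "feature": r.feature,
                "codon_position": r.codon_position if r.codon_position else "",
                "codon_substitution": f"{r.ref_codon}/{r.alt_codon}" if r.ref_codon else "",
                "aa_substitution": (
                    f"{r.ref_aa}/{r.alt_aa}" if r.synonymous is False else ""
                ),
            }
            for r in records
        ]
    )


def write_differences(path: str | Path, records: Sequence[DifferenceRecord]) -> None:
    differences_to_frame(records).to_csv(path, sep="\t", index=False)


def write_distance_matrix(path: str | Path, alignment: SequenceAlignment, D: np.ndarray) -> None:
    """PHYLIP-style square distance matrix."""
    with open(path, "w") as fh:
        fh.write(f"{len(alignment.records)}\n")
        for (rid, _), row in zip(alignment.records, D):
            vals = " ".join("NA" if np.isnan(v) else f"{v:.6f}" for v in row)
            fh.write(f"{rid:<12s}{vals}\n")
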