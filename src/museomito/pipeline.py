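"""End-to-end orchestration: simulate → map → damage → consensus → compare.

One global seed fans out deterministically to per-stage child seeds (a fixed
small offset per stage, kept below 2^31), so any stage can be rerun in
isolation and identical configs produce byte-identical outputs.  The run
report is JSON on disk and mirrors the bookkeeping a reference-based
museomics analysis reports: reads simulated, mapped, unique,
duplicate-filtered, consensus called fraction, differences found.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .compare import (
    align_pair,
    difference_counts,
    pairwise_differences,
    summarize_pair,
    write_differences,
)
from .consensus import (
    call_consensus,
    call_homopolymer_indels,
    consensus_from_reads,
    mask_regions,
    recover_terminal,
)
from .damage import damage_profile, fit_deamination, read_length_histogram, write_profile
from .io import CircularSequence, read_fasta, write_fasta
from .mapping import SeedIndex, filter_alignments, map_reads, mark_duplicates, write_sam
from .simulate import (
    DamageModel,
    FragmentModel,
    SimConfig,
    VariantTruth,
    embed_homopolymer,
    plant_variants,
    random_genome,
    simulate_readset,
    table2_like_variants,
    write_fastq,
    write_read_truth,
    write_variant_truth,
)

logger = logging.getLogger(__name__)

# paper-style defaults for the whole chain
_DEFAULTS = {
    "seed": 0,
    "genome_length": 17408,
    "target_depth": 35.0,
    "contamination_fraction": 0.0,
    "min_depth": 3,
    "rotation_bp": 200,
    "window": 25,
    "k": 12,
    "max_mismatch_frac": 0.05,
    "min_read_len": 20,
    "uniqueness_margin": 5.0,
    "damage_tolerant": True,
    "library": "single_stranded",
    "p_max": 0.30,
    "p_base": 0.01,
    "decay": 0.3,
    "seq_error": 0.001,
    "genetic_code": "vertmito",
    "homopolymer_site": 15986,
    "outdir": "museomito_run",
}


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Flat configuration of one pipeline run; unset keys fall back to
    defaults (min_depth=3, rotation_bp=200, min read length 20, ...)."""

    values: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = sorted(set(self.values) - set(_DEFAULTS))
        if unknown:
            raise ConfigError(f"unknown config keys: {', '.join(unknown)}")
        merged = dict(_DEFAULTS)
        merged.update(self.values)
        self.values = merged

    def __getattr__(self, key):
        try:
            return self.__dict__["values"][key]
        except KeyError:
            raise AttributeError(key) from None

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        values: dict = {}
        for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{ln}: expected key=value, got {line!r}")
            key, raw = (part.strip() for part in line.split("=", 1))
            values[key] = _coerce(key, raw)
        return cls(values)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for key in sorted(self.values):
                fh.write(f"{key}={self.values[key]}\n")

    def child_seed(self, stage_index: int) -> int:
        # fixed derivation; stays below 2^31 for any int32 master seed
        return (int(self.seed) * 1009 + stage_index * 9973) % (2**31)


def _coerce(key: str, raw: str):
    if key not in _DEFAULTS:
        return raw  # caught as unknown key by RunConfig
    default = _DEFAULTS[key]
    if isinstance(default, bool):
        return raw.lower() in ("1", "true", "yes")
    if isinstance(default, int):
        return int(raw)
    if isinstance(default, float):
        return float(raw)
    return raw


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Simulate a degraded read set from a genome carrying a planted truth
    set, reconstruct the consensus, compare it back to the reference and
    report the bookkeeping of every stage."""
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "config": dict(config.values), "stages": {}}

    # stage 0: reference + planted truth
    ref = random_genome(int(config.genome_length), config.child_seed(0))
    ref = embed_homopolymer(ref, int(config.homopolymer_site), "C", 14)
    variants = table2_like_variants(
        ref, config.child_seed(1), homopolymer_site=int(config.homopolymer_site)
    )
    mutated, _ = plant_variants(ref, variants)
    write_fasta(outdir / "reference.fasta", [ref])
    write_variant_truth(outdir / "variant_truth.tsv", variants)

    # stage 1: simulate
    fm = FragmentModel()
    dm = DamageModel(
        library=config.library,
        p_max=config.p_max,
        p_base=config.p_base,
        decay=config.decay,
        seq_error=config.seq_error,
    )
    sim_cfg = SimConfig(
        target_depth=config.target_depth,
        seed=config.child_seed(2),
        contamination_fraction=config.contamination_fraction,
    )
    readset = simulate_readset(mutated, fm, dm, sim_cfg)
    write_fastq(outdir / "reads.fastq", readset)
    write_read_truth(outdir / "read_truth.tsv", readset)
    report["stages"]["simulate"] = {"reads": len(readset.reads)}

    # stage 2: map + dedupe + filter
    index = SeedIndex(ref, int(config.k))
    map_kwargs = dict(
        max_mismatch_frac=config.max_mismatch_frac,
        damage_tolerant=config.damage_tolerant,
        uniqueness_margin=config.uniqueness_margin,
        min_read_len=int(config.min_read_len),
    )
    alns, unmapped = map_reads(readset.reads, index, **map_kwargs)
    alns = mark_duplicates(alns)
    kept, counts = filter_alignments(alns)
    write_sam(outdir / "alignments.sam", alns, ref)
    report["stages"]["map"] = {
        "mapped": len(alns),
        "unmapped": unmapped,
        "unique_kept": counts["kept"],
        "dropped_nonunique": counts["dropped_nonunique"],
        "dropped_duplicate": counts["dropped_duplicate"],
    }

    # stage 3: damage profile
    profile = damage_profile(kept, window=int(config.window))
    write_profile(outdir / "damage_profile.tsv", profile)
    hist = read_length_histogram(kept)
    damage_stage = {
        "mean_read_length": hist["mean_length"],
        "fraction_ge_70": hist["fraction_ge_70"],
    }
    try:
        p_max, p_base, decay, resid = fit_deamination(profile, "5p")
        damage_stage.update(
            {"p_max_fit": p_max, "p_base_fit": p_base, "decay_fit": decay}
        )
    except ValueError:
        pass
    report["stages"]["damage"] = damage_stage

    # stage 4: consensus with terminal recovery + indel candidates
    cons = recover_terminal(
        readset.reads,
        ref,
        rotation_bp=int(config.rotation_bp),
        min_depth=int(config.min_depth),
        k=int(config.k),
        **map_kwargs,
    )
    indels = call_homopolymer_indels(kept, ref)
    cons = dataclasses.replace(cons, indel_candidates=indels)
    write_fasta(outdir / "consensus.fasta", [CircularSequence("consensus", cons.sequence)])
    report["stages"]["consensus"] = {
        "called_fraction": cons.called_fraction,
        "indel_candidates": len(indels),
    }

    # stage 5: compare consensus against the reference
    aln = align_pair(ref, CircularSequence("consensus", cons.sequence, circular=False))
    diffs = pairwise_differences(aln, code=config.genetic_code)
    write_differences(outdir / "differences.tsv", diffs)
    counts_d = difference_counts(diffs)
    truth_subs = {
        (v.site, v.alt) for v in variants if v.kind == "substitution"
    }
    found_subs = {(d.site, d.alt_base) for d in diffs if d.kind == "substitution"}
    recovered = len(truth_subs & found_subs)
    indel_truth = [v for v in variants if v.kind == "deletion"]
    indel_recovered = sum(
        1
        for v in indel_truth
        if any(abs(c.site - v.site) <= 14 for c in indels)
    )
    report["stages"]["compare"] = {
        **counts_d,
        "planted_variants": len(variants),
        "recovered_variants": recovered + indel_recovered,
    }

    config_out = RunConfig(dict(config.values))
    config_out.write(outdir / "run_config.txt")
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
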