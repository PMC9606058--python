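"""Post-mortem damage quantification from ungapped alignments.

Deaminated cytosines are sequenced as thymines, so degraded-DNA alignments
show an excess of C(reference)→T(read) mismatches that rises towards the
read ends.  This module tallies per-position mismatch spectra from both read
ends (conditioning each frequency on the count of the reference base at
risk, i.e. opportunities, not on all bases), summarises read lengths, and
fits the exponential end-decay model
``p(i) = p_base + (p_max - p_base) * exp(-decay * i)``
back to an observed C→T series so simulation parameters can be recovered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .mapping import AlignedRead

_BASES = "ACGT"
SUB_TYPES = [(r, q) for r in _BASES for q in _BASES if r != q]


@dataclass
class DamageProfile:
    """Per-position substitution frequencies from the 5' and 3' read ends.

    ``freq_5p[(ref, read)]`` is a length-``window`` array of mismatch
    frequencies; ``denom_5p[ref]`` the corresponding opportunity counts.
    """

    window: int
    counts_5p: dict[tuple[str, str], np.ndarray]
    counts_3p: dict[tuple[str, str], np.ndarray]
    denom_5p: dict[str, np.ndarray]
    denom_3p: dict[str, np.ndarray]

    def freq(self, end: str, ref: str, read: str) -> np.ndarray:
        counts = (self.counts_5p if end == "5p" else self.counts_3p)[(ref, read)]
        denom = (self.denom_5p if end == "5p" else self.denom_3p)[ref]
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(denom > 0, counts / np.maximum(denom, 1), 0.0)
        return f

    @property
    def freq_5p(self) -> dict[tuple[str, str], np.ndarray]:
        return {st: self.freq("5p", *st) for st in SUB_TYPES}

    @property
    def freq_3p(self) -> dict[tuple[str, str], np.ndarray]:
        return {st: self.freq("3p", *st) for st in SUB_TYPES}


def damage_profile(alignments: Sequence[AlignedRead], window: int = 25) -> DamageProfile:
    """Mismatch spectra over ``window`` positions from each read end.

    Reads shorter than ``2 * window`` contribute each base only to its nearer
    end (ties go to the 5' end), so short reads are never double counted.
    Positions are counted in the read's own orientation: for a minus-strand
    alignment the stored (reference, read) pairs are complemented and the
    read reversed, so "5' end" always means the sequenced 5' end.
    """
    c5 = {st: np.zeros(window, dtype=np.int64) for st in SUB_TYPES}
    c3 = {st: np.zeros(window, dtype=np.int64) for st in SUB_TYPES}
    d5 = {b: np.zeros(window, dtype=np.int64) for b in _BASES}
    d3 = {b: np.zeros(window, dtype=np.int64) for b in _BASES}
    comp = str.maketrans("ACGTN", "TGCAN")
    for a in alignments:
        pairs = a.matched
        if a.strand == "-":
            pairs = [(r.translate(comp), q.translate(comp)) for r, q in reversed(pairs)]
        n = len(pairs)
        for i, (r, q) in enumerate(pairs):
            if r not in _BASES or q not in _BASES:
                continue
            d5_pos = i
            d3_pos = n - 1 - i
            if d5_pos <= d3_pos:  # nearer the 5' end
                if d5_pos < window:
                    d5[r][d5_pos] += 1
                    if q != r:
                        c5[(r, q)][d5_pos] += 1
            else:
                if d3_pos < window:
                    d3[r][d3_pos] += 1
                    if q != r:
                        c3[(r, q)][d3_pos] += 1
    return DamageProfile(window, c5, c3, d5, d3)


def read_length_histogram(alignments: Sequence[AlignedRead]) -> dict:
    """Histogram of aligned read lengths: {length: (read count, total bases)},
    plus the mean length and the fraction of reads at or above 70 bp."""
    lengths = np.array([a.length for a in alignments], dtype=int)
    hist: dict[int, tuple[int, int]] = {}
    for L in sorted(set(lengths.tolist())):
        c = int((lengths == L).sum())
        hist[L] = (c, c * L)
    return {
        "histogram": hist,
        "mean_length": float(lengths.mean()) if len(lengths) else float("nan"),
        "fraction_ge_70": float((lengths >= 70).mean()) if len(lengths) else float("nan"),
        "n_reads": int(len(lengths)),
    }


def fit_deamination(
    profile: DamageProfile, end: str = "5p"
) -> tuple[float, float, float, float]:
    """Least-squares fit of the exponential end-decay model to the C→T series.

    Returns ``(p_max, p_base, decay, residual)``; for an all-zero series the
    decay is returned as ``nan`` (undefined).  Constraints: 0 <= p_base <=
    p_max <= 1, decay >= 0.
    """
    y = profile.freq(end, "C", "T")
    denom = (profile.denom_5p if end == "5p" else profile.denom_3p)["C"]
    usable = denom > 0
    if usable.sum() < 5:
        raise ValueError("need >= 5 positions with nonzero opportunities")
    x = np.arange(profile.window, dtype=float)[usable]
    y = y[usable]
    if np.all(y == 0):
        return 0.0, 0.0, float("nan"), 0.0

    def model(theta):
        p_max, p_base, decay = theta
        return p_base + (p_max - p_base) * np.exp(-decay * x)

    def resid(theta):
        return model(theta) - y

    y0 = float(y[0])
    tail = float(np.median(y[len(y) // 2 :]))
    theta0 = np.array([max(y0, tail + 1e-4, 1e-4), max(tail, 1e-6), 0.3])
    fit = least_squares(
        resid,
        theta0,
        bounds=([0.0, 0.0, 0.0], [1.0, 1.0, 20.0]),
        xtol=1e-12,
        ftol=1e-12,
    )
    p_max, p_base, decay = fit.x
    if p_base > p_max:
        p_max, p_base = p_base, p_max
    residual = float(np.sqrt(np.mean(fit.fun**2)))
    return float(p_max), float(p_base), float(decay), residual


def profile_to_frame(profile: DamageProfile) -> pd.DataFrame:
    """Long-format table of the profile: end, position, ref, read, count,
    opportunities, frequency."""
    rows = []
    for end, counts, denom in (
        ("5p", profile.counts_5p, profile.denom_5p),
        ("3p", profile.counts_3p, profile.denom_3p),
    ):
        for (r, q), arr in sorted(counts.items()):
            freqs = profile.freq(end, r, q)
            for i in range(profile.window):
                rows.append(
                    {
                        "end": end,
                        "position": i,
                        "ref": r,
                        "read": q,
                        "count": int(arr[i]),
                        "opportunities": int(denom[r][i]),
                        "frequency": float(freqs[i]),
                    }
                )
    return pd.DataFrame(rows)


def write_profile(path: str | Path, profile: DamageProfile) -> None:
    profile_to_frame(profile).to_csv(path, sep="\t", index=False)


def plot_profile(profile: DamageProfile, path: str | Path) -> None:
    """Two-panel damage plot (5' left, 3' right): C→T red, G→A blue, rest grey."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(8, 3), sharey=True)
    x = np.arange(profile.window)
    for ax, end in zip(axes, ("5p", "3p")):
        for r, q in SUB_TYPES:
            f = profile.freq(end, r, q)
            if (r, q) == ("C", "T"):
                ax.plot(x, f, color="red", lw=1.5, label="C→T")
            elif (r, q) == ("G", "A"):
                ax.plot(x, f, color="blue", lw=1.5, label="G→A")
            else:
                ax.plot(x, f, color="grey", lw=0.5)
        ax.set_xlabel(f"position from {end[0]}' end")
    axes[0].set_ylabel("mismatch frequency")
    axes[1].invert_xaxis()
    axes[0].legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
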