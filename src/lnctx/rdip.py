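"""R-loop (RDIP-seq) peak annotation.

Called peaks arrive without strand or genomic context.  This module
assigns each peak the strand carrying the majority of overlapping
strand-specific read signal, places its summit into exactly one
genomic category (exon > intron > upstream > downstream > distal,
decided at the summit so the categories partition the peak set), and
compares peak summits between two sets (e.g. R-loops vs DNA-damage
marks) against a uniform repositioning null.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import TranscriptionUnit

CATEGORIES = ("exon", "intron", "upstream", "downstream", "distal")


@dataclass(frozen=True)
class PeakRecord:
    """An interval with a summit, optional strand and genomic category."""

    chrom: str
    start: int
    end: int
    name: str = ""
    score: float = 0.0
    strand: str = "."
    summit: int = -1
    category: str | None = None

    def __post_init__(self) -> None:
        if self.summit >= 0 and not self.start <= self.summit < self.end:
            raise ValueError(f"{self.name}: summit outside [start, end)")

    @property
    def summit_pos(self) -> int:
        return self.summit if self.summit >= 0 else (self.start + self.end) // 2


def assign_peak_strand(
    peaks: Sequence[PeakRecord], stranded_track
) -> list[PeakRecord]:
    """Strand of majority overlapping read signal; ties and empty
    peaks get '.'."""
    out = []
    n_empty = 0
    for p in peaks:
        plus = float(stranded_track.region(p.chrom, p.start, p.end, "+").sum())
        minus = float(stranded_track.region(p.chrom, p.start, p.end, "-").sum())
        if plus > minus:
            strand = "+"
        elif minus > plus:
            strand = "-"
        else:
            strand = "."
            if plus == 0:
                n_empty += 1
        out.append(replace(p, strand=strand))
    assign_peak_strand.n_no_reads = n_empty  # diagnostic counter
    return out


def categorize_peaks(
    peaks: Sequence[PeakRecord],
    tus: Sequence[TranscriptionUnit],
    upstream_bp: int = 2000,
    downstream_bp: int = 2000,
) -> list[PeakRecord]:
    """Place each summit in exactly one genomic category.

    Precedence exon > intron > upstream > downstream > distal; upstream
    and downstream windows are strand-aware relative to the TU.
    """
    by_chrom: dict[str, list[TranscriptionUnit]] = {}
    for t in tus:
        by_chrom.setdefault(t.chrom, []).append(t)

    def categorize(p: PeakRecord) -> str:
        s = p.summit_pos
        cands = by_chrom.get(p.chrom, [])
        in_exon = in_tu = upstream = downstream = False
        for t in cands:
            if t.start <= s < t.end:
                in_tu = True
                if any(es <= s < ee for es, ee in t.exons):
                    in_exon = True
                    break
            else:
                if t.strand == "+":
                    up = (t.start - upstream_bp, t.start)
                    down = (t.end, t.end + downstream_bp)
                else:
                    up = (t.end, t.end + upstream_bp)
                    down = (t.start - downstream_bp, t.start)
                if up[0] <= s < up[1]:
                    upstream = True
                if down[0] <= s < down[1]:
                    downstream = True
        if in_exon:
            return "exon"
        if in_tu:
            return "intron"
        if upstream:
            return "upstream"
        if downstream:
            return "downstream"
        return "distal"

    return [replace(p, category=categorize(p)) for p in peaks]


def category_distribution(
    categorized_peaks: Sequence[PeakRecord],
    category_lengths: dict[str, float] | None = None,
    normalize_by_size: bool = False,
) -> pd.Series:
    """Fraction of peaks per category, optionally as length-normalised
    densities rescaled to sum to 1."""
    if not categorized_peaks:
        raise ValueError("empty peak set")
    counts = pd.Series(0.0, index=list(CATEGORIES))
    for p in categorized_peaks:
        if p.category not in CATEGORIES:
            raise ValueError(f"peak {p.name} is not categorized")
        counts[p.category] += 1
    frac = counts / counts.sum()
    if not normalize_by_size:
        return frac
    if category_lengths is None:
        raise ValueError("category_lengths required when normalize_by_size")
    lens = pd.Series({c: float(category_lengths[c]) for c in CATEGORIES})
    if (lens <= 0).any():
        raise ValueError("category lengths must be positive")
    dens = counts / lens
    return dens / dens.sum()


def summit_overlap(
    peaks_a: Sequence[PeakRecord],
    peaks_b: Sequence[PeakRecord],
    window_bp: int,
    n_random: int = 100,
    seed: int = 0,
    chrom_sizes: dict[str, int] | None = None,
) -> dict:
    """Fraction of A summits within ``window_bp`` of any B summit,
    with an empirical null from uniformly repositioned A summits.

    Returns observed fraction, the null distribution and the empirical
    p-value ``(1 + #null >= observed) / (n_random + 1)``.
    """
    if not peaks_a or not peaks_b:
        raise ValueError("both peak sets must be non-empty")
    b_by_chrom: dict[str, np.ndarray] = {}
    for p in peaks_b:
        b_by_chrom.setdefault(p.chrom, []).append(p.summit_pos)
    b_by_chrom = {c: np.sort(np.asarray(v)) for c, v in b_by_chrom.items()}

    def frac_near(summits: Sequence[tuple[str, int]]) -> float:
        hit = 0
        for chrom, s in summits:
            arr = b_by_chrom.get(chrom)
            if arr is None or len(arr) == 0:
                continue
            i = np.searchsorted(arr, s)
            near = []
            if i < len(arr):
                near.append(arr[i] - s)
            if i > 0:
                near.append(s - arr[i - 1])
            if near and min(near) <= window_bp:
                hit += 1
        return hit / len(summits)

    a_summits = [(p.chrom, p.summit_pos) for p in peaks_a]
    observed = frac_near(a_summits)

    if chrom_sizes is None:
        raise ValueError("chrom_sizes required for the random control")
    for c, size in chrom_sizes.items():
        if window_bp >= size:
            raise ValueError(f"window {window_bp} >= chromosome {c} ({size} bp)")
    rng = np.random.default_rng(seed)
    null = np.empty(n_random)
    chroms = [p.chrom for p in peaks_a]
    for r in range(n_random):
        rand = [(c, int(rng.integers(0, chrom_sizes[c]))) for c in chroms]
        null[r] = frac_near(rand)
    pval = (1 + int(np.sum(null >= observed))) / (n_random + 1)
    return {"observed": observed, "null": null, "pvalue": pval}


def write_categorized_bed(peaks: Sequence[PeakRecord], path: str) -> str:
    """Categorized peaks as BED with the category in the name field."""
    with open(path, "w") as fh:
        for p in sorted(peaks, key=lambda p: (p.chrom, p.start)):
            name = f"{p.name or 'peak'}|{p.category or 'NA'}"
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t{p.score:g}\t{p.strand}\n"
            )
    return path
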