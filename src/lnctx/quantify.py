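"""Region quantification, IP-minus-input normalisation, chromatin
retention index and the statistical comparisons.

All signals are normalised to 100 million paired-end reads
(``norm_factor = 1e8 / library_size``) and to the region's length in
bp, i.e. an FPKM-like unit, before taking log2.  Chromatin-mark
quantification subtracts the normalised input from the normalised IP;
regions non-positive in every sample are discarded and remaining
non-positive values are imputed at half the per-sample minimum so that
log ratios stay defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import TranscriptionUnit

SCALE = 1e8  # reference library size: 100 million read pairs


@dataclass
class RegionQuant:
    """One region x one sample quantification record."""

    chrom: str
    start: int
    end: int
    strand: str
    sample: str
    raw_base_count: float
    norm_factor: float
    length_bp: int
    value: float
    log2_value: float
    imputed: bool = False


@dataclass
class CriRecord:
    """Chromatin retention index over one PROMPT 5-kb window."""

    chrom: str
    start: int
    end: int
    strand: str
    region_id: str
    chromatin_value: float
    nucleoplasm_value: float
    cri: float
    imputed: bool = False


# -- base counting and normalisation -------------------------------------


def region_basecount(
    track, chrom: str, start: int, end: int, strand: str = "+",
    strand_mode: str = "sense",
) -> float:
    """Total per-base signal over [start, end).

    ``strand_mode``: ``sense`` counts the region's annotated strand,
    ``antisense`` the opposite one, ``both`` sums the two, and
    ``unstranded`` reads the pooled signal of an unstranded track.
    """
    if chrom not in track.chrom_sizes:
        raise KeyError(f"unknown chromosome {chrom!r}")
    if strand_mode == "unstranded" or not track.stranded:
        return float(track.region(chrom, start, end, ".").sum())
    if strand_mode == "both":
        return float(
            track.region(chrom, start, end, "+").sum()
            + track.region(chrom, start, end, "-").sum()
        )
    if strand_mode == "antisense":
        strand = "-" if strand == "+" else "+"
    elif strand_mode != "sense":
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    return float(track.region(chrom, start, end, strand).sum())


def normalize_quant(
    count: float,
    library_size: int,
    length_bp: int,
    *,
    chrom: str = "",
    start: int = 0,
    end: int = 0,
    strand: str = "+",
    sample: str = "",
) -> RegionQuant:
    """count * (1e8 / library_size) / length, with its log2.

    A non-positive value leaves ``log2_value`` as NaN; imputation is a
    set-level decision (see :func:`filter_and_impute`).
    """
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    if length_bp <= 0:
        raise ValueError("length_bp must be positive")
    nf = SCALE / library_size
    value = count * nf / length_bp
    return RegionQuant(
        chrom=chrom, start=start, end=end, strand=strand, sample=sample,
        raw_base_count=float(count), norm_factor=nf, length_bp=length_bp,
        value=value, log2_value=float(np.log2(value)) if value > 0 else float("nan"),
    )


def ip_minus_input_value(
    ip_count: float, input_count: float, ip_lib: int, input_lib: int, length_bp: int
) -> float:
    """(IP * nf_IP - Input * nf_Input) / length — one region, one sample."""
    if ip_lib <= 0 or input_lib <= 0:
        raise ValueError("library sizes must be positive")
    if length_bp <= 0:
        raise ValueError("length_bp must be positive")
    return (ip_count * SCALE / ip_lib - input_count * SCALE / input_lib) / length_bp


def filter_and_impute(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the positive-signal filter and the min/2 imputation.

    ``table`` is regions (rows) x samples (columns) of signed normalised
    values.  Rows non-positive in every sample are dropped; in each
    remaining sample column, non-positive entries are replaced by half
    the smallest positive value of that column.  Returns the imputed
    table and a same-shaped boolean mask of imputed cells.
    """
    keep = (table > 0).any(axis=1)
    out = table.loc[keep].copy()
    if out.empty:
        raise ValueError("no region has positive signal in any sample")
    mask = out <= 0
    global_pos = out.values[out.values > 0]
    for col in out.columns:
        if mask[col].any():
            pos = out.loc[out[col] > 0, col]
            # a sample can be non-positive on the whole set (a mark absent
            # from this region class); fall back to the smallest positive
            # value across all samples of the set
            floor = pos.min() if not pos.empty else global_pos.min()
            out.loc[mask[col], col] = floor / 2.0
    return out, mask


def ip_minus_input_quant(
    ip_counts: Sequence[float],
    input_counts: Sequence[float],
    ip_lib: int,
    input_lib: int,
    lengths_bp: Sequence[int],
    *,
    sample: str = "",
) -> np.ndarray:
    """Vectorised IP-minus-input values for one sample over a region set.

    The cross-sample filter/imputation contract lives in
    :func:`filter_and_impute`; assemble per-sample outputs into a
    DataFrame and pass it there.
    """
    ip = np.asarray(ip_counts, dtype=float)
    inp = np.asarray(input_counts, dtype=float)
    ln = np.asarray(lengths_bp, dtype=float)
    if np.any(ln <= 0):
        raise ValueError("region lengths must be positive")
    if ip_lib <= 0 or input_lib <= 0:
        raise ValueError("library sizes must be positive")
    return (ip * SCALE / ip_lib - inp * SCALE / input_lib) / ln


# -- quantification windows ---------------------------------------------


def class_window(tu: TranscriptionUnit, region_class: str) -> tuple[int, int]:
    """The per-class quantification window, oriented by strand.

    PROMPT: TSS to TSS+3 kb; eRNA: center +/- 2 kb; CRI window:
    TSS to TSS+5 kb; lincRNA / coding / intronless / snRNA: TSS to TES.
    Extensions run in the direction of transcription.
    """
    if region_class in ("lincRNA", "coding", "intronless", "snRNA"):
        return tu.start, tu.end
    if region_class == "PROMPT":
        ext = 3000
    elif region_class == "CRI_PROMPT":
        ext = 5000
    elif region_class == "eRNA":
        c = tu.center
        return c - 2000, c + 2000
    else:
        raise ValueError(f"unknown region class {region_class!r}")
    if tu.strand == "+":
        return tu.tss, tu.tss + ext
    return tu.tss - ext, tu.tss


# -- chromatin retention index ------------------------------------------


def chromatin_retention_index(
    chromatin_quant: RegionQuant, nucleoplasm_quant: RegionQuant
) -> CriRecord:
    """log2(chromatin / nucleoplasm) over a matched PROMPT window.

    Both inputs must be normalised quantifications of the identical
    region; non-positive values should be resolved beforehand with
    :func:`cri_table`'s pseudo-value rule.
    """
    a, b = chromatin_quant, nucleoplasm_quant
    if (a.chrom, a.start, a.end, a.strand) != (b.chrom, b.start, b.end, b.strand):
        raise ValueError("chromatin and nucleoplasm quants cover different regions")
    if a.value <= 0 or b.value <= 0:
        raise ValueError("non-positive value; apply the pseudo-value rule first")
    return CriRecord(
        chrom=a.chrom, start=a.start, end=a.end, strand=a.strand,
        region_id=a.sample or "",
        chromatin_value=a.value, nucleoplasm_value=b.value,
        cri=float(np.log2(a.value / b.value)),
        imputed=a.imputed or b.imputed,
    )


def cri_table(
    chromatin_values: pd.Series, nucleoplasm_values: pd.Series
) -> pd.DataFrame:
    """CRI across a PROMPT set with the zero-handling rule.

    Inputs are aligned Series (index = region id) of normalised values.
    Non-positive entries are replaced by half the smallest positive
    value of their own fraction and flagged.
    """
    if not chromatin_values.index.equals(nucleoplasm_values.index):
        raise ValueError("chromatin and nucleoplasm series must share their index")
    df = pd.DataFrame(
        {"chromatin": chromatin_values.astype(float),
         "nucleoplasm": nucleoplasm_values.astype(float)}
    )
    imputed = (df <= 0).any(axis=1)
    for col in df.columns:
        bad = df[col] <= 0
        if bad.any():
            pos = df.loc[~bad, col]
            if pos.empty:
                raise ValueError(f"fraction {col!r} has no positive value")
            df.loc[bad, col] = pos.min() / 2.0
    df["cri"] = np.log2(df["chromatin"] / df["nucleoplasm"])
    df["imputed"] = imputed
    return df


def mark_ratio(
    mark_value: float, denom_value: float, polii_value: float | None = None
) -> float:
    """log2 enrichment of a chromatin mark over its denominator.

    ``log2(mark / denom)``; when a Pol II level is supplied the ratio is
    first divided by it, i.e. ``log2((mark / denom) / polii)``, removing
    the transcription-level component of the mark signal.
    """
    if denom_value <= 0:
        raise ValueError("non-positive denominator; apply the imputation rule first")
    if mark_value <= 0:
        raise ValueError("non-positive mark value; apply the imputation rule first")
    ratio = mark_value / denom_value
    if polii_value is not None:
        if polii_value <= 0:
            raise ValueError("non-positive Pol II value")
        ratio /= polii_value
    return float(np.log2(ratio))


# -- genome-wide binned correlation -------------------------------------


def binned_correlation(
    tracks: Sequence, bin_bp: int = 10_000, method: str = "spearman"
) -> pd.DataFrame:
    """Pairwise correlation of genome-wide binned signal.

    Signal (both strands pooled) is summed in ``bin_bp`` bins over every
    chromosome; bins that are zero in all tracks are skipped; the
    pairwise Spearman (default) matrix is returned as a labelled
    DataFrame.
    """
    if len(tracks) < 2:
        raise ValueError("need at least two tracks")
    chroms = sorted(tracks[0].chrom_sizes)
    cols = []
    for trk in tracks:
        vals = []
        for chrom in chroms:
            size = trk.chrom_sizes[chrom]
            binned = np.zeros(-(-size // bin_bp))
            for strand in trk.strands():
                key = (chrom, strand)
                arr = trk._data.get(key)
                if arr is None:
                    continue
                if trk.bin_size != 1:
                    raise ValueError("binned_correlation expects per-base tracks")
                edges = np.arange(0, size, bin_bp)
                binned += np.add.reduceat(arr, edges)
            vals.append(binned)
        cols.append(np.concatenate(vals))
    mat = np.column_stack(cols)
    nonzero = (mat != 0).any(axis=1)
    mat = mat[nonzero]
    if mat.shape[0] < 2:
        raise ValueError("fewer than two usable bins")
    labels = [t.label or f"track{i}" for i, t in enumerate(tracks)]
    if method == "spearman":
        rho = stats.spearmanr(mat).statistic
        if np.ndim(rho) == 0:  # two tracks
            rho = np.array([[1.0, rho], [rho, 1.0]])
    elif method == "pearson":
        rho = np.corrcoef(mat, rowvar=False)
    else:
        raise ValueError(f"unknown method {method!r}")
    return pd.DataFrame(rho, index=labels, columns=labels)


# -- significance tests --------------------------------------------------


def compare_groups(
    values_a: Sequence[float], values_b: Sequence[float], paired: bool = False
) -> tuple[float, float]:
    """Wilcoxon rank-sum (unpaired) or signed-rank (paired), two-sided."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 values")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison requires equal-length groups")
        if np.all(a == b):
            raise ValueError("all paired differences are zero")
        res = stats.wilcoxon(a, b, alternative="two-sided")
    else:
        if np.all(a == a[0]) and np.all(b == a[0]):
            raise ValueError("degenerate input: all values tied")
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
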