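"""Average signal profiles around reference points or over scaled
regions, at 10-bp resolution.

Two modes mirror the standard metagene idioms: ``reference_point``
(fixed windows around anchors such as TSSs) and ``scale_regions``
(native flanks plus a gene body linearly rescaled to a fixed number of
bins).  Rows are oriented 5'->3' by strand; bins that fall off the
chromosome are missing, not zero, and are excluded from the mean so
edges are not biased downwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


@dataclass
class MetaProfile:
    mode: str  # reference_point | scale_regions
    bin_bp: int
    upstream_bp: int
    downstream_bp: int
    body_bins: int
    matrix: np.ndarray  # regions x bins, NaN for missing
    mean_profile: np.ndarray = field(init=False)
    n_skipped: int = 0

    def __post_init__(self) -> None:
        import warnings

        with warnings.catch_warnings():
            # all-missing columns legitimately yield NaN means
            warnings.simplefilter("ignore", RuntimeWarning)
            self.mean_profile = np.nanmean(self.matrix, axis=0)

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[1]

    def write_tsv(self, path: str) -> str:
        """Matrix plus mean profile as tab-separated plotting data."""
        with open(path, "w") as fh:
            header = "\t".join(f"bin{i}" for i in range(self.n_bins))
            fh.write("row\t" + header + "\n")
            for i, row in enumerate(self.matrix):
                fh.write(f"region{i}\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
            fh.write("mean\t" + "\t".join(f"{v:.6g}" for v in self.mean_profile) + "\n")
        return path


def _region_signal(track, chrom, start, end, strand, strand_mode):
    if strand_mode == "both" or not track.stranded:
        if not track.stranded:
            return track.region(chrom, start, end, ".")
        return track.region(chrom, start, end, "+") + track.region(
            chrom, start, end, "-"
        )
    if strand_mode == "antisense":
        strand = "-" if strand == "+" else "+"
    return track.region(chrom, start, end, strand)


def reference_point_profile(
    track,
    anchors: Sequence[tuple[str, int, str]],
    upstream_bp: int,
    downstream_bp: int,
    bin_bp: int = 10,
    strand_mode: str = "sense",
) -> MetaProfile:
    """Binned signal in [anchor - upstream, anchor + downstream).

    ``anchors`` are ``(chrom, position, strand)``; minus-strand windows
    are mirrored so bin 0 is always the 5'-most (upstream) bin.  Bins
    outside the chromosome are NaN; anchors entirely off-chromosome
    yield all-NaN rows and are counted in ``n_skipped``.
    """
    if not anchors:
        raise ValueError("no anchors supplied")
    if upstream_bp % bin_bp or downstream_bp % bin_bp:
        raise ValueError("window lengths must be multiples of bin_bp")
    n_bins = (upstream_bp + downstream_bp) // bin_bp
    mat = np.full((len(anchors), n_bins), np.nan)
    skipped = 0
    for i, (chrom, pos, strand) in enumerate(anchors):
        size = track.chrom_sizes.get(chrom)
        if size is None:
            skipped += 1
            continue
        if strand == "+":
            w_start = pos - upstream_bp
        else:
            w_start = pos - downstream_bp
        w_end = w_start + n_bins * bin_bp
        if w_end <= 0 or w_start >= size:
            skipped += 1
            continue
        sig = _region_signal(track, chrom, w_start, w_end, strand, strand_mode)
        row = sig.reshape(n_bins, bin_bp).sum(axis=1)
        # mark off-chromosome bins as missing
        bin_starts = w_start + np.arange(n_bins) * bin_bp
        oob = (bin_starts < 0) | (bin_starts + bin_bp > size)
        row = row.astype(float)
        row[oob] = np.nan
        if strand == "-":
            row = row[::-1]
        mat[i] = row
    return MetaProfile(
        mode="reference_point", bin_bp=bin_bp,
        upstream_bp=upstream_bp, downstream_bp=downstream_bp,
        body_bins=0, matrix=mat, n_skipped=skipped,
    )


def _rescale_body(sig: np.ndarray, body_bins: int) -> np.ndarray:
    """Mass-conserving linear rescale of per-base signal to body_bins."""
    cum = np.concatenate(([0.0], np.cumsum(sig)))
    edges = np.linspace(0, len(sig), body_bins + 1)
    cum_at = np.interp(edges, np.arange(len(sig) + 1), cum)
    return np.diff(cum_at)


def scale_regions_profile(
    track,
    regions: Sequence[tuple[str, int, int, str]],
    body_bins: int,
    upstream_bp: int,
    downstream_bp: int,
    bin_bp: int = 10,
    strand_mode: str = "sense",
) -> MetaProfile:
    """Native flanks plus a body rescaled to ``body_bins`` bins.

    ``regions`` are ``(chrom, start, end, strand)``.  Body rescaling
    interpolates the cumulative signal so total body mass is conserved.
    Regions shorter than ``body_bins`` bp are skipped and counted.
    """
    if not regions:
        raise ValueError("no regions supplied")
    if upstream_bp % bin_bp or downstream_bp % bin_bp:
        raise ValueError("flank lengths must be multiples of bin_bp")
    up_bins = upstream_bp // bin_bp
    down_bins = downstream_bp // bin_bp
    n_bins = up_bins + body_bins + down_bins
    rows = []
    skipped = 0
    for chrom, start, end, strand in regions:
        if end - start < body_bins:
            skipped += 1
            continue
        size = track.chrom_sizes.get(chrom)
        if size is None:
            skipped += 1
            continue
        w_start, w_end = start - upstream_bp, end + downstream_bp
        sig = _region_signal(track, chrom, w_start, w_end, strand, strand_mode)
        left = sig[:upstream_bp].reshape(up_bins, bin_bp).sum(axis=1) if up_bins else np.empty(0)
        right = (
            sig[upstream_bp + (end - start):].reshape(down_bins, bin_bp).sum(axis=1)
            if down_bins else np.empty(0)
        )
        body = _rescale_body(sig[upstream_bp : upstream_bp + (end - start)], body_bins)
        row = np.concatenate([left, body, right]).astype(float)
        # missing flank bins (off chromosome)
        left_starts = w_start + np.arange(up_bins) * bin_bp
        row[:up_bins][left_starts < 0] = np.nan
        right_starts = end + np.arange(down_bins) * bin_bp
        row[up_bins + body_bins :][right_starts + bin_bp > size] = np.nan
        if strand == "-":
            row = row[::-1]
        rows.append(row)
    if not rows:
        raise ValueError("every region was skipped")
    return MetaProfile(
        mode="scale_regions", bin_bp=bin_bp,
        upstream_bp=upstream_bp, downstream_bp=downstream_bp,
        body_bins=body_bins, matrix=np.vstack(rows), n_skipped=skipped,
    )
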