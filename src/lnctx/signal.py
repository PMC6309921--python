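"""Strand-specific signal tracks from paired-end alignments.

mNET-seq places RNA polymerase II at single-nucleotide resolution: the
3' end of the second mate marks the last nucleotide transcribed, while
the first mate carries the library strandedness.  RNA-seq, mNuc-seq and
ChIP-seq libraries are instead summarised as full-fragment coverage.
Both reductions land in a :class:`StrandedSignalTrack`, the common
currency of every downstream quantification.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
import pysam

STRANDS = ("+", "-")
#: placeholder strand used for unstranded (mNuc/ChIP) signal
UNSTRANDED = "."


class AlignedPair(NamedTuple):
    """A properly mated read pair reduced to its aligned spans.

    ``read1``/``read2`` are ``(start, end, strand)`` with the aligned
    span on the reference (soft-clips excluded); ``read2`` may be
    ``None`` when the mate did not align.
    """

    query_name: str
    chrom: str
    read1: tuple[int, int, str]
    read2: tuple[int, int, str] | None
    proper_pair: bool = True
    mapped: bool = True
    duplicate: bool = False


class StrandedSignalTrack:
    """Per-base signal held as one dense array per (chromosome, strand).

    Parameters
    ----------
    chrom_sizes
        Mapping chromosome name -> length in bp.
    stranded
        When False all signal is stored under the ``.`` pseudo-strand
        (mNuc-seq / ChIP-seq mode).
    library_size
        Number of retained read pairs behind the track; the
        normalisation factor used everywhere is ``scale / library_size``.
    """

    def __init__(
        self,
        chrom_sizes: dict[str, int],
        *,
        stranded: bool = True,
        library_size: int = 0,
        bin_size: int = 1,
        label: str = "",
    ) -> None:
        if bin_size < 1:
            raise ValueError(f"bin_size must be >= 1, got {bin_size}")
        self.chrom_sizes = dict(chrom_sizes)
        self.stranded = stranded
        self.library_size = library_size
        self.bin_size = bin_size
        self.label = label
        self._data: dict[tuple[str, str], np.ndarray] = {}

    # -- storage ---------------------------------------------------------

    def strands(self) -> tuple[str, ...]:
        return STRANDS if self.stranded else (UNSTRANDED,)

    def _n_bins(self, chrom: str) -> int:
        return -(-self.chrom_sizes[chrom] // self.bin_size)

    def array(self, chrom: str, strand: str) -> np.ndarray:
        """Dense (possibly binned) signal array; allocated on first use."""
        if chrom not in self.chrom_sizes:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not self.stranded:
            strand = UNSTRANDED
        if strand not in self.strands():
            raise ValueError(f"invalid strand {strand!r} for this track")
        key = (chrom, strand)
        if key not in self._data:
            self._data[key] = np.zeros(self._n_bins(chrom), dtype=np.float64)
        return self._data[key]

    def region(self, chrom: str, start: int, end: int, strand: str = "+") -> np.ndarray:
        """Per-base values over [start, end), clipped to the chromosome."""
        if self.bin_size != 1:
            raise ValueError("per-base slicing requires bin_size == 1")
        arr = self.array(chrom, strand)
        lo, hi = max(start, 0), min(end, len(arr))
        out = np.zeros(end - start, dtype=np.float64)
        if hi > lo:
            out[lo - start : hi - start] = arr[lo:hi]
        return out

    def total(self, strand: str | None = None) -> float:
        tot = 0.0
        for (_, s), arr in self._data.items():
            if strand is None or s == strand:
                tot += float(arr.sum())
        return tot

    @property
    def norm_factor(self) -> float:
        """Scale to 100 million read pairs (the unit used throughout)."""
        if self.library_size <= 0:
            raise ValueError("library_size not set on this track")
        return 1e8 / self.library_size

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"StrandedSignalTrack(label={self.label!r}, stranded={self.stranded}, "
            f"library_size={self.library_size}, bin_size={self.bin_size})"
        )


# -- pair filtering ------------------------------------------------------


def filter_proper_pairs(
    pairs: Iterable[AlignedPair], drop_duplicates: bool = False
) -> list[AlignedPair]:
    """Keep only properly paired, mapped pairs (the ``-f 3`` contract).

    With ``drop_duplicates`` (mNuc-seq / ChIP-seq mode) duplicate-flagged
    pairs are removed as well.  The length of the returned list is the
    library size to attach to tracks built from it.
    """
    kept = []
    for p in pairs:
        if not isinstance(p, AlignedPair):
            raise TypeError(f"unpaired or malformed record: {p!r}")
        if not (p.proper_pair and p.mapped):
            continue
        if drop_duplicates and p.duplicate:
            continue
        kept.append(p)
    return kept


# -- track builders ------------------------------------------------------


def extract_net_3prime(
    pairs: Sequence[AlignedPair],
    chrom_sizes: dict[str, int],
    *,
    strand_convention: str = "reverse_of_read1",
    label: str = "net3p",
) -> StrandedSignalTrack:
    """Single-nucleotide Pol II positions from mNET-seq pairs.

    Each pair contributes +1 at the 3'-terminal aligned base of read 2
    (rightmost base of a plus-strand alignment, leftmost of a minus-strand
    one).  The signal strand comes from read 1: ``reverse_of_read1``
    (dUTP-style first-strand libraries, the default) flips it,
    ``same_as_read1`` keeps it.  Pairs lacking read 2 are skipped and
    counted in ``track.n_skipped``.
    """
    if strand_convention not in ("reverse_of_read1", "same_as_read1"):
        raise ValueError(f"unknown strand convention {strand_convention!r}")
    flip = strand_convention == "reverse_of_read1"
    track = StrandedSignalTrack(chrom_sizes, stranded=True, label=label)
    # buffer positions per (chrom, strand) and commit with np.add.at
    buf: dict[tuple[str, str], list[int]] = {}
    skipped = 0
    n = 0
    for p in pairs:
        if p.read2 is None:
            skipped += 1
            continue
        r2s, r2e, r2strand = p.read2
        pos = r2e - 1 if r2strand == "+" else r2s
        s1 = p.read1[2]
        strand = ("-" if s1 == "+" else "+") if flip else s1
        buf.setdefault((p.chrom, strand), []).append(pos)
        n += 1
    for (chrom, strand), positions in buf.items():
        np.add.at(track.array(chrom, strand), np.asarray(positions, dtype=np.intp), 1.0)
    track.library_size = n
    track.n_skipped = skipped
    return track


def coverage_track(
    pairs: Sequence[AlignedPair],
    chrom_sizes: dict[str, int],
    *,
    bin_size: int = 1,
    stranded: bool = True,
    strand_convention: str = "reverse_of_read1",
    label: str = "coverage",
) -> StrandedSignalTrack:
    """Full-fragment coverage (RNA-seq / mNuc-seq / ChIP-seq reduction).

    The fragment is the union span of the two mates; every base it
    covers gains +1 (binned tracks accumulate covered bases per bin).
    Unstranded mode pools both strands, as for chromatin marks.
    """
    if bin_size < 1:
        raise ValueError(f"bin_size must be >= 1, got {bin_size}")
    flip = strand_convention == "reverse_of_read1"
    track = StrandedSignalTrack(
        chrom_sizes, stranded=stranded, bin_size=bin_size, label=label
    )
    n = 0
    for p in pairs:
        spans = [p.read1] + ([p.read2] if p.read2 is not None else [])
        frag_s = min(s for s, _, _ in spans)
        frag_e = max(e for _, e, _ in spans)
        if stranded:
            s1 = p.read1[2]
            strand = ("-" if s1 == "+" else "+") if flip else s1
        else:
            strand = UNSTRANDED
        arr = track.array(p.chrom, strand)
        if bin_size == 1:
            arr[max(frag_s, 0) : min(frag_e, len(arr))] += 1.0
        else:
            lo, hi = max(frag_s, 0), min(frag_e, track.chrom_sizes[p.chrom])
            if hi > lo:
                b0, b1 = lo // bin_size, (hi - 1) // bin_size
                for b in range(b0, b1 + 1):
                    ov = min(hi, (b + 1) * bin_size) - max(lo, b * bin_size)
                    arr[b] += ov
        n += 1
    track.library_size = n
    return track


# -- bedGraph / BED / narrowPeak I/O -------------------------------------


def write_bedgraph(
    track: StrandedSignalTrack,
    path: str,
    strand: str = "+",
    *,
    scale_to: float = 1e8,
    precision: int = 6,
) -> str:
    """Write one strand as 4-column bedGraph, library-size normalised.

    Values are ``raw * scale_to / library_size`` — the bedtools
    ``genomecov -scale`` convention.  Zero runs are omitted.
    """
    scale = scale_to / track.library_size if track.library_size > 0 else 1.0
    with open(path, "w") as fh:
        for chrom in sorted(track.chrom_sizes):
            key = (chrom, strand if track.stranded else UNSTRANDED)
            if key not in track._data:
                continue
            arr = track._data[key]
            # run-length encode
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            bs = track.bin_size
            for s, e in zip(starts, ends):
                v = arr[s]
                if v == 0:
                    continue
                fh.write(
                    f"{chrom}\t{s * bs}\t{min(e * bs, track.chrom_sizes[chrom])}\t"
                    f"{round(v * scale, precision):g}\n"
                )
    return path


def read_bedgraph(
    path: str, chrom_sizes: dict[str, int], strand: str = "+"
) -> StrandedSignalTrack:
    """Read a bedGraph back into a (single-strand) per-base track.

    The values are stored as written; ``library_size`` is set so that
    the track's norm factor is 1 (the file is already normalised).
    """
    track = StrandedSignalTrack(chrom_sizes, stranded=True, library_size=int(1e8))
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: malformed bedGraph line")
            chrom, s, e, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            track.array(chrom, strand)[s:e] += v
    return track


def read_bed(path: str) -> "pd.DataFrame":
    """Read a 3-6 column BED file into a canonical DataFrame."""
    import pandas as pd

    names = ["chrom", "start", "end", "name", "score", "strand"]
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: malformed BED line")
            parts = parts[:6] + ["."] * (6 - len(parts[:6]))
            try:
                rows.append(
                    (
                        parts[0],
                        int(parts[1]),
                        int(parts[2]),
                        parts[3],
                        0.0 if parts[4] in (".", "") else float(parts[4]),
                        parts[5] if parts[5] in ("+", "-") else ".",
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED line ({exc})")
    return pd.DataFrame(rows, columns=names)


def read_peaks(path: str) -> list:
    """Read ENCODE narrowPeak (10 columns; summit = start + 10th column)
    or plain BED (summit = interval midpoint) into PeakRecords."""
    from .rdip import PeakRecord

    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: malformed peak line")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"peak{lineno}"
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            strand = parts[5] if len(parts) > 5 and parts[5] in ("+", "-") else "."
            if len(parts) >= 10:
                offset = int(parts[9])
                summit = start + offset if offset >= 0 else (start + end) // 2
            else:
                summit = (start + end) // 2
            if not start <= summit < end:
                raise ValueError(f"{path}:{lineno}: summit outside peak")
            peaks.append(
                PeakRecord(
                    chrom=chrom, start=start, end=end, name=name,
                    score=score, strand=strand, summit=summit,
                )
            )
    return peaks


# -- SAM round trip ------------------------------------------------------


def write_sam(
    pairs: Sequence[AlignedPair], chrom_sizes: dict[str, int], path: str
) -> str:
    """Write pairs as a coordinate-sorted SAM file (simple M cigars)."""
    chroms = sorted(chrom_sizes)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": chrom_sizes[c]} for c in chroms],
    }
    tid = {c: i for i, c in enumerate(chroms)}
    segs = []
    for p in pairs:
        mates = [(p.read1, True)]
        if p.read2 is not None:
            mates.append((p.read2, False))
        for (s, e, strand), is_r1 in mates:
            a = pysam.AlignedSegment()
            a.query_name = p.query_name
            a.reference_id = tid[p.chrom]
            a.reference_start = s
            a.cigartuples = [(0, e - s)]
            a.query_sequence = "N" * (e - s)
            a.mapping_quality = 50
            flag = 0x1
            if p.proper_pair:
                flag |= 0x2
            if not p.mapped:
                flag |= 0x4
            if strand == "-":
                flag |= 0x10
            flag |= 0x40 if is_r1 else 0x80
            if p.duplicate:
                flag |= 0x400
            mate = p.read2 if is_r1 else p.read1
            if mate is not None:
                if mate[2] == "-":
                    flag |= 0x20
                a.next_reference_id = tid[p.chrom]
                a.next_reference_start = mate[0]
            else:
                flag |= 0x8
                a.next_reference_id = -1
                a.next_reference_start = -1
            a.flag = flag
            segs.append(a)
    segs.sort(key=lambda a: (a.reference_id, a.reference_start))
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for a in segs:
            out.write(a)
    return path


def read_pairs_sam(path: str) -> list[AlignedPair]:
    """Mate SAM/BAM records by query name into AlignedPairs."""
    pending: dict[str, pysam.AlignedSegment] = {}
    pairs: list[AlignedPair] = []
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for seg in fh:
            if seg.is_secondary or seg.is_supplementary:
                continue
            other = pending.pop(seg.query_name, None)
            if other is None:
                pending[seg.query_name] = seg
                continue
            r1, r2 = (seg, other) if seg.is_read1 else (other, seg)
            pairs.append(_pair_from_segments(fh, r1, r2))
    for seg in pending.values():
        # mate absent from the file: keep read1-only records
        if seg.is_read1:
            pairs.append(_pair_from_segments(None, seg, None))
    return pairs


def _pair_from_segments(fh, r1, r2) -> AlignedPair:
    def span(seg):
        return (
            seg.reference_start,
            seg.reference_end,
            "-" if seg.is_reverse else "+",
        )

    chrom = r1.reference_name if fh is None else fh.get_reference_name(r1.reference_id)
    return AlignedPair(
        query_name=r1.query_name,
        chrom=chrom,
        read1=span(r1),
        read2=span(r2) if r2 is not None and not r2.is_unmapped else None,
        proper_pair=r1.is_proper_pair,
        mapped=not r1.is_unmapped,
        duplicate=r1.is_duplicate,
    )
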