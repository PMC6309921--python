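import numpy as np
import pytest

from lnctx.signal import AlignedPair, StrandedSignalTrack


@pytest.fixture
def chrom_sizes():
    return {"chrA": 100_000, "chrB": 50_000}


@pytest.fixture
def make_track(chrom_sizes):
    """Factory for per-base tracks with values planted directly."""

    def _make(values=(), library_size=100_000_000, stranded=True):
        trk = StrandedSignalTrack(
            chrom_sizes, stranded=stranded, library_size=library_size
        )
        for chrom, strand, pos, val in values:
            trk.array(chrom, strand)[pos] += val
        return trk

    return _make


def make_pair(chrom="chrA", r2_start=100, r2_end=None, r2_strand="+",
              sig_strand=None, name="p", proper=True, mapped=True, dup=False):
    """A pair whose read-1 strand encodes the signal strand under the
    default reverse_of_read1 convention."""
    if r2_end is None:
        r2_end = r2_start + 50
    if sig_strand is None:
        sig_strand = r2_strand
    r1_strand = "-" if sig_strand == "+" else "+"
    return AlignedPair(
        query_name=name, chrom=chrom,
        read1=(max(r2_start - 200, 0), max(r2_start - 150, 50), r1_strand),
        read2=(r2_start, r2_end, r2_strand),
        proper_pair=proper, mapped=mapped, duplicate=dup,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
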