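"""Transcription-unit construction and gene-set selection.

A transcription unit (TU) collapses all transcripts of a gene into a
single span running from the 5'-most TSS to the 3'-most transcription
end site, with the union of exons.  From the TU catalogue this module
derives the gene sets used for quantification:

* non-overlapping protein-coding genes (isolated, long, and in the
  upper expression tiers of a k-means clustering of chromatin RNA
  coverage),
* intronless (single-exon) protein-coding genes excluding histones,
* PROMPT <-> nearest antisense mRNA pairs,
* divergent mRNA <-> lincRNA/antisense pairs with TSSs < 3 kb apart
  supported by a minimum number of nascent-transcription reads.

Coordinates are 0-based half-open; GTF input (1-based inclusive) is
converted on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

BIOTYPES = (
    "protein_coding",
    "lincRNA",
    "antisense",
    "snRNA",
    "histone",
    "PROMPT",
    "eRNA",
    "other",
)

#: gene-name prefixes identifying replication-dependent histone genes
HISTONE_PREFIXES = ("HIST", "H1-", "H2A-", "H2B-", "H3-", "H4-")


@dataclass(frozen=True)
class TranscriptionUnit:
    """A gene span from the 5'-most TSS to the 3'-most end site."""

    gene_id: str
    biotype: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"{self.gene_id}: unknown biotype {self.biotype!r}")
        prev = self.start
        for s, e in self.exons:
            if s < prev or e > self.end or s >= e:
                raise ValueError(f"{self.gene_id}: exons must be sorted, "
                                 "non-overlapping and contained in the span")
            prev = e

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def n_introns(self) -> int:
        return max(len(self.exons) - 1, 0)

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class GenePair:
    """Two opposite-strand TUs paired by TSS proximity."""

    kind: str  # prompt_mrna | mrna_lincrna
    partner_a: TranscriptionUnit
    partner_b: TranscriptionUnit
    tss_distance: int

    def __post_init__(self) -> None:
        if self.partner_a.strand == self.partner_b.strand:
            raise ValueError("pair partners must lie on opposite strands")
        if self.kind not in ("prompt_mrna", "mrna_lincrna"):
            raise ValueError(f"unknown pair kind {self.kind!r}")


@dataclass
class TuSetReport:
    """A named gene set plus per-filter survivor counts."""

    set_name: str
    members: list[str]
    provenance: dict[str, int] = field(default_factory=dict)

    def check_monotone(self) -> bool:
        counts = list(self.provenance.values())
        return all(a >= b for a, b in zip(counts, counts[1:]))


# -- GTF -> TUs ----------------------------------------------------------


def extract_tus(
    annotation,
    histone_prefixes: Sequence[str] = HISTONE_PREFIXES,
) -> list[TranscriptionUnit]:
    """Collapse an annotation into one TU per gene.

    ``annotation`` is a GTF path, a ``pyranges.PyRanges`` or a DataFrame
    with pyranges-style columns (Chromosome/Start/End/Strand/Feature,
    gene_id, gene_type or gene_biotype, optional gene_name).  The span
    is the min/max over the gene's exons and transcripts; exons are the
    union of transcript exons.  Genes without exon records are skipped
    with a warning.
    """
    df = _as_annotation_frame(annotation)
    biotype_col = "gene_type" if "gene_type" in df else (
        "gene_biotype" if "gene_biotype" in df else None
    )
    tus: list[TranscriptionUnit] = []
    for gene_id, g in df.groupby("gene_id", sort=True):
        exons = g[g["Feature"] == "exon"]
        if exons.empty:
            warnings.warn(f"gene {gene_id} has no exon records; skipped")
            continue
        strand = str(g["Strand"].iloc[0])
        chrom = str(g["Chromosome"].iloc[0])
        span_rows = g[g["Feature"].isin(["gene", "transcript", "exon"])]
        start = int(span_rows["Start"].min())
        end = int(span_rows["End"].max())
        merged = merge_intervals(
            list(zip(exons["Start"].astype(int), exons["End"].astype(int)))
        )
        raw_bt = str(g[biotype_col].dropna().iloc[0]) if biotype_col else "other"
        name = ""
        if "gene_name" in g:
            names = g["gene_name"].dropna()
            name = str(names.iloc[0]) if len(names) else ""
        tus.append(
            TranscriptionUnit(
                gene_id=str(gene_id),
                biotype=_normalize_biotype(raw_bt, name, histone_prefixes),
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                exons=tuple(merged),
            )
        )
    return tus


def _as_annotation_frame(annotation) -> pd.DataFrame:
    if isinstance(annotation, pd.DataFrame):
        return annotation
    if isinstance(annotation, str):
        import pyranges as pr

        try:
            return pr.read_gtf(annotation).df
        except Exception as exc:
            raise ValueError(f"could not parse GTF {annotation!r}: {exc}") from exc
    # PyRanges
    return annotation.df


def _normalize_biotype(
    raw: str, gene_name: str, histone_prefixes: Sequence[str]
) -> str:
    raw = raw.strip()
    if raw == "protein_coding":
        upper = gene_name.upper()
        if any(upper.startswith(p) for p in histone_prefixes):
            return "histone"
        return "protein_coding"
    if raw in BIOTYPES:
        return raw
    if raw in ("snRNA_pseudogene",):
        return "snRNA"
    return "other"


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of possibly-overlapping intervals, sorted."""
    ivs = sorted(intervals)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


# -- gene-set selections -------------------------------------------------


def select_nonoverlapping_coding(
    tus: Sequence[TranscriptionUnit],
    chromatin_rna_track,
    *,
    window_bp: int = 2500,
    min_len_bp: int = 2000,
    k: int = 4,
    keep_top: int = 3,
    seed: int = 0,
) -> TuSetReport:
    """Isolated, long, expressed protein-coding genes.

    A gene survives the geometric filters when no other annotated
    feature (any biotype, either strand) lies within ``window_bp`` of
    its span on either side and its TU is longer than ``min_len_bp``.
    Chromatin RNA-seq coverage (normalised base count / length,
    log2(x+1)) over survivors is clustered into ``k`` groups by k-means
    and the ``keep_top`` groups with the highest mean coverage are kept.
    """
    provenance: dict[str, int] = {"input": len(tus)}
    coding = [t for t in tus if t.biotype == "protein_coding"]
    provenance["protein_coding"] = len(coding)

    by_chrom: dict[str, list[TranscriptionUnit]] = {}
    for t in tus:
        by_chrom.setdefault(t.chrom, []).append(t)
    isolated = [
        t for t in coding
        if not any(
            o is not t and o.start < t.end + window_bp and o.end > t.start - window_bp
            for o in by_chrom[t.chrom]
        )
    ]
    provenance["isolated_2.5kb"] = len(isolated)
    long_enough = [t for t in isolated if t.length > min_len_bp]
    provenance[f"length_gt_{min_len_bp}"] = len(long_enough)

    if len(long_enough) < k:
        raise ValueError(
            f"only {len(long_enough)} genes survive the geometric filters; "
            f"need at least k={k} for clustering (lower k or relax filters)"
        )

    nf = chromatin_rna_track.norm_factor
    cov = np.array(
        [
            chromatin_rna_track.region(t.chrom, t.start, t.end, t.strand).sum()
            * nf / t.length
            for t in long_enough
        ]
    )
    if not np.any(cov > 0):
        raise ValueError("chromatin RNA track has no coverage on candidate genes")
    x = np.log2(cov + 1.0).reshape(-1, 1)

    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(x)
    means = [x[km.labels_ == c].mean() for c in range(k)]
    top = sorted(range(k), key=lambda c: means[c], reverse=True)[:keep_top]
    selected = [t for t, lab in zip(long_enough, km.labels_) if lab in top]
    provenance[f"top_{keep_top}_of_{k}_clusters"] = len(selected)
    return TuSetReport(
        set_name="nonoverlapping_coding",
        members=sorted(t.gene_id for t in selected),
        provenance=provenance,
    )


def select_intronless(tus: Sequence[TranscriptionUnit]) -> TuSetReport:
    """Single-exon protein-coding genes, histones excluded (their
    replication-coupled regulation is atypical)."""
    provenance = {"input": len(tus)}
    coding = [t for t in tus if t.biotype in ("protein_coding", "histone")]
    provenance["protein_coding_incl_histone"] = len(coding)
    single = [t for t in coding if len(t.exons) == 1]
    provenance["single_exon"] = len(single)
    kept = [t for t in single if t.biotype != "histone"]
    provenance["non_histone"] = len(kept)
    return TuSetReport(
        set_name="intronless_coding",
        members=sorted(t.gene_id for t in kept),
        provenance=provenance,
    )


def pair_prompts(
    prompts: Sequence[TranscriptionUnit], tus: Sequence[TranscriptionUnit]
) -> list[GenePair]:
    """Pair each PROMPT with the nearest opposite-strand coding gene.

    Distance is TSS-to-TSS; ties break toward the candidate with the
    smaller start coordinate.  PROMPTs with no opposite-strand coding
    gene on their chromosome are dropped with a warning.
    """
    coding_by_chrom: dict[str, list[TranscriptionUnit]] = {}
    for t in tus:
        if t.biotype == "protein_coding":
            coding_by_chrom.setdefault(t.chrom, []).append(t)
    pairs: list[GenePair] = []
    for p in prompts:
        cands = [
            t for t in coding_by_chrom.get(p.chrom, []) if t.strand != p.strand
        ]
        if not cands:
            warnings.warn(
                f"PROMPT {p.gene_id}: no opposite-strand coding gene on {p.chrom}"
            )
            continue
        best = min(cands, key=lambda t: (abs(t.tss - p.tss), t.start))
        pairs.append(
            GenePair(
                kind="prompt_mrna",
                partner_a=p,
                partner_b=best,
                tss_distance=abs(best.tss - p.tss),
            )
        )
    return pairs


def pair_mrna_lincrna(
    tus: Sequence[TranscriptionUnit],
    netseq_tracks: dict[str, "object"],
    *,
    max_tss_dist: int = 3000,
    min_reads: int = 10,
) -> list[GenePair]:
    """Divergent mRNA / lincRNA (or antisense) pairs.

    Candidates are opposite-strand (protein-coding, lincRNA|antisense)
    TUs with TSSs closer than ``max_tss_dist``.  A pair is kept when
    each partner accrues at least ``min_reads`` raw nascent-transcription
    reads over its span in at least one condition.
    """
    if len(netseq_tracks) < 1:
        raise ValueError("at least one condition track is required")
    coding = [t for t in tus if t.biotype == "protein_coding"]
    linc = [t for t in tus if t.biotype in ("lincRNA", "antisense")]

    def supported(t: TranscriptionUnit) -> bool:
        return any(
            trk.region(t.chrom, t.start, t.end, t.strand).sum() >= min_reads
            for trk in netseq_tracks.values()
        )

    pairs: list[GenePair] = []
    for m in coding:
        for l in linc:
            if l.chrom != m.chrom or l.strand == m.strand:
                continue
            d = abs(l.tss - m.tss)
            if d >= max_tss_dist:
                continue
            if supported(m) and supported(l):
                pairs.append(
                    GenePair(
                        kind="mrna_lincrna", partner_a=m, partner_b=l, tss_distance=d
                    )
                )
    return pairs


# -- output helpers ------------------------------------------------------


def tus_to_bed(tus: Sequence[TranscriptionUnit], path: str) -> str:
    """Write TUs as 6-column BED."""
    with open(path, "w") as fh:
        for t in sorted(tus, key=lambda t: (t.chrom, t.start)):
            fh.write(
                f"{t.chrom}\t{t.start}\t{t.end}\t{t.gene_id}\t0\t{t.strand}\n"
            )
    return path


def write_report(report: TuSetReport, path: str) -> str:
    """Tab-separated provenance report for a gene-set selection."""
    with open(path, "w") as fh:
        fh.write(f"# set\t{report.set_name}\n")
        for step, count in report.provenance.items():
            fh.write(f"{step}\t{count}\n")
        fh.write("members\t" + ",".join(report.members) + "\n")
    return path
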