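"""Transcription-replication collision analysis over 1-kb replication
origin windows.

Origins are classified genic/intergenic against the TU catalogue; the
nascent-transcription (Pol II) signal over each window is quantified in
the control and depleted conditions (both strands, library- and
length-normalised); origins positive in at least one condition are
retained and flagged as induced when the depleted/control ratio reaches
a fold threshold (default 2, boundary inclusive).  Proximity to
PROMPTs/eRNAs and overlap with signal-defined extended lncRNA
intervals connect induced intergenic transcription to origin firing
sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import TranscriptionUnit
from .quantify import SCALE


@dataclass
class OriginRecord:
    """One 1-kb replication-origin window and its analysis state."""

    origin_id: str
    chrom: str
    start: int
    end: int
    is_intergenic: bool | None = None
    signal_ctrl: float = float("nan")
    signal_depleted: float = float("nan")
    positive_any: bool = False
    fold_change: float = float("nan")
    induced_2x: bool = False
    nearest_ncrna: dict = field(default_factory=dict)  # class -> (gene_id, dist)
    overlaps_extended_lncrna: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


def origins_from_bed(bed: pd.DataFrame) -> list[OriginRecord]:
    """Build records from a BED DataFrame; non-1-kb windows warn."""
    records = []
    for i, row in bed.iterrows():
        if row.end - row.start != 1000:
            warnings.warn(
                f"origin {row['name']}: window is {row.end - row.start} bp, not 1 kb"
            )
        records.append(
            OriginRecord(
                origin_id=str(row["name"]) if row["name"] != "." else f"origin{i}",
                chrom=row.chrom, start=int(row.start), end=int(row.end),
            )
        )
    return records


def classify_origins(
    records: Sequence[OriginRecord], tus: Sequence[TranscriptionUnit]
) -> list[OriginRecord]:
    """Intergenic <=> the window overlaps no TU span on either strand."""
    by_chrom: dict[str, list[TranscriptionUnit]] = {}
    for t in tus:
        by_chrom.setdefault(t.chrom, []).append(t)
    for r in records:
        r.is_intergenic = not any(
            t.start < r.end and t.end > r.start for t in by_chrom.get(r.chrom, [])
        )
    return list(records)


def origin_signal(
    records: Sequence[OriginRecord], netseq_ctrl, netseq_depleted
) -> list[OriginRecord]:
    """Normalised two-condition Pol II signal per window (strands summed).

    Sets ``positive_any``; callers typically keep only positive records
    for the fold-change analysis (the returned list is unfiltered so
    partition counts stay checkable).
    """
    for trk in (netseq_ctrl, netseq_depleted):
        if trk is None:
            raise ValueError("both condition tracks are required")
    nf_c = netseq_ctrl.norm_factor
    nf_d = netseq_depleted.norm_factor
    for r in records:
        raw_c = sum(
            float(netseq_ctrl.region(r.chrom, r.start, r.end, s).sum())
            for s in netseq_ctrl.strands()
        )
        raw_d = sum(
            float(netseq_depleted.region(r.chrom, r.start, r.end, s).sum())
            for s in netseq_depleted.strands()
        )
        r.signal_ctrl = raw_c * nf_c / r.length
        r.signal_depleted = raw_d * nf_d / r.length
        r.positive_any = r.signal_ctrl > 0 or r.signal_depleted > 0
    return list(records)


def flag_induced(records: Sequence[OriginRecord], fold: float = 2.0) -> list[OriginRecord]:
    """induced <=> depleted / control >= fold (boundary inclusive).

    Zero-control windows use a pseudo-count of half the smallest
    positive control signal in the set, mirroring the quantification
    imputation rule.
    """
    if fold <= 0:
        raise ValueError("fold must be positive")
    positive = [r for r in records if r.positive_any]
    ctrl_pos = [r.signal_ctrl for r in positive if r.signal_ctrl > 0]
    pseudo = min(ctrl_pos) / 2.0 if ctrl_pos else 1.0
    for r in records:
        if not r.positive_any:
            r.fold_change = float("nan")
            r.induced_2x = False
            continue
        denom = r.signal_ctrl if r.signal_ctrl > 0 else pseudo
        r.fold_change = r.signal_depleted / denom
        r.induced_2x = r.fold_change >= fold
    return list(records)


def nearest_ncrna(
    records: Sequence[OriginRecord],
    prompts: Sequence[TranscriptionUnit],
    ernas: Sequence[TranscriptionUnit],
    max_dist: int = 100_000,
) -> list[OriginRecord]:
    """Edge-to-edge nearest PROMPT and eRNA per origin, kept when
    within ``max_dist``."""
    groups = {"PROMPT": prompts, "eRNA": ernas}
    for klass, feats in groups.items():
        if not feats:
            raise ValueError(f"empty {klass} set")
    for r in records:
        r.nearest_ncrna = {}
        for klass, feats in groups.items():
            best = None
            for t in feats:
                if t.chrom != r.chrom:
                    continue
                d = max(t.start - r.end, r.start - t.end, 0)
                if best is None or d < best[1]:
                    best = (t.gene_id, d)
            if best is not None and best[1] <= max_dist:
                r.nearest_ncrna[klass] = best
    return list(records)


def define_extended_lncrna(
    track_depleted,
    track_ctrl,
    lncrnas: Sequence[TranscriptionUnit],
    min_signal: float = 1.0,
    max_gap: int = 500,
) -> pd.DataFrame:
    """Signal-defined lncRNA extensions under the depleted condition.

    Starting at each lncRNA TSS and walking in the direction of
    transcription, a base belongs to the extension when the normalised
    depleted signal reaches ``min_signal`` and exceeds the control
    signal; gaps up to ``max_gap`` bp are bridged.  Each lncRNA yields
    one interval covering at least its annotated span.
    """
    nf_d = track_depleted.norm_factor
    nf_c = track_ctrl.norm_factor
    rows = []
    for t in lncrnas:
        size = track_depleted.chrom_sizes[t.chrom]
        if t.strand == "+":
            scan_s, scan_e = t.tss, size
        else:
            scan_s, scan_e = 0, t.tss
        dep = track_depleted.region(t.chrom, scan_s, scan_e, t.strand) * nf_d
        ctl = track_ctrl.region(t.chrom, scan_s, scan_e, t.strand) * nf_c
        ok = (dep >= min_signal) & (dep > ctl)
        if t.strand == "-":
            ok = ok[::-1]  # walk 5'->3'
        idx = np.flatnonzero(ok)
        reach = 0
        last = -1
        for i in idx:
            if i - last > max_gap:
                break
            reach = i + 1
            last = i
        if t.strand == "+":
            ext_start, ext_end = t.start, max(t.end, t.tss + reach)
            ext_end = min(ext_end, size)
        else:
            ext_start, ext_end = min(t.start, t.tss - reach), t.end
            ext_start = max(ext_start, 0)
        rows.append(
            {
                "gene_id": t.gene_id, "chrom": t.chrom,
                "start": int(ext_start), "end": int(ext_end),
                "strand": t.strand,
                "extension_bp": int(ext_end - ext_start) - t.length,
            }
        )
    return pd.DataFrame(rows)


def origin_lncrna_overlap(
    records: Sequence[OriginRecord], extended: pd.DataFrame
) -> float:
    """Fraction of origins whose window intersects any extended-lncRNA
    interval; also sets ``overlaps_extended_lncrna`` per record."""
    if not records:
        raise ValueError("empty origin set")
    ivs: dict[str, list[tuple[int, int]]] = {}
    for _, row in extended.iterrows():
        ivs.setdefault(row.chrom, []).append((row.start, row.end))
    n_hit = 0
    for r in records:
        hit = any(s < r.end and e > r.start for s, e in ivs.get(r.chrom, []))
        r.overlaps_extended_lncrna = hit
        n_hit += hit
    return n_hit / len(records)


def origin_report(records: Sequence[OriginRecord]) -> pd.DataFrame:
    """One row per origin, for the tab-separated report."""
    rows = []
    for r in records:
        near_p = r.nearest_ncrna.get("PROMPT")
        near_e = r.nearest_ncrna.get("eRNA")
        rows.append(
            {
                "origin_id": r.origin_id, "chrom": r.chrom,
                "start": r.start, "end": r.end,
                "is_intergenic": r.is_intergenic,
                "signal_ctrl": r.signal_ctrl,
                "signal_depleted": r.signal_depleted,
                "positive_any": r.positive_any,
                "fold_change": r.fold_change,
                "induced_2x": r.induced_2x,
                "nearest_prompt": near_p[0] if near_p else "",
                "nearest_prompt_dist": near_p[1] if near_p else -1,
                "nearest_erna": near_e[0] if near_e else "",
                "nearest_erna_dist": near_e[1] if near_e else -1,
                "overlaps_extended_lncrna": r.overlaps_extended_lncrna,
            }
        )
    return pd.DataFrame(rows)
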