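"""Synthetic genome, annotation, alignments, peaks and origins with
known ground truth.

The generator emulates the statistical structure of a two-condition
nascent-transcription experiment in which depletion of an elongation
factor induces lncRNA classes while protein-coding transcription is
redistributed 5'-wards:

* region-class-specific expression rates with protein-coding genes
  dominating the library (lncRNA classes are a few percent of nascent
  signal, as in real cells);
* condition-specific fold changes on PROMPTs, eRNAs and lincRNAs, and
  an optional 5'->3' exponential decay of coding-gene 3' ends in the
  depleted condition (the elongation defect);
* termination-defect "extensions": a configurable fraction of lncRNAs
  transcribe tens of kb past their annotated end in the depleted
  condition only;
* chromatin / nucleoplasm partitioning ratios per class;
* IP enrichment folds over a uniform input for chromatin marks;
* R-loop peaks planted in known genomic categories with known strands,
  DNA-damage peaks co-located with a known fraction of their summits,
  and 1-kb replication origins planted genic/intergenic, a subset under
  lncRNA extensions (these acquire induced Pol II signal).

Counts are multinomial at the configured sequencing depth (Poisson
rates conditioned on the library total, so every library has exactly
``depth`` pairs); positions are uniform within regions except for the
coding-gene decay.  Identical configs (including seeds) give identical
output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import TranscriptionUnit
from .signal import AlignedPair


@dataclass
class SimConfig:
    """All knobs of the synthetic experiment; defaults are the study
    conditions every recovery test runs under."""

    seed: int = 0
    n_chromosomes: int = 3
    chrom_length_bp: int = 2_000_000

    # region counts
    n_coding: int = 50
    n_intronless: int = 8
    n_histone: int = 5
    n_lincrna: int = 10
    n_snrna: int = 5
    n_prompt: int = 20
    n_erna: int = 20
    n_origins: int = 100
    n_rdip_peaks: int = 200

    # geometry (bp)
    coding_len_range: tuple[int, int] = (6000, 12000)
    coding_n_exons: int = 3
    intronless_len: int = 2500
    histone_len: int = 1500
    lincrna_len: int = 3000
    snrna_len: int = 200
    prompt_len: int = 1000
    erna_len: int = 1000
    gap_range: tuple[int, int] = (6000, 18000)
    prompt_offset_bp: int = 60
    lincrna_tss_offset_bp: int = 500
    fragment_len: int = 150
    read_len: int = 50

    # expression rates (relative library weights per region)
    coding_rate: float = 100.0
    intronless_rate: float = 50.0
    histone_rate: float = 20.0
    lincrna_rate: float = 2.0
    snrna_rate: float = 5.0
    prompt_rate: float = 2.0
    erna_rate: float = 1.0
    origin_rate: float = 0.5  # faint intergenic transcription per origin window

    # depleted-condition multipliers (assigned cyclically per class)
    prompt_folds: tuple[float, ...] = (4.0,)
    erna_folds: tuple[float, ...] = (4.0,)
    lincrna_folds: tuple[float, ...] = (2.0,)
    coding_depleted_multiplier: float = 1.0
    coding_decay_bp: float = 2000.0  # 0 disables the elongation-defect decay

    # termination-defect extensions (depleted condition only)
    frac_extended: float = 0.5
    extension_bp: int = 20_000
    extension_density_mult: float = 0.3  # readthrough density vs gene body

    # chromatin / nucleoplasm partitioning (chromatin:nucleoplasm ratio)
    retention_ratios: dict = field(
        default_factory=lambda: {"PROMPT": 2.0, "eRNA": 2.0, "lincRNA": 2.0}
    )
    default_retention: float = 1.0

    # IP enrichment folds over input, per mark, class and condition
    ip_enrichment: dict = field(
        default_factory=lambda: {
            "H3K36me3": {
                "control": {"protein_coding": 8.0, "intronless": 8.0},
                "depleted": {
                    "protein_coding": 2.0, "intronless": 2.0,
                    "PROMPT": 4.0, "eRNA": 4.0, "lincRNA": 2.0,
                },
            }
        }
    )
    duplicate_fraction: float = 0.0

    # origins
    frac_origins_intergenic: float = 0.8
    frac_origins_in_extension: float = 0.4  # of the intergenic ones
    origin_induced_fold: float = 4.0
    n_origins_induced: int | None = None  # explicit planting overrides extensions

    # RDIP / damage peaks
    rdip_category_probs: dict = field(
        default_factory=lambda: {
            "exon": 0.25, "intron": 0.30, "upstream": 0.20,
            "downstream": 0.10, "distal": 0.15,
        }
    )
    rdip_peak_halfwidth: int = 150
    gamma_colocal_frac: float = 0.8
    gamma_jitter_bp: int = 100
    n_gamma_extra: int = 40

    strand_convention: str = "reverse_of_read1"

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length_bp for i in range(self.n_chromosomes)}


@dataclass
class GroundTruth:
    """Planted regions, rates and flags that recovery tests assert
    against.  ``regions`` has one row per transcribed unit (including
    the faint per-origin background); peaks and origins are attached by
    :func:`simulate_peaks_and_origins`."""

    config: SimConfig
    regions: pd.DataFrame
    extensions: pd.DataFrame
    origins: pd.DataFrame | None = None
    rdip_peaks: pd.DataFrame | None = None
    gamma_peaks: pd.DataFrame | None = None

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return self.config.chrom_sizes

    def tus(self, classes: tuple[str, ...] | None = None) -> list[TranscriptionUnit]:
        """Regions as TranscriptionUnit objects (gene classes only by
        default; PROMPT/eRNA on request)."""
        if classes is None:
            classes = ("protein_coding", "intronless", "histone", "lincRNA", "snRNA")
        out = []
        for _, r in self.regions.iterrows():
            if r["klass"] not in classes:
                continue
            biotype = {
                "intronless": "protein_coding",
                "origin_bg": "other",
            }.get(r["klass"], r["klass"])
            exons = tuple(
                tuple(map(int, part.split("-")))
                for part in str(r["exons"]).split(",")
                if part
            )
            out.append(
                TranscriptionUnit(
                    gene_id=r["region_id"], biotype=biotype, chrom=r["chrom"],
                    start=int(r["start"]), end=int(r["end"]), strand=r["strand"],
                    exons=exons or ((int(r["start"]), int(r["end"])),),
                )
            )
        return out

    def prompts(self) -> list[TranscriptionUnit]:
        return self.tus(classes=("PROMPT",))

    def ernas(self) -> list[TranscriptionUnit]:
        return self.tus(classes=("eRNA",))

    def write(self, outdir: str) -> dict[str, str]:
        """All truth tables as TSV; annotation/BED writers are separate."""
        import os

        os.makedirs(outdir, exist_ok=True)
        paths = {}
        for name in ("regions", "extensions", "origins", "rdip_peaks", "gamma_peaks"):
            df = getattr(self, name)
            if df is None:
                continue
            p = os.path.join(outdir, f"truth_{name}.tsv")
            df.to_csv(p, sep="\t", index=False)
            paths[name] = p
        return paths


# -- annotation layout ---------------------------------------------------


def make_annotation(config: SimConfig) -> GroundTruth:
    """Lay the synthetic genome out and plant per-region rates.

    Features are placed left to right with random inter-feature gaps,
    round-robin across chromosomes.  PROMPTs sit divergently upstream
    of the first ``n_prompt`` coding TSSs; paired lincRNAs divergently
    upstream of the next ``n_lincrna``; eRNAs and the remaining gene
    classes are standalone.  Raises when the requested features do not
    fit the genome.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    chroms = list(cfg.chrom_sizes)
    cursors = {c: 50_000 for c in chroms}
    rows: list[dict] = []

    def place(chrom: str, length: int) -> int:
        gap = int(rng.integers(cfg.gap_range[0], cfg.gap_range[1] + 1))
        start = cursors[chrom] + gap
        if start + length > cfg.chrom_length_bp - 50_000:
            raise ValueError(
                "synthetic genome too small for the requested feature counts; "
                "increase chrom_length_bp or n_chromosomes"
            )
        cursors[chrom] = start + length
        return start

    def cyc(folds: tuple[float, ...], i: int) -> float:
        return float(folds[i % len(folds)]) if folds else 1.0

    def add_region(region_id, klass, chrom, start, end, strand, exons,
                   base_rate, depleted_fold, retention=None):
        rows.append(
            {
                "region_id": region_id, "klass": klass, "chrom": chrom,
                "start": int(start), "end": int(end), "strand": strand,
                "exons": ",".join(f"{s}-{e}" for s, e in exons),
                "base_rate": float(base_rate),
                "depleted_fold": float(depleted_fold),
                "retention_ratio": float(
                    retention
                    if retention is not None
                    else cfg.retention_ratios.get(klass, cfg.default_retention)
                ),
                "extended": False,
                "ext_start": -1, "ext_end": -1,
            }
        )

    def coding_exons(start: int, end: int, n_exons: int) -> list[tuple[int, int]]:
        if n_exons <= 1:
            return [(start, end)]
        length = end - start
        cuts = np.sort(rng.integers(1, length, size=2 * (n_exons - 1)))
        bounds = [start] + [start + int(c) for c in cuts] + [end]
        exons = [(bounds[2 * i], bounds[2 * i + 1]) for i in range(n_exons)]
        return [(s, e) for s, e in exons if e > s] or [(start, end)]

    ci = 0  # round-robin chromosome index

    def next_chrom() -> str:
        nonlocal ci
        c = chroms[ci % len(chroms)]
        ci += 1
        return c

    # coding genes, with divergent PROMPT / lincRNA partners in the gaps
    for i in range(cfg.n_coding):
        chrom = next_chrom()
        length = int(rng.integers(*cfg.coding_len_range))
        start = place(chrom, length)
        strand = "+" if rng.random() < 0.5 else "-"
        exons = coding_exons(start, start + length, cfg.coding_n_exons)
        add_region(f"gene{i:03d}", "protein_coding", chrom, start, start + length,
                   strand, exons, cfg.coding_rate, cfg.coding_depleted_multiplier)
        tss = start if strand == "+" else start + length
        if i < cfg.n_prompt:
            ps = "-" if strand == "+" else "+"
            if strand == "+":
                pe = tss - cfg.prompt_offset_bp
                pstart, pend = pe - cfg.prompt_len, pe
            else:
                pstart = tss + cfg.prompt_offset_bp
                pend = pstart + cfg.prompt_len
            add_region(f"prompt{i:03d}", "PROMPT", chrom, pstart, pend, ps,
                       [(pstart, pend)], cfg.prompt_rate,
                       cyc(cfg.prompt_folds, i))
        elif i < cfg.n_prompt + cfg.n_lincrna:
            j = i - cfg.n_prompt
            ls = "-" if strand == "+" else "+"
            if strand == "+":
                le = tss - cfg.lincrna_tss_offset_bp
                lstart, lend = le - cfg.lincrna_len, le
            else:
                lstart = tss + cfg.lincrna_tss_offset_bp
                lend = lstart + cfg.lincrna_len
            add_region(f"linc{j:03d}", "lincRNA", chrom, lstart, lend, ls,
                       [(lstart, lend)], cfg.lincrna_rate,
                       cyc(cfg.lincrna_folds, j))

    for i in range(cfg.n_intronless):
        chrom = next_chrom()
        start = place(chrom, cfg.intronless_len)
        strand = "+" if rng.random() < 0.5 else "-"
        add_region(f"intronless{i:02d}", "intronless", chrom, start,
                   start + cfg.intronless_len, strand,
                   [(start, start + cfg.intronless_len)],
                   cfg.intronless_rate, cfg.coding_depleted_multiplier)
    for i in range(cfg.n_histone):
        chrom = next_chrom()
        start = place(chrom, cfg.histone_len)
        strand = "+" if rng.random() < 0.5 else "-"
        add_region(f"histone{i:02d}", "histone", chrom, start,
                   start + cfg.histone_len, strand,
                   [(start, start + cfg.histone_len)], cfg.histone_rate, 1.0)
    for i in range(cfg.n_snrna):
        chrom = next_chrom()
        start = place(chrom, cfg.snrna_len)
        strand = "+" if rng.random() < 0.5 else "-"
        add_region(f"snrna{i:02d}", "snRNA", chrom, start,
                   start + cfg.snrna_len, strand,
                   [(start, start + cfg.snrna_len)], cfg.snrna_rate, 1.0)
    for i in range(cfg.n_erna):
        chrom = next_chrom()
        start = place(chrom, cfg.erna_len)
        strand = "+" if rng.random() < 0.5 else "-"
        add_region(f"erna{i:03d}", "eRNA", chrom, start,
                   start + cfg.erna_len, strand,
                   [(start, start + cfg.erna_len)], cfg.erna_rate,
                   cyc(cfg.erna_folds, i))

    regions = pd.DataFrame(
        rows,
        columns=[
            "region_id", "klass", "chrom", "start", "end", "strand", "exons",
            "base_rate", "depleted_fold", "retention_ratio",
            "extended", "ext_start", "ext_end",
        ],
    )

    # termination-defect extensions on a fraction of PROMPTs/eRNAs
    extensions = []
    lnc_idx = regions.index[regions["klass"].isin(["PROMPT", "eRNA"])].tolist()
    n_ext = int(round(cfg.frac_extended * len(lnc_idx)))
    for idx in lnc_idx[:n_ext]:
        r = regions.loc[idx]
        size = cfg.chrom_length_bp
        if r["strand"] == "+":
            es, ee = int(r["end"]), int(min(r["end"] + cfg.extension_bp, size))
        else:
            es, ee = int(max(r["start"] - cfg.extension_bp, 0)), int(r["start"])
        regions.loc[idx, ["extended", "ext_start", "ext_end"]] = [True, es, ee]
        extensions.append(
            {"gene_id": r["region_id"], "chrom": r["chrom"],
             "start": es, "end": ee, "strand": r["strand"]}
        )
    ext_df = pd.DataFrame(
        extensions, columns=["gene_id", "chrom", "start", "end", "strand"]
    )
    return GroundTruth(config=cfg, regions=regions, extensions=ext_df)


# -- peaks and origins ---------------------------------------------------


def simulate_peaks_and_origins(truth: GroundTruth, config: SimConfig | None = None) -> GroundTruth:
    """Plant R-loop peaks, co-located DNA-damage peaks and replication
    origins; adds per-origin background-transcription rows to the
    region table so origin Pol II signal flows through the read
    simulators."""
    cfg = config or truth.config
    rng = np.random.default_rng(cfg.seed + 1)
    regions = truth.regions
    genes = regions[
        regions["klass"].isin(
            ["protein_coding", "intronless", "histone", "lincRNA", "snRNA"]
        )
    ]
    gene_ivs: dict[str, list[tuple[int, int]]] = {}
    for _, g in genes.iterrows():
        gene_ivs.setdefault(g["chrom"], []).append((int(g["start"]), int(g["end"])))
    for c in gene_ivs:
        gene_ivs[c].sort()

    def in_any_gene(chrom, pos, margin=0):
        return any(s - margin <= pos < e + margin for s, e in gene_ivs.get(chrom, []))

    # ---- RDIP peaks by category, exact planted counts
    cats, probs = zip(*cfg.rdip_category_probs.items())
    counts = [int(round(p * cfg.n_rdip_peaks)) for p in probs]
    counts[-1] = cfg.n_rdip_peaks - sum(counts[:-1])
    multi_exon = genes[genes["exons"].str.contains(",")]
    peak_rows = []

    def sample_summit(cat: str) -> tuple[str, int, str]:
        for _ in range(1000):
            if cat in ("exon", "intron"):
                g = genes.iloc[int(rng.integers(len(genes)))]
                exons = [tuple(map(int, p.split("-"))) for p in g["exons"].split(",")]
                if cat == "exon":
                    es, ee = exons[int(rng.integers(len(exons)))]
                    return g["chrom"], int(rng.integers(es, ee)), g["strand"]
                if len(exons) < 2:
                    continue
                j = int(rng.integers(len(exons) - 1))
                is_, ie_ = exons[j][1], exons[j + 1][0]
                if ie_ - is_ < 4:
                    continue
                return g["chrom"], int(rng.integers(is_ + 1, ie_ - 1)), g["strand"]
            if cat in ("upstream", "downstream"):
                g = genes.iloc[int(rng.integers(len(genes)))]
                tss = g["start"] if g["strand"] == "+" else g["end"]
                tes = g["end"] if g["strand"] == "+" else g["start"]
                anchor = tss if cat == "upstream" else tes
                sign = -1 if (cat == "upstream") == (g["strand"] == "+") else 1
                off = int(rng.integers(200, 1800))
                pos = anchor + sign * off
                if in_any_gene(g["chrom"], pos):
                    continue
                # precedence: a downstream summit must not sit in anyone's
                # upstream window; an upstream one is safe by precedence
                if cat == "downstream" and _in_any_flank(
                    genes, g["chrom"], pos, "upstream", 2000
                ):
                    continue
                if cat == "upstream" and not _in_any_flank(
                    genes, g["chrom"], pos, "upstream", 2000
                ):
                    continue
                strand = "+" if rng.random() < 0.5 else "-"
                return g["chrom"], pos, strand
            # distal
            chrom = f"chr{int(rng.integers(cfg.n_chromosomes)) + 1}"
            pos = int(rng.integers(10_000, cfg.chrom_length_bp - 10_000))
            if in_any_gene(chrom, pos, margin=2100):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            return chrom, pos, strand
        raise RuntimeError(f"could not place a {cat} peak; genome too crowded")

    pid = 0
    for cat, n in zip(cats, counts):
        for _ in range(n):
            chrom, summit, strand = sample_summit(cat)
            hw = cfg.rdip_peak_halfwidth
            peak_rows.append(
                {
                    "peak_id": f"rdip{pid:04d}", "chrom": chrom,
                    "start": max(summit - hw, 0), "end": summit + hw,
                    "summit": summit, "strand": strand, "category": cat,
                }
            )
            pid += 1
    rdip = pd.DataFrame(peak_rows)

    # ---- DNA-damage peaks co-located with a planted fraction of summits
    n_co = int(round(cfg.gamma_colocal_frac * len(rdip)))
    order = rng.permutation(len(rdip))
    gamma_rows = []
    rdip_summits = {
        c: np.sort(rdip.loc[rdip["chrom"] == c, "summit"].to_numpy())
        for c in rdip["chrom"].unique()
    }
    for k, i in enumerate(order[:n_co]):
        r = rdip.iloc[i]
        summit = int(r["summit"] + rng.integers(-cfg.gamma_jitter_bp,
                                                cfg.gamma_jitter_bp + 1))
        gamma_rows.append(
            {"peak_id": f"gamma{k:04d}", "chrom": r["chrom"],
             "start": summit - 200, "end": summit + 200, "summit": summit,
             "colocated": True}
        )
    k = n_co
    while k < n_co + cfg.n_gamma_extra:
        chrom = f"chr{int(rng.integers(cfg.n_chromosomes)) + 1}"
        pos = int(rng.integers(10_000, cfg.chrom_length_bp - 10_000))
        arr = rdip_summits.get(chrom, np.empty(0))
        if len(arr):
            j = np.searchsorted(arr, pos)
            dists = []
            if j < len(arr):
                dists.append(abs(int(arr[j]) - pos))
            if j > 0:
                dists.append(abs(pos - int(arr[j - 1])))
            if dists and min(dists) < 5000:
                continue
        gamma_rows.append(
            {"peak_id": f"gamma{k:04d}", "chrom": chrom,
             "start": pos - 200, "end": pos + 200, "summit": pos,
             "colocated": False}
        )
        k += 1
    gamma = pd.DataFrame(gamma_rows)

    # ---- replication origins
    ext = truth.extensions
    n_intergenic = int(round(cfg.frac_origins_intergenic * cfg.n_origins))
    n_genic = cfg.n_origins - n_intergenic
    origin_rows = []
    oid = 0

    def add_origin(chrom, start, intergenic, in_extension):
        nonlocal oid
        origin_rows.append(
            {"origin_id": f"ori{oid:03d}", "chrom": chrom,
             "start": int(start), "end": int(start) + 1000,
             "is_intergenic": intergenic, "in_extension": in_extension}
        )
        oid += 1

    # intergenic origins under planted extensions
    n_in_ext = min(int(round(cfg.frac_origins_in_extension * n_intergenic)), len(ext))
    placed_ext = 0
    for _, e in ext.iterrows():
        if placed_ext >= n_in_ext:
            break
        # find a 1-kb sub-window of the extension clear of genes
        for _ in range(200):
            if e["end"] - e["start"] < 1200:
                break
            s = int(rng.integers(e["start"], e["end"] - 1000))
            if not any(
                gs < s + 1000 and ge > s for gs, ge in gene_ivs.get(e["chrom"], [])
            ):
                add_origin(e["chrom"], s, True, True)
                placed_ext += 1
                break

    # plain intergenic origins: mid-gap positions away from extensions
    ext_ivs: dict[str, list[tuple[int, int]]] = {}
    for _, e in ext.iterrows():
        ext_ivs.setdefault(e["chrom"], []).append((int(e["start"]), int(e["end"])))
    tries = 0
    while oid < placed_ext + (n_intergenic - n_in_ext):
        tries += 1
        if tries > 20_000:
            raise ValueError("could not place intergenic origins; genome too crowded")
        chrom = f"chr{int(rng.integers(cfg.n_chromosomes)) + 1}"
        s = int(rng.integers(10_000, cfg.chrom_length_bp - 11_000))
        if any(gs < s + 1000 and ge > s for gs, ge in gene_ivs.get(chrom, [])):
            continue
        if any(es < s + 1000 and ee > s for es, ee in ext_ivs.get(chrom, [])):
            continue
        if any(
            o["chrom"] == chrom and abs(o["start"] - s) < 2000 for o in origin_rows
        ):
            continue
        add_origin(chrom, s, True, False)

    # genic origins inside coding gene bodies
    big_genes = genes[genes["end"] - genes["start"] >= 3000]
    for i in range(n_genic):
        g = big_genes.iloc[int(rng.integers(len(big_genes)))]
        s = int(rng.integers(g["start"] + 500, g["end"] - 1500))
        add_origin(g["chrom"], s, False, False)

    origins = pd.DataFrame(origin_rows)

    # induced flags: explicit planting wins, else extensions decide
    if cfg.n_origins_induced is not None:
        inter = origins.index[origins["is_intergenic"]].tolist()
        induced_idx = set(inter[: cfg.n_origins_induced])
        origins["induced"] = [i in induced_idx for i in origins.index]
    else:
        origins["induced"] = origins["in_extension"]

    # faint intergenic transcription over every origin window; explicitly
    # induced origins get the planted fold, extension-covered ones get
    # their extra signal from the extension reads instead
    bg_rows = []
    for _, o in origins.iterrows():
        fold = (
            cfg.origin_induced_fold
            if (cfg.n_origins_induced is not None and o["induced"])
            else 1.0
        )
        bg_rows.append(
            {
                "region_id": f"{o['origin_id']}_bg", "klass": "origin_bg",
                "chrom": o["chrom"], "start": o["start"], "end": o["end"],
                "strand": "+" if rng.random() < 0.5 else "-",
                "exons": f"{o['start']}-{o['end']}",
                "base_rate": cfg.origin_rate, "depleted_fold": fold,
                "retention_ratio": cfg.default_retention,
                "extended": False, "ext_start": -1, "ext_end": -1,
            }
        )
    truth.regions = pd.concat(
        [regions, pd.DataFrame(bg_rows)], ignore_index=True
    )
    truth.origins = origins
    truth.rdip_peaks = rdip
    truth.gamma_peaks = gamma
    return truth


def _in_any_flank(genes: pd.DataFrame, chrom: str, pos: int, side: str, win: int) -> bool:
    for _, g in genes[genes["chrom"] == chrom].iterrows():
        tss = g["start"] if g["strand"] == "+" else g["end"]
        tes = g["end"] if g["strand"] == "+" else g["start"]
        anchor = tss if side == "upstream" else tes
        sign = -1 if (side == "upstream") == (g["strand"] == "+") else 1
        lo, hi = sorted((anchor, anchor + sign * win))
        if lo <= pos < hi:
            return True
    return False


# -- read simulation -----------------------------------------------------


def _emission_components(truth: GroundTruth, condition: str) -> pd.DataFrame:
    """One weighted emission component per region (plus one per
    extension in the depleted condition)."""
    cfg = truth.config
    rows = []
    for _, r in truth.regions.iterrows():
        mult = 1.0 if condition == "control" else float(r["depleted_fold"])
        rows.append(
            {
                "region_id": r["region_id"], "klass": r["klass"],
                "chrom": r["chrom"], "start": int(r["start"]), "end": int(r["end"]),
                "strand": r["strand"], "weight": float(r["base_rate"]) * mult,
                "decay": (
                    cfg.coding_decay_bp
                    if condition == "depleted"
                    and r["klass"] in ("protein_coding", "intronless")
                    and cfg.coding_decay_bp > 0
                    else 0.0
                ),
            }
        )
        if condition == "depleted" and bool(r["extended"]):
            length = int(r["end"]) - int(r["start"])
            ext_len = int(r["ext_end"]) - int(r["ext_start"])
            w = (
                float(r["base_rate"]) * float(r["depleted_fold"])
                * (ext_len / length) * cfg.extension_density_mult
            )
            rows.append(
                {
                    "region_id": f"{r['region_id']}_ext", "klass": "extension",
                    "chrom": r["chrom"], "start": int(r["ext_start"]),
                    "end": int(r["ext_end"]), "strand": r["strand"],
                    "weight": w, "decay": 0.0,
                }
            )
    return pd.DataFrame(rows)


def _positions_in_component(rng, comp, n: int) -> np.ndarray:
    """Sample n single-nucleotide positions within a component."""
    start, end = comp["start"], comp["end"]
    if comp["decay"] > 0:
        # truncated exponential from the TSS (elongation defect)
        L = end - start
        tau = comp["decay"]
        u = rng.random(n)
        x = -tau * np.log1p(-u * (1.0 - np.exp(-L / tau)))
        x = np.minimum(x.astype(np.int64), L - 1)
        if comp["strand"] == "+":
            return start + x
        return end - 1 - x
    return rng.integers(start, end, size=n)


def _pairs_from_positions(
    positions: np.ndarray, chrom: str, sig_strand: str, cfg: SimConfig,
    qprefix: str, start_index: int, flip: bool,
) -> list[AlignedPair]:
    """Build proper pairs whose read-2 3' end hits each position and
    whose read-1 strand encodes the signal strand under the configured
    convention."""
    rl, fl = cfg.read_len, cfg.fragment_len
    size = cfg.chrom_length_bp
    pairs = []
    r1_strand = (
        ("-" if sig_strand == "+" else "+") if flip else sig_strand
    )
    for k, p in enumerate(positions):
        p = int(p)
        if sig_strand == "+":
            r2 = (max(p - rl + 1, 0), p + 1, "+")
            f_lo = max(p - fl + 1, 0)
            r1 = (f_lo, min(f_lo + rl, size), r1_strand)
        else:
            r2 = (p, min(p + rl, size), "-")
            f_hi = min(p + fl, size)
            r1 = (max(f_hi - rl, 0), f_hi, r1_strand)
        pairs.append(
            AlignedPair(
                query_name=f"{qprefix}{start_index + k}", chrom=chrom,
                read1=r1, read2=r2,
            )
        )
    return pairs


def simulate_netseq(
    truth: GroundTruth, condition: str, depth: int, seed: int
) -> list[AlignedPair]:
    """Nascent-transcription pairs: 3' positions per region drawn from
    class rate x condition multiplier (uniform within regions, 5'->3'
    exponential decay for coding genes in the depleted condition,
    uniform over extension footprints for extended lncRNAs).  Exactly
    ``depth`` pairs are emitted."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    if condition not in ("control", "depleted"):
        raise ValueError(f"unknown condition {condition!r}")
    cfg = truth.config
    comps = _emission_components(truth, condition)
    comps = comps[comps["weight"] > 0].reset_index(drop=True)
    if comps.empty:
        raise ValueError("no transcribed region has positive rate")
    rng = np.random.default_rng(seed)
    w = comps["weight"].to_numpy()
    counts = rng.multinomial(depth, w / w.sum())
    flip = cfg.strand_convention == "reverse_of_read1"
    pairs: list[AlignedPair] = []
    for comp, n in zip(comps.to_dict("records"), counts):
        if n == 0:
            continue
        pos = _positions_in_component(rng, comp, int(n))
        pairs.extend(
            _pairs_from_positions(
                pos, comp["chrom"], comp["strand"], cfg,
                f"net_{condition}_{comp['region_id']}_", len(pairs), flip,
            )
        )
    return pairs


def simulate_fraction_rnaseq(
    truth: GroundTruth, fraction: str, depth: int, seed: int
) -> list[AlignedPair]:
    """Chromatin- or nucleoplasm-fraction RNA-seq pairs.

    A region with chromatin:nucleoplasm retention ratio r contributes
    weight r/(1+r) to the chromatin library and 1/(1+r) to the
    nucleoplasmic one, so the normalised chromatin/nucleoplasm ratio
    recovers r."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    if fraction not in ("chromatin", "nucleoplasm"):
        raise ValueError(f"unknown fraction {fraction!r}")
    cfg = truth.config
    reg = truth.regions[truth.regions["base_rate"] > 0].reset_index(drop=True)
    if reg.empty:
        raise ValueError("no transcribed regions")
    r = reg["retention_ratio"].to_numpy(dtype=float)
    part = r / (1.0 + r) if fraction == "chromatin" else 1.0 / (1.0 + r)
    w = reg["base_rate"].to_numpy(dtype=float) * part
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(depth, w / w.sum())
    flip = cfg.strand_convention == "reverse_of_read1"
    rl, fl = cfg.read_len, cfg.fragment_len
    pairs: list[AlignedPair] = []
    for row, n in zip(reg.to_dict("records"), counts):
        if n == 0:
            continue
        start, end, strand = row["start"], row["end"], row["strand"]
        span = max(end - start - fl, 1)
        fs = rng.integers(start, start + span, size=int(n))
        r1_strand = ("-" if strand == "+" else "+") if flip else strand
        for k, f in enumerate(fs):
            f = int(f)
            fe = min(f + fl, end)
            left = (f, min(f + rl, fe))
            right = (max(fe - rl, f), fe)
            if strand == "+":
                r2s, r1s = right, left  # read2 at the 3' (right) end
            else:
                r2s, r1s = left, right
            pairs.append(
                AlignedPair(
                    query_name=f"{fraction}_{row['region_id']}_{k}",
                    chrom=row["chrom"],
                    read1=(r1s[0], r1s[1], r1_strand),
                    read2=(r2s[0], r2s[1], strand),
                )
            )
    return pairs


def simulate_ip_input(
    truth: GroundTruth, mark: str, depth: int, seed: int,
    condition: str = "control",
) -> tuple[list[AlignedPair], list[AlignedPair]]:
    """Matched IP and input libraries for a chromatin mark.

    The input is uniform over the genome; the IP samples the same
    background plus per-region extra mass ``length x (fold - 1)`` from
    the configured class enrichment folds.  A configured fraction of
    pairs is duplicate-flagged in both libraries."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    cfg = truth.config
    if mark not in cfg.ip_enrichment:
        raise ValueError(f"no enrichment configured for mark {mark!r}")
    folds = cfg.ip_enrichment[mark].get(condition, {})
    rng = np.random.default_rng(seed)
    chroms = list(cfg.chrom_sizes)

    comp_rows = [
        {"chrom": c, "start": 0, "end": cfg.chrom_sizes[c],
         "weight": float(cfg.chrom_sizes[c])}
        for c in chroms
    ]
    for _, r in truth.regions.iterrows():
        fold = folds.get(r["klass"], 1.0)
        if fold > 1.0:
            comp_rows.append(
                {"chrom": r["chrom"], "start": int(r["start"]), "end": int(r["end"]),
                 "weight": (r["end"] - r["start"]) * (fold - 1.0)}
            )

    def draw(components, n, qprefix):
        w = np.array([c["weight"] for c in components])
        counts = rng.multinomial(n, w / w.sum())
        out = []
        fl, rl = cfg.fragment_len, cfg.read_len
        for comp, m in zip(components, counts):
            if m == 0:
                continue
            hi = max(comp["end"] - fl, comp["start"] + 1)
            fs = rng.integers(comp["start"], hi, size=int(m))
            for k, f in enumerate(fs):
                f = int(f)
                fe = f + fl
                strand = "+" if rng.random() < 0.5 else "-"
                out.append(
                    AlignedPair(
                        query_name=f"{qprefix}{len(out)}", chrom=comp["chrom"],
                        read1=(f, f + rl, strand),
                        read2=(fe - rl, fe, "-" if strand == "+" else "+"),
                    )
                )
        if cfg.duplicate_fraction > 0:
            n_dup = int(round(cfg.duplicate_fraction * len(out)))
            dup_idx = set(rng.choice(len(out), size=n_dup, replace=False).tolist())
            out = [
                p._replace(duplicate=(i in dup_idx)) for i, p in enumerate(out)
            ]
        return out

    ip = draw(comp_rows, depth, f"ip_{mark}_")
    inp = draw(comp_rows[: len(chroms)], depth, f"input_{mark}_")
    return ip, inp


def simulate_peak_reads(
    peaks: pd.DataFrame, reads_per_peak: int, seed: int, cfg: SimConfig
) -> list[AlignedPair]:
    """Strand-specific reads over planted peaks, for strand assignment."""
    rng = np.random.default_rng(seed)
    flip = cfg.strand_convention == "reverse_of_read1"
    rl = cfg.read_len
    pairs = []
    for _, p in peaks.iterrows():
        strand = p["strand"]
        r1_strand = ("-" if strand == "+" else "+") if flip else strand
        pos = rng.integers(p["start"], max(p["end"] - rl, p["start"] + 1),
                           size=reads_per_peak)
        for k, s in enumerate(pos):
            s = int(s)
            pairs.append(
                AlignedPair(
                    query_name=f"rdipread_{p['peak_id']}_{k}", chrom=p["chrom"],
                    read1=(s, s + rl, r1_strand),
                    read2=(s, s + rl, strand),
                )
            )
    return pairs


# -- file writers --------------------------------------------------------


def write_gtf(truth: GroundTruth, path: str) -> str:
    """Gene/transcript/exon records for the gene classes, 1-based GTF."""
    gene_classes = ("protein_coding", "intronless", "histone", "lincRNA", "snRNA")
    with open(path, "w") as fh:
        for i, (_, r) in enumerate(truth.regions.iterrows()):
            if r["klass"] not in gene_classes:
                continue
            gid = r["region_id"]
            gtype = {"intronless": "protein_coding",
                     "histone": "protein_coding"}.get(r["klass"], r["klass"])
            name = f"HIST1H{i}A" if r["klass"] == "histone" else gid.upper()
            attrs = (
                f'gene_id "{gid}"; gene_name "{name}"; gene_type "{gtype}";'
            )
            s1, e1 = int(r["start"]) + 1, int(r["end"])
            base = f"{r['chrom']}\tsim"
            fh.write(f"{base}\tgene\t{s1}\t{e1}\t.\t{r['strand']}\t.\t{attrs}\n")
            tattrs = attrs + f' transcript_id "{gid}.t1";'
            fh.write(f"{base}\ttranscript\t{s1}\t{e1}\t.\t{r['strand']}\t.\t{tattrs}\n")
            for part in str(r["exons"]).split(","):
                es, ee = map(int, part.split("-"))
                fh.write(
                    f"{base}\texon\t{es + 1}\t{ee}\t.\t{r['strand']}\t.\t{tattrs}\n"
                )
    return path


def write_region_bed(truth: GroundTruth, klass: str, path: str) -> str:
    sel = truth.regions[truth.regions["klass"] == klass]
    with open(path, "w") as fh:
        for _, r in sel.sort_values(["chrom", "start"]).iterrows():
            fh.write(
                f"{r['chrom']}\t{r['start']}\t{r['end']}\t{r['region_id']}\t0\t"
                f"{r['strand']}\n"
            )
    return path


def write_origins_bed(truth: GroundTruth, path: str) -> str:
    with open(path, "w") as fh:
        for _, o in truth.origins.sort_values(["chrom", "start"]).iterrows():
            fh.write(
                f"{o['chrom']}\t{o['start']}\t{o['end']}\t{o['origin_id']}\t0\t.\n"
            )
    return path


def write_narrowpeak(peaks: pd.DataFrame, path: str) -> str:
    with open(path, "w") as fh:
        for _, p in peaks.sort_values(["chrom", "start"]).iterrows():
            fh.write(
                f"{p['chrom']}\t{p['start']}\t{p['end']}\t{p['peak_id']}\t0\t.\t"
                f"1.0\t-1\t-1\t{int(p['summit'] - p['start'])}\n"
            )
    return path
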