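"""End-to-end orchestration of the two-condition analysis on a
synthetic dataset.

``run`` drives: simulation -> signal tracks -> transcription-unit sets
-> per-class quantification and condition ratios -> chromatin retention
index -> IP-minus-input mark ratios -> metagene profiles -> R-loop peak
annotation -> origin collision analysis, writing each stage's output as
plain text under the output directory plus a consolidated ``summary.tsv``
and a machine-readable ``runlog.json``.  Runs are deterministic given
the config: all randomness derives from ``config.sim.seed``.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .annotation import (
    extract_tus,
    pair_mrna_lincrna,
    pair_prompts,
    select_intronless,
    select_nonoverlapping_coding,
    tus_to_bed,
    write_report,
)
from .metagene import reference_point_profile, scale_regions_profile
from .origins import (
    classify_origins,
    define_extended_lncrna,
    flag_induced,
    nearest_ncrna,
    origin_lncrna_overlap,
    origin_report,
    origin_signal,
    origins_from_bed,
)
from .quantify import (
    class_window,
    cri_table,
    filter_and_impute,
    ip_minus_input_quant,
    region_basecount,
)
from .rdip import (
    assign_peak_strand,
    categorize_peaks,
    category_distribution,
    summit_overlap,
    write_categorized_bed,
)
from .signal import (
    coverage_track,
    extract_net_3prime,
    filter_proper_pairs,
    read_bed,
    read_peaks,
    write_bedgraph,
)
from .simulate import (
    SimConfig,
    make_annotation,
    simulate_fraction_rnaseq,
    simulate_ip_input,
    simulate_netseq,
    simulate_peak_reads,
    simulate_peaks_and_origins,
    write_gtf,
    write_narrowpeak,
    write_origins_bed,
    write_region_bed,
)


@dataclass
class RunConfig:
    """One config for the whole synthetic analysis."""

    sim: SimConfig = field(default_factory=SimConfig)
    netseq_depth: int = 300_000
    fraction_depth: int = 200_000
    ip_depth: int = 100_000
    rdip_reads_per_peak: int = 20
    mark: str = "H3K36me3"
    summit_window_bp: int = 500
    n_random_controls: int = 50
    extended_min_signal: float = 1.0
    extended_max_gap: int = 500
    induced_fold: float = 2.0

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(sim=sim, **raw)


def _fmt(df: pd.DataFrame, path: str) -> str:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def run(config: RunConfig, outdir: str) -> dict:
    """Execute every stage; returns a dict of output paths and the
    summary table."""
    cfg = config
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}
    summary: list[dict] = []
    seed = cfg.sim.seed

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return deco

    # ---- simulate ------------------------------------------------------
    @stage("simulate")
    def truth():
        t = make_annotation(cfg.sim)
        t = simulate_peaks_and_origins(t)
        paths.update(t.write(outdir))
        paths["gtf"] = write_gtf(t, os.path.join(outdir, "annotation.gtf"))
        for klass, fname in (("PROMPT", "prompts.bed"), ("eRNA", "ernas.bed")):
            paths[fname] = write_region_bed(t, klass, os.path.join(outdir, fname))
        paths["origins"] = write_origins_bed(t, os.path.join(outdir, "origins.bed"))
        paths["rdip"] = write_narrowpeak(
            t.rdip_peaks, os.path.join(outdir, "rdip_peaks.narrowPeak"))
        paths["gamma"] = write_narrowpeak(
            t.gamma_peaks, os.path.join(outdir, "gamma_peaks.narrowPeak"))
        return t

    sizes = truth.chrom_sizes

    # ---- signal tracks -------------------------------------------------
    @stage("signal")
    def tracks():
        out = {}
        for i, cond in enumerate(("control", "depleted")):
            pairs = filter_proper_pairs(
                simulate_netseq(truth, cond, cfg.netseq_depth, seed + 10 + i))
            out[f"net_{cond}"] = extract_net_3prime(
                pairs, sizes, label=f"mNET-seq {cond}")
        for i, frac in enumerate(("chromatin", "nucleoplasm")):
            pairs = filter_proper_pairs(
                simulate_fraction_rnaseq(truth, frac, cfg.fraction_depth, seed + 20 + i))
            out[frac] = coverage_track(pairs, sizes, label=f"{frac} RNA-seq")
        for i, cond in enumerate(("control", "depleted")):
            ip, inp = simulate_ip_input(
                truth, cfg.mark, cfg.ip_depth, seed + 30 + i, condition=cond)
            out[f"ip_{cond}"] = coverage_track(
                filter_proper_pairs(ip, drop_duplicates=True), sizes,
                stranded=False, label=f"{cfg.mark} IP {cond}")
            out[f"input_{cond}"] = coverage_track(
                filter_proper_pairs(inp, drop_duplicates=True), sizes,
                stranded=False, label=f"{cfg.mark} input {cond}")
        rdip_pairs = filter_proper_pairs(
            simulate_peak_reads(truth.rdip_peaks, cfg.rdip_reads_per_peak,
                                seed + 40, cfg.sim))
        out["rdip_reads"] = coverage_track(rdip_pairs, sizes, label="RDIP reads")
        for name in ("net_control", "net_depleted"):
            for s, tag in (("+", "plus"), ("-", "minus")):
                write_bedgraph(out[name], os.path.join(outdir, f"{name}.{tag}.bedgraph"), s)
        return out

    net_c, net_d = tracks["net_control"], tracks["net_depleted"]

    # ---- transcription-unit sets --------------------------------------
    @stage("tu_sets")
    def tu_bundle():
        tus = extract_tus(paths["gtf"])
        nonov = select_nonoverlapping_coding(tus, tracks["chromatin"], seed=seed)
        intronless = select_intronless(tus)
        prompts = truth.prompts()
        ernas = truth.ernas()
        ppairs = pair_prompts(prompts, tus)
        lpairs = pair_mrna_lincrna(
            tus, {"control": net_c, "depleted": net_d})
        write_report(nonov, os.path.join(outdir, "set_nonoverlapping_coding.tsv"))
        write_report(intronless, os.path.join(outdir, "set_intronless.tsv"))
        tus_to_bed([t for t in tus if t.gene_id in set(nonov.members)],
                   os.path.join(outdir, "nonoverlapping_coding.bed"))
        pair_rows = [
            {"kind": p.kind, "a": p.partner_a.gene_id, "b": p.partner_b.gene_id,
             "tss_distance": p.tss_distance}
            for p in ppairs + lpairs
        ]
        _fmt(pd.DataFrame(pair_rows), os.path.join(outdir, "gene_pairs.tsv"))
        summary.append({"metric": "n_nonoverlapping_coding", "value": len(nonov.members)})
        summary.append({"metric": "n_intronless", "value": len(intronless.members)})
        summary.append({"metric": "n_prompt_mrna_pairs", "value": len(ppairs)})
        summary.append({"metric": "n_mrna_lincrna_pairs", "value": len(lpairs)})
        return {"tus": tus, "nonov": nonov, "prompts": prompts, "ernas": ernas}

    tus = tu_bundle["tus"]
    tu_by_id = {t.gene_id: t for t in tus}
    prompts, ernas = tu_bundle["prompts"], tu_bundle["ernas"]

    # ---- per-class quantification and condition ratios ----------------
    @stage("quantify")
    def quant_df():
        groups = {
            "PROMPT": [(t, class_window(t, "PROMPT")) for t in prompts],
            "eRNA": [(t, class_window(t, "eRNA")) for t in ernas],
            "lincRNA": [(t, class_window(t, "lincRNA"))
                        for t in tus if t.biotype == "lincRNA"],
            "coding": [(tu_by_id[g], class_window(tu_by_id[g], "coding"))
                       for g in tu_bundle["nonov"].members],
            "snRNA": [(t, class_window(t, "snRNA"))
                      for t in tus if t.biotype == "snRNA"],
        }
        rows = []
        for klass, members in groups.items():
            for t, (ws, we) in members:
                rec = {"region_id": t.gene_id, "klass": klass,
                       "chrom": t.chrom, "start": ws, "end": we, "strand": t.strand}
                for cond, trk in (("control", net_c), ("depleted", net_d)):
                    raw = region_basecount(trk, t.chrom, ws, we, t.strand)
                    val = raw * trk.norm_factor / (we - ws)
                    rec[f"raw_{cond}"] = raw
                    rec[f"value_{cond}"] = val
                rows.append(rec)
        df = pd.DataFrame(rows)
        pos = df[(df["value_control"] > 0) & (df["value_depleted"] > 0)].copy()
        pos["log2_ratio"] = np.log2(pos["value_depleted"] / pos["value_control"])
        _fmt(pos, os.path.join(outdir, "netseq_quant.tsv"))
        for klass, g in pos.groupby("klass"):
            summary.append(
                {"metric": f"median_log2_ratio_{klass}",
                 "value": float(g["log2_ratio"].median())})
        return pos

    # ---- chromatin retention index ------------------------------------
    @stage("cri")
    def cri_df():
        chrom_vals, nuc_vals, index = [], [], []
        for t in prompts:
            ws, we = class_window(t, "CRI_PROMPT")
            for trk, acc in ((tracks["chromatin"], chrom_vals),
                             (tracks["nucleoplasm"], nuc_vals)):
                raw = region_basecount(trk, t.chrom, ws, we, t.strand)
                acc.append(raw * trk.norm_factor / (we - ws))
            index.append(t.gene_id)
        df = cri_table(pd.Series(chrom_vals, index=index),
                       pd.Series(nuc_vals, index=index))
        _fmt(df.reset_index(names="region_id"), os.path.join(outdir, "cri.tsv"))
        summary.append({"metric": "median_cri_prompt",
                        "value": float(df["cri"].median())})
        return df

    # ---- IP-minus-input mark quantification ---------------------------
    @stage("mark_ratio")
    def mark_df():
        windows = []
        for t in prompts:
            windows.append((t.gene_id, "PROMPT", t.chrom, *class_window(t, "PROMPT")))
        for g in tu_bundle["nonov"].members:
            t = tu_by_id[g]
            windows.append((g, "coding", t.chrom, t.start, t.end))
        cols = {}
        for cond in ("control", "depleted"):
            ip, inp = tracks[f"ip_{cond}"], tracks[f"input_{cond}"]
            ipc = [region_basecount(ip, c, s, e, strand_mode="unstranded")
                   for (_, _, c, s, e) in windows]
            inc = [region_basecount(inp, c, s, e, strand_mode="unstranded")
                   for (_, _, c, s, e) in windows]
            cols[cond] = ip_minus_input_quant(
                ipc, inc, ip.library_size, inp.library_size,
                [e - s for (_, _, _, s, e) in windows])
        table = pd.DataFrame(cols, index=[w[0] for w in windows])
        klass_of = {w[0]: w[1] for w in windows}
        # the positive-signal filter and min/2 imputation are per
        # region set: apply them within each class
        parts = []
        for klass in sorted(set(klass_of.values())):
            ids = [i for i in table.index if klass_of[i] == klass]
            imputed_table, mask = filter_and_impute(table.loc[ids])
            part = imputed_table.apply(np.log2)
            part.columns = [f"log2_{c}" for c in part.columns]
            part.insert(0, "klass", klass)
            part["imputed"] = mask.any(axis=1)
            parts.append(part)
        out = pd.concat(parts)
        _fmt(out.reset_index(names="region_id"),
             os.path.join(outdir, f"{cfg.mark}_quant.tsv"))
        for klass, g in out.groupby("klass"):
            shift = (g["log2_depleted"] - g["log2_control"]).median()
            summary.append(
                {"metric": f"median_{cfg.mark}_shift_{klass}", "value": float(shift)})
        return out

    # ---- metagene profiles --------------------------------------------
    @stage("metagene")
    def profiles():
        sel = [tu_by_id[g] for g in tu_bundle["nonov"].members]
        regions = [(t.chrom, t.start, t.end, t.strand) for t in sel]
        for cond, trk in (("control", net_c), ("depleted", net_d)):
            prof = scale_regions_profile(trk, regions, body_bins=100,
                                         upstream_bp=3000, downstream_bp=3000)
            prof.write_tsv(os.path.join(outdir, f"metagene_coding_{cond}.tsv"))
        anchors = [(t.chrom, t.tss, t.strand) for t in prompts]
        for cond, trk in (("control", net_c), ("depleted", net_d)):
            prof = reference_point_profile(trk, anchors, 1000, 3000)
            prof.write_tsv(os.path.join(outdir, f"metagene_prompt_{cond}.tsv"))
        return True

    # ---- R-loop peak annotation ---------------------------------------
    @stage("rdip")
    def rdip_out():
        peaks = read_peaks(paths["rdip"])
        peaks = assign_peak_strand(peaks, tracks["rdip_reads"])
        peaks = categorize_peaks(peaks, tus)
        dist = category_distribution(peaks)
        write_categorized_bed(peaks, os.path.join(outdir, "rdip_categorized.bed"))
        dist_df = dist.rename("fraction").rename_axis("category").reset_index()
        _fmt(dist_df, os.path.join(outdir, "rdip_category_distribution.tsv"))
        gamma = read_peaks(paths["gamma"])
        ov = summit_overlap(gamma, peaks, cfg.summit_window_bp,
                            n_random=cfg.n_random_controls, seed=seed + 50,
                            chrom_sizes=sizes)
        for cat, fracv in dist.items():
            summary.append({"metric": f"rdip_frac_{cat}", "value": float(fracv)})
        summary.append({"metric": "gamma_rdip_summit_overlap",
                        "value": float(ov["observed"])})
        summary.append({"metric": "gamma_rdip_summit_overlap_null_mean",
                        "value": float(ov["null"].mean())})
        return peaks

    # ---- origin collision analysis ------------------------------------
    @stage("origins")
    def origin_out():
        records = origins_from_bed(read_bed(paths["origins"]))
        records = classify_origins(records, tus)
        records = origin_signal(records, net_c, net_d)
        n_intergenic = sum(r.is_intergenic for r in records)
        positive = [r for r in records if r.positive_any]
        flag_induced(positive, fold=cfg.induced_fold)
        nearest_ncrna(positive, prompts, ernas)
        lncs = prompts + ernas
        extended = define_extended_lncrna(
            net_d, net_c, lncs, min_signal=cfg.extended_min_signal,
            max_gap=cfg.extended_max_gap)
        _fmt(extended, os.path.join(outdir, "extended_lncrna.bed.tsv"))
        near = [r for r in positive if r.nearest_ncrna]
        overlap_frac = origin_lncrna_overlap(near, extended) if near else 0.0
        report = origin_report(records)
        _fmt(report, os.path.join(outdir, "origin_report.tsv"))
        summary.append({"metric": "n_origins", "value": len(records)})
        summary.append({"metric": "n_intergenic_origins", "value": n_intergenic})
        summary.append({"metric": "n_positive_origins", "value": len(positive)})
        summary.append({"metric": "n_induced_origins",
                        "value": sum(r.induced_2x for r in positive)})
        summary.append({"metric": "origin_extended_lncrna_overlap_frac",
                        "value": overlap_frac})
        return records

    summary_df = pd.DataFrame(summary)
    _fmt(summary_df, os.path.join(outdir, "summary.tsv"))
    runlog = {
        "version": __version__,
        "seed": seed,
        "config": {
            **{k: v for k, v in dataclasses.asdict(cfg).items() if k != "sim"},
            "sim": dataclasses.asdict(cfg.sim),
        },
        "stages": ["simulate", "signal", "tu_sets", "quantify", "cri",
                   "mark_ratio", "metagene", "rdip", "origins"],
        "library_sizes": {k: int(t.library_size) for k, t in tracks.items()},
    }
    with open(os.path.join(outdir, "runlog.json"), "w") as fh:
        json.dump(runlog, fh, indent=2, default=str, sort_keys=True)
    paths["summary"] = os.path.join(outdir, "summary.tsv")
    return {"paths": paths, "summary": summary_df, "truth": truth}
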