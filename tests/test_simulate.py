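"""Ground-truth generator: layout construction, determinism,
conservation and planted-parameter sanity."""

import numpy as np
import pytest

from lnctx.annotation import extract_tus
from lnctx.signal import extract_net_3prime, filter_proper_pairs
from lnctx.simulate import (
    SimConfig,
    make_annotation,
    simulate_fraction_rnaseq,
    simulate_ip_input,
    simulate_netseq,
    simulate_peaks_and_origins,
    write_gtf,
)

SMALL = dict(
    n_coding=12, n_intronless=2, n_histone=2, n_lincrna=3, n_snrna=2,
    n_prompt=5, n_erna=5, n_origins=20, n_rdip_peaks=40, n_gamma_extra=8,
    chrom_length_bp=1_000_000,
)


@pytest.fixture(scope="module")
def truth():
    return simulate_peaks_and_origins(make_annotation(SimConfig(seed=5, **SMALL)))


class TestMakeAnnotation:
    def test_divergent_prompt_pairs(self, truth):
        regions = truth.regions.set_index("region_id")
        for i in range(SMALL["n_prompt"]):
            p = regions.loc[f"prompt{i:03d}"]
            g = regions.loc[f"gene{i:03d}"]
            assert p["strand"] != g["strand"]
            p_tss = p["end"] if p["strand"] == "-" else p["start"]
            g_tss = g["start"] if g["strand"] == "+" else g["end"]
            assert abs(int(p_tss) - int(g_tss)) < 2000

    def test_tus_satisfy_invariants(self, truth):
        # TranscriptionUnit validates span/exon invariants on construction
        tus = truth.tus()
        assert len(tus) == sum(SMALL[k] for k in
                               ("n_coding", "n_intronless", "n_histone",
                                "n_lincrna", "n_snrna"))

    def test_features_do_not_overlap(self, truth):
        by_chrom = {}
        genes = truth.regions[truth.regions["klass"] != "origin_bg"]
        for _, r in genes.iterrows():
            by_chrom.setdefault(r["chrom"], []).append((r["start"], r["end"]))
        for ivs in by_chrom.values():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert e1 <= s2

    def test_zero_counts_give_empty_but_valid_outputs(self, tmp_path):
        cfg = SimConfig(
            n_coding=0, n_intronless=0, n_histone=0, n_lincrna=0, n_snrna=0,
            n_prompt=0, n_erna=0, n_origins=0, n_rdip_peaks=0, n_gamma_extra=0,
        )
        truth = make_annotation(cfg)
        assert truth.regions.empty
        path = write_gtf(truth, str(tmp_path / "empty.gtf"))
        assert open(path).read() == ""

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError, match="genome"):
            make_annotation(SimConfig(chrom_length_bp=150_000, n_coding=200))

    def test_gtf_round_trip_matches_truth(self, truth, tmp_path):
        path = write_gtf(truth, str(tmp_path / "ann.gtf"))
        tus = {t.gene_id: t for t in extract_tus(path)}
        genes = truth.regions[
            truth.regions["klass"].isin(
                ["protein_coding", "intronless", "histone", "lincRNA", "snRNA"])
        ]
        assert len(tus) == len(genes)
        for _, r in genes.iterrows():
            t = tus[r["region_id"]]
            assert (t.chrom, t.start, t.end, t.strand) == (
                r["chrom"], r["start"], r["end"], r["strand"])
        # histone naming propagates to the biotype
        assert all(tus[g].biotype == "histone"
                   for g in genes[genes["klass"] == "histone"]["region_id"])


class TestDeterminismAndConservation:
    def test_identical_configs_identical_outputs(self):
        a = simulate_peaks_and_origins(make_annotation(SimConfig(seed=9, **SMALL)))
        b = simulate_peaks_and_origins(make_annotation(SimConfig(seed=9, **SMALL)))
        assert a.regions.equals(b.regions)
        assert a.origins.equals(b.origins)
        pa = simulate_netseq(a, "control", 5000, seed=3)
        pb = simulate_netseq(b, "control", 5000, seed=3)
        assert pa == pb

    def test_depth_is_exact(self, truth):
        for cond in ("control", "depleted"):
            assert len(simulate_netseq(truth, cond, 7321, seed=1)) == 7321
        assert len(simulate_fraction_rnaseq(truth, "chromatin", 4000, 1)) == 4000

    def test_bad_depth_and_condition(self, truth):
        with pytest.raises(ValueError):
            simulate_netseq(truth, "control", 0, seed=1)
        with pytest.raises(ValueError):
            simulate_netseq(truth, "mock", 100, seed=1)
        with pytest.raises(ValueError):
            simulate_fraction_rnaseq(truth, "cytoplasm", 100, 1)


class TestPlantedSignals:
    def test_netseq_reads_fall_in_their_regions(self, truth):
        pairs = simulate_netseq(truth, "control", 20_000, seed=2)
        track = extract_net_3prime(filter_proper_pairs(pairs), truth.chrom_sizes)
        assert track.total() == 20_000
        # every read's 3' end must fall inside its own source region
        spans = {
            r["region_id"]: (r["chrom"], r["start"], r["end"], r["strand"])
            for _, r in truth.regions.iterrows()
        }
        for p in pairs[::17]:
            rid = p.query_name.removeprefix("net_control_").rsplit("_", 1)[0]
            chrom, start, end, strand = spans[rid]
            s, e, r2strand = p.read2
            pos = e - 1 if r2strand == "+" else s
            assert chrom == p.chrom and start <= pos < end
            assert r2strand == strand

    def test_prompt_fold_ratio_recovered_roughly(self):
        cfg = SimConfig(seed=11, frac_extended=0.0, prompt_folds=(4.0,),
                        coding_decay_bp=0.0, **{k: v for k, v in SMALL.items()})
        truth = simulate_peaks_and_origins(make_annotation(cfg))
        depth = 150_000
        tc = extract_net_3prime(
            simulate_netseq(truth, "control", depth, seed=1), truth.chrom_sizes)
        td = extract_net_3prime(
            simulate_netseq(truth, "depleted", depth, seed=2), truth.chrom_sizes)
        prompts = truth.regions[truth.regions["klass"] == "PROMPT"]
        raw_c = sum(tc.region(r["chrom"], r["start"], r["end"], r["strand"]).sum()
                    for _, r in prompts.iterrows())
        raw_d = sum(td.region(r["chrom"], r["start"], r["end"], r["strand"]).sum()
                    for _, r in prompts.iterrows())
        ratio = (raw_d / td.library_size) / (raw_c / tc.library_size)
        assert np.log2(ratio) == pytest.approx(2.0, abs=0.35)

    def test_coding_decay_shifts_reads_5prime(self, truth):
        pairs = simulate_netseq(truth, "depleted", 30_000, seed=4)
        track = extract_net_3prime(filter_proper_pairs(pairs), truth.chrom_sizes)
        genes = truth.regions[truth.regions["klass"] == "protein_coding"]
        first_half = second_half = 0.0
        for _, g in genes.iterrows():
            sig = track.region(g["chrom"], g["start"], g["end"], g["strand"])
            if g["strand"] == "-":
                sig = sig[::-1]
            first_half += sig[: len(sig) // 2].sum()
            second_half += sig[len(sig) // 2 :].sum()
        assert first_half > 2 * second_half

    def test_retention_ratio_partitions_fractions(self, truth):
        depth = 60_000
        chrom = extract_net_3prime([], truth.chrom_sizes)  # placeholder sizes
        counts = {}
        for frac in ("chromatin", "nucleoplasm"):
            pairs = simulate_fraction_rnaseq(truth, frac, depth, seed=8)
            n_prompt = sum(p.query_name.startswith(f"{frac}_prompt")
                           for p in pairs)
            counts[frac] = n_prompt
        # planted retention ratio 2.0 on PROMPTs
        ratio = counts["chromatin"] / counts["nucleoplasm"]
        assert ratio == pytest.approx(2.0, rel=0.3)

    def test_duplicate_fraction_removed_exactly(self):
        cfg = SimConfig(seed=3, duplicate_fraction=0.25, **SMALL)
        truth = simulate_peaks_and_origins(make_annotation(cfg))
        ip, inp = simulate_ip_input(truth, "H3K36me3", 4000, seed=6)
        kept = filter_proper_pairs(ip, drop_duplicates=True)
        assert len(ip) - len(kept) == round(0.25 * len(ip))

    def test_ip_enrichment_concentrates_on_coding(self, truth):
        ip, inp = simulate_ip_input(truth, "H3K36me3", 30_000, seed=7)
        genes = truth.regions[truth.regions["klass"] == "protein_coding"]
        gene_bp = (genes["end"] - genes["start"]).sum()
        genome_bp = sum(truth.chrom_sizes.values())
        in_genes = sum(
            any(g["chrom"] == p.chrom and g["start"] <= p.read1[0] < g["end"]
                for _, g in genes.iterrows())
            for p in ip[::50]
        )
        frac_ip = in_genes / len(ip[::50])
        assert frac_ip > 2 * gene_bp / genome_bp


class TestPlantedPeaksAndOrigins:
    def test_origin_partition(self, truth):
        o = truth.origins
        assert len(o) == SMALL["n_origins"]
        assert o["is_intergenic"].sum() == round(0.8 * SMALL["n_origins"])

    def test_gamma_colocation_counts(self, truth):
        g = truth.gamma_peaks
        assert g["colocated"].sum() == round(0.8 * SMALL["n_rdip_peaks"])

    def test_rdip_category_counts_match_config(self, truth):
        probs = truth.config.rdip_category_probs
        counts = truth.rdip_peaks["category"].value_counts()
        for cat in ("exon", "intron", "upstream", "downstream"):
            assert counts.get(cat, 0) == round(probs[cat] * SMALL["n_rdip_peaks"])
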