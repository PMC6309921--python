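"""Transcription-unit construction and gene-set selection."""

import numpy as np
import pytest

from lnctx.annotation import (
    GenePair,
    TranscriptionUnit,
    extract_tus,
    merge_intervals,
    pair_mrna_lincrna,
    pair_prompts,
    select_intronless,
    select_nonoverlapping_coding,
)
from lnctx.signal import StrandedSignalTrack


def tu(gene_id="g", biotype="protein_coding", chrom="chrA", start=1000,
       end=5000, strand="+", exons=None):
    if exons is None:
        exons = ((start, end),)
    return TranscriptionUnit(gene_id, biotype, chrom, start, end, strand,
                             tuple(exons))


GTF_FIXTURE = """\
chrA\tsim\tgene\t101\t700\t.\t+\t.\tgene_id "g1"; gene_type "protein_coding"; gene_name "G1";
chrA\tsim\ttranscript\t101\t500\t.\t+\t.\tgene_id "g1"; gene_type "protein_coding"; transcript_id "g1.t1";
chrA\tsim\texon\t101\t200\t.\t+\t.\tgene_id "g1"; gene_type "protein_coding"; transcript_id "g1.t1";
chrA\tsim\texon\t301\t500\t.\t+\t.\tgene_id "g1"; gene_type "protein_coding"; transcript_id "g1.t1";
chrA\tsim\ttranscript\t151\t700\t.\t+\t.\tgene_id "g1"; gene_type "protein_coding"; transcript_id "g1.t2";
chrA\tsim\texon\t151\t700\t.\t+\t.\tgene_id "g1"; gene_type "protein_coding"; transcript_id "g1.t2";
chrA\tsim\ttranscript\t2001\t3000\t.\t-\t.\tgene_id "g2"; gene_type "lincRNA"; transcript_id "g2.t1";
chrA\tsim\texon\t2001\t3000\t.\t-\t.\tgene_id "g2"; gene_type "lincRNA"; transcript_id "g2.t1";
chrB\tsim\ttranscript\t501\t900\t.\t+\t.\tgene_id "g3"; gene_type "protein_coding"; gene_name "HIST1H2BK"; transcript_id "g3.t1";
chrB\tsim\texon\t501\t900\t.\t+\t.\tgene_id "g3"; gene_type "protein_coding"; gene_name "HIST1H2BK"; transcript_id "g3.t1";
"""


class TestTranscriptionUnit:
    def test_tss_tes_by_strand(self):
        plus = tu(strand="+")
        minus = tu(strand="-")
        assert (plus.tss, plus.tes) == (1000, 5000)
        assert (minus.tss, minus.tes) == (5000, 1000)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(start=10, end=10),
            dict(strand="."),
            dict(exons=((900, 1200),)),  # exon outside span
            dict(exons=((1000, 3000), (2000, 4000))),  # overlapping exons
        ],
    )
    def test_invariants_enforced(self, kwargs):
        with pytest.raises(ValueError):
            tu(**kwargs)


class TestExtractTus:
    def test_three_gene_fixture_matches_hand_table(self, tmp_path):
        path = tmp_path / "ann.gtf"
        path.write_text(GTF_FIXTURE)
        tus = {t.gene_id: t for t in extract_tus(str(path))}
        # hand-computed 0-based spans: per-gene min/max over transcripts
        g1 = tus["g1"]
        assert (g1.start, g1.end, g1.tss, g1.tes) == (100, 700, 100, 700)
        # exon union: [100,200)+[300,500) merged with [150,700) -> [100,700)
        assert g1.exons == ((100, 700),)
        g2 = tus["g2"]
        assert (g2.start, g2.end, g2.strand) == (2000, 3000, "-")
        assert (g2.tss, g2.tes) == (3000, 2000)
        assert g2.biotype == "lincRNA"
        assert tus["g3"].biotype == "histone"  # name-prefix rule

    def test_gene_without_exons_skipped_with_warning(self, tmp_path):
        path = tmp_path / "ann.gtf"
        path.write_text(
            'chrA\ts\tgene\t11\t20\t.\t+\t.\tgene_id "gx"; gene_type "protein_coding";\n'
        )
        with pytest.warns(UserWarning, match="gx"):
            assert extract_tus(str(path)) == []

    def test_merge_intervals_union(self):
        assert merge_intervals([(5, 8), (0, 3), (2, 6)]) == [(0, 8)]


def tiered_fixture(tier_means=(0, 10, 100, 1000), n_per_tier=10):
    """40 isolated coding TUs whose coverage sits in separated tiers."""
    sizes = {"chrT": 600_000}
    tus, expected_top = [], set()
    track = StrandedSignalTrack(sizes, library_size=int(1e8))
    pos = 1000
    i = 0
    for tier, mean in enumerate(tier_means):
        for _ in range(n_per_tier):
            t = tu(gene_id=f"t{tier}_{i}", chrom="chrT", start=pos, end=pos + 3000)
            tus.append(t)
            if mean > 0:
                track.array("chrT", "+")[pos : pos + 3000] = mean
            if tier > 0:
                expected_top.add(t.gene_id)
            pos += 3000 + 10_000
            i += 1
    return tus, track, expected_top


class TestSelectNonoverlappingCoding:
    def test_neighbor_within_window_excluded(self, make_track):
        a = tu(gene_id="a", start=10_000, end=15_000)
        # neighbour ends 1 kb upstream of a's TSS
        b = tu(gene_id="b", biotype="lincRNA", start=5000, end=9000)
        c = tu(gene_id="c", start=40_000, end=45_000)
        track = make_track([("chrA", "+", 12_000, 50.0), ("chrA", "+", 42_000, 50.0)])
        rep = select_nonoverlapping_coding([a, b, c], track, k=1, keep_top=1)
        assert "a" not in rep.members and "c" in rep.members
        assert rep.check_monotone()

    def test_short_tu_excluded_regardless_of_coverage(self, make_track):
        short = tu(gene_id="s", start=10_000, end=11_500)
        other = tu(gene_id="o", start=40_000, end=44_000)
        track = make_track([("chrA", "+", 10_500, 1000.0), ("chrA", "+", 41_000, 5.0)])
        rep = select_nonoverlapping_coding([short, other], track, k=1, keep_top=1)
        assert rep.members == ["o"]

    def test_four_tier_kmeans_selects_top_three(self):
        tus, track, expected = tiered_fixture()
        rep = select_nonoverlapping_coding(tus, track, seed=0)
        assert set(rep.members) == expected

    def test_seed_invariant_under_separation(self):
        tus, track, expected = tiered_fixture()
        results = {
            tuple(select_nonoverlapping_coding(tus, track, seed=s).members)
            for s in (0, 1, 17)
        }
        assert len(results) == 1 and set(results.pop()) == expected

    def test_too_few_survivors_raises(self, make_track):
        track = make_track([("chrA", "+", 12_000, 5.0)])
        with pytest.raises(ValueError, match="k"):
            select_nonoverlapping_coding([tu(start=10_000, end=15_000)], track)


class TestSelectIntronless:
    def test_rules(self):
        single = tu(gene_id="ok")
        multi = tu(gene_id="multi",
                   exons=((1000, 2000), (3000, 5000)))
        hist = tu(gene_id="h", biotype="histone")
        linc = tu(gene_id="l", biotype="lincRNA")
        rep = select_intronless([single, multi, hist, linc])
        assert rep.members == ["ok"]
        assert rep.check_monotone()

    def test_idempotent(self):
        tus = [tu(gene_id="ok"), tu(gene_id="h", biotype="histone")]
        rep1 = select_intronless(tus)
        kept = [t for t in tus if t.gene_id in rep1.members]
        assert select_intronless(kept).members == rep1.members


class TestPairPrompts:
    def prompt(self, gene_id="p", start=9000, end=10_000, strand="+", chrom="chrA"):
        return tu(gene_id=gene_id, biotype="PROMPT", chrom=chrom,
                  start=start, end=end, strand=strand)

    def test_nearest_opposite_strand(self):
        p = self.prompt(start=9000, end=10_000, strand="+")  # tss = 9000
        near = tu(gene_id="near", strand="-", start=9300, end=12_000)  # tss 12000
        nearer = tu(gene_id="nearer", strand="-", start=5000, end=9400)  # tss 9400
        far = tu(gene_id="far", strand="-", start=50_000, end=60_000)
        same = tu(gene_id="same", strand="+", start=9000, end=9100)
        (pair,) = pair_prompts([p], [near, nearer, far, same])
        assert pair.partner_b.gene_id == "nearer"
        assert pair.tss_distance == 400

    def test_tie_breaks_toward_smaller_start(self):
        p = self.prompt(start=10_000, end=11_000, strand="+")  # tss 10000
        left = tu(gene_id="left", strand="-", start=5000, end=9000)   # tss 9000
        right = tu(gene_id="right", strand="-", start=10_500, end=11_000)  # tss 11000
        (pair,) = pair_prompts([p], [left, right])
        assert pair.partner_b.gene_id == "left"

    def test_no_candidate_dropped_with_warning(self):
        p = self.prompt(strand="+")
        with pytest.warns(UserWarning):
            assert pair_prompts([p], [tu(strand="+")]) == []

    def test_agrees_with_bruteforce(self, rng):
        prompts = [
            self.prompt(gene_id=f"p{i}", start=s, end=s + 1000,
                        strand="+" if rng.random() < 0.5 else "-")
            for i, s in enumerate(rng.integers(0, 90_000, size=20))
        ]
        coding = [
            tu(gene_id=f"g{i}", start=s, end=s + 2000,
               strand="+" if rng.random() < 0.5 else "-")
            for i, s in enumerate(rng.integers(0, 90_000, size=30))
        ]
        pairs = pair_prompts(prompts, coding)
        got = {pr.partner_a.gene_id: pr.partner_b.gene_id for pr in pairs}
        for p in prompts:
            cands = [c for c in coding if c.strand != p.strand]
            best = min(cands, key=lambda c: (abs(c.tss - p.tss), c.start))
            assert got[p.gene_id] == best.gene_id


class TestPairMrnaLincrna:
    def setup_tracks(self, make_track, linc_reads=50):
        values = [("chrA", "+", 5000 + i, 1.0) for i in range(60)]  # mRNA
        values += [("chrA", "-", 6900 + i, 1.0) for i in range(linc_reads)]
        return {"control": make_track(values), "depleted": make_track([])}

    def test_candidate_by_tss_distance(self, make_track):
        m = tu(gene_id="m", start=5000, end=6000, strand="+")  # tss 5000
        l = tu(gene_id="l", biotype="lincRNA", start=6800, end=7800, strand="-")
        # minus-strand tss = end = 7800 -> distance 2800 < 3000
        pairs = pair_mrna_lincrna([m, l], self.setup_tracks(make_track))
        assert len(pairs) == 1 and pairs[0].tss_distance == 2800
        far = tu(gene_id="f", biotype="lincRNA", start=7200, end=8200, strand="-")
        assert pair_mrna_lincrna([m, far], self.setup_tracks(make_track)) == []

    def test_low_read_partner_dropped(self, make_track):
        m = tu(gene_id="m", start=5000, end=6000, strand="+")
        l = tu(gene_id="l", biotype="lincRNA", start=6800, end=7800, strand="-")
        tracks = self.setup_tracks(make_track, linc_reads=9)
        assert pair_mrna_lincrna([m, l], tracks) == []

    def test_planted_counts_match_hand_selection(self, make_track, rng):
        tus, values, expected = [], [], set()
        for i in range(10):
            base = 3000 + i * 9000
            m = tu(gene_id=f"m{i}", chrom="chrA", start=base, end=base + 2000,
                   strand="+")
            # divergent antisense partner upstream: tss = base - 500
            l = tu(gene_id=f"l{i}", biotype="antisense", chrom="chrA",
                   start=base - 2500, end=base - 500, strand="-")
            tus += [m, l]
            m_reads = int(rng.integers(0, 25))
            l_reads = int(rng.integers(0, 25))
            values += [("chrA", "+", base + j, 1.0) for j in range(m_reads)]
            values += [("chrA", "-", base - 2500 + j, 1.0) for j in range(l_reads)]
            if m_reads >= 10 and l_reads >= 10:
                expected.add((f"m{i}", f"l{i}"))
        tracks = {"c": make_track(values), "d": make_track([])}
        got = {
            (p.partner_a.gene_id, p.partner_b.gene_id)
            for p in pair_mrna_lincrna(tus, tracks)
        }
        assert got == expected

    def test_missing_tracks_error(self):
        with pytest.raises(ValueError):
            pair_mrna_lincrna([], {})


def test_gene_pair_requires_opposite_strands():
    with pytest.raises(ValueError):
        GenePair("prompt_mrna", tu(gene_id="a"), tu(gene_id="b"), 100)
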