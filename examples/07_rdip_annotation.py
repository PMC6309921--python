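"""R-loop peak annotation: strand assignment, genomic categories and
co-location with DNA-damage peaks.

Peaks get the strand carrying the majority of overlapping
strand-specific reads, then one genomic category by summit position
(exon > intron > upstream > downstream > distal).  Damage-peak summits
are compared against a uniform repositioning null.
"""

from lnctx import (
    SimConfig, assign_peak_strand, categorize_peaks, category_distribution,
    coverage_track, filter_proper_pairs, make_annotation, summit_overlap,
    simulate_peaks_and_origins,
)
from lnctx.rdip import PeakRecord
from lnctx.simulate import simulate_peak_reads

cfg = SimConfig(seed=7, n_rdip_peaks=200)
truth = simulate_peaks_and_origins(make_annotation(cfg))

def to_records(df):
    return [PeakRecord(chrom=r["chrom"], start=int(r["start"]),
                       end=int(r["end"]), name=r["peak_id"],
                       summit=int(r["summit"])) for _, r in df.iterrows()]

reads = coverage_track(
    filter_proper_pairs(simulate_peak_reads(truth.rdip_peaks, 20, 3, cfg)),
    truth.chrom_sizes)
peaks = assign_peak_strand(to_records(truth.rdip_peaks), reads)
correct = sum(p.strand == t for p, t in zip(peaks, truth.rdip_peaks["strand"]))
print(f"strand recovery: {correct}/{len(peaks)}")

peaks = categorize_peaks(peaks, truth.tus())
print("\ncategory fractions (planted -> recovered):")
dist = category_distribution(peaks)
for cat, frac in dist.items():
    print(f"  {cat:10s} {truth.config.rdip_category_probs[cat]:.2f} -> {frac:.2f}")

res = summit_overlap(to_records(truth.gamma_peaks), peaks, window_bp=500,
                     n_random=50, seed=9, chrom_sizes=truth.chrom_sizes)
print(f"\ndamage-peak summits within 500 bp of an R-loop summit: "
      f"{res['observed']:.2f} (null {res['null'].mean():.3f}, "
      f"p = {res['pvalue']:.3f})")
# Strand and category recovery are exact by construction; the observed
# co-location far exceeds the random-placement null, as planted.
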