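"""Per-class quantification and condition fold changes.

Signal is normalised to 100 million pairs and region length (an
FPKM-like unit); the log2 depleted/control ratio per region recovers
the planted induction folds, and a Wilcoxon rank-sum test compares
classes.
"""

import numpy as np

from lnctx import (
    SimConfig, compare_groups, extract_net_3prime, filter_proper_pairs,
    make_annotation, region_basecount, simulate_netseq,
    simulate_peaks_and_origins,
)

cfg = SimConfig(seed=4, prompt_folds=(4.0,), erna_folds=(4.0,),
                frac_extended=0.0, coding_decay_bp=0.0)
truth = simulate_peaks_and_origins(make_annotation(cfg))
tracks = {c: extract_net_3prime(
    filter_proper_pairs(simulate_netseq(truth, c, 400_000, 21)),
    truth.chrom_sizes) for c in ("control", "depleted")}

ratios = {}
for klass in ("PROMPT", "eRNA", "protein_coding"):
    sub = truth.regions[truth.regions["klass"] == klass]
    vals = []
    for _, r in sub.iterrows():
        raw = {c: region_basecount(t, r["chrom"], r["start"], r["end"],
                                   r["strand"]) for c, t in tracks.items()}
        if min(raw.values()) > 0:
            norm = {c: raw[c] * tracks[c].norm_factor for c in raw}
            vals.append(np.log2(norm["depleted"] / norm["control"]))
    ratios[klass] = vals
    print(f"{klass:15s} median log2(depleted/control) = {np.median(vals):+.2f} "
          f"(planted {np.log2(sub['depleted_fold'].iloc[0]):+.2f}, n={len(vals)})")

stat, p = compare_groups(ratios["PROMPT"], ratios["protein_coding"])
print(f"\nPROMPT vs coding fold change, Wilcoxon rank-sum p = {p:.2e}")
# PROMPTs/eRNAs were planted 4x induced (log2 = 2); coding genes are
# unchanged, so the rank-sum test separates the classes decisively.
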