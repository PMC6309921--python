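"""Metagene profiles at 10-bp resolution: the elongation defect.

In the depleted condition the coding-gene 3'-end positions decay
exponentially from the TSS (the polymerase fails to elongate), so the
scaled-body profile slopes 5'->3' while the control stays flat.
"""

import numpy as np
from scipy import stats

from lnctx import (
    SimConfig, extract_net_3prime, filter_proper_pairs, make_annotation,
    scale_regions_profile, simulate_netseq, simulate_peaks_and_origins,
)

cfg = SimConfig(seed=6, coding_decay_bp=2000.0, frac_extended=0.0)
truth = simulate_peaks_and_origins(make_annotation(cfg))
genes = truth.regions[truth.regions["klass"] == "protein_coding"]
regions = [(r["chrom"], r["start"], r["end"], r["strand"])
           for _, r in genes.iterrows()]

for cond in ("control", "depleted"):
    track = extract_net_3prime(
        filter_proper_pairs(simulate_netseq(truth, cond, 300_000, 41)),
        truth.chrom_sizes)
    prof = scale_regions_profile(track, regions, body_bins=100,
                                 upstream_bp=0, downstream_bp=0)
    body = prof.mean_profile
    rho = stats.spearmanr(body, np.arange(len(body))).statistic
    ratio = body[:20].mean() / max(body[-20:].mean(), 1e-9)
    print(f"{cond:9s}: 5' / 3' body signal = {ratio:6.2f}, "
          f"Spearman(body, position) = {rho:+.2f}")
# The depleted profile is strongly front-loaded (large 5'/3' ratio,
# negative trend); the control is flat - the signature of an
# elongation defect in nascent transcription.
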