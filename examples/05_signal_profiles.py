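"""Reference-point signal profiles: unimodal vs bimodal binding.

Computes +-2 kb / 5 bp binned profiles of a query signal around target
peak midpoints for two planted geometries: coincident binding (one central
maximum) and flanking binding at +-500 bp (two symmetric maxima, the
pattern produced by a factor occupying the two divergent promoters around
another factor's site).
"""

import numpy as np

import proxitome as px
from proxitome.profiles import summarize_profile

sizes = px.ChromSizes({f"chr{i + 1}": 400_000 for i in range(4)})

for mode in ("coincident", "flanking_bimodal"):
    query, target = px.generate_peak_sets(
        sizes, 120, 60, mode, offset_sd=0.0, seed=6, flank_offset=500,
        query_width=200, target_width=200)
    track = px.generate_signal_track(query, 10.0, 1.0, sizes)
    matrix = px.compute_matrix(track, target, flank=2000, bin_size=5)
    summary = summarize_profile(matrix)
    offsets = ", ".join(f"{o:+.0f} bp" for o in summary.peak_offsets_bp)
    print(f"{mode:18s} -> {summary.shape:8s} maxima at [{offsets}] "
          f"(peak signal {summary.mean_profile.max():.2f})")
# Maxima are located to within one 5-bp bin of the planted offsets.
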