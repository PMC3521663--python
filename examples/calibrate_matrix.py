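"""Calibrate a raw energy matrix to physical kBT units.

Builds a seeded random 41x4 matrix in arbitrary units (AU) plus a random
50 kb genome, then pins the affine AU -> kBT transform with two anchors:
the genome-wide mean window energy (defines zero) and a known specific
binding energy of -5 kBT for a reference site.
"""

import numpy as np

from promtune import CalibrationRefs, EnergyMatrix, PromoterSequence, calibrate, scan_genome, score_sequence
from promtune.synth import generate_random_genome, generate_toy_matrix

raw = EnergyMatrix(entries=generate_toy_matrix(seed=1, width=41).entries * 9.0 + 2.2)
genome = generate_random_genome(seed=2, length=50_000)

scan = scan_genome(raw, genome, circular=True, strands="both")
print(f"raw genome mean: {scan.mean:.3f} AU over {scan.n_windows} windows")

# use the strongest-binding genomic window as the reference site
idx = int(np.nanargmin(scan.forward))
anchor = PromoterSequence((genome + genome[:40])[idx : idx + 41], id="anchor")
refs = CalibrationRefs(wt_lac_sequence=anchor, wt_lac_specific_energy_kbt=-5.0)

calibrated, done = calibrate(raw, genome, refs)
print(f"conversion factor: {done.conversion_au_per_kbt:.3f} AU per kBT")
print(f"genome mean after calibration: {scan_genome(calibrated, genome).mean:.2e} kBT")
print(f"anchor site energy: {score_sequence(calibrated, anchor):.3f} kBT")

# The calibrated scale is genome-zeroed: 0 kBT = average genomic binding,
# negative = stronger than average; the anchor lands exactly on -5 kBT.
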