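"""Unit reductions: Miller units from raw ODs, and the protein burst size.

The Miller unit normalizes the ONPG color change by reaction time, cell
volume and culture density; the burst size divides the protein production
rate by the mRNA production rate at steady state.
"""

from promtune import BurstInputs, MillerAssayRecord, burst_size, miller_units
from promtune.inference import burst_size_from_miller

rec = MillerAssayRecord(od420=0.9, od550=0.2, od600=0.5, t_min=20.0, v_ml=0.5)
mu = miller_units(rec)
print(f"LacZ activity: {mu:.1f} Miller units")

bi = BurstInputs(
    protein_per_cell=1000.0,
    mrna_per_cell=10.0,
    gamma_p=1 / 30.0,  # dilution by growth, 30 min division time
    gamma_m=1 / 1.8,   # mRNA decay, 1.8 min lifetime
)
print(f"burst size: {burst_size(bi):.2f} proteins per mRNA")

b_tet, b_mono = burst_size_from_miller(
    miller_units=mu, mrna_per_cell=5.0, tetramers_per_miller_unit=10.0
)
print(f"from Miller units: {b_tet:.1f} LacZ tetramers = {b_mono:.1f} monomers per mRNA")

# The burst size is set by the ribosome binding site, not the promoter:
# promoters tune how often an mRNA appears, the burst sets the protein
# yield of each one.
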