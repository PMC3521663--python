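"""Physical constants and reference anchors used across the package.

Every number here is a configuration value, not a law: the calibration
anchors come from the primary literature on lac promoter energetics and may
be revised as better measurements appear.  Each constant carries its source
in the comment next to it.
"""

from __future__ import annotations

#: Wild-type *lac* promoter, positions -41..-1 relative to the transcription
#: start (+1).  Canonical lac control-region sequence: the -35 hexamer
#: (TTTACA) sits at -36..-31 and the -10 hexamer (TATGTT) at -12..-7.
WT_LAC_PROMOTER = "CAGGCTTTACACTTTATGCTTCCGGCTCGTATGTTGTGTGG"

#: lacUV5 variant: two point mutations turn the -10 box into the consensus
#: TATAAT, strengthening RNAP binding.
LACUV5_PROMOTER = "CAGGCTTTACACTTTATGCTTCCGGCTCGTATAATGTGTGG"

#: Specific binding energy of RNAP at the WT lac promoter relative to the
#: nonspecific genomic background, in units of kBT.
#: Source: Kuhlman, Zhang, Saier & Hwa, PNAS 2007 (in vivo titration).
WT_LAC_SPECIFIC_ENERGY_KBT = -5.0

#: Number of nonspecific RNAP binding sites: the E. coli chromosome length
#: in base pairs (every position is a potential nonspecific site).
N_NS = 4.6e6

#: LacI-O2 operator binding energy relative to nonspecific background, kBT.
#: Source: Garcia & Phillips, PNAS 2011 (simple-repression calibration).
DE_R_O2_KBT = -13.9

#: LacI is a tetramer with two DNA-binding heads; either head can occupy
#: the operator, doubling the effective repressor count.
LACI_HEADS_FACTOR = 2

#: lacZ mRNA mean lifetime, minutes.  Source: Kennell & Riezman, JMB 1977.
MRNA_LIFETIME_MIN = 1.5

#: Cell division time in M9 + 0.5% glucose, minutes; sets the effective
#: protein dilution rate for a stable protein such as LacZ.
DIVISION_TIME_MIN = 30.0

#: mRNA decay rate (1/min) and protein dilution rate (1/min) derived from
#: the two lifetimes above.
GAMMA_M_PER_MIN = 1.0 / MRNA_LIFETIME_MIN
GAMMA_P_PER_MIN = 1.0 / DIVISION_TIME_MIN

#: Miller-unit formula constants (Miller, *Experiments in Molecular
#: Genetics*, 1972): overall prefactor and the scattered-light correction
#: coefficient applied to OD550.
MILLER_PREFACTOR = 1000.0
MILLER_SCATTER_COEFF = 1.75

#: Conversion from Miller units to LacZ tetramers per cell.  Strain- and
#: instrument-dependent; the default is an order-of-magnitude value for a
#: single-copy chromosomal lacZ reporter and should be supplied explicitly
#: whenever absolute burst sizes matter.
TETRAMERS_PER_MILLER_UNIT = 10.0

#: LacZ is active as a tetramer; monomer counts are 4x tetramer counts.
MONOMERS_PER_TETRAMER = 4

#: Default mutable positions for promoter design: the -35 and -10 hexamer
#: boxes, where matrix weights are largest.
MINUS_35_BOX = tuple(range(-36, -30))
MINUS_10_BOX = tuple(range(-12, -6))
DEFAULT_MUTABLE_POSITIONS = MINUS_35_BOX + MINUS_10_BOX

#: Default energy spacing between rungs of a designed promoter ladder, kBT.
DEFAULT_LADDER_STEP_KBT = 1.0
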