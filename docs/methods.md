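# Methods

## Energy model and conventions

A promoter's RNAP binding energy is additive over positions: row *i* of the
41×4 matrix holds the contributions of A, C, G, T at promoter coordinate
−41+i (first row = −41, last = −1; 0 is the transcription start). The sign
convention is "more positive = less favorable binding". Because only energy
differences are physical, any constant added to every matrix entry is
meaningless; the package therefore fixes the gauge by *genome zeroing*: the
mean energy over all 41-bp windows of a reference chromosome, both strands,
is defined as 0.

Genome scanning treats the chromosome as circular by default (windows wrap
the origin, so each strand contributes exactly L windows); a `circular`
flag disables wrapping and a `strands` flag restricts to the forward
strand. Reverse-strand windows are scored as the reverse complement read
5′→3′, implemented by scoring the forward window with the reversed,
base-complemented matrix — algebraically identical and vectorizable.
Windows containing non-ACGT characters are skipped and counted rather than
imputed, since the matrix has no ambiguity rows. Both choices are exposed
because published genome-mean values depend on them.

## Calibration

Two anchors pin the affine AU → k<sub>B</sub>T map:

1. the genome-wide mean window energy (defines 0 on the calibrated scale);
2. the wild-type *lac* promoter's specific binding energy relative to
   nonspecific background, −5.0 k<sub>B</sub>T (in vivo titration,
   Kuhlman et al. 2007). This is a config value in
   `promtune.constants`, not a hard-coded number, because it is an external
   measurement that may be revised.

The conversion factor is (genome_mean_AU − score_AU(wt lac)) / |−5.0|;
calibration subtracts genome_mean_AU/41 from each entry and divides by the
conversion, so the calibrated matrix reproduces both anchors exactly. A
degenerate-calibration error is raised if the anchor site scores exactly
the genome mean. The WT lac 41-mer shipped as the default anchor is the
canonical lac control-region sequence (−35 TTTACA at −36..−31, −10 TATGTT
at −12..−7).

## Promoter design

Linearity makes each candidate mutation's energy change a single matrix
lookup, so designing to a target energy is a subset-sum-style search over
per-position substitution deltas. The search is exact:

* iterative deepening over the number of mutations — a design with fewer
  mutations always beats one with more, matching the preference order
  (within tolerance) > (fewest mutations) > (smallest residual) >
  (lexicographically smallest sequence);
* within each mutation count, depth-first enumeration with branch-and-bound
  pruning: a subtree is cut when even the extreme achievable delta sums of
  the remaining positions (tabulated min/max sums for exactly r further
  mutations) cannot beat the incumbent residual.

A single exact algorithm is used at every width rather than switching to a
meet-in-the-middle scheme for large position sets: at the realistic scale
of the problem (the 12 positions of the two hexamer boxes) the pruned
search runs in milliseconds, and one code path is easier to trust than two.
Candidate energies at leaves are recomputed with the full scoring sum so
the reported energy matches `score_sequence` bit-for-bit. Design is fully
deterministic; ties are broken lexicographically. Infeasible targets raise
an error carrying the closest achievable design (minimum residual over the
whole search space, ignoring the mutation-count preference), and ladders
report infeasible rungs in place rather than dropping them. Ladder rungs
exclude previously returned sequences, so a ladder is always a set of
distinct promoters.

Default mutable positions are the −35 box (−36..−31) and the −10 box
(−12..−7), where matrix weights are largest; the default mutation cap is 9
and the default ladder step 1 k<sub>B</sub>T (an e-fold in weak-limit
expression).

## Thermodynamic models

All energies are in k<sub>B</sub>T with β = 1 absorbed; there is no
temperature parameter. The constitutive occupancy is x/(1+x) with
x = (P/N_NS)·exp(−Δε_P); the weak-promoter limit returns x itself (relative
error exactly x/(1+x), so the caller can bound it). N_NS defaults to
4.6×10⁶, the *E. coli* chromosome length. Simple repression adds a
mutually exclusive repressor state of weight (h·R/N_NS)·exp(−Δε_R) with
h = 2 binding heads for LacI (configurable); the default operator energy is
−13.9 k<sub>B</sub>T (O2, Garcia & Phillips 2011). At R = 0 the repressed
forms reduce bit-for-bit to the constitutive ones. `energy_to_kd` re-expresses
the same occupancy in dissociation-constant language given a
concentration-per-copy conversion.

## Fitting

All fits are in natural-log expression space, where multiplicative
measurement scatter is additive and the RMSD has a direct fold-error
interpretation (RMSD 1.0 ≈ factor e). By default every individual
measurement enters the fit; per-promoter averaging of replicates is an
option (both behaviours are tested; they coincide for balanced designs of
log-symmetric noise only in expectation).

* **Intercept fit** (slope fixed at −1): log k is the mean of
  (ln value + energy) — the closed-form least-squares intercept. log k here
  is the *lumped* constant ln(k·P/N_NS), i.e. the expected ln expression at
  zero (genome-average) binding energy.
* **Full occupancy fit**: writing ln v = L − ε − ln(1+x) with
  x = p·e^(−ε) and L the lumped intercept, L is profiled out in closed form
  and the fit reduces to a bounded 1-D minimization over ln p
  (p ∈ [10⁻⁸, 1]). This profile formulation is deliberate: deep in the weak
  limit the (ln k, ln p) likelihood valley is flat and a joint 2-D search
  stalls short of the conditional optimum. When the largest occupancy
  weight x in the data is below 0.01 the fitted p is flagged as not
  identified (the data never bend away from the Boltzmann line).

`measured_energy` inverts the fitted line (ε = log k − ln value) to assign
each promoter an empirical binding energy. Feeding these corrected energies
into the repression model removes the constant log-offset that
mis-predicted model energies inherit across an entire repressor titration —
the correction workflow is exact in the weak limit because the prefactor
k·(P/N_NS)·e^(−ε) is shared by all R.

Unit reductions: Miller units are computed as
1000·d·(OD420 − 1.75·OD550)/(t·v·OD600) with the scattered-light
coefficient 1.75 and prefactor 1000 from the classical assay and d a
dilution factor for nonstandard stop-solution volumes (default 1.0). The
burst size is (protein·γ_p)/(mRNA·γ_m), with defaults γ_m = 1/1.5 min⁻¹
(lacZ mRNA lifetime, Kennell & Riezman) and γ_p = 1/30 min⁻¹ (division
time in M9+glucose). The tetramers-per-Miller-unit conversion (default 10)
is strain- and instrument-dependent and should be supplied explicitly
whenever absolute burst sizes matter.

## Synthetic data

The generators emulate the structure of the real experiment at its stated
scale: 18 promoters evenly spanning 7 k<sub>B</sub>T (−4.5 to +2.5 on the
genome-zeroed scale), expression exp(log k − ε) — or the full occupancy
form when a true P/N_NS is configured — with multiplicative lognormal
scatter of σ = 1 in ln units (the fold-~e deviation scale seen in real
ladder data); repressor titrations over R ∈ {0, 11, 30, 62, 130, 610, 900}
per cell with the O2 operator energy. Random genomes are uniform ACGT; toy
matrices concentrate their weight in the hexamer boxes (per-position deltas
up to ~3 k<sub>B</sub>T there, ~10× smaller elsewhere). Every generator is
a pure function of (seed, config) and byte-reproducible.

What the synthetic data does **not** emulate: sequence-dependent
correlations between positions (real promoter scatter partly reflects
spacer/twist effects a linear matrix cannot capture), day-to-day assay
drift, repressor copy-number measurement error, or any saturation of the
reporter. Passing tests therefore demonstrate the correctness and
calibration behaviour of the machinery under the model's own assumptions,
not the predictive accuracy of the linear energy model on real promoters.
The repression generator's mis-specification knob exists precisely to
emulate the dominant real-data failure mode (per-promoter energy
mis-prediction) and to verify that the correction workflow removes it.

## Problem sizes and numerics

Synthetic genome scans use 50 kb chromosomes (10⁵ windows both strands),
Monte Carlo fit calibrations use 200 seeds × 18 promoters, and design
oracle comparisons enumerate ≤ C(8,3)·3³ candidates per trial — sizes
chosen so the whole suite and the acceptance script each complete in
seconds while keeping Monte Carlo standard errors an order of magnitude
below the tolerances they are compared against. Calibration closure is
asserted to 10⁻⁹ relative; design pruning carries a 10⁻⁹ slack so floating
accumulation can never discard a true optimum; tie-breaks are exact string
comparisons. Degenerate inputs (all-identical windows, zero expression,
zero OD600, genomes shorter than the matrix) raise typed errors rather
than producing NaNs.

## Known limitations

* The energy model is strictly additive: no dinucleotide or epistatic
  terms, no spacer-length or twist-registry effects, and no activator
  (CRP) contribution.
* The occupancy models are equilibrium, mean-field descriptions: no
  transcriptional noise, bursting kinetics, looping or multi-operator
  architectures.
* The genome-mean anchor of the published matrix can only be reproduced
  with the real MG1655 sequence and the published AU matrix, which must be
  supplied by the user (see `data/` note in the README); all shipped
  calibrations of record run on synthetic genomes.
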