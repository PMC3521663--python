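# promtune

Model-based tuning of promoter strength in *E. coli*: score RNA polymerase
(σ70) binding sites with a linear energy matrix, calibrate the matrix to
physical k<sub>B</sub>T units against the genome-wide mean, design promoter
sequences that hit targeted binding energies, and predict absolute gene
expression under constitutive and simple-repression thermodynamic models.

It is written for synthetic biologists and quantitative biologists who want
to pick a promoter sequence *by computation* — choosing an expression level
first and deriving the sequence from it — rather than by screening random
mutant libraries.

## The model

**Additive binding energy.** The binding energy of RNAP to a 41-bp site
(positions −41..−1 relative to the transcription start) is a sum of
per-position, per-base contributions ε<sub>ij</sub>:

    E(seq) = Σ_j ε(base_j, j)

More positive = less favorable binding. The published matrix is in
arbitrary units (AU); two anchors pin the affine conversion to
k<sub>B</sub>T: the genome-wide mean window energy defines zero, and the
wild-type *lac* promoter must score its known specific binding energy
(−5 k<sub>B</sub>T relative to nonspecific background, from in vivo
titration data).

**Occupancy → expression.** With P polymerases competing for N_NS
nonspecific genomic sites, the equilibrium probability that RNAP occupies a
promoter with genome-zeroed energy Δε_P is

    p_bound = x / (1 + x),    x = (P/N_NS) · exp(−Δε_P)

and expression = k · p_bound. In the weak-promoter limit (x ≪ 1) a semi-log
plot of expression against Δε_P is a straight line of slope −1 (Boltzmann
scaling), so a 1 k<sub>B</sub>T ladder of designed binding energies is an
e-fold ladder of expression.

**Simple repression.** A repressor with copy number R and operator energy
Δε_R (e.g. LacI on O2, −13.9 k<sub>B</sub>T) multiplies weak-limit
expression by the fold-change

    FC = 1 / (1 + (2R/N_NS) · exp(−Δε_R))

(the 2 counts LacI's two binding heads). Because FC is
promoter-independent, any error in a promoter's predicted Δε_P is inherited
as a constant log-offset across a whole repressor titration — and is
removed by re-estimating the energy from the R = 0 measurement.

## Worked example

```bash
python examples/design_promoter_ladder.py
```

```
start sequence energy: 1.273 kBT
  target  achieved  muts  residual  sequence
   -2.23    -2.305     2    0.0779  TGGCCAAAATGTGGTGGGGTCTGACTGATGAAAGAGACCCC
   -1.23    -1.222     2    0.0045  TGGCCAAAATTTGGTGGGGTCTGACTGATGAAATAGACCCC
   ...
    4.77     4.815     2    0.0415  TGGCCAAACTGTGGTGGGGTCTGACTGATGTATTAGACCCC
```

Eight distinct promoters, 1 k<sub>B</sub>T apart over a 7 k<sub>B</sub>T
span, each within 0.1 k<sub>B</sub>T of its target using at most two
mutations confined to the −35/−10 boxes — i.e. a designed e-fold expression
ladder. The other examples cover calibration
(`calibrate_matrix.py`: conversion factor, genome mean exactly zero after
calibration, anchor at −5 k<sub>B</sub>T), expression prediction with a
repressor titration (`predict_expression.py`), fitting noisy ladders and
back-calculating measured energies (`fit_promoter_ladder.py`), and
Miller-unit / burst-size arithmetic (`burst_size_and_miller.py`).

A `promtune` console script exposes the same operations
(`score`, `scan`, `calibrate`, `design`, `predict`, `fit`, `simulate`);
run `promtune --help`.

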