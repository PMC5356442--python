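# Methods

`clonotype` quantifies how phenotypic plasticity — the ratio of epithelial
(E, keratin 8/18 high) to mesenchymal (M, keratin 8/18 low) progeny —
varies across DNA-barcoded clones in a cancer cell population, and uses
the resulting clone-level parameters to simulate phenotype-selective
combination therapies.  This note records the models, the numerical
choices, and what the synthetic data does and does not emulate.

## Barcode processing

**Quality filtering.**  Two named policies ship with `barcode_io`.  For
libraries amplified from sorted cells, a read is accepted iff it has fewer
than 6 bases with Phred quality < 25 and no base < 15.  For the barcode
plasmid pool (fewer PCR cycles, higher complexity) the thresholds are
14 and 10, and every index/flank base must additionally exceed Q25.
Demultiplexing is by exact index match: indexes are designed at pairwise
Hamming distance >= 2 and no one-mismatch rescue is attempted — a
conservative assignment that wastes a small amount of depth rather than
risking cross-library bleed.

**Error collapse.**  Random 14-mers are on average 10.5 mismatches apart,
while PCR/sequencing errors put mutant reads an average of 1.7 bases from
their parent, so read clouds can be re-attached by radius: barcodes seen
fewer than twice (per library) are dropped, then for radii d = 1..4 the
surviving barcodes are traversed in descending abundance, absorbing any
less-abundant barcode within Hamming distance d.  Ties in abundance break
lexicographically; a barcode merged in a round cannot absorb others in
that round.  One consequence worth stating plainly: among 1372 uniformly
random 14-mers roughly a third have *another true barcode* within
distance 4, and the procedure merges such pairs (smaller into larger) by
construction.  Parameter-recovery tests therefore report the mean
absolute error on the collision-free subset; the correlation criterion is
met on all detected clones.

**Persistence filter.**  A barcode is kept only if it is detected in at
least one library of every time point.

## Clone quantification

Per library, a clone's normalized abundance is
(reads / library total) x state fraction at the sort (0.6 for the E gate,
0.4 for the M gate), so the E and M columns of a time point sum to one;
absent barcodes receive a pseudo-value of 1e-6.  Sort contamination is
subtracted per library: the clone's average raw read fraction in the
*other* state's libraries at that time point, multiplied by that gate's
measured mis-sort fraction sigma; results <= 0 are floored at 1e-6, and
sorted replicates are then averaged.  The per-time-point replicate scope
of the "average fraction" is a reading choice (the source prose is
ambiguous); it is the only scope under which the correction uses data
from the same sort.

Phenotypes follow directly: fraction epithelial E/(E+M), log2(E/M), and a
time-averaged log ratio (arithmetic mean of per-time-point log ratios).
Growth rates assume the population holds 2.9e7 cells at day 0 and doubles
three times per week; a clone's cell number is its normalized fraction of
that population, and k_c (doublings/week) is the mean of
log2(N_t/N_0)/weeks over the two later time points.  The growth formula
is reconstructed from prose (the displayed equation is not available in
the source text).  The Shannon entropy of plasticity bins clone
log-ratios into width-1 bins anchored at the observed minimum; the anchor
makes H sensitive to extreme pseudo-floored values, which is inherent to
the printed procedure.

## Statistical tests

**Contamination probabilities.**  With sigma_e the mis-sort fraction of
the E gate, the E-sorted read total splits into E = (1-sigma_e) x total
(true epithelial) and, from the M gate, E' = sigma_m x M-total.  The
probability that an epithelial clone's read lands in the M-sorted library
is pC_e = E'/(E+E'); symmetrically for pC_m.

**Bi-lineage test.**  For each clone and time point the null "all cells
epithelial" is scored by the inclusive upper binomial tail
P(X >= r_m) with n = r_e + r_m and p = pC_e (the inclusive tail is the
reading consistent with the worked reference values; n is the clone's
total reads, the only self-consistent choice).  All states and time
points form a single Benjamini–Hochberg family at FDR 0.05.  A clone is
mono-lineage if the opposite null is rejected at every time point and its
own at none; bi-lineage if both nulls are rejected at the same time point
at least once (read as a single time point with both rejections).  Note a
statistical subtlety the tests document: BH bounds the false-discovery
proportion of the pooled family, not the per-clone false-bilineage rate;
with many true rejections in the family the clone-level false-call rate
sits slightly above alpha (~6% in null simulations).

**Bias test.**  Chi-squared goodness of fit with one degree of freedom of
the clone's (r_e, r_m) against the population read split, BH-corrected
over all clones and time points; "biased" requires rejection at every
time point.

**Permutation tests.**  Pearson correlations (week-to-week stability,
subclone-vs-pool heritability) are tested by shuffling the barcode
pairing; the empirical p is (exceed+1)/(reps+1), avoiding p = 0, with the
raw exceed count also reported.

## CNV inference from scRNA-seq

Mean-normalized log2(TPM+1) values are clipped to [-3, 3]; a mean over a
sliding window of 101 chromosomally ordered genes (windows confined
within chromosomes — copy-number events are chromosome-bounded) gives
each cell a positional profile, centred to zero per cell.  Profiles are
referenced to the average profile of declared normal cells; deviations
with |d| <= 0.3 (a ~23% expression change) are zeroed.  Cells are grouped
into clones by Ward clustering on Euclidean distances, cut at k clusters
(default 4) or at a height.  Per-cell program scores are the mean
expression of a classifier gene set minus the cell's global mean; a score
is called enriched (depleted) if it exceeds the 95th (falls below the
5th) percentile of 100 size-matched random gene sets — the depleted tail
is read symmetrically, since a literal "less than 95% of random scores"
would label most cells.  Clone-level differences are tested with
Kruskal–Wallis.  Two numerical notes: the clipping threshold "greater
than 3" resolves an obvious typo in the source prose, and per-cell
centring attenuates a whole-chromosome shift by a factor
(1 - chromosome windows / total windows), which the tests account for.

## Treatment simulator

A tumour is 500 clones resampled with replacement from an observed clone
table (fraction epithelial, doubling time, day-0 cells).  Fifteen time
points model a day; per point, in order: exponential growth
(x 2^(1/D_i)), state switching, and (in treatment blocks) the kill.
Switching uses per-division probabilities P(e->m) = psi(1-f_i) and
P(m->e) = psi f_i with psi = 0.2 — 20% of cells switch per division, the
ratio of the two probabilities equals the clone's equilibrium E:M ratio
R_i, and the probabilities are spread uniformly over the D_i points of
one division.  This parameterization is bounded, conserves cells, and has
f_i as its fixed point; the update equations are reconstructions from the
prose contracts (the displayed equations are unavailable), and
state-pure clones never transition.  A course of therapy is 30 treated
points (2 days) at kill fraction `kill_frac` on the targeted state and
`kill_frac/10` on the other, followed by 20 rest points.  Counts are
real-valued and dynamics deterministic; the only randomness is tumour
seeding, giving the across-simulation spread reported over 500
replicates.  The per-point kill fraction is not printed in the source;
the default 0.142 kills ~99% of the targeted state per course, and every
schedule comparison in the acceptance tests is evaluated across the
documented grid {0.08, 0.10, 0.12, 0.142, 0.16, 0.20}.  Both reference
effect sizes (alternating ~48x better than sequential; combination
>= 11x better than the best monotherapy) are reproduced simultaneously
near kill_frac = 0.10, and the qualitative orderings hold at every grid
point.  Clone extinction is not thresholded by default (fractional cells
persist); an optional threshold would only strengthen the alternating
schedules' advantage.

## Synthetic data: what it emulates, and how it was calibrated

The `mda157` preset fixes the generator to the headline marginals of the
modelled experiment: 1372 clones; clone log2(E/M) Normal with sd 1.8 and
mean -0.645; a per-time-point fluctuation of each clone's log ratio drawn
from a two-component scale mixture (sd 0.3 with probability 0.8, else the
variance-completing sd ~2.0, total rms 0.949); 3% pure-epithelial and 7%
pure-mesenchymal clones flagged explicitly (file formats stay finite);
log-normal clone sizes (log-sd 0.8) tilted by exp(0.529 x centred log
ratio) toward epithelial-biased clones; growth rates Normal(3, 0.45)
doublings/week truncated positive; sort mis-sort fractions of 1.5–3.5%
per gate per time point; 80k reads per library.

These constants were calibrated jointly against the package's own
quantification pipeline on deep count tables and then frozen: the sd sets
the binned-ratio entropy (~3.5 bits), the mean/sd ratio the fraction of
mesenchymal-biased clones (64%), the total fluctuation variance the
cross-week Pearson correlation (~0.89), the mixture weight the share of
clones moving < 0.15 in fraction epithelial over two weeks (~81%), and
the size tilt the population-level fraction of epithelial cells (~60%).
Calibrating against the measured statistic (rather than closed forms)
matters because pseudo-floored single-lineage clones contribute extreme
log ratios to the entropy and correlation, and because fluctuation
broadening shifts the size-weighted population fraction; both effects are
properties of the printed procedure, not of the generator.

Sequencing errors substitute bases uniformly at 0.0905 per barcode base —
the rate at which mutated reads average 1.7 bases from their parent —
with a lower rate (0.005) on index and flank bases so that demultiplexing
is not starved; the split is a modelling convenience (per-region rates
are not published).  Erroneous bases draw lower quality scores
(Q10–Q30 vs Q30–Q40), so the quality filters do real work on synthetic
reads.  The clone-size law at barcoding is not published; the log-normal
choice and its parameters are a flagged convenience.

What the generator does *not* emulate: PCR amplification bias and
chimeras, sequencer-specific error profiles (errors are uniform
substitutions), index hopping, cell-cycle or density effects on sorting,
and any genetic change during culture.  Passing recovery tests on this
preset therefore shows the pipeline inverts its own generative model at
realistic noise levels — not that it is robust to every artifact of real
amplicon data.

Problem sizes in the test suite are chosen for a desk-scale run: the
FASTQ-level end-to-end test uses the preset's ~1e6 total reads (the
modelled experiment had ~1e8), and the deep count-level tables use 1e6
reads per library, which put measurement noise near the scale of the
original data for per-clone statistics.

## Known limitations

- The collapse procedure merges true barcodes that fall within radius 4
  of a more abundant barcode; at 1372 random 14-mers this affects roughly
  a third of clones (see above).  Larger barcode spaces or
  separation-screened libraries avoid this.
- The coverage-based complexity estimate is a lower bound under uneven
  abundances; for the uniform pools of the recovery simulation it is
  close to consistent even at 1% sampling.
- Heritability and stability are Pearson correlations on log ratios and
  inherit their sensitivity to the pseudo-floored extremes.
- The treatment simulator has no spatial structure, pharmacokinetics, or
  acquired resistance, and treats kill fractions as constant within a
  course.
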