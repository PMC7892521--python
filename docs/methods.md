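# Methods

`selexkit` analyses SELEX-seq experiments for MADS-domain transcription
factors — iterative in-vitro selection of protein-bound DNA from a
randomised 25-bp library, sequenced at every round — and ships a simulator
that generates such experiments from a planted binding model, so that every
analysis stage can be validated against known ground truth.

## Probe model and coordinates

A probe is `adapter5 + N25 + barcode4 + adapter3`, 99 nt in total.  All
coordinates are 0-based half-open.  Barcode matching is exact: a 4-nt
barcode has no redundancy for error correction, and mismatch-tolerant
assignment would cross-contaminate libraries.  The shipped adapter
sequences are synthetic placeholders of the correct lengths (33 and 37 nt);
what matters downstream is only that the 5' adapter ends in `CT`, which is
faithful to the sequencing chemistry and is the source of the position-bias
artifact discussed below.  Real adapter sequences can be injected through
the `ProbeDesign` config.

## The planted binding model

A dimer site is a 10-nt window scored on both strands of the probe,
including the adapter tail/head context:

    weight(probe) = eps + sum_windows sum_strands exp(beta * score(window))
    score = -E(window) + flank_bonus + atract_bonus * [A-tract in centre 6 bp]

* `E` is a 10x4 positional energy matrix (lower = tighter).
* `flank_bonus` rewards bases just outside the window (defaults encode the
  weak TTN- / -NAA preference).
* `atract_bonus` is a strand-symmetric non-additive term for windows whose
  central 6 bp contain an A-tract (A^nT^m, n+m >= 4, no TpA step).  A
  purely positional matrix cannot express "no intervening TpA step", yet
  A-tract preference via minor-groove shape readout is exactly the
  behaviour of interest; this term emulates it directly.
* `beta` scales the whole score, so `beta = 0` is exactly selection-free —
  a convenient null in which every probe has weight `eps + #windows`.
* The Boltzmann *sum* over windows (not max) keeps the target of the
  `(obs/exp)^(1/r)` estimator analytically predictable.

The wildtype preset plants consensus `CCAAAAATGG` with a W-tolerant centre
(per-mismatch cost 0.24), hard outer borders, recognition bonus 0.19 per
matched position, A-tract bonus 0.55, flank bonuses 0.15 and a mild
tolerance (penalty 0.25) for `T` at position 2 and `A` at position 9, which
lets the adapter's terminal `CT` substitute for the `CC` border and makes
CT-bordered boxes nearly perfect sites.  The
mutant preset shortens the A/T core and tolerates C/G at the centre borders
(`CCSAAAASGG`) with no A-tract readout.  The preset magnitudes were chosen
once so that all recovery analyses succeed with robust margins at the
default simulation scale; they are conditions of the synthetic study, not
fitted to any measured dataset.

### Sampling regime

Real synthesis libraries contain ~1e13 molecules; a sequencing run samples
a few 1e7 of them.  Per-molecule sequencing multiplicity is therefore
negligible even after two selection rounds.  A naive simulation that
resamples the *sequenced* R0 pool (1e5 reads) collapses library complexity
onto sequencing depth: after two rounds single strong-binding molecules
appear hundreds of times, and their private flanking sequence becomes
statistically "real" signal at large k.  `simulate_experiment` therefore
samples each round independently from the selection-tilted generative
distribution `q0(s) * weight(s)^r`, implemented as importance resampling
from an oversampled pool of fresh candidates (50x for round 1, growing
4x per round, capped at `library_oversample = 200x`).  The finite-pool
alternative (`run_rounds`, weighted resampling with replacement of an
explicit pool) remains available and is the right tool for studying
carry-over, bottleneck and duplication effects.  PCR bias is a smooth
per-round factor `exp(gamma*(GC-0.5))`; positive-control contamination is
spiked in after selection at a configurable fraction, mimicking carry-over.

## Background model

R0 biases are captured by an order-m Markov model with additive pseudocount
(default 0.5, which keeps order >= 4 fits proper on small pools).  Each
read window is assumed to start from the m-mer marginal estimated from all
read positions; at L = 25 the inhomogeneous end effects are negligible.
The order is selected by cross-replicate prediction of 8-mer counts,
scored by R^2 over all 4^8 8-mers, averaged over both train/test
directions; the smallest order within 0.001 of the best R^2 wins, because
neighbouring orders are frequently near-tied and parsimony resolves the
tie deterministically.

## Motif length by information gain

For each k the divergence between the selected-round k-mer distribution and
the background is estimated as

    IG(k) = sum over canonical k-mers with count >= 5 of f * log2(f / p0)

with `f = count / windows` and `p0` the background probability merged onto
canonical (strand-collapsed) keys.  Two deliberate choices:

* **Canonical keys.**  Binding has no strand, so a k-mer and its reverse
  complement are one binding event; merged background probabilities sum to
  one over canonical keys without renormalisation.
* **Reliability floor.**  The unrestricted plug-in estimator grows without
  bound in k at finite depth (singleton cells contribute
  `f*log2(f/p0) ~ 2k` bits each).  Restricting to cells observed at least
  5 times — the same floor the affinity table uses for its low-confidence
  flag — keeps only reproducibly observed k-mers.  Unobserved cells
  contribute zero by continuity, so no global additive smoothing over the
  4^k table (infeasible at k = 14 and mass-distorting at desk scale) is
  needed.

True KL divergence is non-decreasing under refinement, so "the optimal k"
is read as the onset of saturation: the smallest k whose IG reaches 99% of
the profile maximum.  At the default simulation scale the profile rises
steeply to k = 10 (the planted site length) and falls beyond it as
signal cells drop below the floor; the floor also sharpens the peak, so at
much shallower or deeper simulated depths the profile shape — like any
finite-depth estimate — reflects counting resolution as well as site
length.

## Relative affinities

`raw(w) = (observed / expected)^(1/r)`, normalised so the best k-mer is
exactly 1.  k-mers observed fewer than 5 times are kept but flagged
low-confidence rather than removed, preserving auditability.  Two rounds
are integrated by LOESS (tricube weights, local degree 1, span 0.5,
nearest-neighbour windows) of `log aff_R2` on `log aff_R1` — the log scale
because enrichment is multiplicative across rounds.  The smoother is exact
per point up to 2000 shared k-mers and grid-interpolated (201 knots) above,
which is numerically indistinguishable at the default span.

## Motif discovery

Training sequences are the k-mers with affinity > 0.4, padded with k/2 N's
per side and weighted by 1e3 x affinity.  A one-occurrence-per-sequence EM
fits a single PWM of length 10 over all windows x both strands with a
uniform position/strand prior.  N positions emit factor 1 under both motif
and background, keeping likelihoods comparable across sequences regardless
of padding overlap.  The M-step is maximum likelihood (numerical floor
1e-9); the weighted log-likelihood is asserted non-decreasing in every run.
Default 200 random restarts (seeded); ties between runs are broken by the
lexicographically smaller consensus.  The final reported PWM adds
pseudocount 0.5 per cell.  Orientation is canonicalised so the consensus
reads CC-before-GG where that rule discriminates, falling back to the
lexicographically smaller consensus, then to the best run's orientation.

## Guided flank analysis

All 18-nt read windows whose centre matches `CC(A/T)6GG` on either strand
are extracted.  Because that pattern is closed under reverse complement,
every extracted window is two-fold orientation-ambiguous; a two-component
orientation-mixture EM over all 18 columns resolves it, assigning each
window the orientation with posterior > 0.5.  A final deterministic global
flip (lexicographically smaller consensus) fixes the remaining mirror
ambiguity.  Flank preferences are read from columns 1-4 and 15-18 of the
resulting PWM.  The planted flank preference is deliberately weak, so it
shows as elevated T/A probabilities rather than as consensus letters.

## Position-bias diagnostics

Exact forward-strand match offsets are tabulated for a k-mer list (usually
the top 100 by affinity), and each k-mer is classified as a complete
SRF-type CArG-box, an incomplete box (`W2 N6 W2` on either strand but not
complete), or other.  Under the wildtype preset the incomplete class piles
up at probe offsets 1-2: the adapter's terminal `CT` serves as the 5'
border of a nearly complete box, so selection favours reads whose first
bases continue the site.

## Dependence models and intra-motif complexity

Positions may depend on strictly preceding positions (acyclic left-to-right
factorisation, so the joint is always proper).  Proximal models fix the
parents to the d adjacent predecessors; distal models search all parent
subsets of size <= d per position, scored by weighted log-likelihood minus
a BIC penalty `(free params / 2) * ln(N_eff)` with Kish's effective sample
size `(sum w)^2 / sum w^2` for weighted data.  Conditionals are
pseudocount-smoothed (0.5) weighted estimates.  Optional context-tree
merging picks, per conditioning level, the best of the 15 set-partitions of
{A,C,G,T} under the same score.  Sequences containing N are dropped with a
warning (excluding columns would change the motif length).

Intra-motif complexity (IMC) is the weighted mean per-sequence log2
likelihood gain of a dependence model over the mononucleotide (PWM) model
fitted on the same data — exactly 0 for the PWM itself, and non-negative
and monotone in model flexibility for unpenalised ML fits (the nestedness
property suite runs with pseudocount 0 and no penalty for that reason; BIC
fits may order differently by design).

## Motif comparison

Per-column Jensen-Shannon divergence in bits (`H((p+q)/2) - (H(p)+H(q))/2`,
bounded by [0,1]), aggregated by sum over positions (mean available).
Because discovery strand is arbitrary, the second motif is also evaluated
reverse-complemented and the smaller aggregate is reported with its
orientation.  Difference logos give each letter the signed share of the
positional JSD proportional to its probability difference; signed heights
sum to zero per position.

## Pipeline and reproducibility

`run_full_analysis` chains simulate/load -> contamination QC -> background
order selection -> motif-length selection -> affinities (R1, R2, LOESS) ->
discovery -> flank analysis -> position bias -> dependence/IMC -> pairwise
JSD, writing TSV/MEME/JSON artifacts whose leading comment carries the seed
and a config hash; a rerun with the same config is byte-identical.
Contamination above threshold warns but does not abort — exclusion of a
library is a judgement call.  The default analysis round is R2.

## Scales, defaults, and what the tests do and do not show

Default simulated depth is 1e5 reads/round (pipeline smoke runs use less),
two selection rounds, uniform R0 composition, candidate oversampling 200x.
Analyses of these synthetic libraries recover the planted truth: motif
length 10, the planted consensus to within IUPAC ambiguity, A-tract
dominance of the top CArG-boxes, weak flank preferences, small IMC values,
and replicate-vs-mutant divergence ordering.  The generator does not
emulate sequencing error, quality-score structure, gel-extraction
efficiency, sequence-specific PCR amplification tables, or dimer
cooperativity; conclusions about those effects cannot be drawn from these
tests.  Likewise the simulator's graded, soft-bordered energy model is far
simpler than protein biophysics — passing tests certify the *analysis
machinery*, not the realism of any particular binding constant.

## Numerical notes

* Window scores accumulate in float32 (weights are exp'd in float64);
  strand symmetry holds to ~1e-7 relative.
* Occupancy weights of windows overlapping N are zero (scored -inf).
* Ranking ties anywhere (top-k tables, CArG ranking, EM run selection) are
  broken lexicographically for determinism.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; simulation candidate streams are regenerated
  two-pass to bound memory.
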